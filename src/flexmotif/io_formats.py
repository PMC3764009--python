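"""Readers and writers for the formats the framework touches.

Coordinates are 0-based half-open (BED convention) everywhere.  Model
serialization is JSON with explicit state labels ("bg", "m1", "m1.A", ...),
so order-1 and detailed files are self-describing and round-trip losslessly
(float64 survives JSON exactly).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .hmm import ConditionalEmissionHMM
from .models import TFFM, FlexEdit, ModelError, PositionFrequencyMatrix


class FormatError(ValueError):
    """Malformed input file."""


class DatasetTooSmallError(ValueError):
    pass


@dataclass
class NucleotideSequence:
    """A named DNA sequence over {A, C, G, T, N}, uppercase-normalized."""

    identifier: str
    residues: str
    has_n: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.identifier!r} is empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise FormatError(f"sequence {self.identifier!r} contains "
                              f"invalid residues {sorted(bad)}")
        self.has_n = "N" in self.residues

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.identifier + "_rc",
                                  revcomp(self.residues))


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    return residues.translate(_COMP)[::-1]


@dataclass
class PeakRecord:
    """A ChIP-seq peak: genomic interval with enrichment signal and summit.

    summit_offset is relative to start; -1 marks an absent summit."""

    chrom: str
    start: int
    end: int
    signal_value: float
    summit_offset: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak {self.chrom}:{self.start}-{self.end}: "
                              "start must be < end")
        if self.signal_value < 0:
            raise FormatError("signal value must be non-negative")
        if self.summit_offset >= 0 and self.start + self.summit_offset >= self.end:
            raise FormatError("summit offset falls outside the peak")


@dataclass
class PeakWindow:
    """A summit-centred scan window: [summit-flank, summit+flank+1)."""

    chrom: str
    start: int
    end: int
    signal_value: float
    clipped: bool = False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """All records of a FASTA file, in file order, uppercased."""
    path = Path(path)
    records = []
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        if not first.startswith(">"):
            raise FormatError(f"{path}, line 1: expected a FASTA header")
        handle.seek(0)
        for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            try:
                records.append(NucleotideSequence(rec.id, str(rec.seq)))
            except FormatError as exc:
                raise FormatError(f"{path}, record {i}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: list[NucleotideSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as out:
        for s in seqs:
            out.write(f">{s.identifier}\n")
            for i in range(0, len(s.residues), width):
                out.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# ENCODE narrowPeak (BED6+4)
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Parse a 10-column narrowPeak file (signal in column 7, summit offset
    in column 10)."""
    records = []
    with open(path) as handle:
        for ln, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(f"{path}, line {ln}: expected 10 "
                                  f"tab-separated columns, got {len(fields)}")
            try:
                records.append(PeakRecord(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    signal_value=float(fields[6]),
                    summit_offset=int(fields[9])))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}, line {ln}: {exc}") from exc
    return records


def read_narrowpeak_windows(path: str | Path, flank: int = 50,
                            min_peaks: int = 0,
                            chrom_sizes: dict[str, int] | None = None,
                            ) -> list[PeakWindow]:
    """Summit-centred windows of width 2*flank+1 with their signal values.

    Peaks without a summit (offset -1) are skipped (counted in a warning).
    Windows crossing a contig boundary are clipped and flagged.  If fewer
    than ``min_peaks`` usable windows remain, an error is raised."""
    windows = []
    skipped = 0
    for rec in read_narrowpeak(path):
        if rec.summit_offset < 0:
            skipped += 1
            continue
        summit = rec.start + rec.summit_offset
        start, end = summit - flank, summit + flank + 1
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if chrom_sizes is not None and rec.chrom in chrom_sizes:
            size = chrom_sizes[rec.chrom]
            if end > size:
                end, clipped = size, True
        windows.append(PeakWindow(rec.chrom, start, end, rec.signal_value,
                                  clipped))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} peak(s) without a summit")
    if min_peaks > 0 and len(windows) < min_peaks:
        raise DatasetTooSmallError(
            f"{path}: {len(windows)} usable peaks < required {min_peaks}")
    return windows


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_minimal(path: str | Path) -> list[PositionFrequencyMatrix]:
    """All letter-probability matrices of a MEME minimal-format motif file,
    rows renormalized to sum to 1."""
    pfms = []
    name = None
    rows: list[list[float]] | None = None
    expect = 0
    with open(path) as handle:
        for ln, line in enumerate(handle, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "MOTIF":
                if rows:                      # finish a block without w=
                    pfms.append(_finish_pfm(rows, name, path))
                elif name is not None and rows is None:
                    raise FormatError(f"{path}: motif {name!r} has no "
                                      "letter-probability matrix")
                name = tokens[1] if len(tokens) > 1 else f"motif{len(pfms)+1}"
                rows = None
            elif line.startswith("letter-probability matrix"):
                parts = line.split(":", 1)[1].split() if ":" in line else tokens[2:]
                meta = {parts[i].rstrip("="): parts[i + 1]
                        for i in range(0, len(parts) - 1, 2)
                        if parts[i].endswith("=")}
                expect = int(meta.get("w", 0))
                rows = []
            elif rows is not None and (expect == 0 or len(rows) < expect):
                try:
                    vals = [float(t) for t in tokens]
                except ValueError:
                    continue
                if len(vals) != 4:
                    raise FormatError(f"{path}, line {ln}: expected 4 "
                                      "probabilities per matrix row")
                rows.append(vals)
                if expect and len(rows) == expect:
                    pfms.append(_finish_pfm(rows, name or f"motif{len(pfms)+1}",
                                            path))
                    name, rows = None, None
    if rows:                                  # file without w= hint
        pfms.append(_finish_pfm(rows, name or f"motif{len(pfms)+1}", path))
        rows = None
    if name is not None and rows is None and not pfms:
        raise FormatError(f"{path}: motif {name!r} has no "
                          "letter-probability matrix")
    if not pfms:
        raise FormatError(f"{path}: no motifs found")
    return pfms


def _finish_pfm(rows, name, path):
    arr = np.asarray(rows, dtype=float)
    sums = arr.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise FormatError(f"{path}: motif {name!r} has a zero row")
    return PositionFrequencyMatrix(arr / sums, name=name)


# ---------------------------------------------------------------------------
# JASPAR-style PFM text
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str | Path) -> PositionFrequencyMatrix:
    """A single JASPAR-style matrix: four lines A/C/G/T of counts, optionally
    bracketed (``A [ 3 10 ... ]``), with an optional ``>`` header."""
    name = "pfm"
    rows = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] or name
                continue
            tokens = line.replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0] in "ACGT" and len(tokens[0]) == 1:
                rows[tokens[0]] = [float(t) for t in tokens[1:]]
            elif len(rows) < 4 and tokens:
                rows["ACGT"[len(rows)]] = [float(t) for t in tokens]
    if set(rows) != set("ACGT"):
        raise FormatError(f"{path}: need A, C, G and T rows")
    counts = np.array([rows[c] for c in "ACGT"], dtype=float).T
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise FormatError(f"{path}: zero column in matrix")
    return PositionFrequencyMatrix(counts / sums, name=name)


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path: str | Path,
                     total: int = 100) -> None:
    with open(path, "w") as out:
        out.write(f">{pfm.name}\n")
        counts = pfm.probs * total
        for i, c in enumerate("ACGT"):
            vals = " ".join(f"{v:8.2f}" for v in counts[:, i])
            out.write(f"{c} [{vals} ]\n")


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "flexmotif-tffm"


def save_model(model: TFFM, path: str | Path) -> None:
    doc = {
        "format": _MODEL_FORMAT,
        "version": 1,
        "name": model.name,
        "kind": model.kind,
        "length_range": list(model.length_range),
        "state_labels": list(model.hmm.state_labels),
        "initial": model.hmm.initial.tolist(),
        "transitions": model.hmm.transitions.tolist(),
        "emissions": model.hmm.emissions.tolist(),
        "match_map": {str(k): v for k, v in model.match_map.items()},
        "final_states": sorted(model.final_states),
        "match_states": sorted(model.match_states),
        "edits": [{"kind": e.kind, "positions": list(e.positions),
                   "prob": e.prob,
                   "alt_pfm": (e.alt_pfm.probs.tolist()
                               if e.alt_pfm is not None else None)}
                  for e in model.edits],
    }
    with open(path, "w") as out:
        json.dump(doc, out, indent=1)
        out.write("\n")


def load_model(path: str | Path) -> TFFM:
    with open(path) as handle:
        doc = json.load(handle)
    if doc.get("format") != _MODEL_FORMAT:
        raise FormatError(f"{path}: not a {_MODEL_FORMAT} file")
    try:
        hmm = ConditionalEmissionHMM(
            np.asarray(doc["initial"], dtype=float),
            np.asarray(doc["transitions"], dtype=float),
            np.asarray(doc["emissions"], dtype=float),
            list(doc["state_labels"]))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: invalid model tables: {exc}") from exc
    edits = [FlexEdit(e["kind"], tuple(e["positions"]), e["prob"],
                      (PositionFrequencyMatrix(np.asarray(e["alt_pfm"]))
                       if e.get("alt_pfm") is not None else None))
             for e in doc.get("edits", [])]
    try:
        return TFFM(kind=doc["kind"], hmm=hmm,
                    match_map={int(k): list(v)
                               for k, v in doc["match_map"].items()},
                    final_states=set(doc["final_states"]),
                    length_range=tuple(doc["length_range"]),
                    match_states=set(doc.get("match_states", [])),
                    edits=edits, name=doc.get("name", "tffm"))
    except (KeyError, ModelError) as exc:
        raise FormatError(f"{path}: invalid model: {exc}") from exc
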