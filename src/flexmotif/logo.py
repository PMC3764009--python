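"""Summary and dense motif logos with dinucleotide dependencies.

For each motif position ``i`` the model defines conditional probabilities
``P_i(n | m)`` of nucleotide ``n`` given nucleotide ``m`` at position
``i-1`` (emission tables for order-0/order-1 models, between-position
transitions for detailed models).  Marginals are propagated from a uniform
distribution ahead of the first position:

    P_i(n) = sum_m P_{i-1}(m) * P_i(n | m),   P_0 uniform.

The summary logo is a classic information-content stack over the marginals;
the dense logo is a 4 x L grid whose cell (m, i) draws ``P_i(. | m)``
probability-scaled, with cell opacity tracking ``P_{i-1}(m)`` so the rows a
scanning model actually visits stand out.  Information content per position
is ``2 + sum_n P log2 P`` bits (0 log 0 = 0); the model IC is the sum over
positions, between 0 and 2L.

Only fixed-length, unedited topologies have a well-defined per-position
table; flexible models are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import TFFM, ModelError

NT = "ACGT"
_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


class UnsupportedTopologyError(ModelError):
    """Logos are undefined for variable-length or edited motif topologies."""


@dataclass
class LogoData:
    """Per-position marginals, conditionals and row opacities of a motif."""

    marginal: np.ndarray       # (L, 4)
    conditional: np.ndarray    # (L, 4, 4): [i, m, n] = P_i(n | m)
    opacity: np.ndarray        # (L, 4): [i, m] = P_{i-1}(m)

    @property
    def length(self) -> int:
        return self.marginal.shape[0]

    def position_ic(self) -> np.ndarray:
        p = self.marginal
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1)), 0.0)
        return 2.0 + plogp.sum(axis=1)


def _conditionals(model: TFFM) -> np.ndarray:
    L = model.motif_length
    cond = np.empty((L, 4, 4))
    if model.kind == "detailed":
        A = model.hmm.transitions
        prev_groups = [sorted(set(range(model.hmm.n_states))
                              - model.match_states)] + \
                      [model.match_map[i] for i in range(1, L)]
        for i in range(L):
            cur = model.match_map[i + 1]
            sub = A[np.ix_(prev_groups[i], cur)]
            sums = sub.sum(axis=1, keepdims=True)
            if np.any(sums <= 0):
                raise UnsupportedTopologyError(
                    "a motif position is unreachable from its predecessor")
            cond[i] = sub / sums
    else:
        for i in range(L):
            (state,) = model.match_map[i + 1]
            cond[i] = model.hmm.emissions[state]
    return cond


def logo_data(model: TFFM) -> LogoData:
    """Marginal/conditional tables of a fixed-length TFFM."""
    if model.is_flexible or model.edits:
        raise UnsupportedTopologyError(
            "logos are only defined for fixed-length, unedited models")
    cond = _conditionals(model)
    L = model.motif_length
    marginal = np.empty((L, 4))
    opacity = np.empty((L, 4))
    prev = np.full(4, 0.25)
    for i in range(L):
        opacity[i] = prev
        marginal[i] = prev @ cond[i]
        prev = marginal[i]
    return LogoData(marginal, cond, opacity)


def information_content(model: TFFM) -> float:
    """Total information content of the motif in bits (0 .. 2L)."""
    return float(logo_data(model).position_ic().sum())


# ---------------------------------------------------------------------------
# SVG rendering (deterministic: same LogoData -> byte-identical file)
# ---------------------------------------------------------------------------

_COL_W = 30.0
_ROW_H = 60.0
_PAD = 24.0


def _letter(x: float, y_base: float, height: float, letter: str,
            width: float = _COL_W) -> str:
    """A glyph scaled to the requested height, baseline at y_base."""
    if height <= 1e-4:
        return ""
    sx = width / 20.0
    sy = height / 20.0
    return (f'<text x="0" y="0" font-family="monospace" font-size="24" '
            f'font-weight="bold" fill="{_COLORS[letter]}" '
            f'transform="translate({x:.2f},{y_base:.2f}) '
            f'scale({sx:.4f},{sy:.4f})" text-anchor="middle">{letter}</text>')


def _svg(width: float, height: float, body: list[str]) -> str:
    head = (f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{width:.0f}" height="{height:.0f}" '
            f'viewBox="0 0 {width:.0f} {height:.0f}">')
    return "\n".join([head, *body, "</svg>"]) + "\n"


def render_summary(data: LogoData) -> str:
    """One IC-scaled stack per position (letter height = P * IC, in bits;
    full column height corresponds to 2 bits)."""
    L = data.length
    ic = data.position_ic()
    body = []
    for i in range(L):
        x = _PAD + (i + 0.5) * _COL_W
        order = np.argsort(data.marginal[i], kind="stable")  # tallest on top
        y = _PAD + 2 * _ROW_H
        for n in order:
            h = data.marginal[i, n] * ic[i] / 2.0 * 2 * _ROW_H
            body.append(_letter(x, y, h, NT[n]))
            y -= h
        body.append(f'<text x="{x:.2f}" y="{_PAD + 2 * _ROW_H + 16:.2f}" '
                    f'font-family="monospace" font-size="12" '
                    f'text-anchor="middle">{i + 1}</text>')
    return _svg(2 * _PAD + L * _COL_W, 2 * _PAD + 2 * _ROW_H + 8,
                [b for b in body if b])


def render_dense(data: LogoData, opacity_floor: float = 0.1) -> str:
    """4 x L grid: row m of column i draws P_i(. | m), cell opacity linear
    in P_{i-1}(m) with a legibility floor."""
    L = data.length
    body = []
    for m in range(4):
        y0 = _PAD + m * _ROW_H
        body.append(f'<text x="{_PAD - 8:.2f}" y="{y0 + _ROW_H / 2:.2f}" '
                    f'font-family="monospace" font-size="14" '
                    f'text-anchor="end">{NT[m]}</text>')
        for i in range(L):
            x0 = _PAD + i * _COL_W
            op = opacity_floor + (1.0 - opacity_floor) * data.opacity[i, m]
            cell = [f'<g opacity="{op:.3f}">',
                    f'<rect x="{x0:.2f}" y="{y0:.2f}" width="{_COL_W:.2f}" '
                    f'height="{_ROW_H:.2f}" fill="none" stroke="#ccc"/>']
            order = np.argsort(data.conditional[i, m], kind="stable")
            y = y0 + _ROW_H
            for n in order:
                h = data.conditional[i, m, n] * _ROW_H
                glyph = _letter(x0 + _COL_W / 2, y, h, NT[n])
                if glyph:
                    cell.append(glyph)
                y -= h
            cell.append("</g>")
            body.extend(cell)
    for i in range(L):
        x = _PAD + (i + 0.5) * _COL_W
        body.append(f'<text x="{x:.2f}" y="{_PAD + 4 * _ROW_H + 16:.2f}" '
                    f'font-family="monospace" font-size="12" '
                    f'text-anchor="middle">{i + 1}</text>')
    return _svg(2 * _PAD + L * _COL_W, 2 * _PAD + 4 * _ROW_H + 8, body)


def render_logos(data: LogoData, out: str | Path,
                 style: str = "summary") -> None:
    """Write a summary or dense logo as a well-formed SVG document."""
    if style == "summary":
        doc = render_summary(data)
    elif style == "dense":
        doc = render_dense(data)
    else:
        raise ModelError(f"unknown logo style {style!r}")
    Path(out).write_text(doc)


def write_logo_tables(data: LogoData, out: str | Path) -> None:
    """LogoData as a tab-separated dump (marginals then conditionals)."""
    with open(out, "w") as fh:
        fh.write("# marginal\nposition\tA\tC\tG\tT\tIC\n")
        ic = data.position_ic()
        for i in range(data.length):
            vals = "\t".join(f"{v:.6f}" for v in data.marginal[i])
            fh.write(f"{i + 1}\t{vals}\t{ic[i]:.6f}\n")
        fh.write("# conditional\nposition\tprev\tA\tC\tG\tT\topacity\n")
        for i in range(data.length):
            for m in range(4):
                vals = "\t".join(f"{v:.6f}" for v in data.conditional[i, m])
                fh.write(f"{i + 1}\t{NT[m]}\t{vals}\t{data.opacity[i, m]:.6f}\n")
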