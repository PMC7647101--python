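"""Significance-aware sequence logos and heatmaps of DAU results.

The logo draws, per window position, only the symbols whose differential
usage is significant: over-represented symbols stack above the axis and
under-represented ones mirror below it.  Letter heights are the frequency
difference in percentage points (input minus background), with the largest
difference nearest the axis; an optional metric uses -log10 p instead.
The heatmap shows the full statistic (Z-score or odds ratio) or frequency
difference for every cell, on a diverging palette centred at zero, with
untestable cells in a distinct NA style.

SVG is the reference output (timestamps suppressed, so identical results
render byte-identically); PNG is a rasterisation of the same figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.rcParams["svg.hashsalt"] = "pepdau"

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.path import Path as MplPath
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .alphabets import GroupingScheme, get_scheme
from .dau import DAUResult

_FONT = FontProperties(family="DejaVu Sans", weight="bold")


@dataclass
class Glyph:
    """One rendered logo letter (for structural inspection in tests)."""

    position: int  # offset relative to anchor
    symbol: str
    height: float  # stack height in axis units (percentage points)
    over: bool


def _glyph_patch(symbol, x, y0, width, height, color, gid):
    """A letter scaled to exactly (width x height) in data coordinates."""
    tp = TextPath((0, 0), symbol, size=1.0, prop=_FONT)
    bb = tp.get_extents()
    if bb.width == 0 or bb.height == 0:  # pragma: no cover - glyphless char
        return None
    trans = (
        Affine2D()
        .translate(-bb.x0, -bb.y0)
        .scale(width / bb.width, height / bb.height)
        .translate(x, y0)
    )
    return PathPatch(
        MplPath(trans.transform(tp.vertices), tp.codes),
        facecolor=color, edgecolor="none", gid=gid,
    )


def _stack_heights(result: DAUResult, metric: str) -> np.ndarray:
    if metric == "diff_pct":
        return np.abs(result.diff) * 100.0
    if metric == "neglog10p":
        with np.errstate(divide="ignore"):
            return -np.log10(np.maximum(result.p_value, 1e-300))
    raise ValueError(f"unknown height metric {metric!r}")


def render_logo(
    result: DAUResult,
    path,
    scheme: GroupingScheme | str | None = None,
    height_metric: str = "diff_pct",
    label_style: str = "offset",
    title: str | None = None,
    figsize: tuple[float, float] | None = None,
) -> list[Glyph]:
    """Render the significant cells of ``result`` as a sequence logo.

    Returns the list of drawn glyphs (position, symbol, height, side) so
    callers and tests can inspect the structure without parsing the file.
    An all-null result produces an axis-only figure with a notice, not an
    error.
    """
    if scheme is None:
        scheme = result.metadata.get("scheme", "identity")
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    colors = scheme.colors
    L = result.L
    heights = _stack_heights(result, height_metric)
    glyphs: list[Glyph] = []

    fig, ax = plt.subplots(figsize=figsize or (max(4.0, 0.42 * L), 3.4))
    top = bottom = 0.0
    for i in range(L):
        pos = i - result.anchor_column
        for over in (True, False):
            cells = [
                (heights[i, j], result.symbols[j])
                for j in range(len(result.symbols))
                if result.significant[i, j]
                and np.isfinite(heights[i, j])
                and (result.diff[i, j] > 0) == over
                and result.diff[i, j] != 0
            ]
            cells.sort(reverse=True)  # largest nearest the axis
            y = 0.0
            for h, sym in cells:
                if h <= 0:
                    continue
                y0 = y if over else -(y + h)
                patch = _glyph_patch(
                    sym, i + 0.08, y0, 0.84, h, colors.get(sym, "#444444"),
                    gid=f"logo-{'over' if over else 'under'}-p{pos}-{sym}",
                )
                if patch is not None:
                    ax.add_patch(patch)
                glyphs.append(Glyph(pos, sym, h, over))
                y += h
            if over:
                top = max(top, y)
            else:
                bottom = max(bottom, y)

    span = max(top, bottom, 1e-9)
    ax.set_xlim(0, L)
    ax.set_ylim(-(bottom + 0.08 * span + 1e-9), top + 0.08 * span + 1e-9)
    ax.axhline(0.0, color="black", lw=1.0)
    ax.set_xticks(np.arange(L) + 0.5)
    labels = _column_labels(result, label_style)
    ax.set_xticklabels(labels, fontsize=7,
                       rotation=90 if max(map(len, labels)) > 3 else 0)
    ylabel = ("frequency difference (pp)" if height_metric == "diff_pct"
              else "-log10 p")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    if not glyphs:
        ax.text(0.5, 0.5, "no significant differential usage",
                transform=ax.transAxes, ha="center", va="center",
                color="#777777", gid="logo-empty-notice")
    for side in ("top", "right"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    _save(fig, path)
    plt.close(fig)
    return glyphs


def _column_labels(result: DAUResult, style: str) -> list[str]:
    if style == "offset":
        return [f"{p:+d}" if p else "0" for p in result.positions()]
    if style == "protease":
        u = result.anchor_column
        d = result.L - 1 - u
        return ([f"P{u + 1 - i}" for i in range(u)] + ["P1"]
                + [f"P{i}'" for i in range(1, d + 1)])
    raise ValueError(f"unknown label style {style!r}")


def render_heatmap(
    result: DAUResult,
    path,
    value: str = "statistic",
    label_style: str = "offset",
    title: str | None = None,
) -> np.ndarray:
    """Render a symbols x positions heatmap of Z-scores/odds ratios or
    frequency differences; returns the plotted matrix (rows = symbols).

    Values are shown on a diverging palette centred at 0 (odds ratios are
    shown as log2); NA cells are hatched grey.
    """
    if value == "statistic":
        mat = result.statistic.T.copy()
        if result.metadata.get("test_mode") == "fisher":
            with np.errstate(divide="ignore", invalid="ignore"):
                mat = np.log2(mat)
        label = ("Z-score" if result.metadata.get("test_mode") == "ztest"
                 else "log2 odds ratio")
    elif value == "diff":
        mat = result.diff.T * 100.0
        label = "frequency difference (pp)"
    else:
        raise ValueError(f"value must be 'statistic' or 'diff', got {value!r}")
    mat = np.where(result.na.T, np.nan, mat)

    finite = mat[np.isfinite(mat)]
    vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
    vmax = vmax or 1.0
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("#bbbbbb")
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.38 * result.L), max(2.5, 0.3 * len(result.symbols)))
    )
    capped = np.clip(mat, -vmax, vmax)  # keep +/-inf cells at palette ends
    mesh = ax.pcolormesh(
        np.ma.masked_invalid(capped), cmap=cmap, vmin=-vmax, vmax=vmax
    )
    for (j, i) in zip(*np.where(result.na.T)):
        ax.add_patch(Rectangle((i, j), 1, 1, facecolor="#bbbbbb",
                               hatch="//", edgecolor="#888888", lw=0.2,
                               gid=f"heatmap-na-p{i - result.anchor_column}"))
    ax.set_xticks(np.arange(result.L) + 0.5)
    labels = _column_labels(result, label_style)
    ax.set_xticklabels(labels, fontsize=7,
                       rotation=90 if max(map(len, labels)) > 3 else 0)
    ax.set_yticks(np.arange(len(result.symbols)) + 0.5)
    ax.set_yticklabels(result.symbols, fontsize=7)
    ax.invert_yaxis()
    fig.colorbar(mesh, ax=ax, label=label, fraction=0.04)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    _save(fig, path)
    plt.close(fig)
    return mat


def _save(fig, path) -> None:
    path = str(path)
    if path.endswith(".svg"):
        fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        fig.savefig(path, dpi=150)
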