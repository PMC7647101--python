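"""Differential amino-acid (group) usage tests.

For each window position ``l`` and alphabet symbol, the input set's observed
frequency ``p_l`` is compared with the background.  Two tests are offered:

* **Z-test** against a bootstrap background: ``Z = (p_l - p_bar_l) / se_l``
  with the bootstrap mean ``p_bar_l`` and the binomial standard error
  ``se_l = sqrt(p_bar_l (1 - p_bar_l) / N)``, referred to the standard normal
  for a two-sided p-value.  Fast, appropriate when input and background sets
  are large.
* **Fisher's exact test** against an exhaustive background: per cell, the
  2x2 table of (symbol, other) x (input, background) counts is tested
  exactly, two-sided by the point-probability convention — the p-value sums
  the hypergeometric probabilities of all tables (margins fixed) no more
  likely than the observed one.  Small tables are evaluated in exact integer
  arithmetic; large ones in log space.

Every cell reports ``diff`` (input minus background frequency, the quantity
logos draw), a statistic (Z-score or sample odds ratio), the p-value, and a
significance flag at level ``alpha`` (raw p-values by default; optional
Benjamini-Hochberg across cells).  Columns with no countable residues are
reported as NA cells, never dropped from the result shape.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .alphabets import GroupingScheme, get_scheme
from .background import BackgroundModel, count_windows
from .peptides import PeptideSet

#: Above this total table count, Fisher switches from exact integer
#: arithmetic to log-space evaluation (tie tolerance 1e-7, relative).
_EXACT_FISHER_LIMIT = 2000


class DAUError(ValueError):
    """Raised for mismatched inputs to the DAU tests."""


@dataclass
class FrequencyMatrix:
    """Observed per-position symbol frequencies of a peptide set."""

    symbols: list[str]
    counts: np.ndarray  # (L, n_symbols) integer counts
    totals: np.ndarray  # (L,) countable residues per position

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    @property
    def values(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals[:, None] > 0,
                            self.counts / np.maximum(self.totals[:, None], 1),
                            np.nan)


def position_frequencies(
    peptides: PeptideSet, scheme: GroupingScheme | str = "identity"
) -> FrequencyMatrix:
    """Count scheme symbols per window column.

    Padding and non-standard residues are excluded from both numerator and
    denominator; a column with no countable residue has undefined
    frequencies (NaN) and is excluded from testing downstream.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if len(peptides) == 0:
        raise DAUError("empty peptide set")
    from .alphabets import encode_residues

    codes = np.stack([encode_residues(w) for w in peptides.windows])
    counts, totals = count_windows(codes, scheme.member_index())
    return FrequencyMatrix(scheme.symbols, counts, totals)


# ---------------------------------------------------------------------------
# Fisher's exact test, two-sided (point-probability convention)

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities <= that of the observed table at
    fixed margins.  Exact integer arithmetic when the table total is small;
    log-space with a 1e-7 relative tie tolerance otherwise.  Zero-margin
    tables return 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - r2), min(r1, k)
    if n <= _EXACT_FISHER_LIMIT:
        weights = [
            math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)
        ]
        obs = weights[a - lo]
        s = sum(w for w in weights if w <= obs)
        return float(Fraction(s, math.comb(n, k)))
    xs = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(xs, n, k, r1)
    keep = logpmf <= logpmf[a - lo] + 1e-7
    from scipy.special import logsumexp

    return float(min(1.0, math.exp(logsumexp(logpmf[keep]))))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio a*d / (b*c); inf when b*c = 0 with a*d > 0, NaN when
    both products vanish."""
    num, den = a * d, b * c
    if den > 0:
        return num / den
    return math.inf if num > 0 else math.nan


# ---------------------------------------------------------------------------
# Results

@dataclass
class DAUResult:
    """Per-position, per-symbol differential-usage test results."""

    symbols: list[str]
    anchor_column: int
    diff: np.ndarray       # input freq - background freq (L, S)
    statistic: np.ndarray  # Z-score or sample odds ratio (L, S)
    p_value: np.ndarray    # (L, S); NaN for NA cells
    significant: np.ndarray  # bool (L, S)
    na: np.ndarray         # bool (L, S): untestable cells
    metadata: dict = field(default_factory=dict)
    degenerate: np.ndarray | None = None  # se = 0 cells (Z mode)

    @property
    def L(self) -> int:
        return self.diff.shape[0]

    def positions(self) -> list[int]:
        """Column offsets relative to the anchor (anchor = 0)."""
        return [i - self.anchor_column for i in range(self.L)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, pos in enumerate(self.positions()):
            for j, sym in enumerate(self.symbols):
                rows.append({
                    "position": pos,
                    "symbol": sym,
                    "diff": self.diff[i, j],
                    "statistic": self.statistic[i, j],
                    "p_value": self.p_value[i, j],
                    "significant": bool(self.significant[i, j]),
                    "na": bool(self.na[i, j]),
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")

    def to_json(self, path=None) -> str:
        payload = {
            "metadata": self.metadata,
            "symbols": self.symbols,
            "anchor_column": self.anchor_column,
            "cells": json.loads(
                self.to_dataframe().to_json(orient="records")
            ),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "DAUResult":
        """Reload a result written by :meth:`to_json`."""
        with open(path) as fh:
            payload = json.load(fh)
        symbols = list(payload["symbols"])
        cells = pd.DataFrame(payload["cells"])
        anchor = int(payload["anchor_column"])
        L = cells["position"].nunique()
        S = len(symbols)
        shape = (L, S)
        col = {s: j for j, s in enumerate(symbols)}
        diff = np.full(shape, np.nan)
        stat = np.full(shape, np.nan)
        pval = np.full(shape, np.nan)
        sig = np.zeros(shape, dtype=bool)
        na = np.zeros(shape, dtype=bool)
        for _, row in cells.iterrows():
            i = int(row["position"]) + anchor
            j = col[row["symbol"]]
            diff[i, j] = np.nan if row["diff"] is None else row["diff"]
            stat[i, j] = np.nan if row["statistic"] is None else row["statistic"]
            pval[i, j] = np.nan if row["p_value"] is None else row["p_value"]
            sig[i, j] = bool(row["significant"])
            na[i, j] = bool(row["na"])
        return cls(symbols, anchor, diff, stat, pval, sig, na,
                   dict(payload.get("metadata", {})))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values over the finite entries."""
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    flat = p[mask]
    m = flat.size
    if m == 0:
        return q
    order = np.argsort(flat)
    ranked = flat[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def _finalize(
    symbols, anchor_col, diff, statistic, p, na, alpha, adjust, metadata,
    degenerate=None,
) -> DAUResult:
    p_eff = _bh_adjust(p) if adjust == "bh" else p
    with np.errstate(invalid="ignore"):
        significant = np.where(np.isnan(p_eff), False, p_eff < alpha)
    metadata = dict(metadata, alpha=alpha, adjust=adjust or "none")
    return DAUResult(list(symbols), anchor_col, diff, statistic, p, significant,
                     na, metadata, degenerate)


def _check_alphabets(symbols_a, symbols_b) -> None:
    if list(symbols_a) != list(symbols_b):
        raise DAUError(
            f"alphabet mismatch: input symbols {list(symbols_a)} vs "
            f"background symbols {list(symbols_b)}"
        )


def ztest_dau(
    freqs: FrequencyMatrix,
    bg: BackgroundModel,
    alpha: float = 0.05,
    anchor_column: int = 0,
    adjust: str | None = None,
    metadata: dict | None = None,
) -> DAUResult:
    """Two-sided Z-test of input frequencies against a bootstrap background."""
    if bg.mode != "ztest":
        raise DAUError("ztest_dau requires a Z-mode background")
    _check_alphabets(freqs.symbols, bg.symbols)
    if freqs.L != bg.L:
        raise DAUError(f"window length mismatch: input L={freqs.L}, "
                       f"background L={bg.L}")
    p = freqs.values
    pbar, se = bg.mean_freq, bg.se
    na = np.isnan(p) | np.isnan(pbar)
    diff = p - pbar
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        pval = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = (se == 0) & (diff != 0) & ~na
    z = np.where(na, np.nan, z)
    pval = np.where(na, np.nan, pval)
    diff = np.where(na, np.nan, diff)
    meta = dict(metadata or {}, test_mode="ztest")
    return _finalize(freqs.symbols, anchor_column, diff, z, pval, na,
                     alpha, adjust, meta, degenerate)


def fisher_dau(
    freqs: FrequencyMatrix,
    bg: BackgroundModel,
    alpha: float = 0.05,
    anchor_column: int = 0,
    adjust: str | None = None,
    metadata: dict | None = None,
) -> DAUResult:
    """Fisher's exact test of input counts against background counts.

    Per cell the 2x2 table is [[a, b], [c, d]] with a = input count of the
    symbol at the position, b = input countable total - a, c = background
    count, d = background total - c.
    """
    if bg.mode != "fisher":
        raise DAUError("fisher_dau requires a Fisher-mode background")
    _check_alphabets(freqs.symbols, bg.symbols)
    if freqs.L != bg.L:
        raise DAUError(f"window length mismatch: input L={freqs.L}, "
                       f"background L={bg.L}")
    L, S = freqs.counts.shape
    pval = np.full((L, S), np.nan)
    orat = np.full((L, S), np.nan)
    bg_freq = bg.freq()
    diff = freqs.values - bg_freq
    na = np.isnan(freqs.values) | np.isnan(bg_freq)
    for i in range(L):
        n_in = int(freqs.totals[i])
        n_bg = int(bg.totals[i])
        if n_in == 0 or n_bg == 0:
            continue
        for j in range(S):
            a = int(freqs.counts[i, j])
            c = int(bg.counts[i, j])
            b, d = n_in - a, n_bg - c
            pval[i, j] = fisher_two_sided(a, b, c, d)
            orat[i, j] = odds_ratio(a, b, c, d)
    diff = np.where(na, np.nan, diff)
    meta = dict(metadata or {}, test_mode="fisher")
    return _finalize(freqs.symbols, anchor_column, diff, orat, pval, na,
                     alpha, adjust, meta)


def test_dau(
    peptides: PeptideSet,
    bg: BackgroundModel,
    scheme: GroupingScheme | str = "identity",
    alpha: float = 0.05,
    adjust: str | None = None,
) -> DAUResult:
    """Test differential symbol usage of ``peptides`` against ``bg``.

    Dispatches on the background's test mode; the grouping scheme must be the
    one the background was built with (backgrounds are scheme-specific).
    The anchor column is tested like any other column.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if scheme.name != bg.scheme_name:
        raise DAUError(
            f"scheme mismatch: background was built with "
            f"{bg.scheme_name!r}, test requested {scheme.name!r}"
        )
    freqs = position_frequencies(peptides, scheme)
    digest = hashlib.sha256(
        json.dumps(bg.config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]
    meta = {
        "scheme": scheme.name,
        "background": digest,
        "n_input": len(peptides),
        "L": peptides.L,
    }
    fn = ztest_dau if bg.mode == "ztest" else fisher_dau
    return fn(freqs, bg, alpha=alpha, anchor_column=peptides.anchor_column,
              adjust=adjust, metadata=meta)
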