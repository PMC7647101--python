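"""Background models for differential amino-acid usage tests.

A background model captures, per window position and per symbol of the chosen
alphabet, what residue usage looks like in the absence of the biological
signal under study.  Twelve models arise from crossing

* the proteome-level space — whole proteome, only the input proteins
  (``inputSet``), or the proteome minus the input proteins (``nonInputSet``);
* the position-level space — protein N-termini, C-termini, or anywhere; and
* for "anywhere", whether sampled windows are anchored on a residue set
  (e.g. K for acetyl-lysine data) or unanchored.

Two estimation modes are supported.  In Z mode, bootstrapping draws ``T``
background sets of ``N`` windows each; the per-set frequencies ``p_lt`` give
the mean

    p_bar_l = sum_t p_lt / T                                       (per symbol)

and its binomial standard error

    se_l = sqrt(p_bar_l * (1 - p_bar_l) / N),

which together parameterise the normal approximation used by the Z-test.
(The ``p(1-p)/N`` form is the correct binomial variance of a proportion; some
earlier logo tools used ``p/N``.)  In Fisher mode a single exhaustive (or
capped) background set is stored as raw counts for exact 2x2 testing.

Padding (X) and non-standard residues are excluded from both numerator and
denominator of every frequency, position-wise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .alphabets import GroupingScheme, encode_residues, get_scheme
from .proteome import PAD, STANDARD_AA, Proteome

PROTEOME_SPACES = ("wholeProteome", "inputSet", "nonInputSet")
POSITIONAL_SPACES = ("nterm", "cterm", "anywhere")


class BackgroundError(ValueError):
    """Raised for invalid background configuration or empty sampling pools."""


def valid_configurations() -> list[tuple[str, str, bool]]:
    """Enumerate the twelve valid (proteome_space, positional_space,
    anchored) combinations: 3 proteome spaces x (nterm, cterm,
    anywhere-unanchored, anywhere-anchored)."""
    out = []
    for ps in PROTEOME_SPACES:
        for pos in POSITIONAL_SPACES:
            if pos == "anywhere":
                out.append((ps, pos, False))
                out.append((ps, pos, True))
            else:
                out.append((ps, pos, False))
    return out


@dataclass
class BackgroundConfig:
    """Construction recipe for a background model.

    ``T`` bootstrap sets of ``N`` windows are used in Z mode; Fisher mode
    collects every eligible window (optionally capped at ``max_windows``).
    """

    proteome_space: str = "wholeProteome"
    positional_space: str = "anywhere"
    anchored: bool = False
    anchor_AAs: frozenset[str] = frozenset()
    upstream: int = 7
    downstream: int = 7
    test_mode: str = "ztest"
    T: int = 300
    N: int | None = None  # default: size of the input set
    max_windows: int | None = None  # Fisher-mode cap; None = all available
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.proteome_space not in PROTEOME_SPACES:
            raise BackgroundError(
                f"proteome_space must be one of {PROTEOME_SPACES}, "
                f"got {self.proteome_space!r}"
            )
        if self.positional_space not in POSITIONAL_SPACES:
            raise BackgroundError(
                f"positional_space must be one of {POSITIONAL_SPACES}, "
                f"got {self.positional_space!r}"
            )
        if self.anchored and self.positional_space != "anywhere":
            raise BackgroundError(
                "anchored sampling is only meaningful with "
                "positional_space='anywhere'"
            )
        self.anchor_AAs = frozenset(a.upper() for a in self.anchor_AAs)
        if self.anchored and not self.anchor_AAs:
            raise BackgroundError("anchored=True requires non-empty anchor_AAs")
        if self.test_mode not in ("ztest", "fisher"):
            raise BackgroundError(
                f"test_mode must be 'ztest' or 'fisher', got {self.test_mode!r}"
            )
        if self.upstream < 0 or self.downstream < 0:
            raise BackgroundError("offsets must be >= 0")
        if self.test_mode == "ztest":
            if self.T < 2:
                raise BackgroundError("Z mode requires T >= 2 bootstrap sets")
            if self.N is not None and self.N < 1:
                raise BackgroundError("Z mode requires N >= 1 windows per set")

    @property
    def L(self) -> int:
        return self.upstream + 1 + self.downstream

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchor_AAs"] = sorted(self.anchor_AAs)
        return d


# ---------------------------------------------------------------------------
# Encoded sampling pool

class _EncodedPool:
    """Proteome flattened into one padded code buffer for vectorised
    window extraction.

    Proteins are laid out with at least max(upstream, downstream) padding
    codes (-1) between them, so ``buf[anchor-upstream : anchor+downstream+1]``
    is a valid window for any in-protein anchor without bounds checks.
    """

    def __init__(self, proteome: Proteome, upstream: int, downstream: int):
        gap = max(upstream, downstream) + 1
        chunks = [np.full(gap, -1, dtype=np.int8)]
        starts: list[int] = []
        lengths: list[int] = []
        pos = gap
        for _pid, seq in proteome.records:
            codes = encode_residues(seq)
            starts.append(pos)
            lengths.append(len(codes))
            chunks.append(codes)
            chunks.append(np.full(gap, -1, dtype=np.int8))
            pos += len(codes) + gap
        self.buf = np.concatenate(chunks)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.upstream = upstream
        self.downstream = downstream
        self.offsets = np.arange(-upstream, downstream + 1, dtype=np.int64)

    def anchor_pool(self, anchored: bool, anchor_codes: np.ndarray | None) -> np.ndarray:
        """Buffer indices of eligible anchor residues ('anywhere' spaces).

        Non-standard residues are never anchors: an anchor must be a
        countable residue.
        """
        countable = np.flatnonzero(self.buf >= 0)
        if not anchored:
            return countable
        mask = np.isin(self.buf[countable], anchor_codes)
        return countable[mask]

    def terminal_anchors(self, which: str) -> np.ndarray:
        """Buffer indices of every protein's first (nterm) or last (cterm)
        residue."""
        if which == "nterm":
            return self.starts
        return self.starts + self.lengths - 1

    def windows_at(self, anchors: np.ndarray) -> np.ndarray:
        """Window code matrix (n, L) for the given buffer anchor indices."""
        return self.buf[anchors[:, None] + self.offsets[None, :]]


def _restrict(proteome: Proteome, space: str, input_ids) -> Proteome:
    if space == "wholeProteome":
        return proteome
    if input_ids is None:
        raise BackgroundError(
            f"proteome_space={space!r} requires the input protein ids"
        )
    return proteome.subset(input_ids, complement=(space == "nonInputSet"))


def _decode_windows(codes: np.ndarray) -> list[str]:
    table = np.frombuffer((STANDARD_AA + PAD).encode("ascii"), dtype=np.uint8)
    return [
        bytes(table[row]).decode("ascii")
        for row in np.where(codes >= 0, codes, 20)
    ]


def sample_windows(
    proteome: Proteome,
    config: BackgroundConfig,
    n: int,
    rng: np.random.Generator,
    input_ids=None,
    replace: bool | None = None,
) -> list[str]:
    """Sample ``n`` background windows under ``config``'s sampling spaces.

    Returns windows as strings with X at padded/non-standard positions.
    ``replace=None`` samples without replacement when the pool allows and
    falls back to replacement with a warning otherwise.
    """
    if n < 1:
        raise BackgroundError("n must be >= 1")
    restricted = _restrict(proteome, config.proteome_space, input_ids)
    pool_obj = _EncodedPool(restricted, config.upstream, config.downstream)
    pool = _anchor_candidates(pool_obj, config)
    anchors = _draw(pool, n, rng, replace)
    return _decode_windows(pool_obj.windows_at(anchors))


def _anchor_candidates(pool_obj: _EncodedPool, config: BackgroundConfig) -> np.ndarray:
    if config.positional_space in ("nterm", "cterm"):
        pool = pool_obj.terminal_anchors(config.positional_space)
        # terminal anchors may be non-standard residues (rare); drop them
        pool = pool[pool_obj.buf[pool] >= 0]
        if pool.size == 0:
            raise BackgroundError(
                f"no countable {config.positional_space} anchor residues"
            )
        return pool
    anchor_codes = None
    if config.anchored:
        anchor_codes = encode_residues("".join(sorted(config.anchor_AAs)))
    pool = pool_obj.anchor_pool(config.anchored, anchor_codes)
    if pool.size == 0:
        what = (f"residues in {sorted(config.anchor_AAs)}"
                if config.anchored else "countable residues")
        raise BackgroundError(f"no eligible anchor positions: no {what}")
    return pool


def _draw(
    pool: np.ndarray, n: int, rng: np.random.Generator, replace: bool | None
) -> np.ndarray:
    if replace is None:
        replace = pool.size < n
        if replace:
            warnings.warn(
                f"sampling {n} windows from a pool of {pool.size}: "
                "falling back to sampling with replacement", stacklevel=3,
            )
    elif not replace and pool.size < n:
        raise BackgroundError(
            f"cannot draw {n} windows without replacement from pool of "
            f"{pool.size}"
        )
    return rng.choice(pool, size=n, replace=replace)


def bootstrap_se(p_bar, N: int):
    """Binomial standard error of a frequency estimated from ``N`` windows:
    ``sqrt(p_bar * (1 - p_bar) / N)``."""
    p = np.asarray(p_bar, dtype=float)
    out = np.sqrt(p * (1.0 - p) / N)
    return float(out) if np.isscalar(p_bar) else out


# ---------------------------------------------------------------------------
# Model construction

@dataclass
class BackgroundModel:
    """Per-position, per-symbol background statistics.

    Z mode stores the bootstrap mean frequency and its standard error
    (matrices of shape L x n_symbols); Fisher mode stores raw counts and
    per-position countable totals.
    """

    config: BackgroundConfig
    scheme_name: str
    symbols: list[str]
    mean_freq: np.ndarray | None = None
    se: np.ndarray | None = None
    counts: np.ndarray | None = None
    totals: np.ndarray | None = None
    bootstrap_freqs: np.ndarray | None = field(default=None, repr=False)

    @property
    def mode(self) -> str:
        return self.config.test_mode

    @property
    def L(self) -> int:
        return self.config.L

    def freq(self) -> np.ndarray:
        """Background frequency matrix (L x n_symbols) in either mode."""
        if self.mode == "ztest":
            return self.mean_freq
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.totals[:, None] > 0,
                self.counts / np.maximum(self.totals[:, None], 1),
                np.nan,
            )

    def to_json(self, path=None) -> str:
        """Serialise config + matrices (stable key order for determinism)."""
        payload: dict = {
            "config": self.config.to_dict(),
            "scheme": self.scheme_name,
            "symbols": self.symbols,
        }
        if self.mode == "ztest":
            payload["mean_freq"] = _round_list(self.mean_freq)
            payload["se"] = _round_list(self.se)
        else:
            payload["counts"] = self.counts.astype(int).tolist()
            payload["totals"] = self.totals.astype(int).tolist()
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "BackgroundModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = dict(payload["config"])
        cfg["anchor_AAs"] = frozenset(cfg.get("anchor_AAs", []))
        config = BackgroundConfig(**cfg)
        kw: dict = {}
        if config.test_mode == "ztest":
            kw["mean_freq"] = np.asarray(payload["mean_freq"], dtype=float)
            kw["se"] = np.asarray(payload["se"], dtype=float)
        else:
            kw["counts"] = np.asarray(payload["counts"], dtype=np.int64)
            kw["totals"] = np.asarray(payload["totals"], dtype=np.int64)
        return cls(config, payload["scheme"], list(payload["symbols"]), **kw)


def _round_list(a: np.ndarray) -> list:
    # round to 12 decimals so JSON round-trips are byte-stable across runs
    return [[float(f"{v:.12g}") if np.isfinite(v) else None for v in row]
            for row in a]


def count_windows(
    codes: np.ndarray, member_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residue counts collapsed onto scheme groups.

    ``codes``: (n, L) int8 window codes.  Returns (counts (L, G), totals (L,))
    where totals count countable residues per column.
    """
    n, L = codes.shape
    flat = codes.astype(np.int64) + 1  # 0 = non-countable
    col = np.broadcast_to(np.arange(L), (n, L))
    idx = col.ravel() * 21 + flat.ravel()
    per_residue = np.bincount(idx, minlength=L * 21).reshape(L, 21)
    residue_counts = per_residue[:, 1:]  # drop non-countable bin
    counts = residue_counts @ member_index
    return counts, residue_counts.sum(axis=1)


def build_background(
    proteome: Proteome,
    config: BackgroundConfig,
    scheme: GroupingScheme | str = "identity",
    input_ids=None,
    input_size: int | None = None,
    keep_bootstrap: bool = False,
) -> BackgroundModel:
    """Construct a background model from a proteome.

    Z mode draws ``config.T`` bootstrap sets of ``config.N`` windows
    (``N`` defaults to ``input_size``, the size of the input peptide set) and
    stores the bootstrap mean frequency and its standard error per position
    and symbol.  Fisher mode stores counts over all eligible windows (capped
    at ``config.max_windows`` by uniform subsampling if set).

    Residue-to-group collapsing happens before any frequency computation.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    restricted = _restrict(proteome, config.proteome_space, input_ids)
    pool_obj = _EncodedPool(restricted, config.upstream, config.downstream)
    pool = _anchor_candidates(pool_obj, config)
    rng = np.random.default_rng(config.rng_seed)
    M = scheme.member_index()
    symbols = scheme.symbols
    L = config.L

    if config.test_mode == "fisher":
        anchors = pool
        if config.max_windows is not None and pool.size > config.max_windows:
            anchors = rng.choice(pool, size=config.max_windows, replace=False)
        counts, totals = count_windows(pool_obj.windows_at(anchors), M)
        return BackgroundModel(config, scheme.name, symbols,
                               counts=counts, totals=totals)

    N = config.N if config.N is not None else input_size
    if N is None:
        raise BackgroundError(
            "Z mode needs N (windows per bootstrap set): set config.N or "
            "pass input_size"
        )
    if N < 1 or config.T < 1:
        raise BackgroundError("T and N must be >= 1")
    without = pool.size >= N
    if not without:
        warnings.warn(
            f"bootstrap sets of {N} windows from a pool of {pool.size}: "
            "sampling with replacement within sets", stacklevel=2,
        )
    T = config.T
    freqs = np.empty((T, L, len(symbols)), dtype=float)
    for t in range(T):
        anchors = rng.choice(pool, size=N, replace=not without)
        counts, totals = count_windows(pool_obj.windows_at(anchors), M)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[t] = np.where(totals[:, None] > 0,
                                counts / np.maximum(totals[:, None], 1),
                                np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(freqs, axis=0)
    se = bootstrap_se(mean, N)
    return BackgroundModel(
        config, scheme.name, symbols, mean_freq=mean, se=se,
        bootstrap_freqs=freqs if keep_bootstrap else None,
    )


def background_from_windows(
    windows: list[str],
    scheme: GroupingScheme | str = "identity",
    upstream: int | None = None,
    downstream: int | None = None,
    anchor_column: int | None = None,
) -> BackgroundModel:
    """Fisher-mode background built directly from a supplied window set.

    Used when the background is itself an aligned peptide collection — e.g.
    comparing one kinase's substrate windows against another kinase's.
    """
    if not windows:
        raise BackgroundError("no background windows supplied")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise BackgroundError("background windows are not equal length")
    if anchor_column is None:
        anchor_column = upstream if upstream is not None else L // 2
    up = anchor_column
    down = L - 1 - anchor_column
    config = BackgroundConfig(
        proteome_space="wholeProteome", positional_space="anywhere",
        upstream=up, downstream=down, test_mode="fisher",
    )
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    codes = np.stack([encode_residues(w) for w in windows])
    counts, totals = count_windows(codes, scheme.member_index())
    return BackgroundModel(config, scheme.name, scheme.symbols,
                           counts=counts, totals=totals)
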