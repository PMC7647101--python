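"""Synthetic proteomes and peptide sets with known statistical structure.

These generators provide the controlled inputs the test suite and the
reproduction script run on: an i.i.d. random proteome with specified residue
frequencies, peptide windows with planted per-position enrichments or
depletions, and null windows drawn exactly like the unanchored background
sampler (for type-I calibration).  They are statistical fixtures — no
protease chemistry or kinase biology is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background import BackgroundConfig, sample_windows
from .peptides import PeptideSet
from .proteome import STANDARD_AA, Proteome

#: Uniform residue frequencies (1/20 each), the default baseline.
UNIFORM_AA_FREQS = np.full(20, 0.05)

#: Approximate proteome-wide residue frequencies of the human proteome
#: (order = alphabetical one-letter codes ACDEFGHIKLMNPQRSTVWY), rounded from
#: published large-scale averages (UniProt human reference statistics);
#: offered for more realistic nulls, never required by the tests.
HUMAN_AA_FREQS = np.array([
    0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.057, 0.100,
    0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.027,
])
HUMAN_AA_FREQS = HUMAN_AA_FREQS / HUMAN_AA_FREQS.sum()


class SimulationError(ValueError):
    """Raised for infeasible simulation specifications."""


def _check_freqs(aa_freqs) -> np.ndarray:
    f = np.asarray(aa_freqs, dtype=float)
    if f.shape != (20,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise SimulationError(
            "aa_freqs must be a length-20 non-negative vector summing to 1"
        )
    return f


def synth_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 800),
    aa_freqs=UNIFORM_AA_FREQS,
    seed: int = 0,
    species: str = "synthetic",
) -> Proteome:
    """Generate a random proteome of i.i.d. residues.

    Protein lengths are uniform over ``length_range`` (inclusive); residues
    are drawn i.i.d. from ``aa_freqs`` (alphabetical AA order).  Deterministic
    under ``seed``.
    """
    f = _check_freqs(aa_freqs)
    if n_proteins < 1:
        raise SimulationError("n_proteins must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise SimulationError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(STANDARD_AA.encode("ascii"), dtype=np.uint8)
    records = []
    width = len(str(n_proteins))
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(20, size=length, p=f)
        records.append((f"syn{i + 1:0{width}d}", bytes(aa[codes]).decode()))
    return Proteome(records, species=species, source=f"synth(seed={seed})")


@dataclass
class MotifSpec:
    """Description of planted per-position effects in a peptide set.

    ``effects`` lists ``(column, symbol, target_frequency)`` triples:
    at that 0-based column the residue ``symbol`` is drawn with exactly
    ``target_frequency``; the remaining mass follows ``baseline`` renormalised
    over the non-planted residues.  A target of 0 plants a depletion.
    """

    L: int
    anchor_column: int
    effects: list[tuple[int, str, float]] = field(default_factory=list)
    baseline: np.ndarray = field(default_factory=lambda: UNIFORM_AA_FREQS.copy())

    def __post_init__(self) -> None:
        self.baseline = _check_freqs(self.baseline)
        if not 0 <= self.anchor_column < self.L:
            raise SimulationError("anchor_column outside window")
        per_col: dict[int, float] = {}
        for col, sym, tgt in self.effects:
            if not 0 <= col < self.L:
                raise SimulationError(f"effect column {col} outside window")
            if sym not in STANDARD_AA:
                raise SimulationError(f"effect symbol {sym!r} is not a "
                                      "standard amino acid")
            if not 0 <= tgt <= 1:
                raise SimulationError(f"target frequency {tgt} outside [0,1]")
            per_col[col] = per_col.get(col, 0.0) + tgt
        for col, tot in per_col.items():
            if tot > 1 + 1e-12:
                raise SimulationError(
                    f"target frequencies at column {col} sum to {tot} > 1"
                )

    def column_distribution(self, col: int) -> np.ndarray:
        """Residue distribution at one column (the generating law)."""
        planted = [(s, t) for c, s, t in self.effects if c == col]
        if not planted:
            return self.baseline
        dist = np.zeros(20)
        idx = {aa: i for i, aa in enumerate(STANDARD_AA)}
        rest = self.baseline.copy()
        for sym, tgt in planted:
            dist[idx[sym]] = tgt
            rest[idx[sym]] = 0.0
        free = 1.0 - sum(t for _, t in planted)
        if rest.sum() == 0 and free > 1e-12:
            raise SimulationError(
                f"column {col}: no residues left to carry remaining mass"
            )
        if free > 0:
            dist += rest / rest.sum() * free
        return dist


def plant_motif_peptides(
    spec: MotifSpec, n: int, seed: int = 0
) -> tuple[PeptideSet, pd.DataFrame]:
    """Draw ``n`` windows with the planted effects of ``spec``.

    Returns the peptide set and a truth table of planted
    ``(column, symbol, target, baseline, direction)`` rows; direction is
    "enriched" when the target exceeds the baseline frequency of the symbol,
    "depleted" otherwise.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(STANDARD_AA.encode("ascii"), dtype=np.uint8)
    cols = []
    for col in range(spec.L):
        dist = spec.column_distribution(col)
        cols.append(rng.choice(20, size=n, p=dist))
    codes = np.stack(cols, axis=1)
    windows = [bytes(aa[row]).decode() for row in codes]
    idx = {a: i for i, a in enumerate(STANDARD_AA)}
    truth = pd.DataFrame(
        [
            {
                "column": col,
                "symbol": sym,
                "target": tgt,
                "baseline": spec.baseline[idx[sym]],
                "direction": "enriched" if tgt > spec.baseline[idx[sym]]
                             else "depleted",
            }
            for col, sym, tgt in spec.effects
        ],
        columns=["column", "symbol", "target", "baseline", "direction"],
    )
    pset = PeptideSet(windows, spec.anchor_column,
                      spec.L - 1 - spec.anchor_column,
                      source_ids=[f"sim{i + 1}" for i in range(n)])
    return pset, truth


def null_peptides(
    proteome: Proteome, n: int, L: int, seed: int = 0
) -> PeptideSet:
    """Sample ``n`` windows exactly as the anywhere-unanchored background
    sampler does — the null for type-I calibration of the DAU tests."""
    upstream = (L - 1) // 2
    downstream = L - 1 - upstream
    config = BackgroundConfig(
        proteome_space="wholeProteome", positional_space="anywhere",
        upstream=upstream, downstream=downstream, test_mode="fisher",
    )
    rng = np.random.default_rng(seed)
    windows = sample_windows(proteome, config, n, rng)
    return PeptideSet(windows, upstream, downstream,
                      source_ids=[f"null{i + 1}" for i in range(n)])


def write_fixture(
    proteome: Proteome,
    peptides: PeptideSet,
    out_dir,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a fixture to disk: proteome FASTA, window TSV, optional truth
    TSV — so tests can exercise the real I/O paths."""
    from .proteome import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"proteome": out / "proteome.fasta",
             "peptides": out / "peptides.tsv"}
    write_fasta(proteome, paths["proteome"])
    pd.DataFrame({
        "protein_id": peptides.source_ids or
                      [f"w{i + 1}" for i in range(len(peptides))],
        "window": peptides.windows,
    }).to_csv(paths["peptides"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
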