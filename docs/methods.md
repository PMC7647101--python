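# Methods

## Model and procedure

`pepdau` tests, per window position `l` and alphabet symbol `s`, whether the
input peptide set uses `s` at `l` more or less often than a background model
predicts. The input is a set of equal-length windows aligned on an anchoring
residue; windows that overrun a protein terminus are padded with `X`.

**Background models.** A background is defined by three orthogonal choices:
the proteome-level space (`wholeProteome`, `inputSet` — only proteins
contributing input peptides, `nonInputSet` — their complement), the
position-level space (`nterm`, `cterm`, `anywhere`), and, for `anywhere`,
whether sampled windows are anchored on a residue set. That yields twelve
valid configurations (3 × 4). Terminal spaces take one window per protein,
anchored at the first/last residue; `anywhere` draws anchors uniformly over
eligible residues.

**Z mode (bootstrap).** `T` background sets of `N` windows are drawn. Per
set, per position, symbol frequencies `p_lt` are computed; the model stores
their mean `p̄_l = Σ_t p_lt / T` and the binomial standard error
`s_l = sqrt(p̄_l (1 − p̄_l) / N)`. The test statistic is
`Z = (p_l − p̄_l) / s_l` with a two-sided standard-normal p-value. The
implicit assumptions: input windows are independent draws, `N` is large
enough for the normal approximation to the binomial, and the bootstrap mean
estimates the sampling-space frequency (its own Monte-Carlo error is
`O(1/sqrt(TN))` and is neglected by the test). `s_l` uses the `p(1−p)/N`
binomial variance of a proportion, not the `p/N` form found in some earlier
logo software.

**Fisher mode (exact).** One exhaustive background set is collected (every
eligible window; optionally capped by uniform subsampling, for very large
proteomes). Each cell's 2×2 table — input symbol count `a`, input
countable total − `a`, background count `c`, background total − `c` — is
tested two-sided by the point-probability convention: the p-value is the
sum of hypergeometric point probabilities (margins fixed) not exceeding
that of the observed table. Two-sided conventions differ between software
packages; this one matches `scipy.stats.fisher_exact`.

**Reduced alphabets.** A grouping scheme is a total partition of the 20
standard amino acids; collapsing happens *before* any frequency
computation, so group counts are exact sums of member counts and results on
the reduced alphabet are identical whichever route (collapse-then-count or
count-then-pool) produced them. Built-ins: 3-class hydrophobicity
(hydrophobic WFYLIVMC / neutral HATPGNSQ / hydrophilic RKDE), 3-class
charge at physiological pH (HKR / DE / rest), 5-class side-chain size (GSA
/ DNCEH / RQKT / MPYF / ILVW). One membership decision was forced: the
published hydrophobicity grouping we follow lists the neutral class with a
duplicated alanine and no glutamine, which cannot partition 20 residues;
glutamine is placed in the neutral class and the duplicate read as a typo.
Groupings by isoelectric point, polarity, bulkiness, volume, consensus
similarity or substitutability are property-table choices with no single
canonical membership; they load as custom schemes (JSON or
`register_scheme`) rather than shipping hard-coded.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `upstream`, `downstream` | 7, 7 | window extent around the anchor (15-mer), the common phosphosite convention; protease studies use 14/15 (P15–P15′) |
| `T` | 300 | bootstrap sets; mean's MC error shrinks as `1/sqrt(T)` |
| `N` | input-set size | windows per bootstrap set; the Z-test is calibrated when `N` matches the input size, since `s_l` then matches the input frequency's sampling SD |
| `alpha` | 0.05 | per-cell significance level, raw p-values |
| `adjust` | none | optional Benjamini–Hochberg across cells (`adjust="bh"`) |
| `max_windows` | none | Fisher-mode cap on background size |
| `rng_seed` | 0 | single seeded generator for all sampling; recorded in the model |

No multiple-testing adjustment is applied by default: each cell is tested
at `alpha` as is conventional for logo displays, and the BH option is there
for users who want family-wise control across the `L × |symbols|` cells.

## Numerical and edge-case choices

- **Padding and non-standard residues.** `X` padding and the non-standard
  symbols `U B Z *` (retained on FASTA ingest so that backgrounds are not
  biased by dropping whole proteins) are excluded from both numerator and
  denominator of every frequency, position-wise. A column whose countable
  total is zero is reported as a row of NA cells, never dropped from the
  result shape. Anchors must be standard residues.
- **Sampling replacement.** Background anchors are drawn without
  replacement within a bootstrap set when the pool allows, with replacement
  (and a warning) otherwise; sets are independent of each other.
- **Fisher arithmetic.** Tables with total ≤ 2000 are evaluated in exact
  integer arithmetic (binomial-coefficient weights, rational division), so
  ties are exact; larger tables switch to log-space summation with a 1e-7
  relative tie tolerance, the same guard scipy uses. Zero-margin tables
  return p = 1 and are flagged. The sample odds ratio is reported as
  `ad/bc` (infinite when only `bc` vanishes, undefined when both products
  do); any continuity correction is a display concern, not part of testing.
- **Degenerate Z cells.** `s_l = 0` with `p ≠ p̄` yields `Z = ±inf`,
  p = 0, and a `degenerate` flag; `p = p̄` yields `Z = 0`, p = 1.
- **Anchor column.** Tested like any other column — anchored *input* sets
  are trivially enriched there unless the background is anchored on the
  same residues, which is exactly the comparison the anchored background
  models exist for.
- **Logo rendering.** Only significant cells are drawn; letter height is
  the frequency difference in percentage points (|diff|·100), largest
  nearest the axis, under-represented mirrored below; a `-log10 p` height
  metric is available. This is a display choice — the test itself defines
  significance. SVG output suppresses timestamps so identical results
  render byte-identically.
- **Determinism.** Same seed + same configuration reproduces bit-identical
  background models, result tables and SVGs. Z-mode matrices serialise
  rounded to 12 significant digits, which is what makes the JSON
  round-trip byte-stable.

## What the synthetic generator does and does not emulate

`synth_proteome` draws i.i.d. residues (uniform by default; a human-like
frequency vector is provided), `plant_motif_peptides` draws window columns
independently with exact planted target frequencies, and `null_peptides`
samples windows exactly as the unanchored background sampler does. This
gives fixtures with *known truth*: planted effect sizes, exact baseline
frequencies, and nulls that are null by construction. Real proteomes are
not i.i.d. — they have compositional autocorrelation, low-complexity
regions, homologous (non-independent) proteins, and input sets share
evolutionary structure. Passing tests therefore demonstrate statistical
correctness of the machinery (calibration, recovery, exactness), not that
any particular biological dataset satisfies the tests' independence
assumptions.

Test and reproduction problem sizes mirror the package defaults: input sets
of 400–416 windows of 15 or 30 residues, backgrounds of `T = 300` sets, 
synthetic proteomes of 100–200 proteins of 300–700 residues. These sizes
give the planted-signal Z-scores (~50–70) and calibration bands the suite
asserts.

## Known limitations

- The Z-test treats `p̄` and `s_l` as known; for small inputs or rare
  symbols the normal approximation is poor and Fisher mode should be used
  (the cross-method concordance degrades exactly where expected: cells with
  expected counts near zero).
- Z-mode and Fisher-mode backgrounds estimated from the same proteome
  differ by Monte-Carlo noise in the mean; cells whose input frequency sits
  within that noise of the background can flip the *sign* of their
  (near-zero, insignificant) difference between methods. Concordance is
  therefore meaningful for significant cells only.
- Proteome retrieval is local FASTA only; no network access.
- Fisher mode on a whole mammalian proteome without `max_windows` is exact
  but slow by design; the cap trades exactness of the background census for
  time without affecting the test's validity.
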