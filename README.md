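# pepdau

Differential amino-acid (and amino-acid-group) usage analysis of anchored
peptide sets, with significance-aware sequence logos and heatmaps.

## The problem

Many proteomics experiments produce a set of short peptide sequences aligned
on a biologically meaningful *anchoring residue*: the P1 position of protease
substrates, the phosphorylated Ser/Thr of kinase substrates, the mature
N-terminus of acetylated proteins. The question is always the same — at each
position of the window, which residues (or residue classes such as "acidic"
or "tiny") occur more or less often than chance?

"Chance" is the crux. A sensible answer needs a background model that matches
the experiment: the whole proteome or only the proteins the peptides came
from; windows drawn from anywhere in a protein, from N-/C-termini only, or
anchored on the same residue as the input. `pepdau` builds any of the twelve
combinations of these choices and tests each (position, symbol) cell of the
input against it, either with a bootstrap Z-test or with Fisher's exact test.

## The statistic

For the Z-test, `T` background sets of `N` windows are drawn (bootstrap).
With `p_lt` the frequency of a symbol at position `l` in bootstrap set `t`:

    p̄_l = Σ_t p_lt / T
    s_l  = sqrt( p̄_l (1 − p̄_l) / N )        # binomial SE of a proportion
    Z    = (p_l − p̄_l) / s_l                # input frequency p_l

referred to the standard normal, two-sided. Note the SE is `p(1−p)/N`, the
correct binomial variance — not `p/N`, a form that has appeared in earlier
logo tools. For Fisher's exact test, a single exhaustive background set is
collected and each cell's 2×2 table (symbol/other × input/background) gets
an exact two-sided p-value by the point-probability convention, computed in
exact integer arithmetic for small tables.

Both tests run either on the 20-letter alphabet or on a *reduced alphabet*
that pools residues of similar physicochemical character (built-ins:
3-class hydrophobicity, 3-class charge, 5-class size; custom partitions via
JSON or `register_scheme`). Pooling raises power for group-level
preferences that single residues do not show. Padding (`X`, used where a
window overruns a protein terminus) is excluded from every numerator and
denominator.

## Worked example

```python
from pepdau import (BackgroundConfig, MotifSpec, build_background,
                    plant_motif_peptides, synth_proteome, test_dau)

# a synthetic proteome and 416 15-mer windows with a planted aspartate
# enrichment at the anchor (target frequency 0.6) and a lysine depletion
proteome = synth_proteome(200, (300, 700), seed=7)
spec = MotifSpec(L=15, anchor_column=7, effects=[(7, "D", 0.6), (5, "K", 0.0)])
peptides, truth = plant_motif_peptides(spec, 416, seed=8)

# bootstrap background: 300 sets of 416 windows sampled anywhere in the proteome
config = BackgroundConfig(upstream=7, downstream=7, T=300, N=416, rng_seed=9)
background = build_background(proteome, config, "identity")
result = test_dau(peptides, background, "identity", alpha=0.05)

df = result.to_dataframe()
print(df[df.significant].nsmallest(4, "p_value").to_string(index=False))
```

prints

```
 position symbol      diff  statistic  p_value  significant    na
        0      D  0.508622  46.948489 0.000000         True False
       -2      K -0.048888  -4.624169 0.000004         True False
        0      F -0.041554  -3.935159 0.000083         True False
        0      Y -0.037107  -3.501766 0.000462         True False
```

The planted aspartate dominates its column (observed frequency ≈ 0.56 vs a
background of ≈ 0.05, Z ≈ 47); the planted lysine depletion at position −2
is recovered with a significant negative difference; the weaker calls at the
anchor are the mass the enrichment displaced. `render_logo(result,
"logo.svg")` draws the significant cells as a logo (over-represented above
the axis, under-represented below, letter heights in percentage points);
`render_heatmap(result, "heatmap.svg")` shows the full Z-score matrix.

The same workflow is available from the shell:

```
pepdau simulate --n-proteins 200 --n-peptides 416 -L 15 --plant 7:D:0.6 \
       --seed 7 --out fixture/
pepdau run --proteome fixture/proteome.fasta --windows fixture/peptides.tsv \
       --seed 9 --out results/
```

which writes `dau.tsv`, `dau.json`, `background.json`, `logo.svg`,
`heatmap.svg` and the resolved run configuration.

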