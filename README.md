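# chromocline

Positional gradients in molecular evolutionary rates, pairwise dN/dS
estimation, and depth-based sex chromosome identification.

## The problem

In comparisons of orthologous protein-coding genes between two related
genomes, the synonymous substitution rate (dS) is not uniform: rates (and GC
content) are elevated near chromosome ends and decay toward the centers — a
within-chromosome gradient we call a **chromocline**. Because short
chromosomes consist mostly of end-proximal sequence, per-chromosome median
dS then correlates negatively with chromosome length even when length has no
intrinsic effect: the classical chromosome-length effect can be purely
compositional. Separately, in XY systems, male-driven evolution predicts a
genome-wide reduction of neutral divergence on the X chromosome, independent
of gene position.

`chromocline` is for comparative genomicists who want to quantify and
disentangle these effects in a two-species ortholog set. It provides:

- **`dnds`** — pairwise NG86 estimation (Nei–Gojobori counting with
  Jukes–Cantor correction): per-codon site counts with S + N = 3 exactly,
  pathway-averaged difference counts (stop-codon pathways excluded), dS, dN,
  ω = dN/dS and total divergence t = 3·(S·dS + N·dN)/(S + N), plus the
  exclusion rules (divergence thresholds 0.01 ≤ t ≤ 2, removal of
  X/autosome-discordant "translocated" orthologs).
- **`orthofilter`** — selection of ortholog groups in which the two focal
  species form a single-copy sister pair, as an unrooted bipartition test
  (invariant to rerooting of the input gene trees).
- **`sexchrom`** — X / Y / pseudoautosomal-region identification from
  normalized female and male read-depth tracks (X: female:male ≈ 2;
  Y: male-restricted coverage; PAR: terminal runs of sex-balanced windows),
  via `DepthRatioModel(...).fit()`.
- **`cline`** — the positional-statistics battery via
  `ChromoclineModel(...).fit()`: chromosome-length regressions on log–log
  axes, per-chromosome distance-from-end slopes with sign/significance
  tallies, quadratic (U-shape) and LOESS fits along chromosomes, GC
  gradients, end/center positional subsets, and an X-vs-autosome
  randomization test (difference of medians, label permutation).
- **`synth`** — a fully seeded generator of karyotypes, gene positions and
  rates, codon sequence pairs of known divergence, male/female depth tracks,
  GC tracks and gene-tree fixtures, so the entire battery is testable with
  no external data.
- **`pipeline`** — `run_simulation_study` / `run_real_data` plus a
  `chromocline` CLI (`run-all`, `simulate`, `dnds`, `orthofilter`,
  `sexchrom`, `cline`).

## Worked example

```python
from chromocline import ClineParams, ChromoclineModel, pairwise_dnds, synth

# estimate dS/dN for one aligned codon pair of known divergence
s1, s2 = synth.simulate_codon_pair(true_ds=0.08, omega=0.25, n_codons=5000, seed=7)
est = pairwise_dnds(s1, s2)
print(f"dS={est.dS:.4f}  dN={est.dN:.4f}  omega={est.omega:.3f}  t={est.t:.4f}")
# dS=0.0771  dN=0.0171  omega=0.222  t=0.0959

# run the positional battery on a synthetic shark-like genome
karyotype = synth.simulate_karyotype(51, 3.97e6, 185e6, x_rank=40, seed=1, x_len=21e6)
genes = synth.simulate_gene_rates(karyotype, ClineParams(), genes_per_mb=3.6, seed=1)
res = ChromoclineModel(genes, karyotype).fit(n_perm=10_000, seed=1)
print(res.summary())
```

The summary (abridged) reads:

```
median dS across chromosomes: 0.05087 to 0.1278

Length effect (log10 median rate ~ log10 length):
  [all   ] ds    slope=-0.137 (SE 0.013) p=1.26e-14 * (n=51)
  [ends  ] ds    slope=-0.010 (SE 0.014) p=0.472 ns (n=51)
  [center] ds    slope=-0.145 (SE 0.019) p=1.35e-09 * (n=51)

Distance-from-end gradients (per-chromosome dS slopes):
  51 of 51 chromosomes negative (45 significant); 0 positive (0 significant)

X vs autosomes (randomization, 10000 permutations):
  [all ] ds    diff=-0.01179 p=0.0005 (n_X=86)
  [all ] dn    diff=-0.002222 p=0.2392 (n_X=86)
  [ends] ds    diff=-0.02563 p=9.999e-05 (n_X=52)
```

Reading the output: every chromosome shows dS falling with distance from its
ends; median dS falls with chromosome length on all genes (slope −0.137,
p ≈ 1e-14) but the effect **vanishes** when genes are restricted to within
5 Mb of chromosome ends (p = 0.47) and **persists** in the central 10 Mb
(p ≈ 1e-9) — the length effect is positional composition, not chromosome
size. The X chromosome's dS is reduced relative to autosomes both overall
(p = 0.0005) and among end-proximal genes only (p = 1e-4), while dN is not
(p = 0.24): a genome-wide, position-independent reduction of the neutral
rate on the X, as male-driven evolution predicts.

`res.plot_length_effect()`, `res.plot_chromosome("chr9")` and
`res.plot_x_boxplot()` draw the corresponding panels;
`DepthRatioModel(female, male, lengths).fit().summary()` does the same for
the depth-based sex-chromosome scan.

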