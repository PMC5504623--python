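# segcorr

Detection of chromosomal regions of correlated gene expression.

Neighbouring genes along a chromosome are often co-expressed across
patients: sometimes because of a baseline "background" correlation that
exists genome-wide, sometimes because a shared mechanism — a copy-number
alteration, an epigenetic mark such as DNA methylation, a common
transcription factor — drives a whole block of genes together.  `segcorr`
finds those blocks and decides whether their correlation significantly
exceeds the background, and can first remove the part of the correlation
explained by a measured cause (copy-number variation from SNP arrays), so
that what remains points at *unexplained* regulation.

## The model and the method

Patient expression profiles (rows of the `n × p` matrix `Y`, genes ordered
along the genome and standardized so that `YᵀY/n` has unit diagonal) are
modelled as i.i.d. Gaussian vectors with a **block-diagonal correlation
matrix**: the genes of a chromosome split into `K` contiguous regions, and
within region `k` every pair of genes shares one correlation `ρ_k`
(compound symmetry); genes in different regions are independent.

* **Segmentation.**  For fixed boundaries, the within-region MLE has a
  closed form, `ρ̂_k = (Σ_block Ĝ − p_k) / (p_k² − p_k)` with
  `Ĝ = YᵀY/n`, and so does the maximised likelihood,
  `−2L̂_k = n[p_k + (p_k−1)log(1−ρ̂_k) + log(1+(p_k−1)ρ̂_k)]`.
  Because the likelihood is additive over regions, the globally optimal
  boundaries for every `K` are found exactly by dynamic programming in
  `O(Kp²)`, with each block's Gram sum obtained in `O(n)` from per-patient
  prefix sums.
* **Model selection.**  `K` is chosen by a slope heuristic: the normalized
  criterion `L̃_K` (rescaled with the penalty `K̃_j = 5j + 2j·log(p/j)`)
  is scanned for the largest `K` whose slope change exceeds a threshold
  `S` (default 0.7).
* **Exact test.**  For a region of `p_k` genes,
  `T_k = Σ_i (Ȳ_i − Ȳ)²` (within-region patient means) follows
  `λ(p_k, ρ_k)·χ²_{n−1}` with `λ(p, ρ) = (1+(p−1)ρ)/p` — exactly, with no
  resampling.  Each region is tested one-sided against the chromosome's
  background correlation `ρ0`, estimated robustly as the absolute median
  of adjacent-gene correlations; p-values are adjusted genome-wide
  (Benjamini–Hochberg by default).  Power has the closed form
  `Po = Pr{Z > (λ(p0,ρ0)/λ(p0,ρ))·q_{n−1,1−α}}`.
* **CNV correction.**  Each patient's SNP-array signal is segmented into
  piecewise-constant copy-number levels (exact least-squares DP, same
  slope heuristic), the fitted levels are mapped onto genes (averaging
  probes inside a gene, interpolating at the gene midpoint otherwise),
  and log-scale expression is regressed on this covariate
  (`Y_ij = β0 + β1·x_ij + ε`); the re-standardized residuals feed the
  segmentation.

## Worked example

Simulate one 500-gene chromosome with four planted regions (lengths 5, 10,
20, 40; within-region correlation 0.7 over a 0.08 background) for 100
patients, then run the pipeline:

```bash
segcorr simulate --scenario 1 --rho0 0.08 --rho1 0.7 --n 100 --seed 42 --out sim
segcorr run --expr sim.expr.tsv --bed sim.genes.bed --no-correct --no-log --out regions.tsv
```

`regions.tsv` (condensed):

```
chromosome  first  last  p_k  rho_k    T_k     pvalue    adj_pvalue  significant
chr1          1    100   100  0.051    6.08   9.76e-01    9.96e-01   False
chr1        101    105     5  0.736   78.87   9.83e-23    2.21e-22   True
chr1        106    200    95  0.045    5.52   9.96e-01    9.96e-01   False
chr1        201    210    10  0.662   69.60   9.58e-41    2.88e-40   True
chr1        211    300    90  0.047    5.79   9.91e-01    9.96e-01   False
chr1        301    320    20  0.695   71.01   5.83e-71    2.62e-70   True
chr1        321    400    80  0.055    6.73   9.35e-01    9.96e-01   False
chr1        401    440    40  0.644   65.33   4.65e-86    4.18e-85   True
chr1        441    500    60  0.049    6.46   9.80e-01    9.96e-01   False
```

All four planted regions are recovered at their exact boundaries, with
`ρ̂_k` close to the simulated 0.7, and only they are significant; the
background stretches show `ρ̂ ≈ 0.05` and p-values near 1.  The run
summary (`regions.tsv.summary.json`) records per-chromosome `K̂` and
`ρ̂0`.  The analytic power of the test is available directly:

```bash
$ segcorr power --n 100 --p0 3 --rho 0.7 --rho0 0.15
0.994673
```

Other subcommands: `segment`, `test`, `correct` (CNV regression),
`evaluate` (gene/region-level TPR, FPR, AUC against a simulation truth),
`scan-s` (stability of detected regions across the selection threshold).
The same functionality is available as a library (`segcorr.simulate`,
`segcorr.analyze_expression`, `segcorr.run_benchmark`, ...).

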