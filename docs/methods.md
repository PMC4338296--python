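# Methods

## Measurement model

A paired design splits one DNA sample into 2r aliquots: r through bisulfite
(BS) conversion and r through oxidative bisulfite (oxBS), each hybridised
to an Infinium-style array. Unmodified C converts (reads as T); 5mC resists
both chemistries; 5hmC resists BS but is oxidised to 5fC — which converts —
under oxBS. Writing the per-probe true fractions (c, m, h) with
c + m + h = 1:

- BS arm expected beta: m + h
- oxBS arm expected beta: m

The subtraction estimator averages betas within each arm and takes
ĥ = β̄_BS − β̄_oxBS, m̂ = β̄_oxBS, ĉ = 1 − β̄_BS. The three estimates sum to
one identically. ĥ may be negative; negatives are retained as a noise
diagnostic rather than clamped, and constrained joint estimation of
(c, m, h) is deliberately out of scope.

## Synthetic data generator

The generator is first-class, tested code: every downstream stage is
exercised against known truth without any external download.

**Genome and truth.** One synthetic chromosome is tiled with genes (5'UTR /
exon / intron / 3'UTR structure, random strand) separated by intergenic
gaps; CpG islands sit at 60% of TSSs plus occasional intergenic sites.
Probes are placed uniformly and annotated by the package's own interval
annotators. True 5mC is drawn per context (Beta distributions: islands
lowest, TSS-proximal low, gene bodies high, open sea intermediate, clipped
to [0.01, 0.98] to keep betas off the boundary). A fraction π₀ = 0.7 of
probes carries exactly zero 5hmC; the *probability* of a nonzero draw is
region-weighted (islands 0.3× … gene bodies 1.3×, rescaled by bisection so
the overall nonzero fraction equals 1 − π₀ exactly), while nonzero levels
come from one distribution everywhere (default uniform on [0.005, 0.45]).
This reproduces two observed features at once: positive-probe proportions
differ strongly by region, while the level distribution among positives is
similar across regions.

**Noise and intensities.** Per-probe beta-scale noise SD is drawn uniform
on [0.005, 0.05]. Replicate noise is injected on the logit scale with SD
s_logit = sd/(b(1−b)) (delta method; b clamped to [0.02, 0.98]) and the
perturbation is mean-centred *numerically* (Gauss–Hermite quadrature +
Newton on the logit shift) so that E[β_noisy] = β exactly — an uncentred
logit-normal is skewed and would bias high-beta probes downward. Each
probe × array cell draws a total intensity T ~ Gamma(mean 5000, CV 0.2)
and splits it as M = Tβ_noisy, U = T(1−β_noisy); with probability 0.002 a
cell is replaced by a background-level draw (mean 200, SD 50), emulating
hybridisation failure. Negative-control probes are pure background on
every array. All draws descend from a single seed; identical configs give
bit-identical outputs, including on-disk TSV/BED fixtures.

**Calibration.** With these defaults the between-replicate beta
correlations land at ≈ 97–98 (×100) within each arm, bracketing the
reproducibility of real replicate arrays (high 96s–98s).

## Preprocessing

Order: SWAN-style normalization of intensities → detection filtering
(against the *raw* negative-control background) → betas.

- **Beta:** β = M/(M + U + α) with α = 100 intensity units (platform
  convention; zero-signal cells return 0). Note the offset attenuates
  betas multiplicatively by E[T/(T + α)] ≈ 0.98 at the default intensity
  scale — a stabilisation-vs-bias tradeoff inherited from the platform,
  worth remembering when interpreting absolute levels (≈ −0.46 points on a
  23% 5hmC level). Estimator-calibration checks therefore run at α = 0.
- **Detection:** per array, background total-intensity Gaussian with
  μ_bg = mean(M_neg) + mean(U_neg), σ_bg = sd(M_neg) + sd(U_neg); the
  detection p-value is the upper tail at M + U. A cell *fails* when
  p ≥ 0.01 (low p = real signal); probes failing in more than one array are
  excluded. The filter rule is sometimes phrased with the inequality
  inverted ("detection p < 0.01 in more than one array excluded"); the
  standard-convention reading (p ≥ 0.01 marks failure) is the default and
  a switch exposes the literal one.
- **SWAN:** per array and channel, random CpG-content-matched (1/2/3+)
  equal-count subsets of Type I and Type II probes are drawn; the reference
  distribution is the pointwise mean of the two subsets' sorted
  intensities; subset probes map by rank, non-subset probes by linear
  interpolation between flanking subset quantiles with a constant offset
  beyond the extremes, clipped at zero. Deterministic given its seed.
  Because the mapping is nonlinear, normalization can shift arm means by
  O(5·10⁻⁴) beta units — visible only as a tiny asymmetry in null
  subtraction estimates; the null-symmetry check therefore runs on raw
  betas.

## Differential testing

Pooled two-group model per probe on betas (not M-values — levels are
interpreted directly as modification fractions): s² with d = n₁ + n₂ − 2.
The prior is fitted by moment matching on e = log s² − ψ(d/2) + log(d/2):
the excess of var(e) over ψ′(d/2) gives d₀ via the trigamma inverse
(Newton, tolerance 1e-10, asymptotic start 0.5 + 1/y), and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)); no excess dispersion gives
d₀ = ∞ with s₀² = exp(mean(e)) (note for *constant* sample variances this
equals s²·(d/2)/e^{ψ(d/2)}, the χ² log-bias correction — not s² itself).
Zero variances are floored at 1e-8 before taking logs. The moderated
F = Δ²/(s̃²(1/n₁ + 1/n₂)) is referred to F(1, d + d₀) (χ²₁ at d₀ = ∞); at
d₀ = 0 it reproduces the classical pooled t² exactly. BH step-up is
implemented directly and cross-checked against brute force and
statsmodels. Significance: q < 0.01, signed by Δ.

## Regional annotation

Gene features come as BED6 rows (type in the name field) plus `gene` spans
whose strand defines 1 kb upstream/downstream flanks. Precedence for
probes under multiple features: 5'UTR > 3'UTR > exon > intron > upstream >
downstream; inside a gene span but no feature → *other*; nothing within a
gene ± flank → *intergenic*. Island context by gap distance to merged
islands: 0 → island, (0, 2000] → shore, (2000, 4000] → shelf, else open
sea (half-open on the outer edge; a probe one base past an island edge is
at distance 1). The TSS profile bins signed strand-aware distance
(negative = upstream) in 200 bp bins to ±4 kb.

## Replicate power and detection floor

Replicate subsets (default pairs {1,3} and {2,4} in both arms) are
re-analysed independently, including refitting the shrinkage prior —
mirroring a genuinely smaller experiment. Reported: significant counts per
analysis (both "any sign" and "positive only" accountings, since the two
differ), pair overlap, pair-only calls relative to the full analysis (these
occur at a rate consistent with the 1% FDR), and the detection floor — the
minimum estimated 5hmC among significant positive calls, restricted to
truly modified probes when simulator truth is available — plus a detection
power curve in 1% bins of true level.

## qPCR validation arithmetic

β-glucosyltransferase glucosylates 5hmC, protecting CCGG sites from MspI.
With amplification efficiency E (default 2.0, configurable per site) and
Cq values for glucosylated+digested, mock+digested and undigested
reactions, the surviving fractions are R_glu = E^−(Cq_glu−Cq_undig) and
R_mock = E^−(Cq_mock−Cq_undig), and the site's 5hmC fraction is
R_glu − R_mock (clamped to [−1, 1]); only ΔCq matters and technical
replicates are averaged on the Cq scale. The simulation helper selects a
27-site panel spanning 0–40% (negative array estimates included), converts
true levels + Gaussian noise (SD 0.02) exactly to Cq triplets with a 5%
mock-digestion background protection, and measures Pearson concordance;
true-zero sites come back centred on zero.

## Numerical and design choices

- Seeds: every stochastic component (simulation, SWAN subsets, qPCR panel)
  takes an explicit seed; the pipeline reruns byte-identically.
- Degenerate inputs: zero-signal betas return 0; all-zero variances raise;
  fewer than 2 replicates per arm raise; empty SWAN strata raise naming
  the stratum; sub-3-pair concordance reports r as absent.
- Problem sizes: the calibration study runs 100k probes (seconds on one
  CPU); power comparisons use 10 seeds × 15k probes; estimator-recovery
  checks 10k probes with noise SD uniform [0.005, 0.035] (mean 0.02) and
  the failure mechanism off, isolating estimator calibration from the
  detection filter's concern.

## Limitations

The generator emulates replicate noise, Type I/II design, detection
failures and regional structure, but not dye bias, batch effects, probe
cross-hybridisation, SNP-affected probes, or between-sample biological
variation — so passing calibration here certifies the *statistics* of the
pipeline under its stated noise model, not robustness to every artifact of
real arrays. The subtraction estimator ignores the sum-to-one constraint
(by design); constrained maximum-likelihood estimation would be the
natural extension. Absolute levels inherit the beta-offset attenuation
noted above.
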