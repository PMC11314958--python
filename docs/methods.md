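# Methods

## Problem setting

Postmortem cohort studies of Parkinson's disease (PD) relate structural
brain-network organization — estimated from diffusion MRI tractography as a
subject-level weighted connectivity matrix over a 225-region parcellation —
to regional neuropathology (Lewy body density, β-amyloid, phosphorylated
tau, neurofilament light chain, synaptophysin) and to global staging
systems (Braak α-synuclein, Braak NFT, Thal). This package implements the
downstream analysis of such a study: network topology, virtual-lesion
resilience, and covariate-adjusted rank-based inference. Everything
upstream (tractography, atlas registration, histology quantification) is
out of scope; the package consumes finished matrices and tables.

## Network measures

Connectomes are symmetric, non-negative, zero-diagonal weight matrices.
Each subject's matrix is thresholded independently to retain the
proportion `p = 0.20` of strongest connections (k = round(p·n(n−1)/2)
largest positive upper-triangular weights; ties at the cutoff broken by
row-major edge order; rounding half-away-from-zero) and binarized. A
config switch computes the proportion over nonzero rather than possible
edges.

On the binary graph:

* **Global efficiency** `GE = (1/(n(n−1))) Σ_{i≠j} 1/d(i,j)` with
  `1/∞ := 0`; distances by simultaneous breadth-first search (boolean
  frontier–adjacency products).
* **Clustering coefficient** `cc_i = 2t_i/(k_i(k_i−1))`, zero when
  `k_i < 2`, included in the unweighted mean over all nodes.
* **Eigenvector centrality**: entrywise non-negative leading eigenvector
  of the adjacency (dense symmetric eigendecomposition), Euclidean norm 1,
  sign fixed by the largest-magnitude entry. On disconnected graphs the
  vector localizes on the component with the largest spectral radius; a
  degenerate leading eigenvalue (isomorphic twin components) is resolved
  deterministically in favour of the component containing the smallest
  node index, with a log warning. Max-entry normalization is available as
  a config option.

**Virtual lesioning.** `ΔGE = GE_lesion − GE` for the failure of a single
region, computed independently per region on the intact thresholded graph.
The default "delete" mode removes the node's row/column so `GE_lesion`
averages over the remaining `(n−1)(n−2)` ordered pairs; a "zero" mode
masks the row/column while keeping `n`, which by construction strands
`2(n−1)` pairs (e.g., on K4 the two modes give ΔGE 0 and −0.5). Deletion
is the default because zeroing conflates masking with disconnection.
Re-thresholding after lesioning is deliberately not done. ΔGE can be
positive (removing a poorly connected node raises the mean inverse
distance).

## Statistical machinery

**Rank regression.** Group differences and adjusted correlations use
Jaeckel's rank-dispersion estimator with Wilcoxon scores: minimize
`D(β) = Σ_i a(R(e_i)) e_i`, `a(i) = √12(i/(n+1) − 1/2)`, equivalent to
minimizing `Σ_{i<j} |e_i − e_j|`. Minimization is coordinate descent with
exact weighted-median line minimization on the pairwise-difference form
(OLS warm start, sweep cap 500, dispersion tolerance 1e−8, Powell polish
as a fallback). The intercept is the median residual. Standard errors use
`τ̂²(X_cᵀX_c)⁻¹`, where `τ̂` estimates `1/(√12 ∫f²)` by a Gaussian-window
estimate of the density of pairwise residual differences at zero with
bandwidth `0.6·min(sd, IQR/1.349)·n^{−1/5}` and a `√(n/(n−p−1))`
degrees-of-freedom inflation. The bandwidth constant 0.6 (rather than the
usual 0.9) reflects that the pairwise-difference density is peaked at
zero; with 0.9 the estimator over-smooths and the test is conservative
(null rejection 0.039 instead of 0.049 at n=34, p=4 in our calibration).
Tests are t with df = n − p − 1.

**Group tests** regress each measure on [PD indicator, age, sex (M=1),
postmortem delay]; Cohen's d is reported on the raw values (conventional
standardized mean difference, sign PD − control). FDR (Benjamini–Hochberg)
is applied per metric family — 8 regional tests each for EC, CC and ΔGE,
and the 2 global measures — with a config switch for one joint family of
24. Every test is rerun excluding subjects flagged by a robust outlier
rule (|value − median| > 3 × 1.4826·MAD per group and region-metric; the
scaled MAD makes this a robust |z| > 3); both rows are always reported,
nothing is silently dropped.

**Deviation tests.** Control ΔGE is tested against median zero per region
with the Wilcoxon signed-rank test: exact null distribution for n ≤ 25
(dynamic programming over doubled average ranks, so midranks from ties are
handled exactly), normal approximation with tie and continuity corrections
above; FDR over the 8 regions.

**Partial Spearman.** x, y and covariates are rank-transformed (average
ranks), ranked x and y are residualized on ranked covariates + intercept
by least squares, and r_s is the Pearson correlation of the residuals with
a t approximation on df = n − 2 − #covariates. With no covariates this is
exactly classic Spearman ρ. Under strong confounding the rank-linear
partialling is imperfect and mildly inflates the null rejection rate; with
the moderate covariate effects of this design it is calibrated (~0.05–0.06
measured).

**Correlation families.** Pathology correlations (insula ΔGE vs the 5
markers in the insula, anterior cingulate and entorhinal cortex;
parahippocampal EC vs its own markers) run within-PD and across the whole
cohort, FDR over the 5 markers per family. Staging correlations (insula
ΔGE vs Braak α-synuclein, Braak NFT, Thal as numeric ordinals) run across
the combined cohort with age/sex/PMD covariates, FDR over the 3 systems;
clinical correlations use postmortem delay as the only covariate. Each
test is try/reported independently (a constant staging vector, for
example, errors only its own row). Missing clinical values (CDR is
available for 11 of 19 PD donors by design) lead to complete-case analysis
with the n reported per test.

Global pathology group differences are assessed with the same rank-based
test on region-averaged values rather than a linear mixed model; this is a
documented simplification of the package's scope.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes,
not tractography physics or histology imaging:

* **Base connectome** — 225 nodes in 8 contiguous modules; module centres
  uniform in the unit cube, nodes scattered around them (sd 0.12);
  expected weight `exp(−dist/0.35)·(1 + 1.5·same-module)` with log-normal
  noise (sd 0.20). After default thresholding the binary density is 0.20
  by construction of the thresholding rule. The 8 ROI labels are placed
  one per module. (The real atlas's label names are not bundled; the
  packaged ROI table uses synthetic right-hemisphere mnemonics.)
* **Subjects** — 15 controls / 19 PD; ages truncated-normal 73±9 / 81±7 in
  [50, 100]; postmortem delay uniform 5–11 h / 3.5–10.5 h; sexes 7M/8F and
  12M/7F; Braak α-synuclein counts 13×0, 1×1, 1×2 (controls) and 1×3,
  2×4, 16×(5 or 6) (PD); Braak NFT and Thal counts likewise drawn from
  fixed pools mirroring the emulated cohort table; disease duration
  uniform 8–23 y with 2 missing; CDR available for 11/19.
* **Reliance effect** — per PD subject, edges incident to the dorsal
  anterior insula node are multiplied by
  `ρ = 1 + κ·braak/6 + N(0, σ_ρ)` (floored at 0.05) and the whole matrix
  rescaled to conserve total weight; `κ = 0` switches the effect (and its
  noise) off exactly, giving the null configuration. Subject-level
  log-normal edge noise has sd 0.30.
* **Pathology** — Lewy body density is 0 for Braak ≤ 2 and Gamma
  distributed with mean `vulnerability·45·braak/6` (region vulnerability
  highest in entorhinal/parahippocampal/insula), clipped to [0, 80]
  LB/mm²; NfL load has mean 8% with a ×1.48 PD elevation in the
  parahippocampal gyrus only; Aβ and p-tau loads increase weakly with
  Thal phase and Braak NFT stage; synaptophysin density (~0.55 puncta/μm³)
  has no group effect. An optional `marker_dge_coupling` ties one marker
  to the subject's reliance factor for coupling-recovery experiments.

All randomness flows from one integer seed through `SeedSequence` child
streams keyed by (purpose, subject index), so adding a subject never
perturbs other subjects' draws and regeneration is byte-identical.

### Calibration of the default effect size

The defaults `κ = 1.0`, `σ_ρ = 0.5` were fixed by a one-off calibration at
the 60-node experiment scale: they yield ≈88% detection of the insula-ΔGE
group difference (p_FDR < 0.05 over the 8 ΔGE regions) and a mean
combined-cohort partial Spearman of Braak stage vs insula ΔGE of ≈ −0.65
(stored as `braak_dge_rho`, the value the recovery experiments check
against). A weaker effect matching the ≈ −0.40 correlation scale reported
in comparable postmortem work was examined and rejected: because simulated
Braak staging is bimodal (controls 0–2, PD 3–6), the combined-cohort
correlation is nearly the same statistic as the group contrast, and at
−0.40 the group test's detection rate falls to ≈50%, too low for a
generator whose purpose is to exercise the pipeline's positive path. At
the full 225-node scale the same defaults produce a stronger observed
correlation (≈ −0.8) because ΔGE is measured with less topological noise.

### What passing tests do and do not show

The generator reproduces the inferential *shape* of a real study: group
contrasts detectable under covariate adjustment, stage-coupled pathology,
null markers, missingness. Passing tests therefore validate the pipeline's
correctness and calibration, not any claim about real PD brains: real
connectomes have non-modular idiosyncratic topology, spatially correlated
noise, and unknown pathology–connectivity coupling, none of which are
modelled.

## Numerical and design choices

* Matrix asymmetries below 1e−6 on read are averaged away (tractography
  export artifacts); larger asymmetries are errors.
* Proportional thresholding counts possible (not nonzero) edges by
  default; both behaviours are exposed.
* Eigenvector centrality uses unit Euclidean norm (max-entry normalization
  available); group contrasts are invariant to the choice only if one
  convention is fixed package-wide.
* The replicated experiments run at 60 nodes (the statistical stages are
  scale-independent; the network stage is ~15× cheaper than at 225),
  with 600 null replicates and 200 effect replicates in the test suite
  and 300/100 in the acceptance script.
* results.json is serialized with sorted keys and NaN mapped to null, so
  end-to-end runs are byte-reproducible.

## Known limitations

* The τ̂ window estimator is calibrated for continuous responses; for
  heavily tied, clumpy metrics (some regional clustering coefficients at
  small network sizes) the regional test's type-I error can drift to
  ≈0.075 while the pooled rate over all regional tests stays ≈0.055.
* Confidence intervals for rank-fit coefficients are on the coefficient
  scale; no attempt is made to reproduce interval conventions of other
  software.
* Partial Spearman's rank-linear residualization under-corrects strong
  nonlinear confounding (see above).
* Single-node lesions only; no attack sequences, percolation analyses, or
  weighted-graph metric variants.
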