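# Methods

This note documents the models, numerical choices and known limitations of
each `cystkit` component, and what the synthetic-data generators do and do
not emulate.

## 3D cyst quantification (`cyst3d`)

**Model.** A well is an ordered stack of grayscale focal planes (default
spacing 150 µm; 28 planes in the emulated acquisition). Cysts are treated
as spheres: a cyst detected across consecutive planes is measured from its
largest cross-section, r = mean centroid-to-boundary radius of that
object, and V = 4/3·π·r³ (px³, or µm³ when a pixel size is supplied).

**Segmentation operator.** The acquisition protocol this emulates
specifies only that each plane "undergoes segmentation"; the operator here
is Gaussian smoothing (σ = 2 px) → local mean threshold (window 101 px,
raised by 10% of the plane's dynamic range) → hole filling → connected
components. Expressing the threshold offset as a fraction of the dynamic
range makes segmentation invariant to global contrast rescaling; the local
window makes it robust to uneven illumination. Components smaller than
50 px² are discarded before shape statistics. The operator is a
configuration object (`SegmentationConfig`) and can be replaced wholesale.
Parity with any particular historical script is not claimed — only
ground-truth recovery on synthetic stacks, which the test suite verifies
(count exact, volumes within 10% for R in roughly [20, 150] px).

**Shape statistics.** Radius statistics are computed over the 8-connected
inner border (pixels of the object with at least one 8-neighbour outside);
eccentricity is that of the second-central-moment ellipse,
sqrt(1 − (b/a)²), 0 for a perfect circle. Filter defaults — mean radius in
[15, 200] px, radius CV ≤ 0.2, eccentricity ≤ 0.75, all inclusive — are
configuration, not constants in logic. Border-touching objects are kept
but flagged, so either retention policy can be applied downstream.

**Linking.** Objects in consecutive planes are the same cyst when their
centroid distance is ≤ 0.5 × (r₁ + r₂); consecutive sections of one sphere
always satisfy this. Matching is greedy in ascending distance. Tracks may
span a single plane (small cysts falling between planes). By default no
detection gaps are allowed within a track; `LinkConfig.max_gap` relaxes
this. Axial spacing is expressed in the same pixel unit as in-plane radii
(5.5 px ≈ 150 µm at ~27 µm/px); it only affects how many planes a sphere
crosses, never the volume, which uses the in-plane radius alone.

**Degenerate inputs.** A blank (constant) plane segments to no objects;
an empty tissue mask is an error for the cyst index, as is cystic area
outside the tissue mask. The module contains no randomness.

## PD-Sig scoring and derivation (`signature`)

Normalization subtracts the per-sample arithmetic mean of the housekeeping
genes in log2 space (the geometric mean in linear space — standard ΔΔCt
practice). Ct input is handled as ΔCt = mean(Ct_HK) − Ct so that higher
always means more expressed. Per-gene log2FC is taken against the mean of
the reference samples (mock or PBS, selectable); the score is the
unweighted mean over the panel, and group scores average replicates.
Missing panel genes are a hard error naming the absentees.

Derivation: candidates must be seed-match targets, up in every anti-miR
contrast and down in every mimic contrast. The ranking statistic — mean
across contrasts of the rank of |log2FC| (rank 1 = largest) — and the
non-redundancy rule (symbol-level deduplication) are the simplest
defensible readings of a procedure whose exact statistic is not public;
both are isolated behind the function interface. Ties keep input order
(stable sort). If fewer than `n_select` candidates survive, all are
returned with `insufficient_candidates=True`.

## miPSA (`mipsa`)

score = log2(HMW_control / HMW_treated), pct = (1 − 2^(−score)) × 100.
The log2 form is a reconstruction: the assay's defining publication is
external, but all three published score/percent pairs (3.16 → 89,
2.58 → 83, 2.56 → 83) are consistent with this conversion at printed
precision, which the tests pin. Display rounding is half-up to integer
percent; full precision is retained in results. Optional normalization by
a control miRNA's HMW sum is implemented but off by default. Zero treated
HMW abundance (infinite displacement) is an error rather than ±inf.

## De-repression and improvement (`derepression`)

**Seed matching** implements canonical site types only: 7mer-m8
(reverse complement of miRNA positions 2–8), 7mer-A1 (positions 2–7
followed by A on the mRNA), 8mer (positions 2–8 followed by A). A 7mer-m8
followed by A counts once, as an 8mer. No 6mers, no context scoring; an
external target list (e.g., a TargetScan export) can replace the built-in
matcher everywhere an annotation is accepted.

**DE engine.** Deliberately simple: log2 CPM with pseudocount 0.5, Welch t
per gene, Benjamini–Hochberg adjustment (via statsmodels; an independent
brute-force step-up is the test oracle). It is a stand-in for a
full count-model engine and exists so that the comparative procedures are
self-contained; all downstream operations equally accept externally
produced contrast tables (gene, log2fc, p_value, fdr). Genes with zero
variance in both groups get p = 1. Under null NB simulations its type-I
error sits near 0.05 (the tests allow 0.05 ± 0.015, covering Monte-Carlo
error plus the Welch-on-log2CPM approximation at n = 8 per group).

**K-S test** is two-sided via `scipy.stats.ks_2samp`; `method="auto"` uses
the exact small-sample distribution where scipy supports it. The result
carries the median target-vs-non-target shift so the direction of
de-repression is explicit. Minimum group size defaults to 10.

**Improvement.** Dysregulated = disease-contrast FDR < 0.05 (the
|log2FC| > 0.5 threshold applies to the treated contrast only, where the
improved-gene count is defined). Improved additionally requires sign
reversal relative to the disease change — "improvement" means movement
back toward control — toggleable to magnitude-only. rho is Spearman over
the dysregulated set by default (`rho_over="all"` provided, since either
reading of the published procedure is possible). An empty dysregulated set
yields rho = NaN with `rho_defined=False`. Reproducing the published
improved-gene counts and rho values would require the deposited RNA-seq
dataset; that workflow is supported through the external-table loaders but
is not part of the test envelope.

## Dose-response (`doseresponse`)

The 4PL is fitted by bounded least squares in (log10 EC50, hill, top,
bottom); the EC50 SE comes from the Jacobian covariance by the delta
method. Initialization: asymptotes from the extreme-dose means, EC50 from
the dose nearest half-response, hill = 1. Both asymptotes are free by
default for robustness to partial curves; for background-subtracted,
control-normalized data (bottom ≈ 0, top ≈ 1 by construction) fixing them
via `fix_top`/`fix_bottom` is the appropriate and better-conditioned
choice, and is what the acceptance computation uses. Note the exact
symmetry (hill, top, bottom) ↔ (−hill, bottom, top): fits are unique as
curves, not as signed parameterizations. Non-convergence returns the best
iterate flagged `converged=False`; responses running against the fitted
direction by > 3 RMSE set a monotonicity warning.

## Noncompartmental PK (`pk_nca`)

Linear (not log-linear) trapezoid throughout — the simplest defensible
convention; Cmax/Tmax are the observed maximum (earliest on ties);
AUC_last integrates to the last quantifiable point. Below-LOQ values enter
as 0 and embedded zeros are retained. Terminal half-life: unweighted
log-linear regression over the terminal strictly-descending positive run
(≥ 3 points, starting no earlier than Tmax), reported absent when
r² < 0.8. Lambda-z point selection beyond this rule is deliberately not
automated.

## Synthetic-data generators (`synthgen`)

All randomness flows through one explicit integer seed per call
(`numpy.random.default_rng`); no global state. Identical seeds give
byte-identical outputs.

- **Image stacks**: spheres rendered per plane as filled disks of radius
  sqrt(R² − dz²) on a flat background, plus clutter placed to violate each
  filter rule — specks (radius), giant disks (radius max), bars
  (eccentricity), crosses (radius CV) — and additive Gaussian noise. Not
  emulated: brightfield optics, refraction, debris texture, uneven
  illumination, overlapping cysts. Passing tests therefore demonstrate
  correctness of the measurement chain, not segmentation performance on
  real micrographs.
- **Expression matrices**: per-gene baselines uniform in [6, 12] log2
  units; signature genes shift +effect under anti-miR and −effect under
  mimic; Gaussian log2 noise everywhere (default σ = 0.2, 4 replicates per
  arm). No batch effects or gene–gene correlation.
- **Polysome pairs**: treated HMW = control × (1 − inhibition); displaced
  mass is redistributed to the non-HMW fractions proportionally, so total
  abundance is conserved. Optional multiplicative lognormal noise.
- **Dose-response**: 4PL times mean-1 lognormal noise of given CV
  (σ² = ln(1 + CV²)).
- **Counts**: negative binomial with fixed dispersion (default 0.05),
  lognormal baseline abundances (median CPM ≈ library/n_genes), default
  library 10⁶, 8 samples per group. Dysregulated genes receive
  |log2FC| = lfc_min + |N(0, σ)| with random sign; the floor (default 1.0)
  keeps true dysregulation well separated from the detection thresholds, so
  the improved-gene count tracks rescue_fraction × detected dysregulated
  without being confounded by borderline power. Rescued genes move back by
  rescue_strength × their disease shift.
- **3'UTRs**: random site-free DNA backgrounds (300 nt) with at most one
  planted site per sequence; planting is verified against the classifier
  and re-drawn on accidental context collisions.
- **PK curves**: biexponential disposition with optional lognormal noise.

## Problem sizes used in the test envelope

Chosen to give stable statistics while keeping the suite quick: the
cyst-recovery scenario uses one 28 × 1280 × 1280 stack with 5 spheres and
4 clutter objects; null calibrations use 1000 K-S replicates (group size
200, asymptotic p) and one 5000-gene null count simulation; EC50 recovery
uses 7 experiments × 8 doses per potency; improvement recovery uses 3000
genes. The whole suite runs in well under a minute on one core except the
image scenario (~15 s).

## Known limitations

- The segmentation operator and the derivation ranking statistic are
  reconstructions of procedures whose exact definitions are not public;
  both are pluggable and documented as such above.
- The DE stage is not a count-model engine (no dispersion shrinkage, no
  GLM offsets); use external contrast tables for real RNA-seq.
- The seed matcher ignores non-canonical and 3'-supplementary pairing and
  UTR context features.
- NCA implements single-profile analysis only; no dose-proportionality or
  compartmental modeling.
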