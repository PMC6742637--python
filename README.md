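# cystkit

`cystkit` is a tested, reusable implementation of the quantitative analyses
used in preclinical anti-miR-17 pharmacology for autosomal dominant
polycystic kidney disease (ADPKD): 3D cyst quantification from image
stacks, miR-17 pharmacodynamic-signature (PD-Sig) scoring and derivation,
polysome-shift (miPSA) target-engagement scoring, target de-repression and
transcriptome-improvement analysis, four-parameter logistic (4PL)
dose-response fitting, and noncompartmental pharmacokinetics (NCA). Every
stage ships with a synthetic-data generator that produces its inputs with
known ground truth, so the whole pipeline is exercisable and testable
without any experimental data.

It is intended for computational biologists and DMPK/pharmacology analysts
who need these readouts as composable, scriptable components rather than
as one-off spreadsheet or GUI workflows.

## The quantities it computes

**Cyst quantification.** Wells of Matrigel-grown cysts are imaged as
stacks of focal planes (by default 28 planes, 150 µm apart). Each plane is
segmented; objects are described by mean centroid-to-boundary radius r̄,
the CV of those radii, and moment-ellipse eccentricity; objects with
r̄ ∉ [15, 200] px, CV > 0.2 or eccentricity > 0.75 are removed; surviving
objects in the same location on consecutive planes are linked into one
cyst; and, assuming sphericity, each cyst's volume is V = 4/3·π·r³ with r
the mean radius of its largest cross-section. A 2D cyst index
(cystic area / tissue area) is provided for histology masks.

**PD-Sig.** The miR-17 PD-Sig score of a sample is the mean
housekeeping-normalized log2 fold change of a fixed panel of direct miR-17
target genes versus a reference condition. Bundled panels: `mouse18`
(18 targets, 6 housekeeping), the in-vivo subset `mouse10`, and `human13`.
`derive_signature` reconstructs panel derivation from anti-miR/mimic
perturbation contrasts.

**miPSA.** Target engagement is the displacement of the miRNA from
high-molecular-weight polysome fractions:
score = log2(HMW_control / HMW_treated), converted to percent inhibition
as (1 − 2^(−score)) × 100.

**De-repression / improvement.** A two-sample Kolmogorov–Smirnov test
compares the log2FC cumulative distributions of predicted seed-match
targets (8mer, 7mer-m8, 7mer-A1 site types) against non-targets;
transcriptome improvement is the Spearman anti-correlation between the
disease and treatment contrasts over the dysregulated genes plus an
improved-gene count (treated FDR < 0.05, |log2FC| > 0.5, sign opposite to
disease).

**Dose-response and PK.** 4PL fits
(response = bottom + (top − bottom)/(1 + (EC50/d)^hill)) in log10(EC50)
with delta-method EC50 standard errors; NCA reports Cmax, Tmax, linear
trapezoid AUC_last, terminal log-linear half-life and kidney/liver
exposure ratios.

## Worked example

```bash
cystkit demo --seed 1 --out demo_out/
```

runs every stage on synthetic data and prints a JSON report; with seed 1:

```json
{
  "cysts":       {"recovered_count": 2, "true_count": 2,
                  "volumes_px3": [113601.5, 299148.7]},
  "pdsig":       {"antimir": 1.1868, "mimic": -0.906, "mock": -0.0},
  "mipsa":       {"score": 3.1844, "pct_inhibition": 89},
  "ec50":        {"true": 28.3, "fitted": 33.44, "se": 3.79},
  "improvement": {"rho": -0.738, "n_dysregulated": 231, "n_improved": 121},
  "nca":         {"cmax": 6.61, "tmax": 0.5, "auc_last": 8.63, "t_half": 0.693}
}
```

Reading it: the two rendered spheres (true volumes 4/3·π·30³ ≈ 113 097 and
4/3·π·42³ ≈ 310 339 px³) are both recovered within a few percent; the
PD-Sig group scores recover the injected ±1 log2 effect to within the
replicate noise; a gradient pair built at 89% inhibition scores
3.18 ≈ −log2(0.11); the 4PL fit recovers the generating EC50 of 28.3 nM
within ~1.4 standard errors on a single noisy experiment; treated counts
anti-correlate with disease dysregulation (rho = −0.74), with about half of
the detected dysregulated genes improved — consistent with the generator's
60% rescue fraction after detection losses; and the exponential plasma
curve yields its analytic half-life ln 2/1.0 ≈ 0.69 h.

Library use mirrors the CLI, e.g.:

```python
from cystkit import cyst3d, synthgen
spec = synthgen.CystFieldSpec(cysts=[synthgen.Cyst((256., 256., 74.25), 50.)])
stack, truth = synthgen.gen_cyst_stack(spec)
summary = cyst3d.quantify_well(stack)
```

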