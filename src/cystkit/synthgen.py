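"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator emulates one input modality of the anti-miR-17 analysis
pipeline — cyst image stacks, perturbation expression matrices, polysome
gradient profiles, dose-response tables, disease/treatment count matrices,
3'UTR sequence sets and biexponential PK curves — and returns the exact
ground truth alongside, so every downstream stage is testable without any
real data.  All randomness flows through one explicit integer seed per
call; the same seed reproduces byte-identical output.

Noise models: additive Gaussian grayscale for images, Gaussian in log2
space for expression, negative binomial with fixed dispersion for counts,
multiplicative lognormal for dose-response and PK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cyst3d import ImageStack, sphere_volume
from .doseresponse import DoseResponseFit, four_pl
from .mipsa import PolysomeProfile
from .signature import ExpressionMatrix

__all__ = [
    "Cyst",
    "Clutter",
    "CystFieldSpec",
    "ExpressionDesign",
    "DiseaseDesign",
    "DiseaseCounts",
    "gen_cyst_stack",
    "gen_expression_experiment",
    "gen_polysome_pair",
    "gen_dose_response",
    "half_log_doses",
    "gen_disease_treatment_counts",
    "gen_utr_fasta",
    "gen_pk_profile",
]

CLUTTER_KINDS = ("speck", "streak", "giant", "ragged")


# ---------------------------------------------------------------------------
# cyst image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cyst:
    """A spherical cyst: center (row, col, z) in px, radius in px, intensity."""

    center: tuple[float, float, float]
    radius_px: float
    intensity: float = 100.0


@dataclass(frozen=True)
class Clutter:
    """A non-cyst artifact.

    Kinds and the filter rule each violates: ``speck`` (tiny disk →
    radius_min), ``giant`` (oversized disk → radius_max), ``streak``
    (elongated bar → eccentricity), ``ragged`` (cross shape → radius CV).
    ``size_px`` is the disk radius for specks/giants, the bar width for
    streaks and the arm width for crosses.
    """

    kind: str
    size_px: float
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in CLUTTER_KINDS:
            raise ValueError(f"clutter kind must be one of {CLUTTER_KINDS}")


@dataclass
class CystFieldSpec:
    """Specification of one synthetic per-well image stack.

    Defaults mirror the acquisition protocol emulated: 28 focal planes with
    an axial spacing of 5.5 px (150 µm at ~27 µm/px, so that axial distances
    share the in-plane pixel unit).
    """

    stack_depth: int = 28
    slice_spacing_px: float = 5.5
    image_shape: tuple[int, int] = (512, 512)
    cysts: Sequence[Cyst] = field(default_factory=list)
    clutter: Sequence[Clutter] = field(default_factory=list)
    noise_sd: float = 2.0
    background: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stack_depth < 1:
            raise ValueError("stack_depth must be >= 1")
        if self.slice_spacing_px <= 0:
            raise ValueError("slice_spacing_px must be positive")
        z_max = (self.stack_depth - 1) * self.slice_spacing_px
        h, w = self.image_shape
        for cyst in self.cysts:
            r, c, z = cyst.center
            if cyst.radius_px <= 0:
                raise ValueError("cyst radius must be positive")
            if not (0 <= r < h and 0 <= c < w and 0 <= z <= z_max):
                raise ValueError(f"cyst center {cyst.center} outside the imaged volume")
            if r - cyst.radius_px < 0 or r + cyst.radius_px >= h \
                    or c - cyst.radius_px < 0 or c + cyst.radius_px >= w:
                raise ValueError(
                    f"cyst of radius {cyst.radius_px} at {cyst.center} exceeds image bounds"
                )


def _fill_disk(img: np.ndarray, row: float, col: float, radius: float, value: float) -> None:
    h, w = img.shape
    r0, r1 = max(int(row - radius) - 1, 0), min(int(row + radius) + 2, h)
    c0, c1 = max(int(col - radius) - 1, 0), min(int(col + radius) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    region = img[r0:r1, c0:c1]
    region[inside] = np.maximum(region[inside], value)


def _fill_rect(img: np.ndarray, row: float, col: float, half_h: float, half_w: float,
               value: float) -> None:
    h, w = img.shape
    r0, r1 = max(int(row - half_h), 0), min(int(row + half_h) + 1, h)
    c0, c1 = max(int(col - half_w), 0), min(int(col + half_w) + 1, w)
    img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], value)


def _clutter_extent(item: Clutter) -> float:
    if item.kind == "speck" or item.kind == "giant":
        return item.size_px
    if item.kind == "streak":
        return 5.0 * item.size_px  # bar half-length
    return 3.0 * item.size_px  # cross arm half-length


def gen_cyst_stack(spec: CystFieldSpec) -> tuple[ImageStack, pd.DataFrame]:
    """Render a per-well image stack plus its ground-truth cyst table.

    Each cyst appears in slice i (axial position z_i = i × spacing) as a
    filled disk of radius sqrt(R² − dz²) where dz = |z_i − z_center|.
    Clutter artifacts are placed on random single slices at positions that
    do not overlap any cyst.  Gaussian noise of ``noise_sd`` is added on top
    of the flat background.  The truth table lists every cyst's center,
    radius and analytic volume 4/3·π·R³.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    stack = np.full((spec.stack_depth, h, w), float(spec.background))

    for cyst in spec.cysts:
        crow, ccol, cz = cyst.center
        for i in range(spec.stack_depth):
            dz = abs(i * spec.slice_spacing_px - cz)
            if dz < cyst.radius_px:
                r_slice = float(np.sqrt(cyst.radius_px**2 - dz**2))
                if r_slice >= 1.0:
                    _fill_disk(stack[i], crow, ccol, r_slice,
                               spec.background + cyst.intensity)

    for item in spec.clutter:
        extent = _clutter_extent(item)
        row, col = _place_clutter(rng, spec, extent)
        i = int(rng.integers(0, spec.stack_depth))
        value = spec.background + item.intensity
        if item.kind in ("speck", "giant"):
            _fill_disk(stack[i], row, col, item.size_px, value)
        elif item.kind == "streak":
            _fill_rect(stack[i], row, col, item.size_px / 2.0, 5.0 * item.size_px, value)
        else:  # ragged cross: two perpendicular bars
            _fill_rect(stack[i], row, col, item.size_px / 2.0, 3.0 * item.size_px, value)
            _fill_rect(stack[i], row, col, 3.0 * item.size_px, item.size_px / 2.0, value)

    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    truth = pd.DataFrame(
        [
            {
                "cyst_id": k,
                "row": c.center[0],
                "col": c.center[1],
                "z_px": c.center[2],
                "radius_px": c.radius_px,
                "volume_px3": sphere_volume(c.radius_px),
            }
            for k, c in enumerate(spec.cysts)
        ],
        columns=["cyst_id", "row", "col", "z_px", "radius_px", "volume_px3"],
    )
    return ImageStack(slices=stack), truth


def _place_clutter(rng: np.random.Generator, spec: CystFieldSpec, extent: float
                   ) -> tuple[float, float]:
    """Random in-plane position whose footprint clears every cyst."""
    h, w = spec.image_shape
    lo = extent + 1
    if h - extent - 1 <= lo or w - extent - 1 <= lo:
        raise ValueError("clutter too large for the image")
    for _ in range(500):
        row = rng.uniform(lo, h - extent - 1)
        col = rng.uniform(lo, w - extent - 1)
        if all(
            np.hypot(row - c.center[0], col - c.center[1]) > c.radius_px + extent + 5
            for c in spec.cysts
        ):
            return row, col
    raise RuntimeError("could not place clutter without overlapping a cyst")


# ---------------------------------------------------------------------------
# perturbation expression experiment (signature derivation / scoring)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDesign:
    """Design of a mock / anti-miR / mimic perturbation experiment."""

    n_signature_genes: int = 18
    n_housekeeping: int = 6
    n_background_genes: int = 500
    effect_antimir: float = 1.0
    effect_mimic: float = 1.0
    noise_sd_log2: float = 0.2
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_signature_genes, self.n_housekeeping,
               self.n_background_genes, self.n_replicates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")


def gen_expression_experiment(design: ExpressionDesign
                              ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a log2 expression matrix for mock/anti-miR/mimic arms.

    Signature genes shift +effect_antimir in the anti-miR arm and
    −effect_mimic in the mimic arm; housekeeping and background genes are
    unshifted.  Gaussian log2 noise applies to every entry.  Returns the
    matrix (with sample annotations) and a truth table of gene roles.
    """
    rng = np.random.default_rng(design.seed)
    genes = (
        [f"SIG{i + 1:03d}" for i in range(design.n_signature_genes)]
        + [f"HK{i + 1:02d}" for i in range(design.n_housekeeping)]
        + [f"BG{i + 1:04d}" for i in range(design.n_background_genes)]
    )
    roles = (
        ["signature"] * design.n_signature_genes
        + ["housekeeping"] * design.n_housekeeping
        + ["background"] * design.n_background_genes
    )
    baseline = rng.uniform(6.0, 12.0, size=len(genes))

    arms = ["mock", "antimir", "mimic"]
    shift = {"mock": 0.0, "antimir": design.effect_antimir, "mimic": -design.effect_mimic}
    columns, annot, data = [], [], []
    is_sig = np.array([r == "signature" for r in roles], dtype=float)
    for arm in arms:
        for rep in range(1, design.n_replicates + 1):
            name = f"{arm}_{rep}"
            col = baseline + shift[arm] * is_sig
            if design.noise_sd_log2 > 0:
                col = col + rng.normal(0.0, design.noise_sd_log2, size=len(genes))
            columns.append(name)
            annot.append({"sample": name, "arm": arm, "replicate": rep})
            data.append(col)

    values = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene"),
                          columns=columns)
    matrix = ExpressionMatrix(
        values=values,
        value_kind="log2_expression",
        sample_annotations=pd.DataFrame(annot).set_index("sample"),
    )
    truth = pd.DataFrame({"gene": genes, "role": roles}).set_index("gene")
    return matrix, truth


# ---------------------------------------------------------------------------
# polysome gradient pair
# ---------------------------------------------------------------------------

def gen_polysome_pair(
    inhibition_frac: float,
    n_fractions: int = 12,
    hmw_indices: Optional[Sequence[int]] = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    total_abundance: float = 1000.0,
) -> tuple[PolysomeProfile, PolysomeProfile]:
    """Simulate control/treated polysome gradient profiles of one miRNA.

    In the treated gradient the HMW abundance is control × (1 −
    inhibition_frac) and the displaced mass is redistributed over the
    non-HMW fractions proportionally to their control abundances.  With
    ``noise_cv`` > 0, multiplicative lognormal noise of that CV is applied
    per fraction.  Returns (control, treated).
    """
    if not 0.0 <= inhibition_frac <= 1.0:
        raise ValueError("inhibition_frac must lie in [0, 1]")
    if hmw_indices is None:
        hmw_indices = tuple(range(n_fractions - 4, n_fractions))
    hmw = np.zeros(n_fractions, dtype=bool)
    hmw[list(hmw_indices)] = True

    # control shape: monosome-heavy light fractions, enriched HMW tail
    weights = np.ones(n_fractions)
    weights[hmw] = 2.0
    control = weights / weights.sum() * total_abundance

    treated = control.copy()
    displaced = float(control[hmw].sum()) * inhibition_frac
    treated[hmw] *= 1.0 - inhibition_frac
    non_hmw_total = float(control[~hmw].sum())
    treated[~hmw] += displaced * control[~hmw] / non_hmw_total

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        mu = -0.5 * sigma**2  # mean-1 lognormal
        control = control * rng.lognormal(mu, sigma, n_fractions)
        treated = treated * rng.lognormal(mu, sigma, n_fractions)

    idx = tuple(int(i) for i in np.nonzero(hmw)[0])
    return (
        PolysomeProfile(abundances=control, hmw_indices=idx),
        PolysomeProfile(abundances=treated, hmw_indices=idx),
    )


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def half_log_doses(center: float, n: int = 8) -> np.ndarray:
    """n doses at half-log10 spacing, geometrically centered on ``center``."""
    offsets = (np.arange(n) - (n - 1) / 2.0) * 0.5
    return 10.0 ** (np.log10(center) + offsets)


def gen_dose_response(
    true_fit: DoseResponseFit,
    doses,
    cv: float = 0.1,
    n_rep: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dose/response table from a known 4PL curve.

    Responses are the 4PL value times mean-1 multiplicative lognormal noise
    with coefficient of variation ``cv``.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        resp = four_pl(doses, true_fit.ec50, true_fit.hill, true_fit.top, true_fit.bottom)
        if cv > 0:
            sigma = float(np.sqrt(np.log1p(cv**2)))
            resp = resp * rng.lognormal(-0.5 * sigma**2, sigma, doses.size)
        for d, r in zip(doses, resp):
            rows.append({"dose": d, "response": r, "rep": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disease / treatment count matrices
# ---------------------------------------------------------------------------

@dataclass
class DiseaseDesign:
    """Design of a control / disease / treated RNA-seq count simulation.

    Dysregulated genes get a disease-vs-control log2 shift of magnitude
    ``lfc_min + |N(0, dysregulation_lfc_sd)|`` with random sign; the floor
    keeps true dysregulation well separated from the detection thresholds,
    emulating clearly disease-dependent genes.  In the treated group a
    ``rescue_fraction`` of them move back toward control by
    ``rescue_strength`` (1 = fully back).  Counts are negative binomial with
    fixed dispersion.
    """

    n_genes: int = 10000
    frac_dysregulated: float = 0.1
    dysregulation_lfc_sd: float = 1.0
    lfc_min: float = 1.0
    rescue_fraction: float = 0.6
    rescue_strength: float = 1.0
    dispersion: float = 0.05
    library_size: float = 1e6
    n_per_group: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dysregulated", "rescue_fraction", "rescue_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class DiseaseCounts:
    """Count matrices per group plus the per-gene ground truth."""

    control: pd.DataFrame
    disease: pd.DataFrame
    treated: pd.DataFrame
    truth: pd.DataFrame

    def combined(self) -> tuple[pd.DataFrame, pd.Series]:
        """All samples in one matrix with a sample → group label series."""
        counts = pd.concat([self.control, self.disease, self.treated], axis=1)
        labels = pd.Series(
            ["control"] * self.control.shape[1]
            + ["disease"] * self.disease.shape[1]
            + ["treated"] * self.treated.shape[1],
            index=counts.columns,
        )
        return counts, labels


def gen_disease_treatment_counts(design: DiseaseDesign) -> DiseaseCounts:
    """Simulate control/disease/treated NB count matrices with known rescue.

    Truth columns: ``is_dysregulated``, ``lfc_disease_true`` (disease vs
    control), ``is_rescued``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    genes = pd.Index([f"G{i + 1:05d}" for i in range(n)], name="gene")

    # baseline mean counts: lognormal abundance, median ~ library/n
    base_log2 = rng.normal(np.log2(design.library_size / n), 1.5, size=n)
    mu_control = 2.0 ** base_log2

    n_dys = int(round(design.frac_dysregulated * n))
    dys_idx = rng.choice(n, size=n_dys, replace=False)
    lfc = np.zeros(n)
    if n_dys:
        magnitude = design.lfc_min + np.abs(
            rng.normal(0.0, design.dysregulation_lfc_sd, size=n_dys)
        )
        lfc[dys_idx] = magnitude * rng.choice([-1.0, 1.0], size=n_dys)

    rescued = np.zeros(n, dtype=bool)
    if n_dys:
        n_resc = int(round(design.rescue_fraction * n_dys))
        rescued[rng.choice(dys_idx, size=n_resc, replace=False)] = True

    mu_disease = mu_control * 2.0**lfc
    mu_treated = mu_disease.copy()
    mu_treated[rescued] = mu_disease[rescued] * 2.0 ** (
        -design.rescue_strength * lfc[rescued]
    )

    def draw(mu: np.ndarray, tag: str) -> pd.DataFrame:
        cols = {}
        r = 1.0 / design.dispersion
        for j in range(design.n_per_group):
            p = r / (r + mu)
            cols[f"{tag}_{j + 1}"] = rng.negative_binomial(r, p)
        return pd.DataFrame(cols, index=genes)

    truth = pd.DataFrame(
        {
            "is_dysregulated": lfc != 0.0,
            "lfc_disease_true": lfc,
            "is_rescued": rescued,
        },
        index=genes,
    )
    return DiseaseCounts(
        control=draw(mu_control, "control"),
        disease=draw(mu_disease, "disease"),
        treated=draw(mu_treated, "treated"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# 3'UTR sequences with planted seed-match sites
# ---------------------------------------------------------------------------

def gen_utr_fasta(
    n_seqs: int,
    site_plan,
    mirna_seq: str,
    seed: int = 0,
    utr_length: int = 300,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate 3'UTR sequences with planted canonical seed-match sites.

    ``site_plan`` is either a sequence of per-UTR entries from
    {None, '8mer', '7mer-m8', '7mer-A1'} (padded with None to ``n_seqs``) or
    a dict mapping site type to count.  Each UTR is a random site-free DNA
    background with at most one site planted; the truth table records the
    planted type.  Returns (name → sequence dict, truth DataFrame).
    """
    from .derepression import _classify_sites, seed_sites

    motifs = seed_sites(mirna_seq)  # validates the miRNA (>= 8 nt)
    if isinstance(site_plan, dict):
        plan: list[Optional[str]] = []
        for site_type, count in site_plan.items():
            plan.extend([site_type] * count)
    else:
        plan = list(site_plan)
    if len(plan) > n_seqs:
        raise ValueError("site_plan longer than n_seqs")
    plan += [None] * (n_seqs - len(plan))
    bad = {t for t in plan if t is not None and t not in motifs}
    if bad:
        raise ValueError(f"unknown site type(s): {sorted(bad)}")

    rng = np.random.default_rng(seed)
    m8_comp = motifs["8mer"][0]
    seqs: dict[str, str] = {}
    rows = []
    for k, site_type in enumerate(plan):
        name = f"UTR{k + 1:04d}"
        seqs[name] = _plant_site(rng, utr_length, site_type, motifs, m8_comp)
        planted = _classify_sites(seqs[name], motifs)
        expected = {t: (1 if t == site_type else 0) for t in motifs}
        assert planted == expected, "generator postcondition violated"
        rows.append({"gene": name, "site_type": site_type or "",
                     "is_target": site_type is not None})
    truth = pd.DataFrame(rows).set_index("gene")
    return seqs, truth


def _random_site_free(rng: np.random.Generator, length: int, motifs) -> str:
    from .derepression import _classify_sites

    bases = np.array(list("ACGT"))
    for _ in range(200):
        seq = "".join(rng.choice(bases, size=length))
        if sum(_classify_sites(seq, motifs).values()) == 0:
            return seq
    raise RuntimeError("failed to sample a site-free background sequence")


def _plant_site(rng, length: int, site_type, motifs, m8_comp: str) -> str:
    seq = list(_random_site_free(rng, length, motifs))
    if site_type is None:
        return "".join(seq)
    motif = motifs[site_type]
    pos = int(rng.integers(1, length - len(motif) - 1))
    seq[pos:pos + len(motif)] = motif
    non_a = "CGT"
    if site_type == "7mer-m8" and seq[pos + 7] == "A":
        seq[pos + 7] = non_a[rng.integers(0, 3)]  # would upgrade to 8mer
    if site_type == "7mer-A1" and seq[pos - 1] == m8_comp:
        alt = [b for b in "ACGT" if b != m8_comp]
        seq[pos - 1] = alt[rng.integers(0, 3)]
    out = "".join(seq)
    from .derepression import _classify_sites

    planted = _classify_sites(out, motifs)
    if planted != {t: (1 if t == site_type else 0) for t in motifs}:
        return _plant_site(rng, length, site_type, motifs, m8_comp)  # rare clash: retry
    return out


# ---------------------------------------------------------------------------
# biexponential PK curves
# ---------------------------------------------------------------------------

def gen_pk_profile(
    times,
    a: float,
    alpha: float,
    b: float = 0.0,
    beta: float = 0.0,
    cv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Concentrations of a biexponential disposition curve at given times.

    C(t) = a·exp(−alpha·t) + b·exp(−beta·t), optionally with mean-1
    multiplicative lognormal noise of coefficient of variation ``cv``.
    """
    times = np.asarray(times, dtype=float)
    conc = a * np.exp(-alpha * times) + b * np.exp(-beta * times)
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(cv**2)))
        conc = conc * rng.lognormal(-0.5 * sigma**2, sigma, times.size)
    return conc
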