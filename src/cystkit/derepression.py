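"""Target de-repression and transcriptome-improvement analysis.

Given per-gene differential-expression contrasts, this module tests whether
predicted miR-17 targets shift up as a population after anti-miR treatment
(two-sample Kolmogorov-Smirnov comparison of the log2FC cumulative
distributions, targets vs non-targets) and quantifies how much a treatment
reverses disease-dysregulated expression (Spearman anti-correlation of the
disease and treatment contrasts over the dysregulated genes, plus an
improved-gene count under FDR and fold-change thresholds).

Target annotation comes either from the built-in canonical seed matcher
(8mer, 7mer-m8, 7mer-A1 site types against a supplied miRNA sequence) or
from an external target list (e.g., a TargetScan export).

The differential-expression stage is a deliberately simple engine
(log2-CPM, Welch t, Benjamini-Hochberg): every downstream operation also
accepts externally produced contrast tables (gene, log2fc, p_value, fdr).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KSResult",
    "ImprovementResult",
    "seed_match_targets",
    "load_target_table",
    "differential_expression",
    "bh_fdr",
    "ks_derepression_test",
    "improvement_analysis",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _as_dna(seq: str, what: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if not s or set(s) - set("ACGT"):
        raise ValueError(f"{what} must be a non-empty RNA/DNA sequence (ACGU/T)")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_sites(mirna_sequence: str) -> dict[str, str]:
    """Target-site motifs (written 5'→3' on the mRNA) for a miRNA's seed.

    The seed is miRNA positions 2-8.  Site types: 7mer-m8 pairs positions
    2-8; 7mer-A1 pairs 2-7 with an A opposite position 1; 8mer pairs 2-8
    with the A1.  Because the duplex is antiparallel, the mRNA site is the
    reverse complement of the seed with the A1 at its 3' end.
    """
    mirna = _as_dna(mirna_sequence, "miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core7 = _revcomp(mirna[1:8])  # positions 2-8
    core6 = _revcomp(mirna[1:7])  # positions 2-7
    return {"8mer": core7 + "A", "7mer-m8": core7, "7mer-A1": core6 + "A"}


def _classify_sites(utr: str, motifs: Mapping[str, str]) -> dict[str, int]:
    """Count non-overlapping-in-kind canonical sites in one UTR.

    Every 7mer-m8 match is upgraded to 8mer when followed by A; a 7mer-A1
    is only counted where the preceding base does not extend it to an 8mer.
    """
    counts = {t: 0 for t in SITE_TYPES}
    core7 = motifs["7mer-m8"]
    core6_a = motifs["7mer-A1"]
    m8_base = motifs["8mer"][0]  # complement of miRNA position 8

    start = 0
    while (i := utr.find(core7, start)) != -1:
        if i + 7 < len(utr) and utr[i + 7] == "A":
            counts["8mer"] += 1
        else:
            counts["7mer-m8"] += 1
        start = i + 1
    start = 0
    while (i := utr.find(core6_a, start)) != -1:
        if not (i > 0 and utr[i - 1] == m8_base):
            counts["7mer-A1"] += 1
        start = i + 1
    return counts


def seed_match_targets(utrs, mirna_sequence: str) -> pd.DataFrame:
    """Scan 3'UTRs for canonical miRNA seed-match sites.

    Parameters
    ----------
    utrs : FASTA path, mapping of name -> sequence, or iterable of SeqRecords
    mirna_sequence : str
        Mature miRNA, 5'→3', at least 8 nt, RNA or DNA alphabet.

    Returns
    -------
    DataFrame indexed by gene with columns ``is_target``, ``n_sites``,
    ``n_8mer``, ``n_7mer_m8``, ``n_7mer_a1`` and ``site_types`` (comma-joined).
    """
    motifs = seed_sites(mirna_sequence)
    if isinstance(utrs, (str, Path)):
        utrs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(utrs), "fasta")}
    elif not isinstance(utrs, Mapping):
        utrs = {rec.id: str(rec.seq) for rec in utrs}

    rows = []
    for name, seq in utrs.items():
        counts = _classify_sites(_as_dna(seq, f"UTR {name}"), motifs)
        n_sites = sum(counts.values())
        rows.append(
            {
                "gene": name,
                "is_target": n_sites >= 1,
                "n_sites": n_sites,
                "n_8mer": counts["8mer"],
                "n_7mer_m8": counts["7mer-m8"],
                "n_7mer_a1": counts["7mer-A1"],
                "site_types": ",".join(t for t in SITE_TYPES if counts[t] > 0),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def load_target_table(path, gene_col: str = "gene", sites_col: str = "n_sites") -> pd.DataFrame:
    """Load an external target list (e.g., a TargetScan-style TSV).

    Listed genes with at least one site are targets; the table replaces the
    built-in seed matcher wherever a target annotation is accepted.
    """
    df = pd.read_csv(path, sep="\t")
    if gene_col not in df.columns:
        raise ValueError(f"column {gene_col!r} not found in {path}")
    n_sites = df[sites_col] if sites_col in df.columns else pd.Series(1, index=df.index)
    out = pd.DataFrame(
        {"gene": df[gene_col], "n_sites": n_sites.astype(int)}
    ).groupby("gene").sum()
    out["is_target"] = out["n_sites"] >= 1
    return out[["is_target", "n_sites"]]


def _target_gene_set(annotation) -> set:
    if isinstance(annotation, pd.DataFrame):
        return set(annotation.index[annotation["is_target"].astype(bool)])
    return set(annotation)


def differential_expression(
    counts: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    reference: str,
    treatment: str,
    contrast: Optional[str] = None,
) -> pd.DataFrame:
    """Simple two-group differential expression on a count matrix.

    log2FC is the difference of group means of log2 CPM (pseudocount 0.5);
    the p-value is a per-gene Welch t-test on log2 CPM, BH-adjusted.  Each
    group needs >= 2 samples.  The result is a DataFrame (gene index;
    log2fc, p_value, fdr) with the contrast label in ``attrs``.
    """
    labels = pd.Series(group_labels)
    ref_samples = labels.index[labels == reference]
    trt_samples = labels.index[labels == treatment]
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("each group needs at least 2 samples")

    lib = counts.sum(axis=0)
    log2cpm = np.log2((counts + 0.5).div(lib + 1.0, axis=1) * 1e6)
    a = log2cpm[trt_samples].to_numpy()
    b = log2cpm[ref_samples].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes: no evidence

    out = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "fdr": bh_fdr(p)}, index=counts.index
    )
    out.attrs["contrast"] = contrast or f"{treatment}_vs_{reference}"
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class KSResult:
    """Two-sample K-S comparison of target vs non-target log2FC distributions."""

    d_statistic: float
    p_value: float
    median_shift: float  # median(targets) − median(non-targets)
    n_targets: int
    n_nontargets: int


def ks_derepression_test(
    de: pd.DataFrame,
    annotation,
    min_group: int = 10,
    method: str = "auto",
) -> KSResult:
    """Test whether predicted targets shift as a population.

    Splits the contrast's log2FCs into targets and non-targets and runs a
    two-sided two-sample Kolmogorov-Smirnov test (``method='auto'`` uses the
    exact small-sample distribution below scipy's size cutoff, asymptotic
    otherwise).  The median shift makes the direction of de-repression
    explicit: positive = targets up.
    """
    targets = _target_gene_set(annotation)
    is_t = de.index.isin(targets)
    x = de.loc[is_t, "log2fc"].to_numpy()
    y = de.loc[~is_t, "log2fc"].to_numpy()
    if x.size < min_group or y.size < min_group:
        raise ValueError(
            f"need >= {min_group} genes per group (targets={x.size}, non-targets={y.size})"
        )
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return KSResult(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_shift=float(np.median(x) - np.median(y)),
        n_targets=int(x.size),
        n_nontargets=int(y.size),
    )


@dataclass
class ImprovementResult:
    """Reversal of disease-dysregulated expression after treatment."""

    rho: float
    rho_p_value: float
    n_dysregulated: int
    n_improved: int
    improved_genes: tuple[str, ...]
    fdr_cut: float
    lfc_cut: float
    rho_defined: bool = True


def improvement_analysis(
    contrast_disease: pd.DataFrame,
    contrast_treated: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.5,
    require_sign_reversal: bool = True,
    rho_over: str = "dysregulated",
) -> ImprovementResult:
    """Quantify transcriptome improvement after treatment.

    Dysregulated genes are those with fdr < ``fdr_cut`` in the disease
    contrast.  rho is the Spearman correlation between the disease and
    treated log2FCs over that set (``rho_over='all'`` uses the full shared
    universe); a negative rho means treatment moves dysregulated genes back
    toward control.  A dysregulated gene counts as improved when the treated
    contrast has fdr < ``fdr_cut``, |log2FC| > ``lfc_cut`` and (by default)
    the opposite sign to its disease change.
    """
    if rho_over not in ("dysregulated", "all"):
        raise ValueError("rho_over must be 'dysregulated' or 'all'")
    shared = contrast_disease.index.intersection(contrast_treated.index)
    dis = contrast_disease.loc[shared]
    trt = contrast_treated.loc[shared]

    dys = shared[dis["fdr"] < fdr_cut]
    rho_idx = shared if rho_over == "all" else dys
    if len(rho_idx) >= 2:
        rho, rho_p = stats.spearmanr(
            dis.loc[rho_idx, "log2fc"], trt.loc[rho_idx, "log2fc"]
        )
        rho_defined = bool(np.isfinite(rho))
    else:
        rho, rho_p, rho_defined = float("nan"), float("nan"), False

    d, t = dis.loc[dys], trt.loc[dys]
    improved_mask = (t["fdr"] < fdr_cut) & (t["log2fc"].abs() > lfc_cut)
    if require_sign_reversal:
        improved_mask &= np.sign(t["log2fc"]) == -np.sign(d["log2fc"])
    improved = tuple(dys[improved_mask.to_numpy()])

    return ImprovementResult(
        rho=float(rho),
        rho_p_value=float(rho_p),
        n_dysregulated=int(len(dys)),
        n_improved=len(improved),
        improved_genes=improved,
        fdr_cut=fdr_cut,
        lfc_cut=lfc_cut,
        rho_defined=rho_defined,
    )
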