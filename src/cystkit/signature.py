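"""miR-17 pharmacodynamic-signature (PD-Sig) scoring and derivation.

The PD-Sig score of a sample is the average, over a fixed panel of direct
miR-17 target genes, of the genes' housekeeping-normalized log2 fold changes
relative to a reference condition (mock transfection in vitro, PBS in vivo).
Because miR-17 represses its targets, anti-miR treatment de-represses the
panel and pushes the score up, while a miR-17 mimic pushes it down; higher
score = more miR-17 inhibition.

Three panels are bundled: the 18-gene mouse panel with its 6 housekeeping
genes, the 10-gene in-vivo mouse subset, and the 13-gene human panel.

``derive_signature`` reconstructs the derivation procedure: direct seed-match
targets that move up under every anti-miR perturbation and down under every
mimic perturbation are ranked by mean across-experiment rank of |log2FC| and
the top genes are selected after symbol-level deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignatureDefinition",
    "ExpressionMatrix",
    "PDSigResult",
    "DerivationResult",
    "MOUSE18",
    "MOUSE10",
    "HUMAN13",
    "get_signature",
    "normalize_expression",
    "pdsig_score",
    "derive_signature",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named PD-Sig panel: target genes plus housekeeping normalizers."""

    name: str
    species: str
    target_genes: tuple[str, ...]
    housekeeping_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        targets = tuple(self.target_genes)
        hks = tuple(self.housekeeping_genes)
        if not targets or not hks:
            raise ValueError("target and housekeeping sets must be non-empty")
        if len(set(targets)) != len(targets) or len(set(hks)) != len(hks):
            raise ValueError("duplicate gene symbols in signature")
        if set(targets) & set(hks):
            raise ValueError("target and housekeeping sets must be disjoint")
        object.__setattr__(self, "target_genes", targets)
        object.__setattr__(self, "housekeeping_genes", hks)


_MOUSE_HK = ("Tbp", "Gusb", "Rplp0", "Hprt1", "B2m", "Pak1ip1")

MOUSE18 = SignatureDefinition(
    name="mouse18",
    species="mouse",
    target_genes=(
        "Plekha3", "Rhoc", "D030056l22rik", "Clock", "Polq", "Mtf1",
        "E2f1", "Tgfbr2", "P2rx4", "Nagk", "Mink1", "Zfp367",
        "Fyco1", "Pfkp", "Ddhd1", "Cdc37l1", "Wfs1", "St6galnac6",
    ),
    housekeeping_genes=_MOUSE_HK,
)

MOUSE10 = SignatureDefinition(
    name="mouse10",
    species="mouse",
    target_genes=(
        "Plekha3", "Clock", "Polq", "Mtf1", "Nagk",
        "Mink1", "Zfp367", "Fyco1", "Ddhd1", "Cdc37l1",
    ),
    housekeeping_genes=_MOUSE_HK,
)

HUMAN13 = SignatureDefinition(
    name="human13",
    species="human",
    target_genes=(
        "AMPD3", "BTG3", "C7ORF43", "CROT", "ENPP5", "LIMK1", "MINK1",
        "NAGK", "NKIRAS1", "PLEKHA3", "PTPN4", "TBC1D9", "TGFBR2",
    ),
    housekeeping_genes=("B2M", "GUSB", "HPRT1", "RPLP0", "TBP", "UBC"),
)

_BUNDLED = {s.name: s for s in (MOUSE18, MOUSE10, HUMAN13)}


def get_signature(name: str) -> SignatureDefinition:
    """Look up a bundled signature by name (mouse18, mouse10, human13)."""
    try:
        return _BUNDLED[name]
    except KeyError:
        raise KeyError(
            f"unknown signature {name!r}; bundled: {sorted(_BUNDLED)}"
        ) from None


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample annotations.

    ``value_kind`` is ``log2_expression`` or ``ct`` (qPCR cycle threshold,
    where smaller means more expressed).
    """

    values: pd.DataFrame
    value_kind: str = "log2_expression"
    sample_annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.value_kind not in ("log2_expression", "ct"):
            raise ValueError("value_kind must be 'log2_expression' or 'ct'")
        if self.value_kind == "ct" and (self.values.values <= 0).any():
            raise ValueError("Ct values must be positive")


@dataclass
class PDSigResult:
    """Per-sample PD-Sig scores with their per-gene log2FC breakdown."""

    scores: pd.Series  # per sample
    per_gene_log2fc: pd.DataFrame  # signature genes × samples
    reference_samples: tuple[str, ...]
    signature: SignatureDefinition
    group_scores: Optional[pd.Series] = None


def _require_genes(index: pd.Index, genes: Iterable[str], what: str) -> None:
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"missing {what} gene(s): {', '.join(missing)}")


def normalize_expression(
    matrix: ExpressionMatrix | pd.DataFrame,
    housekeeping_genes: Sequence[str],
) -> pd.DataFrame:
    """Housekeeping-normalize to a log2 scale.

    For log2 expression the per-sample arithmetic mean of the housekeeping
    genes (the geometric mean in linear space) is subtracted, so the
    housekeeping mean of the normalized matrix is 0 in every sample and
    adding any constant to all genes of a sample leaves the result
    unchanged.  For Ct input the gene-wise value is ΔCt = mean(Ct_HK) − Ct,
    which is on the same higher-is-more-expressed log2 scale.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = ExpressionMatrix(values=matrix)
    values = matrix.values
    _require_genes(values.index, housekeeping_genes, "housekeeping")
    hk_mean = values.loc[list(housekeeping_genes)].mean(axis=0)
    if matrix.value_kind == "ct":
        return hk_mean - values
    return values - hk_mean


def pdsig_score(
    normalized: pd.DataFrame,
    reference_samples: Sequence[str],
    signature: SignatureDefinition,
    group_by: Optional[Mapping[str, str] | pd.Series] = None,
) -> PDSigResult:
    """PD-Sig scores from a housekeeping-normalized log2 matrix.

    Per gene, log2FC = normalized value − mean normalized value over the
    reference samples; the sample score is the arithmetic mean of the
    signature genes' log2FCs.  With ``group_by`` (sample → group label),
    replicate scores are additionally averaged per group.
    """
    reference_samples = tuple(reference_samples)
    if not reference_samples:
        raise ValueError("reference_samples must be non-empty")
    missing_ref = [s for s in reference_samples if s not in normalized.columns]
    if missing_ref:
        raise KeyError(f"reference sample(s) not in matrix: {', '.join(missing_ref)}")
    _require_genes(normalized.index, signature.target_genes, "signature")

    sig = normalized.loc[list(signature.target_genes)]
    ref_mean = sig[list(reference_samples)].mean(axis=1)
    log2fc = sig.sub(ref_mean, axis=0)
    scores = log2fc.mean(axis=0)
    scores.name = f"pdsig_{signature.name}"

    group_scores = None
    if group_by is not None:
        groups = pd.Series(group_by)
        group_scores = scores.groupby(groups.reindex(scores.index)).mean()
    return PDSigResult(
        scores=scores,
        per_gene_log2fc=log2fc,
        reference_samples=reference_samples,
        signature=signature,
        group_scores=group_scores,
    )


@dataclass
class DerivationResult:
    """Outcome of signature derivation: the panel plus the ranking table."""

    signature: SignatureDefinition
    ranking: pd.DataFrame = field(repr=False)
    insufficient_candidates: bool = False


def derive_signature(
    de_tables: Mapping[tuple[str, str], pd.DataFrame],
    target_genes: Iterable[str],
    n_select: int = 18,
    housekeeping_genes: Sequence[str] = _MOUSE_HK,
    name: str = "derived",
    species: str = "mouse",
) -> DerivationResult:
    """Derive a PD-Sig panel from anti-miR / mimic perturbation contrasts.

    Parameters
    ----------
    de_tables : mapping of (cell_line, arm) -> DataFrame
        ``arm`` is ``"antimir"`` or ``"mimic"``; each table has gene symbols
        in a ``gene`` column (or as the index) and a ``log2fc`` column.
    target_genes : iterable of str
        Genes carrying a miR-17 family seed match in their 3'UTR; only these
        are eligible.

    A candidate must be a seed-match target, move up (log2FC > 0) in every
    anti-miR table and down (log2FC < 0) in every mimic table.  Candidates
    are ranked per table by |log2FC| (rank 1 = strongest), averaged across
    tables, deduplicated by symbol, and the ``n_select`` best are returned.
    If fewer survive, all are returned with ``insufficient_candidates=True``.
    """
    arms = {arm for (_, arm) in de_tables}
    if not arms <= {"antimir", "mimic"}:
        raise ValueError(f"unknown arm(s): {sorted(arms - {'antimir', 'mimic'})}")
    if "antimir" not in arms or "mimic" not in arms:
        raise ValueError("need at least one anti-miR and one mimic table")

    tables = {}
    for key, df in de_tables.items():
        t = df.copy()
        if "gene" in t.columns:
            t = t.set_index("gene")
        t = t[~t.index.duplicated(keep="first")]
        tables[key] = t["log2fc"]

    targets = set(target_genes)
    common = set.intersection(*(set(s.index) for s in tables.values())) & targets
    candidates = sorted(
        g
        for g in common
        if all(
            (s[g] > 0 if arm == "antimir" else s[g] < 0)
            for (_, arm), s in tables.items()
        )
    )

    rank_cols = {}
    for key, s in tables.items():
        mag = s[candidates].abs()
        rank_cols["{}__{}".format(*key)] = mag.rank(ascending=False, method="average")
    ranking = pd.DataFrame(rank_cols, index=pd.Index(candidates, name="gene"))
    ranking["mean_rank"] = ranking.mean(axis=1)
    ranking = ranking.sort_values("mean_rank", kind="mergesort")

    insufficient = len(ranking) < n_select
    chosen = tuple(ranking.index[:n_select])
    signature = SignatureDefinition(
        name=name,
        species=species,
        target_genes=chosen,
        housekeeping_genes=tuple(housekeeping_genes),
    )
    return DerivationResult(
        signature=signature, ranking=ranking, insufficient_candidates=insufficient
    )
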