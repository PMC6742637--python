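"""miRNA polysome shift assay (miPSA) target-engagement scoring.

An anti-miR that engages its miRNA displaces it from the translationally
active high-molecular-weight (HMW) polysome fractions of a sucrose gradient.
The miPSA score quantifies that displacement in log2 units,

    score = log2( HMW(control) / HMW(treated) ),

and converts to percent inhibition as (1 − 2^(−score)) × 100.  The log2 form
is reconstructed from the published score/percent pairs, which are all
consistent with this conversion at the printed precision; the formula is
pluggable should a different convention be needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PolysomeProfile",
    "MiPSAResult",
    "hmw_abundance",
    "mipsa_score",
    "pct_inhibition",
    "score_from_pct",
]


@dataclass
class PolysomeProfile:
    """Fraction-level abundances of one miRNA across a polysome gradient.

    Parameters
    ----------
    abundances : array of non-negative floats
        Abundance of the assayed miRNA per gradient fraction, in gradient
        order (light to heavy).
    hmw_indices : sequence of int
        0-based indices of the translationally active HMW polysome fractions.
    normalizer : array, optional
        Fraction-level abundances of an unaffected control miRNA, used to
        normalize the HMW abundance when requested.
    """

    abundances: np.ndarray
    hmw_indices: Sequence[int]
    normalizer: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        idx = np.asarray(self.hmw_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("hmw_indices must be non-empty")
        if idx.min() < 0 or idx.max() >= self.abundances.size:
            raise ValueError("hmw_indices out of range")
        self.hmw_indices = tuple(int(i) for i in idx)
        if self.normalizer is not None:
            self.normalizer = np.asarray(self.normalizer, dtype=float)
            if self.normalizer.shape != self.abundances.shape:
                raise ValueError("normalizer must match abundances in shape")


@dataclass
class MiPSAResult:
    """miPSA displacement score with its percent-inhibition conversion."""

    score: float
    pct_inhibition: float
    pct_inhibition_rounded: int


def hmw_abundance(profile: PolysomeProfile, normalize: bool = False) -> float:
    """Total assayed-miRNA abundance over the HMW polysome fractions.

    With ``normalize=True`` the sum is divided by the control miRNA's HMW
    sum, making the readout robust to loading differences between gradients.
    """
    total = float(profile.abundances[list(profile.hmw_indices)].sum())
    if normalize:
        if profile.normalizer is None:
            raise ValueError("profile has no normalizer miRNA")
        norm = float(profile.normalizer[list(profile.hmw_indices)].sum())
        if norm == 0.0:
            raise ValueError("normalizer HMW abundance is zero")
        if total == 0.0:
            raise ValueError("all-zero HMW abundance cannot be normalized")
        return total / norm
    return total


def mipsa_score(
    treated: PolysomeProfile, control: PolysomeProfile, normalize: bool = False
) -> MiPSAResult:
    """log2 displacement of the miRNA from HMW polysomes, treated vs control."""
    if treated.abundances.shape != control.abundances.shape or tuple(
        treated.hmw_indices
    ) != tuple(control.hmw_indices):
        raise ValueError("treated and control profiles must share the fraction layout")
    t = hmw_abundance(treated, normalize=normalize)
    c = hmw_abundance(control, normalize=normalize)
    if t == 0.0:
        raise ValueError("treated HMW abundance is zero (infinite displacement)")
    score = math.log2(c / t)
    pct = pct_inhibition(score)
    return MiPSAResult(score=score, pct_inhibition=pct, pct_inhibition_rounded=_round_half_up(pct))


def pct_inhibition(score: float) -> float:
    """Convert a miPSA log2 displacement score to percent inhibition.

    pct = (1 − 2^(−score)) × 100; 0 at score 0, approaching 100 as the score
    grows.  The unrounded value is returned; use round-half-up to the nearest
    integer for display.
    """
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    return (1.0 - 2.0 ** (-score)) * 100.0


def score_from_pct(pct: float) -> float:
    """Inverse conversion: score = −log2(1 − pct/100)."""
    if pct >= 100.0:
        raise ValueError("percent inhibition must be < 100")
    return -math.log2(1.0 - pct / 100.0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))
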