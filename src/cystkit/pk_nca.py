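"""Noncompartmental pharmacokinetic analysis and tissue-preference ratios.

Conventions: concentrations below the limit of quantification are entered as
zero and retained; AUC_last is the linear trapezoid to the last quantifiable
(non-zero) point; the terminal half-life comes from an unweighted log-linear
regression over the terminal run of at least three strictly descending
positive concentrations and is reported absent when r² < 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["PKProfile", "NCAResult", "TissueRatio", "nca", "tissue_ratio"]


@dataclass
class PKProfile:
    """Concentration-time points for one tissue (times strictly increasing)."""

    times: np.ndarray
    concentrations: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class NCAResult:
    cmax: float
    tmax: float
    auc_last: float
    t_half: Optional[float]
    t_half_r2: Optional[float] = None
    n_terminal: Optional[int] = None


def nca(profile: PKProfile) -> NCAResult:
    """Noncompartmental parameters of one concentration-time profile.

    Cmax/Tmax are the observed maximum and its time (earliest on ties).
    """
    t, c = profile.times, profile.concentrations
    if t.size < 3:
        raise ValueError("need at least 3 concentration-time points")

    imax = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    cmax, tmax = float(c[imax]), float(t[imax])

    quant = np.nonzero(c > 0)[0]
    if quant.size == 0:
        auc_last = 0.0
    else:
        last = quant[-1]
        auc_last = float(np.trapezoid(c[: last + 1], t[: last + 1]))

    t_half, r2, n_term = _terminal_half_life(t, c, imax)
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_last=auc_last,
        t_half=t_half, t_half_r2=r2, n_terminal=n_term,
    )


def _terminal_half_life(t, c, imax):
    """Half-life from the terminal strictly descending positive run.

    The run ends at the last quantifiable point and extends backwards while
    concentrations are strictly decreasing; it must start no earlier than
    Cmax and contain >= 3 points.
    """
    quant = np.nonzero(c > 0)[0]
    if quant.size == 0:
        return None, None, None
    last = quant[-1]
    start = last
    while start - 1 >= imax and c[start - 1] > c[start] > 0:
        start -= 1
    idx = np.arange(start, last + 1)
    idx = idx[c[idx] > 0]
    if idx.size < 3:
        return None, None, None
    reg = stats.linregress(t[idx], np.log(c[idx]))
    r2 = float(reg.rvalue**2)
    if reg.slope >= 0 or r2 < 0.8:
        return None, r2, int(idx.size)
    return float(np.log(2.0) / -reg.slope), r2, int(idx.size)


@dataclass
class TissueRatio:
    """Elementwise exposure ratios between two tissues (e.g., kidney/liver)."""

    cmax_ratio: float
    auc_ratio: float


def tissue_ratio(kidney: NCAResult, liver: NCAResult) -> TissueRatio:
    """Kidney-to-liver exposure ratios by Cmax and AUC_last."""
    if liver.cmax <= 0 or liver.auc_last <= 0:
        raise ValueError("liver Cmax and AUC_last must be positive")
    return TissueRatio(
        cmax_ratio=kidney.cmax / liver.cmax,
        auc_ratio=kidney.auc_last / liver.auc_last,
    )
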