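"""Four-parameter logistic (4PL) dose-response fitting.

The 4PL model is

    response(d) = bottom + (top − bottom) / (1 + (ec50 / d)^hill)

so that response → bottom as d → 0 and → top as d → ∞ for hill > 0 (a
negative fitted hill accommodates descending curves).  Fitting is bounded
least squares parameterized in log10(EC50); the EC50 standard error is
obtained from the Jacobian-based covariance by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "four_pl", "fit_4pl", "normalize_luciferase"]


def four_pl(dose, ec50: float, hill: float, top: float, bottom: float):
    """Evaluate the 4PL curve at the given dose(s)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


@dataclass
class DoseResponseFit:
    """Fitted (or true, when used as a generator input) 4PL parameters."""

    ec50: float
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0
    ec50_se: Optional[float] = None
    converged: bool = True
    rmse: Optional[float] = None
    n_obs: Optional[int] = None
    monotonicity_warning: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")

    def predict(self, dose):
        return four_pl(dose, self.ec50, self.hill, self.top, self.bottom)

    @property
    def midpoint_response(self) -> float:
        """Response on the fitted curve at dose = EC50, (top + bottom)/2."""
        return 0.5 * (self.top + self.bottom)


def fit_4pl(
    doses,
    responses,
    fix_top: Optional[float] = None,
    fix_bottom: Optional[float] = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses against doses.

    Requires at least 5 distinct positive doses (3 when both asymptotes are
    fixed).  Initialization: asymptotes from the extreme-dose means, EC50
    from the dose closest to the half-response, hill = 1.  On failure to
    converge the best iterate is returned with ``converged=False``.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    n_distinct = np.unique(doses).size
    n_free_asym = (fix_top is None) + (fix_bottom is None)
    if n_distinct < 2 + n_free_asym + 1:
        raise ValueError(
            f"need at least {2 + n_free_asym + 1} distinct doses for "
            f"{2 + n_free_asym} free parameters"
        )

    order = np.argsort(doses)
    d_sorted, r_sorted = doses[order], responses[order]
    lo_mean = float(r_sorted[d_sorted == d_sorted[0]].mean())
    hi_mean = float(r_sorted[d_sorted == d_sorted[-1]].mean())
    bottom0 = lo_mean if fix_bottom is None else fix_bottom
    top0 = hi_mean if fix_top is None else fix_top
    half = 0.5 * (top0 + bottom0)
    ec50_0 = float(d_sorted[np.argmin(np.abs(r_sorted - half))])
    log_d = np.log10(doses)

    def unpack(theta):
        log_ec50, hill = theta[0], theta[1]
        k = 2
        if fix_top is None:
            top = theta[k]
            k += 1
        else:
            top = fix_top
        bottom = theta[k] if fix_bottom is None else fix_bottom
        return log_ec50, hill, top, bottom

    def residuals(theta):
        log_ec50, hill, top, bottom = unpack(theta)
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - log_d)))
        return pred - responses

    theta0 = [np.log10(ec50_0), 1.0]
    lower = [np.log10(d_sorted[0]) - 3.0, -20.0]
    upper = [np.log10(d_sorted[-1]) + 3.0, 20.0]
    span = max(abs(top0 - bottom0), np.ptp(responses), 1e-12)
    if fix_top is None:
        theta0.append(top0)
        lower.append(min(responses.min(), top0) - 10 * span)
        upper.append(max(responses.max(), top0) + 10 * span)
    if fix_bottom is None:
        theta0.append(bottom0)
        lower.append(min(responses.min(), bottom0) - 10 * span)
        upper.append(max(responses.max(), bottom0) + 10 * span)

    result = least_squares(residuals, theta0, bounds=(lower, upper), method="trf")
    log_ec50, hill, top, bottom = unpack(result.x)
    ec50 = 10.0 ** log_ec50

    n, p = responses.size, result.x.size
    rmse = float(np.sqrt(np.mean(result.fun**2)))
    ec50_se = None
    if n > p:
        s2 = float(np.sum(result.fun**2)) / (n - p)
        jtj = result.jac.T @ result.jac
        try:
            cov = np.linalg.inv(jtj) * s2
            se_log = float(np.sqrt(cov[0, 0]))
            ec50_se = np.log(10.0) * ec50 * se_log  # delta method
        except np.linalg.LinAlgError:
            pass

    # flag responses that run against the fitted direction by far more than
    # the residual scale (a crude sanity signal, not an error)
    mono_warn = False
    if n_distinct >= 3:
        means = np.array([r_sorted[d_sorted == d].mean() for d in np.unique(d_sorted)])
        diffs = np.diff(means) * np.sign(top - bottom) * np.sign(hill)
        mono_warn = bool(np.any(diffs < -3.0 * max(rmse, 1e-12)))

    return DoseResponseFit(
        ec50=ec50,
        hill=hill,
        top=top,
        bottom=bottom,
        ec50_se=ec50_se,
        converged=bool(result.success),
        rmse=rmse,
        n_obs=int(n),
        monotonicity_warning=mono_warn,
    )


def normalize_luciferase(raw, background: float, untreated_control: float):
    """Background-subtract and scale raw luciferase counts to the untreated
    control: (raw − background) / (control − background)."""
    if untreated_control <= background:
        raise ValueError("untreated control must exceed background")
    raw = np.asarray(raw, dtype=float)
    return (raw - background) / (untreated_control - background)
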