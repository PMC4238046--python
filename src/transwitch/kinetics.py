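"""First-order decay fitting and relative-expression utilities.

Chase experiments (cycloheximide for protein, actinomycin-D for mRNA) are
modelled as first-order decay A(t) = A0 * exp(-k t): ordinary least squares
of ln(abundance) on time gives the rate k = -slope and half-life ln2 / k.
A non-negative slope is reported as a stable species (infinite half-life)
rather than an error. Confidence intervals come from residual-resampling
bootstrap. Densitometry and qPCR inputs are normalized with the usual
loading-control ratio and delta-Ct conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError

LN2 = math.log(2.0)


@dataclass
class DecayFit:
    """Log-linear decay fit: rate (per hour), half-life (h), diagnostics."""

    rate: float
    half_life: float  # math.inf when the fit shows no decay
    intercept: float  # ln abundance at t = 0
    r_squared: float
    ci_half_life: tuple[float, float]
    n_points: int
    stable: bool  # non-negative slope flag

    def __post_init__(self) -> None:
        if self.rate > 0 and not self.half_life > 0:
            raise DataValidationError("positive rate must give positive half-life")


def _ols(t: np.ndarray, ln_y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, ln_y, 1)
    return float(slope), float(intercept)


def _half_life(slope: float) -> tuple[float, bool]:
    if slope >= 0:
        return math.inf, True
    return LN2 / -slope, False


def fit_decay(
    times: np.ndarray,
    abundance: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> DecayFit:
    """Fit first-order decay to (possibly replicated) time-course data.

    ``times`` and ``abundance`` are flat, parallel arrays; replicates simply
    repeat time points (pooled regression). Abundances must be positive
    (normalize to a loading control first, see
    :func:`densitometry_ratio`). The half-life CI is the 2.5-97.5 percentile
    range of ``n_boot`` residual-resampling refits; bootstrap refits with a
    non-negative slope push the upper bound to infinity.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(abundance, dtype=float)
    if t.shape != y.shape:
        raise DataValidationError("times and abundance must have equal length")
    if len(np.unique(t)) < 3:
        raise DataValidationError("need >= 3 distinct time points")
    if np.any(y <= 0):
        raise DataValidationError("abundances must be positive")
    if np.any(t < 0):
        raise DataValidationError("times must be non-negative")

    ln_y = np.log(y)
    slope, intercept = _ols(t, ln_y)
    fitted = slope * t + intercept
    resid = ln_y - fitted
    ss_tot = np.sum((ln_y - ln_y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    half, stable = _half_life(slope)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        s, _ = _ols(t, y_star)
        boot[i], _ = _half_life(s)
    finite = boot[np.isfinite(boot)]
    lo = float(np.percentile(finite, 2.5)) if finite.size else math.inf
    hi = (
        math.inf
        if (boot.size - finite.size) / boot.size > 0.025
        else float(np.percentile(finite, 97.5))
    )

    return DecayFit(
        rate=-slope,
        half_life=half,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r2)),
        ci_half_life=(lo, hi),
        n_points=int(t.size),
        stable=stable,
    )


def fit_decay_table(
    table, n_boot: int = 1000, seed: int = 0, per_replicate: bool = False
):
    """Fit a long time-course table (columns time_h, abundance[, replicate]).

    Pooled regression by default; with ``per_replicate`` each replicate is
    fitted separately and the list of fits returned.
    """
    if per_replicate:
        return [
            fit_decay(sub["time_h"].to_numpy(), sub["abundance"].to_numpy(), n_boot, seed)
            for _, sub in table.groupby("replicate", sort=True)
        ]
    return fit_decay(table["time_h"].to_numpy(), table["abundance"].to_numpy(), n_boot, seed)


def densitometry_ratio(
    target_signal: np.ndarray,
    loading_signal: np.ndarray,
    rescale_to_t0: bool = False,
) -> np.ndarray:
    """Band-intensity ratio target / loading control (e.g. GAPDH).

    With ``rescale_to_t0`` the series is divided by its first element so the
    time course starts at 1, ready for :func:`fit_decay`.
    """
    target = np.asarray(target_signal, dtype=float)
    loading = np.asarray(loading_signal, dtype=float)
    if np.any(loading <= 0):
        raise DataValidationError("loading-control signal must be positive")
    ratio = target / loading
    if rescale_to_t0:
        if ratio[0] <= 0:
            raise DataValidationError("t=0 ratio must be positive to rescale")
        ratio = ratio / ratio[0]
    return ratio


def relative_expression(
    ct_target: float, ct_reference: float, efficiency: float = 2.0
) -> float:
    """Fold expression of a target relative to a reference gene (delta-Ct).

    fold = efficiency^(Ct_reference - Ct_target); the ratio of two such
    folds across conditions is the delta-delta-Ct comparison.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise DataValidationError("Ct values must be finite")
    return float(efficiency ** (ct_reference - ct_target))
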