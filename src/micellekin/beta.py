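"""Inference of the beta-matrices of mutual rate modification.

The composition dependence of a probe's rate coefficient is modelled as
``k(f) = k_basal * (1 + f * beta)`` where ``f`` is the modulator fraction in
the cluster.  Binned rate estimates are fitted by weighted least squares
(weights 1/SEM^2, falling back to event counts when SEMs are unavailable)
and the fitted slope divided by the probe's basal rate -- measured in pure
(100% probe) clusters -- gives the dimensionless beta, reported also as a
percentage.  Same-species (diagonal) modulation is zero by definition: the
basal rate *is* the pure-cluster rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .kinetics import (
    EmptyReactionsError,
    RateEstimate,
    entry_rate_coefficient,
    exit_rate_coefficient,
    rate_vs_modulator_fraction,
)


@dataclass
class FitResult:
    """Weighted linear fit y ~ a + b x with the weighted R^2."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n_points: int
    weights: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared out of range")


def weighted_linear_fit(x, y, weights=None) -> FitResult:
    """Weighted least squares of y on x; minimises sum w (y - a - b x)^2.

    With constant y the slope is 0 and R^2 is reported as 0 (no variance
    explained).  All-identical x leaves the slope undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("all x identical; slope undefined")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        r2 = model.rsquared
        bse = np.asarray(model.bse)
    if not np.isfinite(r2):  # zero total (weighted) variance in y
        r2 = 0.0
    r2 = float(min(max(r2, 0.0), 1.0))
    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(bse[1]),
        intercept_se=float(bse[0]),
        r_squared=r2,
        n_points=len(x),
        weights=w,
    )


def beta_coefficient(fit: FitResult, basal: float, basal_se: float = 0.0):
    """Slope of the composition-rate regression over the basal rate.

    Returns ``(beta, beta_se)``; the SE propagates both the slope SE and,
    when given, the basal-rate SE.
    """
    if basal <= 0:
        raise ValueError("basal rate must be positive")
    beta = fit.slope / basal
    var = (fit.slope_se / basal) ** 2
    if basal_se and np.isfinite(basal_se):
        var += (fit.slope * basal_se / basal**2) ** 2
    return beta, float(np.sqrt(var))


def stars(r_squared: float) -> int:
    """Linearity-score annotation: 1 star for R^2 in [0.55, 0.7), 2 in
    [0.7, 0.85), 3 in [0.85, 1]; 0 below."""
    if 0.85 <= r_squared <= 1.0:
        return 3
    if 0.7 <= r_squared < 0.85:
        return 2
    if 0.55 <= r_squared < 0.7:
        return 1
    return 0


@dataclass
class BetaMatrix:
    """Basal rates plus the probe-by-modulator rate-modification matrix.

    ``beta[i, j]`` is the fractional modification of probe ``species[i]``'s
    rate by modulator ``species[j]``; ``beta_percent`` is exactly 100x that.
    Rows without an estimable basal rate are flagged in ``missing_basal``.
    """

    species: list[str]
    channel: str
    basal: np.ndarray
    basal_se: np.ndarray
    beta: np.ndarray
    beta_se: np.ndarray
    r_squared: np.ndarray
    star_matrix: np.ndarray
    missing_basal: list[str] = field(default_factory=list)

    @property
    def beta_percent(self) -> np.ndarray:
        return 100.0 * self.beta

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, probe in enumerate(self.species):
            for j, mod in enumerate(self.species):
                if i == j:
                    continue
                rows.append(
                    {
                        "probe": probe,
                        "modulator": mod,
                        "channel": self.channel,
                        "beta": self.beta[i, j],
                        "beta_percent": self.beta_percent[i, j],
                        "beta_se": self.beta_se[i, j],
                        "r_squared": self.r_squared[i, j],
                        "stars": int(self.star_matrix[i, j]),
                        "basal_rate": self.basal[i],
                    }
                )
        return pd.DataFrame(rows)


def basal_rate(reactions, probe: str, channel: str = "exit", pure_tol: float = 1e-6) -> RateEstimate:
    """Basal rate of a probe measured in pure (100% probe) clusters."""
    pure = [
        r
        for r in reactions
        if r.species == probe and r.composition.get(probe, 0.0) >= 1.0 - pure_tol
    ]
    est = exit_rate_coefficient if channel == "exit" else entry_rate_coefficient
    return est(pure, probe=probe, fraction=0.0)


def build_beta_matrix(
    reactions,
    channel: str,
    species: list[str],
    bin_width: float = 0.10,
    min_bin_events: int = 1,
    pure_tol: float = 1e-6,
) -> BetaMatrix:
    """Infer the full beta-matrix from (filtered) reactions of binary systems.

    For every probe-modulator pair the binary reactions are binned by
    modulator fraction, the binned rates fitted by WLS, and the slope divided
    by the probe's pure-cluster basal rate.  The diagonal is zero by
    convention; missing basal rates flag the whole row as absent (NaN).
    """
    s = len(species)
    beta = np.zeros((s, s))
    beta_se = np.zeros((s, s))
    r2 = np.zeros((s, s))
    star_m = np.zeros((s, s), dtype=int)
    basal = np.full(s, np.nan)
    basal_sem = np.full(s, np.nan)
    missing = []
    for i, probe in enumerate(species):
        try:
            b = basal_rate(reactions, probe, channel, pure_tol)
        except EmptyReactionsError:
            missing.append(probe)
            beta[i, :] = np.nan
            beta_se[i, :] = np.nan
            r2[i, :] = np.nan
            continue
        basal[i] = b.rate
        basal_sem[i] = b.sem
        for j, mod in enumerate(species):
            if i == j:
                continue
            ests = rate_vs_modulator_fraction(
                reactions, probe, mod, bin_width, channel, min_bin_events=min_bin_events
            )
            xs = np.array([e.fraction for e in ests])
            if len(ests) < 2 or np.ptp(xs) == 0:
                beta[i, j] = np.nan
                beta_se[i, j] = np.nan
                r2[i, j] = np.nan
                continue
            ys = np.array([e.rate for e in ests])
            sems = np.array([e.sem for e in ests])
            if np.all(np.isfinite(sems)) and np.all(sems > 0):
                w = 1.0 / sems**2
            else:  # SEM undefined for single-event bins: weight by counts
                w = np.array([e.n_events for e in ests], dtype=float)
            fit = weighted_linear_fit(xs, ys, w)
            beta[i, j], beta_se[i, j] = beta_coefficient(fit, basal[i], basal_sem[i])
            r2[i, j] = fit.r_squared
            star_m[i, j] = stars(fit.r_squared)
    return BetaMatrix(
        species=list(species),
        channel=channel,
        basal=basal,
        basal_se=basal_sem,
        beta=beta,
        beta_se=beta_se,
        r_squared=r2,
        star_matrix=star_m,
        missing_basal=missing,
    )
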