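"""Length normalization and linear temperature-trend fitting.

Chain-level N_w and N_pp scale with construct length, so curves are
divided by the peptide residue count before fitting.  Trends are ordinary
least squares on (temperature, normalized mean) with the slope confidence
interval taken from the t distribution with n-2 degrees of freedom at 90%
two-sided coverage; a weighted mode uses per-point standard errors
(sd / sqrt(n_frames)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_ci90: tuple[float, float]
    r_squared: float
    n_points: int
    confidence: float = 0.90
    _results: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci90
        if not (lo <= self.slope <= hi):
            raise ValueError("slope must lie inside its confidence interval")


def normalize_series(values, n_residues: int) -> np.ndarray:
    """Divide per-temperature means by the peptide residue count."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return np.asarray(values, dtype=float) / n_residues


def fit_linear_trend(
    x,
    y,
    y_sd=None,
    n_frames=None,
    confidence: float = 0.90,
) -> TrendFit:
    """Fit y = intercept + slope * x with a t-based slope CI.

    Supplying both ``y_sd`` and ``n_frames`` switches to weighted least
    squares with weights 1 / se^2 where se = sd / sqrt(n_frames).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values to fit a trend")
    exog = sm.add_constant(x)
    if y_sd is not None and n_frames is not None:
        se = np.asarray(y_sd, dtype=float) / np.sqrt(np.asarray(n_frames, dtype=float))
        if np.any(se <= 0):
            raise ValueError("weighted fit needs strictly positive standard errors")
        results = sm.WLS(y, exog, weights=1.0 / se**2).fit()
    else:
        results = sm.OLS(y, exog).fit()
    ci = results.conf_int(alpha=1.0 - confidence)
    ci = np.asarray(ci, dtype=float)
    r2 = float(results.rsquared)
    if not np.isfinite(r2):
        r2 = 1.0  # zero-residual fit on constant-free data
    return TrendFit(
        slope=float(results.params[1]),
        intercept=float(results.params[0]),
        slope_ci90=(float(ci[1, 0]), float(ci[1, 1])),
        r_squared=r2,
        n_points=len(x),
        confidence=confidence,
        _results=results,
    )


def confidence_band(fit: TrendFit, x_grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise confidence band of the fitted regression line.

    Returns (predicted mean, lower, upper) at ``fit.confidence`` coverage,
    using the standard regression-line variance formula.
    """
    if fit._results is None:
        raise ValueError("fit carries no underlying regression results")
    x_grid = np.asarray(x_grid, dtype=float)
    exog = sm.add_constant(x_grid, has_constant="add")
    pred = fit._results.get_prediction(exog)
    frame = pred.summary_frame(alpha=1.0 - fit.confidence)
    return (
        frame["mean"].to_numpy(),
        frame["mean_ci_lower"].to_numpy(),
        frame["mean_ci_upper"].to_numpy(),
    )
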