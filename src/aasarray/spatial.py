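"""Spatial analysis: pairwise station distances, posterior pairwise
correlations of the hour-level random effects, and the
correlation-versus-distance regression with its zero crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geometry import EARTH_RADIUS_M, haversine_matrix  # noqa: F401  (re-export)


def correlation_pairs(posterior, distances: np.ndarray) -> pd.DataFrame:
    """Posterior summaries of each station pair's correlation.

    For every unordered pair (j, k) the median and 25/75% quantiles
    of the posterior draws of R[j, k] are joined with the pair's
    great-circle distance.  J stations yield J(J-1)/2 rows.
    """
    R = posterior.stacked("R")  # (n_draws, J, J)
    J = R.shape[-1]
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (J, J):
        raise ValueError("distance matrix does not match the posterior's station count")
    ids = list(posterior.station_ids) or [f"s{j}" for j in range(J)]
    rows = []
    for j, k in combinations(range(J), 2):
        draws = R[:, j, k]
        q25, med, q75 = np.percentile(draws, [25, 50, 75])
        rows.append(
            {
                "station_a": ids[j],
                "station_b": ids[k],
                "distance_m": float(distances[j, k]),
                "rho_median": med,
                "rho_q25": q25,
                "rho_q75": q75,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DistanceRegression:
    """OLS fit of pair correlation on pair distance."""

    slope: float  # per meter
    intercept: float
    zero_crossing_m: float  # distance where the fitted correlation hits 0
    slope_se: float
    intercept_se: float
    r_squared: float
    n_pairs: int
    model: object = None  # fitted statsmodels results, for the CI band

    def predict_band(self, distances_m: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
        """Fitted line with its 95% confidence band."""
        X = sm.add_constant(np.asarray(distances_m, dtype=float))
        pred = self.model.get_prediction(X).summary_frame(alpha=alpha)
        return pd.DataFrame(
            {
                "distance_m": np.asarray(distances_m, dtype=float),
                "fit": pred["mean"].to_numpy(),
                "lo": pred["mean_ci_lower"].to_numpy(),
                "hi": pred["mean_ci_upper"].to_numpy(),
            }
        )


def corr_distance_regression(
    pairs: pd.DataFrame, response: str = "rho_median"
) -> DistanceRegression:
    """Ordinary least squares of pair correlation on distance.

    The response defaults to the posterior median per pair (the
    plotted points of the decay figure).  The zero crossing
    -intercept/slope is the distance at which the fitted correlation
    reaches zero; it is NaN for a flat fitted line.
    """
    d = pairs["distance_m"].to_numpy(dtype=float)
    rho = pairs[response].to_numpy(dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    if np.allclose(d, d[0]):
        raise ValueError("all pair distances identical: singular design")
    X = sm.add_constant(d)
    res = sm.OLS(rho, X).fit()
    intercept, slope = res.params
    bse = res.bse
    zero = -intercept / slope if slope != 0 else float("nan")
    return DistanceRegression(
        slope=float(slope),
        intercept=float(intercept),
        zero_crossing_m=float(zero),
        slope_se=float(bse[1]),
        intercept_se=float(bse[0]),
        r_squared=float(res.rsquared),
        n_pairs=len(d),
        model=res,
    )


def drawwise_regression(posterior, distances: np.ndarray) -> pd.DataFrame:
    """Per-draw regression variant propagating posterior uncertainty.

    Fits the correlation-distance line to every posterior draw of R
    and returns one row per draw (slope, intercept, zero_crossing_m),
    whose quantiles summarize the uncertainty of the decay.
    """
    R = posterior.stacked("R")
    J = R.shape[-1]
    ji, ki = np.triu_indices(J, k=1)
    d = np.asarray(distances, dtype=float)[ji, ki]
    X = np.column_stack([np.ones_like(d), d])
    XtX_inv_Xt = np.linalg.pinv(X)
    coefs = R[:, ji, ki] @ XtX_inv_Xt.T  # (n_draws, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        zero = np.where(coefs[:, 1] != 0, -coefs[:, 0] / coefs[:, 1], np.nan)
    return pd.DataFrame(
        {"intercept": coefs[:, 0], "slope": coefs[:, 1], "zero_crossing_m": zero}
    )
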