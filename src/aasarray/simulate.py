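"""Synthetic-data generator for the hydrophone-array pipeline.

Generates every input the analysis needs from one seeded
configuration: array geometry, a fish-mass trajectory with proximity
categories, hourly AAS counts from the hierarchical Poisson process,
per-minute detection streams in 2-s bins with injected interference,
and paired true/predicted classifier label streams.

The hourly counts follow the call-rate model exactly: for station j
and study hour i,

    V[j,i] ~ Poisson(mu[j,i]),
    log mu[j,i] = log tau[j,i] + T[t(i)] + D[d(i)] + FP[f(j,i)] + h[j,i],
    h[.,i] ~ MVNormal(0, diag(sigma) R diag(sigma)),

so fits to generated data are parameter-recovery experiments with a
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess
from .config import SimulationConfig
from .geometry import StationGeometry, haversine_matrix, make_geometry
from .preprocess import BINS_PER_MINUTE, MINUTES_PER_HOUR, MINUTE, HOUR


@dataclass
class TrueParameters:
    """The generating parameter set of the call-rate process."""

    T: np.ndarray  # (24,) hour-of-day log-rate effects
    D: np.ndarray  # (7,) DAFS -4..+2 log-rate effects
    FP: np.ndarray  # (3,) proximity log-rate effects
    sigma_h: np.ndarray  # (J,) per-station random-effect SDs
    R: np.ndarray  # (J, J) station correlation matrix
    h: np.ndarray | None = None  # (H, J) random-effect draws, filled on simulation

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.FP = np.asarray(self.FP, dtype=float)
        self.sigma_h = np.asarray(self.sigma_h, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.T.shape != (24,) or self.D.shape != (7,) or self.FP.shape != (3,):
            raise ValueError("effect templates must have lengths 24, 7, 3")
        if np.any(self.sigma_h < 0):
            raise ValueError("sigma_h must be >= 0")
        validate_correlation(self.R)


def validate_correlation(R: np.ndarray, tol: float = 1e-8) -> None:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=tol):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=tol):
        raise ValueError("R must have a unit diagonal")
    if np.any(np.abs(R) > 1.0 + tol):
        raise ValueError("correlation entries must lie in [-1, 1]")
    if np.linalg.eigvalsh(R).min() < -tol:
        raise ValueError("R must be positive semidefinite")


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation
    matrix: clip negative eigenvalues, renormalize the diagonal."""
    R = 0.5 * (np.asarray(R, dtype=float) + np.asarray(R, dtype=float).T)
    w, v = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    A = (v * w) @ v.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return 0.5 * (A + A.T)


def distance_corr_matrix(distances_m: np.ndarray, decay_m: float) -> np.ndarray:
    """Exponential distance kernel R[j,k] = exp(-d[j,k] / decay_m).

    Monotone nonincreasing in pair distance and always a valid
    correlation matrix.
    """
    if decay_m <= 0:
        raise ValueError("decay_m must be positive")
    R = np.exp(-np.asarray(distances_m, dtype=float) / decay_m)
    np.fill_diagonal(R, 1.0)
    return nearest_psd_correlation(R)


def true_parameters(config: SimulationConfig, geometry=None) -> TrueParameters:
    """Assemble the generating parameters implied by a configuration."""
    if geometry is None:
        geometry = make_geometry(config)
    if config.corr_matrix is not None:
        R = nearest_psd_correlation(np.asarray(config.corr_matrix, dtype=float))
    else:
        R = distance_corr_matrix(haversine_matrix(geometry), config.corr_decay_m)
    return TrueParameters(
        T=np.asarray(config.effects_T, dtype=float),
        D=np.asarray(config.effects_D, dtype=float),
        FP=np.asarray(config.effects_FP, dtype=float),
        sigma_h=config.sigma_vector,
        R=R,
    )


# ----------------------------------------------------------------------
# fish-mass trajectory and proximity categories
# ----------------------------------------------------------------------
def simulate_fsa_trajectory(config: SimulationConfig, geometry) -> pd.DataFrame:
    """Hourly proximity category (0/1/2) of the fish mass per station.

    The aggregation's bulk position is a 1-D along-array reflected
    Gaussian random walk (the array is linear; observed movement is
    along-shelf), optionally with a persistent shift episode moving
    the mass several hundred meters partway through the study.
    Categories: 2 if the mass is within 20 m of the station, 1 within
    100 m, else 0.

    Returns a long DataFrame: station_id, hour, hour_start, FP_index,
    plus the latent along-array position (m) for recovery tests.
    """
    if not geometry:
        raise ValueError("geometry must be nonempty")
    rng = config.rng("trajectory")
    n_st = len(geometry)
    station_pos = np.arange(n_st) * config.spacing_m
    lo = -config.traj_margin_m
    hi = station_pos[-1] + config.traj_margin_m

    start = config.traj_start_m
    if start is None:
        start = station_pos[min(2, n_st - 1)]
    shift_hour = config.traj_shift_hour
    if shift_hour is None:
        shift_hour = config.first_spawn_hour

    pos = np.empty(config.n_hours)
    p = float(np.clip(start, lo, hi))
    for t in range(config.n_hours):
        if t > 0:
            p += rng.normal(0.0, config.traj_walk_sd_m)
        if t == shift_hour and config.traj_shift_m:
            p += config.traj_shift_m
        # reflect into [lo, hi]
        span = hi - lo
        if span > 0:
            q = (p - lo) % (2.0 * span)
            p = lo + (q if q <= span else 2.0 * span - q)
        else:
            p = lo
        pos[t] = p

    t0 = pd.Timestamp(config.start_time)
    rows = []
    for j, g in enumerate(geometry):
        dist = np.abs(pos - station_pos[j])
        fp = np.where(dist <= 20.0, 2, np.where(dist <= 100.0, 1, 0))
        rows.append(
            pd.DataFrame(
                {
                    "station_id": g.station_id,
                    "hour": np.arange(config.n_hours),
                    "hour_start": t0 + pd.to_timedelta(np.arange(config.n_hours), unit="h"),
                    "FP_index": fp.astype(int),
                    "mass_position_m": pos,
                    "station_position_m": station_pos[j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------------
# minute annotation table (interference process) and covariate design
# ----------------------------------------------------------------------
def simulate_minute_table(config: SimulationConfig, geometry) -> pd.DataFrame:
    """Per-minute annotation table with the interference process.

    Every 5th minute of each station's record is in the inspection
    subsample; each sampled minute is independently flagged as
    interference with probability ``interference_frac``.  Flags are
    expanded +/- 2 min (the annotation convention for uninspected
    neighbors), yielding the ``observed`` flag used for effort.
    """
    rng = config.rng("interference")
    t0 = pd.Timestamp(config.start_time)
    n_min = config.n_hours * MINUTES_PER_HOUR
    minute_starts = t0 + pd.to_timedelta(np.arange(n_min), unit="m")
    frames = []
    for g in geometry:
        sampled = np.arange(n_min) % 5 == 0
        interference = np.zeros(n_min, dtype=bool)
        interference[sampled] = rng.random(int(sampled.sum())) < config.interference_frac
        frames.append(
            pd.DataFrame(
                {
                    "station_id": g.station_id,
                    "minute_start": minute_starts,
                    "sampled": sampled,
                    "interference": interference,
                }
            )
        )
    minutes = pd.concat(frames, ignore_index=True)
    return preprocess.apply_interference(minutes)


def dafs_index(hour: np.ndarray, first_spawn_hour: int) -> np.ndarray:
    """Study-hour index -> D category (0..6 for DAFS -4..+2)."""
    d = np.floor_divide(np.asarray(hour, dtype=int) - int(first_spawn_hour), 24) + 4
    if np.any(d < 0) or np.any(d > 6):
        raise ValueError("hour range implies DAFS outside -4..+2; adjust first_spawn_hour")
    return d.astype(int)


def build_design(config: SimulationConfig, minutes: pd.DataFrame, trajectory: pd.DataFrame) -> pd.DataFrame:
    """Station-hour design: tau from observed minutes, covariate indices.

    Station-hours with zero observed minutes are absent (dropped
    upstream of the count model, mirroring effort computation).
    """
    eff = preprocess.compute_effort(minutes)
    t0 = pd.Timestamp(config.start_time)
    eff["hour"] = ((eff["hour_start"] - t0) / HOUR).astype(int)
    eff["T_index"] = eff["hour_start"].dt.hour.astype(int)
    eff["D_index"] = dafs_index(eff["hour"].to_numpy(), config.first_spawn_hour)
    design = eff.merge(
        trajectory[["station_id", "hour_start", "FP_index"]],
        on=["station_id", "hour_start"],
        how="left",
    )
    if design["FP_index"].isna().any():
        raise ValueError("trajectory does not cover all observed station-hours")
    design["FP_index"] = design["FP_index"].astype(int)
    return design.sort_values(["station_id", "hour_start"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# hourly counts
# ----------------------------------------------------------------------
def simulate_hour_counts(
    params: TrueParameters, design: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Draw the HourCell table from the hierarchical Poisson process.

    ``design`` needs station_id, hour (int study-hour), hour_start,
    tau, T_index, D_index, FP_index; all tau must lie in (0, 1].  One
    J-dimensional h-vector is drawn per distinct hour from
    MVNormal(0, diag(sigma) R diag(sigma)); stations missing from an
    hour simply do not use their component.  The latent h is returned
    in column ``h`` for recovery tests.
    """
    tau = design["tau"].to_numpy(dtype=float)
    if np.any(tau <= 0) or np.any(tau > 1):
        raise ValueError("tau must lie in (0, 1]; drop zero-effort cells upstream")
    for col, n in (("T_index", 24), ("D_index", 7), ("FP_index", 3)):
        idx = design[col].to_numpy(dtype=int)
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(f"{col} out of range 0..{n - 1}")

    stations = sorted(design["station_id"].unique())
    J = len(stations)
    if params.R.shape[0] != J:
        raise ValueError(f"params are {params.R.shape[0]}-station but design has {J}")
    hours = np.sort(design["hour"].unique())
    H = len(hours)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))
    cov = np.diag(params.sigma_h) @ params.R @ np.diag(params.sigma_h)
    # draw via Cholesky with a tiny jitter for semidefinite R
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(J))
    h_all = rng.standard_normal((H, J)) @ L.T

    st_idx = design["station_id"].map({s: j for j, s in enumerate(stations)}).to_numpy()
    hr_idx = design["hour"].map({h: i for i, h in enumerate(hours)}).to_numpy()
    h_cell = h_all[hr_idx, st_idx]
    eta = (
        params.T[design["T_index"].to_numpy(dtype=int)]
        + params.D[design["D_index"].to_numpy(dtype=int)]
        + params.FP[design["FP_index"].to_numpy(dtype=int)]
        + h_cell
    )
    mu = tau * np.exp(eta)
    V = rng.poisson(mu)

    out = design.copy()
    out["h"] = h_cell
    out["V"] = V.astype(int)
    out["rate"] = out["V"] / out["tau"]
    params.h = h_all
    return out


# ----------------------------------------------------------------------
# minute-level detection streams
# ----------------------------------------------------------------------
def simulate_minute_stream(
    hourcells: pd.DataFrame, minutes: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Place each hour's V detections into distinct 2-s bins.

    Events are scattered uniformly at random over the 2-s bins of the
    hour's observed minutes, at most one per bin (the classifier
    convention), and never fall in non-observed (interference)
    minutes.  Raises if V exceeds the available bins.

    Returns the event table: station_id, minute_start, bin_index.
    """
    if seed is None:
        rng = config.rng("events")
    else:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(2,)))
    if (hourcells["V"] < 0).any():
        raise ValueError("hour counts must be >= 0")
    obs = minutes.loc[minutes["observed"], ["station_id", "minute_start"]].copy()
    obs["hour_start"] = obs["minute_start"].dt.floor("h")
    obs_by_cell = {
        key: grp["minute_start"].sort_values().to_numpy()
        for key, grp in obs.groupby(["station_id", "hour_start"], sort=False)
    }
    recs = []
    for row in hourcells.itertuples(index=False):
        V = int(row.V)
        if V == 0:
            continue
        mins = obs_by_cell.get((row.station_id, pd.Timestamp(row.hour_start)))
        n_bins = 0 if mins is None else len(mins) * BINS_PER_MINUTE
        if V > n_bins:
            raise ValueError(
                f"{row.station_id} {row.hour_start}: V={V} exceeds the "
                f"{n_bins} available 2-s bins in observed minutes"
            )
        slots = rng.choice(n_bins, size=V, replace=False)
        recs.append(
            pd.DataFrame(
                {
                    "station_id": row.station_id,
                    "minute_start": mins[slots // BINS_PER_MINUTE],
                    "bin_index": (slots % BINS_PER_MINUTE).astype(int),
                }
            )
        )
    if not recs:
        return pd.DataFrame(columns=["station_id", "minute_start", "bin_index"])
    events = pd.concat(recs, ignore_index=True)
    return events.sort_values(["station_id", "minute_start", "bin_index"]).reset_index(drop=True)


def simulate_classifier(
    true_events: pd.DataFrame,
    minutes: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired true/predicted 2-s-bin detection streams.

    Each true event is detected independently with probability
    ``classifier_tpr``; false alarms are added in empty bins of
    observed minutes, each of a minute's 30 bins firing with
    probability ``classifier_fp_per_min / 30`` (an expected
    ``classifier_fp_per_min`` false alarms per observed minute when
    the stream is sparse).
    """
    if seed is None:
        rng = config.rng("classifier")
    else:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(3,)))
    detected = true_events.loc[
        rng.random(len(true_events)) < config.classifier_tpr
    ].copy()

    obs = minutes.loc[minutes["observed"], ["station_id", "minute_start"]].reset_index(drop=True)
    p_bin = config.classifier_fp_per_min / BINS_PER_MINUTE
    fa_mask = rng.random((len(obs), BINS_PER_MINUTE)) < p_bin
    rows, cols = np.nonzero(fa_mask)
    false_alarms = pd.DataFrame(
        {
            "station_id": obs["station_id"].to_numpy()[rows],
            "minute_start": obs["minute_start"].to_numpy()[rows],
            "bin_index": cols.astype(int),
        }
    )
    # false alarms land only in bins with no true event
    if len(false_alarms) and len(true_events):
        key = ["station_id", "minute_start", "bin_index"]
        false_alarms = false_alarms.merge(
            true_events[key].assign(_true=True), on=key, how="left"
        )
        false_alarms = false_alarms.loc[false_alarms["_true"].isna(), key]
    predicted = pd.concat([detected, false_alarms], ignore_index=True)
    predicted = predicted.sort_values(
        ["station_id", "minute_start", "bin_index"]
    ).reset_index(drop=True)
    true_sorted = true_events.sort_values(
        ["station_id", "minute_start", "bin_index"]
    ).reset_index(drop=True)
    return true_sorted, predicted


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------
def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator stage from one configuration.

    Returns a dict with geometry, true parameters, trajectory, minute
    table, hourcell table (with latent h), true/predicted event
    streams — everything the downstream pipeline consumes, all
    bit-reproducible for a fixed seed.
    """
    geometry = make_geometry(config)
    params = true_parameters(config, geometry)
    trajectory = simulate_fsa_trajectory(config, geometry)
    minutes = simulate_minute_table(config, geometry)
    design = build_design(config, minutes, trajectory)
    hourcells = simulate_hour_counts(params, design, seed=config.seed)
    events = simulate_minute_stream(hourcells, minutes, config)
    true_stream, predicted_stream = simulate_classifier(events, minutes, config)
    return {
        "geometry": geometry,
        "params": params,
        "trajectory": trajectory,
        "minutes": minutes,
        "design": design,
        "hourcells": hourcells,
        "events": true_stream,
        "predicted_events": predicted_stream,
    }


def geometry_frame(geometry: list[StationGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"station_id": g.station_id, "instrument": g.instrument, "lat": g.lat, "lon": g.lon} for g in geometry]
    )
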