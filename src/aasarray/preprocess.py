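"""Detection preprocessing: 2-s dedup binning, interference
subsampling/exclusion, effort computation, hourly aggregation, and
abundance/proximity categorization.

The unit this module produces is the HourCell: station j x hour i with
detection count V, effort tau (fraction of the hour's minutes retained
after interference exclusion, in (0, 1]), and the covariate category
indices consumed by the call-rate model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIN_SECONDS = 2
BINS_PER_MINUTE = 30
MINUTES_PER_HOUR = 60

MINUTE = pd.Timedelta(minutes=1)
HOUR = pd.Timedelta(hours=1)


# ----------------------------------------------------------------------
# 2-s binning
# ----------------------------------------------------------------------
def bin_events(call_times, station_id: str, minute_start) -> pd.DataFrame:
    """Collapse within-minute call times onto the 2-s bin grid.

    Bins are anchored at even seconds from the start of the minute;
    each bin holds at most one detection, and when several calls share
    a bin the earliest is retained.  Times outside [0, 60) s are
    rejected (dropped with a log message).

    Returns a DataFrame with columns station_id, minute_start,
    bin_index sorted by bin_index.
    """
    minute_start = pd.Timestamp(minute_start)
    times = np.asarray(list(call_times), dtype=float)
    ok = (times >= 0.0) & (times < 60.0)
    if not ok.all():
        logger.warning(
            "dropping %d out-of-range call time(s) at %s %s",
            int((~ok).sum()), station_id, minute_start,
        )
        times = times[ok]
    if times.size == 0:
        return pd.DataFrame(columns=["station_id", "minute_start", "bin_index"])
    order = np.argsort(times, kind="stable")
    bins = (times[order] // BIN_SECONDS).astype(int)
    # first occurrence per bin == earliest call in that bin
    _, first = np.unique(bins, return_index=True)
    kept = np.sort(bins[np.sort(first)])
    return pd.DataFrame(
        {"station_id": station_id, "minute_start": minute_start, "bin_index": kept}
    )


# ----------------------------------------------------------------------
# interference subsample / exclusion
# ----------------------------------------------------------------------
def subsample_minutes(minutes, period: int = 5) -> pd.Series:
    """Deterministic 1-in-``period`` subsample of each station's record.

    ``minutes`` is a DataFrame with station_id and minute_start.
    Selection starts from the first minute of each station's record;
    returns a boolean Series aligned with ``minutes``.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    sampled = pd.Series(False, index=minutes.index)
    for _, grp in minutes.groupby("station_id", sort=False):
        order = grp["minute_start"].sort_values(kind="stable")
        idx = np.arange(len(order))
        sampled.loc[order.index[idx % period == 0]] = True
    return sampled


def expand_interference(flagged_minutes, record_minutes, window_min: int = 2) -> set:
    """Union of closed +/- ``window_min`` windows around each flagged
    minute, clipped to the station's record.

    Both arguments are iterables of minute-start timestamps for one
    station; returns the set of excluded minute starts.  Two flags in
    the same 5-min subsample block (e.g. 10:00 and 10:05) produce one
    contiguous exclusion covering everything in between.
    """
    record = {pd.Timestamp(m) for m in record_minutes}
    excluded: set = set()
    for m in flagged_minutes:
        m = pd.Timestamp(m)
        for k in range(-window_min, window_min + 1):
            t = m + k * MINUTE
            if t in record:
                excluded.add(t)
    return excluded


def apply_interference(minutes: pd.DataFrame, window_min: int = 2) -> pd.DataFrame:
    """Attach the ``observed`` flag to a per-minute annotation table.

    ``minutes`` needs columns station_id, minute_start, sampled,
    interference (flags meaningful only on sampled minutes).  A minute
    is observed iff it does not fall inside the +/- ``window_min``
    exclusion window of any flagged sampled minute of its station.
    """
    out = minutes.copy()
    out["minute_start"] = pd.to_datetime(out["minute_start"])
    observed = pd.Series(True, index=out.index)
    for sid, grp in out.groupby("station_id", sort=False):
        flagged = grp.loc[grp["sampled"] & grp["interference"], "minute_start"]
        if len(flagged) == 0:
            continue
        excluded = expand_interference(flagged, grp["minute_start"], window_min)
        observed.loc[grp.index[grp["minute_start"].isin(excluded)]] = False
    out["observed"] = observed
    return out


# ----------------------------------------------------------------------
# effort and hourly aggregation
# ----------------------------------------------------------------------
def compute_effort(minute_records: pd.DataFrame) -> pd.DataFrame:
    """Effort tau per (station, hour): observed minutes / 60.

    Hours with zero observed minutes are dropped (logged), never
    emitted as tau = 0.  The denominator is fixed at 60 even for
    partially recorded edge hours, which simply get lower tau.
    """
    m = minute_records
    hours = m["minute_start"].dt.floor("h")
    eff = (
        m.assign(hour_start=hours)
        .groupby(["station_id", "hour_start"], sort=True)["observed"]
        .sum()
        .rename("observed_minutes")
        .reset_index()
    )
    n_zero = int((eff["observed_minutes"] == 0).sum())
    if n_zero:
        logger.info("dropping %d station-hour(s) with no observable minutes", n_zero)
    eff = eff[eff["observed_minutes"] > 0].copy()
    eff["tau"] = eff["observed_minutes"] / MINUTES_PER_HOUR
    return eff.drop(columns="observed_minutes")


def aggregate_hourly(
    events: pd.DataFrame, minute_records: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Sum detections per (station, hour) into model-ready HourCells.

    ``events``: station_id, minute_start, bin_index (deduped 2-s bins).
    ``minute_records``: per-minute table carrying the observed flag.
    ``covariates``: station_id, hour_start, D_index, FP_index (the
    hour-of-day index T_index is derived from the clock).

    Raises if any event falls in a non-observed minute — the pipeline
    must exclude interference before counting.
    """
    eff = compute_effort(minute_records)
    obs_key = minute_records.loc[minute_records["observed"], ["station_id", "minute_start"]]
    if len(events):
        ev = events.merge(
            obs_key.assign(_obs=True), on=["station_id", "minute_start"], how="left"
        )
        if ev["_obs"].isna().any():
            bad = ev.loc[ev["_obs"].isna()].iloc[0]
            raise ValueError(
                "event in non-observed minute "
                f"({bad['station_id']} {bad['minute_start']}): interference "
                "exclusion must run before aggregation"
            )
        counts = (
            ev.assign(hour_start=ev["minute_start"].dt.floor("h"))
            .groupby(["station_id", "hour_start"], sort=True)
            .size()
            .rename("V")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["station_id", "hour_start", "V"])
    cells = eff.merge(counts, on=["station_id", "hour_start"], how="left")
    cells["V"] = pd.to_numeric(cells["V"]).fillna(0).astype(int)
    cells["rate"] = cells["V"] / cells["tau"]
    cells["T_index"] = cells["hour_start"].dt.hour.astype(int)
    cov = covariates.copy()
    cov["hour_start"] = pd.to_datetime(cov["hour_start"])
    cells = cells.merge(
        cov[["station_id", "hour_start", "D_index", "FP_index"]],
        on=["station_id", "hour_start"],
        how="left",
    )
    if cells[["D_index", "FP_index"]].isna().any().any():
        missing = cells.loc[cells["D_index"].isna() | cells["FP_index"].isna()].iloc[0]
        raise ValueError(
            f"missing covariates for {missing['station_id']} {missing['hour_start']}"
        )
    cells["D_index"] = cells["D_index"].astype(int)
    cells["FP_index"] = cells["FP_index"].astype(int)
    cols = ["station_id", "hour_start", "V", "tau", "rate", "T_index", "D_index", "FP_index"]
    return cells[cols].sort_values(["station_id", "hour_start"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# abundance / proximity categorization
# ----------------------------------------------------------------------
def categorize_maxn(maxn: int) -> int:
    """MaxN count -> abundance category.

    absent (0), individual (1), few 2-10 (2), many 11-100 (3),
    abundant >100 (4).
    """
    maxn = int(maxn)
    if maxn < 0:
        raise ValueError("MaxN must be >= 0")
    if maxn == 0:
        return 0
    if maxn == 1:
        return 1
    if maxn <= 10:
        return 2
    if maxn <= 100:
        return 3
    return 4


#: distance-class labels accepted by composite_proximity
_PROX_CLASS = {"within_20m": 2, "within_100m": 1, "beyond_100m": 0, "none": 0}


def proximity_from_distance(distance_m: float) -> int:
    """Distance of the fish mass to the hydrophone -> FP category."""
    if distance_m <= 20.0:
        return 2
    if distance_m <= 100.0:
        return 1
    return 0


def composite_proximity(observations) -> int:
    """Fuse multiple sourced distance claims into one FP category.

    Each observation is a distance class label (within_20m /
    within_100m / beyond_100m / none) or a numeric distance in meters.
    "present" dominates "nearby" dominates "not observed": the most
    informative source wins.
    """
    cat = 0
    for obs in observations:
        if isinstance(obs, str):
            try:
                c = _PROX_CLASS[obs]
            except KeyError:
                raise ValueError(f"unknown distance class {obs!r}") from None
        else:
            c = proximity_from_distance(float(obs))
        cat = max(cat, c)
    return cat
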