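"""Pipeline orchestration: run stages in dependency order under a run
directory, with a manifest recording the configuration, seed and a
checksum of every artifact.

Stages and their products (all headered CSV, ISO-8601 local-clock
timestamps):

    simulate    geometry, minute annotations, trajectory, true
                hourcells (with latent h), true/predicted event streams
    preprocess  model-ready hourcells from the minute/event tables
    evaluate    per-station evaluation samples, confusion counts and
                metrics (plus the published reference tables)
    fit         posterior draws, effect summaries, convergence table
    spatial     pair correlation summaries, distance regression
    report      heat-map matrices and box-plot summary tables

Identical configuration and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import confusion as cf
from . import model as mdl
from . import preprocess as pp
from . import reporting, simulate, spatial
from .config import SimulationConfig
from .geometry import haversine_matrix
from .lkj import n_cpc  # noqa: F401
from .simulate import geometry_frame

STAGES = ("simulate", "preprocess", "evaluate", "fit", "spatial", "report")

_FLOAT_FMT = "%.12g"
_BOOL_COLS = ("sampled", "interference", "observed")


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream product."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)  # relpath -> sha256
    versions: dict = field(default_factory=dict)
    created: str = ""

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in _BOOL_COLS:
        if c in out.columns:
            out[c] = out[c].astype(int)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv(path: Path, time_cols=()) -> pd.DataFrame:
    if not path.exists():
        raise DependencyError(f"missing upstream table {path.name}; run its stage first")
    df = pd.read_csv(path)
    for c in time_cols:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    for c in _BOOL_COLS:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df


def run_pipeline(
    config: SimulationConfig | str | Path,
    out_dir: str | Path,
    stages=None,
    seed: int | None = None,
    chains: int = 3,
    iterations: int = 1000,
    figures: bool = False,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``stages`` is any subset of {simulate, preprocess, evaluate, fit,
    spatial, report} (default all).  All randomness flows from the
    configured seed (``seed`` overrides the config's).  Outputs land
    under ``out_dir``; a manifest.json lists every artifact with its
    checksum.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        versions={
            "aasarray": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        created=datetime.now(timezone.utc).isoformat(),
    )
    posterior = None  # carried between fit and spatial within one run

    for stage in requested:
        if stage == "simulate":
            sim = simulate.simulate_all(config)
            _write_csv(geometry_frame(sim["geometry"]), out / "geometry.csv")
            _write_csv(sim["minutes"], out / "minutes.csv")
            _write_csv(sim["trajectory"], out / "trajectory.csv")
            _write_csv(sim["hourcells"], out / "hourcells_true.csv")
            _write_csv(sim["events"], out / "events.csv")
            _write_csv(sim["predicted_events"], out / "predicted_events.csv")
            p = sim["params"]
            with open(out / "true_parameters.json", "w") as fh:
                json.dump(
                    {
                        "T": p.T.tolist(),
                        "D": p.D.tolist(),
                        "FP": p.FP.tolist(),
                        "sigma_h": p.sigma_h.tolist(),
                        "R": p.R.tolist(),
                    },
                    fh,
                    indent=1,
                )

        elif stage == "preprocess":
            minutes = _read_csv(out / "minutes.csv", time_cols=("minute_start",))
            events = _read_csv(out / "events.csv", time_cols=("minute_start",))
            trajectory = _read_csv(out / "trajectory.csv", time_cols=("hour_start",))
            minutes = pp.apply_interference(minutes[["station_id", "minute_start", "sampled", "interference"]])
            t0 = pd.Timestamp(config.start_time)
            cov = trajectory[["station_id", "hour_start", "FP_index"]].copy()
            hour_idx = ((cov["hour_start"] - t0) / pp.HOUR).astype(int)
            cov["D_index"] = simulate.dafs_index(hour_idx.to_numpy(), config.first_spawn_hour)
            hourcells = pp.aggregate_hourly(events, minutes, cov)
            _write_csv(hourcells, out / "hourcells.csv")

        elif stage == "evaluate":
            minutes = _read_csv(out / "minutes.csv", time_cols=("minute_start",))
            events = _read_csv(out / "events.csv", time_cols=("minute_start",))
            predicted = _read_csv(out / "predicted_events.csv", time_cols=("minute_start",))
            rng = config.rng("evaluate")
            counts = []
            for sid in sorted(minutes["station_id"].unique()):
                cand = minutes[(minutes["station_id"] == sid) & minutes["observed"]]
                ev = events[events["station_id"] == sid]
                sample = cf.draw_eval_sample(cand, ev, seed=rng)
                c = cf.confusion_counts(
                    events, predicted, sample.minutes, label=f"{sid} simulated"
                )
                counts.append(c)
            counts.append(cf.pool(counts, label="all stations simulated"))
            _write_csv(cf.counts_table(counts), out / "confusion_table.csv")
            _write_csv(cf.metrics_table(counts), out / "metrics.csv")
            ref = cf.load_reference_counts()
            ref_counts = [cf.counts_from_row(r) for _, r in ref.iterrows()]
            _write_csv(cf.counts_table(ref_counts), out / "reference_counts.csv")
            _write_csv(cf.metrics_table(ref_counts), out / "reference_metrics.csv")

        elif stage == "fit":
            hourcells = _read_csv(out / "hourcells.csv", time_cols=("hour_start",))
            design = mdl.encode_design(hourcells)
            posterior = mdl.fit(
                design, chains=chains, iterations=iterations, seed=config.seed
            )
            _write_csv(_draws_frame(posterior), out / "posterior_draws.csv")
            with open(out / "posterior_meta.json", "w") as fh:
                json.dump(
                    {
                        "station_ids": posterior.station_ids,
                        "chains": posterior.n_chains,
                        "draws_per_chain": posterior.n_draws,
                        "sampler": posterior.sampler_info,
                    },
                    fh,
                    indent=1,
                )
            _write_csv(mdl.predict_effects(posterior), out / "effects_summary.csv")
            conv = mdl.convergence(posterior)
            _write_csv(conv, out / "convergence.csv")

        elif stage == "spatial":
            geometry = _read_csv(out / "geometry.csv")
            if posterior is None:
                posterior = _load_posterior(out)
            order = {sid: k for k, sid in enumerate(geometry["station_id"])}
            geo = sorted(
                (row for _, row in geometry.iterrows() if row["station_id"] in posterior.station_ids),
                key=lambda r: posterior.station_ids.index(r["station_id"]),
            )
            from .geometry import StationGeometry

            dist = haversine_matrix(
                [StationGeometry(r["station_id"], r["instrument"], r["lat"], r["lon"]) for r in geo]
            )
            pairs = spatial.correlation_pairs(posterior, dist)
            _write_csv(pairs, out / "pairs.csv")
            reg = spatial.corr_distance_regression(pairs)
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "slope_per_m": reg.slope,
                            "intercept": reg.intercept,
                            "zero_crossing_m": reg.zero_crossing_m,
                            "slope_se": reg.slope_se,
                            "intercept_se": reg.intercept_se,
                            "r_squared": reg.r_squared,
                            "n_pairs": reg.n_pairs,
                        }
                    ]
                ),
                out / "regression.csv",
            )

        elif stage == "report":
            hourcells = _read_csv(out / "hourcells.csv", time_cols=("hour_start",))
            _write_csv(
                reporting.proximity_matrix(hourcells).reset_index(), out / "proximity_matrix.csv"
            )
            _write_csv(reporting.rate_matrix(hourcells).reset_index(), out / "rate_matrix.csv")
            _write_csv(reporting.hourly_box_table(hourcells), out / "hourly_box.csv")
            _write_csv(reporting.daily_box_table(hourcells), out / "daily_box.csv")
            if figures:
                reporting.save_figures(out, hourcells)

        manifest.stages.append(stage)

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.files[path.name] = _sha256(path)
    manifest.to_json(out / "manifest.json")
    return manifest


# ----------------------------------------------------------------------
def _draws_frame(posterior) -> pd.DataFrame:
    """Wide per-draw table of the interpretable parameters (the bulky
    latent h draws stay in memory; persisted columns are the effect
    vectors, SDs and the correlation entries)."""
    J = posterior.R.shape[-1]
    cols = {}
    chains, draws = posterior.T.shape[:2]
    idx = pd.MultiIndex.from_product([range(chains), range(draws)], names=["chain", "draw"])
    for name, k in (("T", 24), ("D", 7), ("FP", 3)):
        arr = getattr(posterior, name).reshape(-1, k)
        for i in range(k):
            cols[f"{name}[{i}]"] = arr[:, i]
    sig = posterior.sigma_h.reshape(-1, J)
    for j in range(J):
        cols[f"sigma_h[{j}]"] = sig[:, j]
    R = posterior.R.reshape(-1, J, J)
    for j in range(J):
        for k in range(j):
            cols[f"R[{j},{k}]"] = R[:, j, k]
    cols["lp"] = posterior.lp.reshape(-1)
    df = pd.DataFrame(cols, index=idx).reset_index()
    return df


def _load_posterior(out: Path):
    """Rebuild the minimal posterior (R draws + station ids) that the
    spatial stage needs from the persisted draw table."""
    draws = _read_csv(out / "posterior_draws.csv")
    meta_path = out / "posterior_meta.json"
    if not meta_path.exists():
        raise DependencyError("missing posterior_meta.json; run the fit stage first")
    meta = json.loads(meta_path.read_text())
    station_ids = meta["station_ids"]
    J = len(station_ids)
    chains = draws["chain"].nunique()
    per_chain = len(draws) // chains
    R = np.zeros((chains, per_chain, J, J))
    R[..., range(J), range(J)] = 1.0
    for j in range(J):
        for k in range(j):
            vals = draws[f"R[{j},{k}]"].to_numpy().reshape(chains, per_chain)
            R[:, :, j, k] = vals
            R[:, :, k, j] = vals

    class _RPosterior:
        def __init__(self, R, station_ids):
            self.R = R
            self.station_ids = station_ids

        def stacked(self, name):
            arr = getattr(self, name)
            return arr.reshape(-1, *arr.shape[2:])

    return _RPosterior(R, station_ids)
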