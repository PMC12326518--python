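"""Report tables: station-by-hour heat-map matrices and box-plot
summary tables of effort-normalized detection rates.

Box statistics follow the standard convention used throughout the
study's figures: median, first and third quartiles (linear
interpolation), whiskers at the data points nearest to 1.5 x IQR
beyond the quartiles, outliers omitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def proximity_matrix(hourcells: pd.DataFrame) -> pd.DataFrame:
    """Station x hour matrix of proximity categories (heat-map analogue)."""
    _require(hourcells)
    return hourcells.pivot(index="station_id", columns="hour_start", values="FP_index")


def rate_matrix(hourcells: pd.DataFrame) -> pd.DataFrame:
    """Station x hour matrix of effort-normalized detection rates."""
    _require(hourcells)
    return hourcells.pivot(index="station_id", columns="hour_start", values="rate")


def box_stats(values) -> dict:
    """Box-plot statistics of one sample.

    Whiskers extend to the data points nearest to (i.e. within)
    1.5 x IQR from the quartiles; quartiles use linear interpolation.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    in_lo = x[x >= q1 - 1.5 * iqr]
    in_hi = x[x <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(in_lo.min()),
        "whisker_hi": float(in_hi.max()),
        "n": int(x.size),
    }


def _box_table(hourcells: pd.DataFrame, by: str) -> pd.DataFrame:
    _require(hourcells)
    rows = []
    for (sid, key), grp in hourcells.groupby(["station_id", by], sort=True):
        rows.append({"station_id": sid, by: key, **box_stats(grp["rate"])})
    return pd.DataFrame(rows)


def hourly_box_table(hourcells: pd.DataFrame) -> pd.DataFrame:
    """Per-station box statistics of rate by hour of day (T_index)."""
    return _box_table(hourcells, "T_index")


def daily_box_table(hourcells: pd.DataFrame) -> pd.DataFrame:
    """Per-station box statistics of rate by day after first spawn
    (D_index 0..6 for DAFS -4..+2)."""
    return _box_table(hourcells, "D_index")


def _require(hourcells: pd.DataFrame) -> None:
    if hourcells is None or len(hourcells) == 0:
        raise ValueError("HourCell table is empty")


# ----------------------------------------------------------------------
# optional figures
# ----------------------------------------------------------------------
def save_figures(run_dir, hourcells: pd.DataFrame, pairs: pd.DataFrame | None = None,
                 regression=None) -> list:
    """Write quick-look PNGs (rate heat map; correlation-distance
    scatter with the fitted line if spatial results are given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    run_dir = Path(run_dir)
    written = []

    mat = rate_matrix(hourcells)
    fig, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="Greens_r", interpolation="nearest")
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.set_xlabel("study hour")
    fig.colorbar(im, ax=ax, label="AAS per full-effort hour")
    path = run_dir / "rate_heatmap.png"
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    if pairs is not None and regression is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(
            pairs["distance_m"], pairs["rho_median"],
            yerr=[pairs["rho_median"] - pairs["rho_q25"], pairs["rho_q75"] - pairs["rho_median"]],
            fmt="o", color="seagreen", ecolor="gray", capsize=2,
        )
        grid = np.linspace(pairs["distance_m"].min(), pairs["distance_m"].max(), 50)
        band = regression.predict_band(grid)
        ax.plot(band["distance_m"], band["fit"], "k-")
        ax.fill_between(band["distance_m"], band["lo"], band["hi"], alpha=0.2, color="gray")
        ax.axhline(0.0, ls="--", color="k", lw=0.8)
        ax.set_xlabel("pair distance (m)")
        ax.set_ylabel("posterior median correlation")
        path = run_dir / "correlation_distance.png"
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
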