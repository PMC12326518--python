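"""Confusion-matrix evaluation of paired detection streams.

Conventions follow the published evaluation protocol for the FADAR
grouper-call classifier: agreement is scored per 2-s bin for
presences (TP / FP / FN), while a true negative is a whole evaluation
minute containing no detection in either stream — call presence is
rare, and scoring every empty bin would inflate accuracy.

A quirk supported throughout: the reference evaluation table carries a
printed total n that, for one station, disagrees with the sum of its
four cells.  ``ConfusionCounts`` therefore stores n separately, uses
it as the denominator of accuracy / expected agreement (matching the
published metric values), and flags the inconsistency.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BIN_KEY = ["station_id", "minute_start", "bin_index"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cells with the evaluation-unit total n.

    Marginals (act_pres, act_abs, pred_pres, pred_abs) are always
    derived from the cells.  When constructed by this module,
    n = TP + TN + FP + FN.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    n: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n is None:
            object.__setattr__(self, "n", self.cell_total)

    @property
    def cell_total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def consistent(self) -> bool:
        """True when the stored n equals the sum of the four cells."""
        return self.n == self.cell_total

    @property
    def act_pres(self) -> int:
        return self.TP + self.FN

    @property
    def act_abs(self) -> int:
        return self.TN + self.FP

    @property
    def pred_pres(self) -> int:
        return self.TP + self.FP

    @property
    def pred_abs(self) -> int:
        return self.TN + self.FN


@dataclass(frozen=True)
class MetricsRow:
    """Accuracy indices of one confusion matrix.

    kappa is Cohen's chance-corrected agreement,
    (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    Undefined ratios (zero denominators) are NaN.
    """

    kappa: float
    accuracy: float
    mcr: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "kappa": self.kappa,
            "accuracy": self.accuracy,
            "mcr": self.mcr,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "fpr": self.fpr,
            "fnr": self.fnr,
        }


@dataclass
class EvalSample:
    """Evaluation minute set for one station."""

    minutes: pd.DataFrame  # station_id, minute_start
    n_true: int
    exhausted: bool = False  # ran out of minutes before min_true


# ----------------------------------------------------------------------
def draw_eval_sample(
    minutes: pd.DataFrame,
    true_events: pd.DataFrame,
    n_base: int = 200,
    min_true: int = 100,
    seed: int | np.random.Generator = 0,
) -> EvalSample:
    """Sample evaluation minutes for one station.

    ``n_base`` minutes are drawn uniformly without replacement from
    the candidate minutes (post interference removal).  If the sample
    contains fewer than ``min_true`` true detections, additional
    uniform draws are appended until the threshold is met or the
    station's minutes are exhausted (flagged on the result).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cand = minutes[["station_id", "minute_start"]].drop_duplicates().reset_index(drop=True)
    if cand["station_id"].nunique() > 1:
        raise ValueError("draw_eval_sample operates on one station at a time")
    if len(cand) < n_base:
        raise ValueError(f"station has only {len(cand)} candidate minutes, need {n_base}")
    per_minute = (
        true_events.groupby("minute_start").size() if len(true_events) else pd.Series(dtype=int)
    )

    order = rng.permutation(len(cand))
    take = n_base
    while True:
        chosen = cand.iloc[order[:take]]
        n_true = int(per_minute.reindex(chosen["minute_start"]).fillna(0).sum())
        if n_true >= min_true or take >= len(cand):
            break
        take += 1
    sample = chosen.sort_values("minute_start").reset_index(drop=True)
    return EvalSample(minutes=sample, n_true=n_true, exhausted=n_true < min_true)


def _restrict(stream: pd.DataFrame, sample_minutes: pd.DataFrame) -> pd.DataFrame:
    key = ["station_id", "minute_start"]
    out = stream.merge(sample_minutes[key].drop_duplicates(), on=key, how="inner")
    if out.duplicated(_BIN_KEY).any():
        raise ValueError("stream violates the one-detection-per-2-s-bin rule")
    return out


def confusion_counts(
    true_stream: pd.DataFrame,
    predicted_stream: pd.DataFrame,
    minutes: pd.DataFrame,
    label: str = "",
) -> ConfusionCounts:
    """Score predicted against true detections over evaluation minutes.

    TP: 2-s bins where both streams have a detection; FP: predicted
    only; FN: true only; TN: whole minutes with no detection in either
    stream.  n = TP + TN + FP + FN.
    """
    sample = minutes[["station_id", "minute_start"]].drop_duplicates()
    t = _restrict(true_stream, sample)
    p = _restrict(predicted_stream, sample)
    merged = t[_BIN_KEY].merge(p[_BIN_KEY].assign(_p=True), on=_BIN_KEY, how="outer", indicator=True)
    tp = int((merged["_merge"] == "both").sum())
    fn = int((merged["_merge"] == "left_only").sum())
    fp = int((merged["_merge"] == "right_only").sum())
    busy = pd.concat([t[["station_id", "minute_start"]], p[["station_id", "minute_start"]]])
    busy_key = busy.drop_duplicates()
    tn = len(sample) - len(sample.merge(busy_key, on=["station_id", "minute_start"], how="inner"))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn, label=label)


def metrics(c: ConfusionCounts) -> MetricsRow:
    """All accuracy indices of one confusion matrix.

    accuracy = (TP + TN) / n and the expected agreement of kappa use
    the stored n (the printed total when reproducing published
    tables); the four rate terms use their own marginals.
    """
    if c.n is None or c.n <= 0:
        raise ValueError("n must be positive")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    acc = (c.TP + c.TN) / c.n
    p_e = (c.act_pres * c.pred_pres + c.act_abs * c.pred_abs) / (c.n**2)
    kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else float("nan")
    return MetricsRow(
        kappa=kappa,
        accuracy=acc,
        mcr=1.0 - acc,
        tpr=ratio(c.TP, c.act_pres),
        fnr=ratio(c.FN, c.act_pres),
        tnr=ratio(c.TN, c.act_abs),
        fpr=ratio(c.FP, c.act_abs),
        label=c.label,
    )


def pool(counts_list, label: str = "pooled") -> ConfusionCounts:
    """Cellwise sum of confusion matrices.

    n sums the members' stored n values (not recomputed from cells),
    so pooled metrics of published rows reproduce the published
    aggregate rows exactly even where a member's printed n disagrees
    with its cell sum.
    """
    counts_list = list(counts_list)
    if not counts_list:
        raise ValueError("nothing to pool")
    return ConfusionCounts(
        TP=sum(c.TP for c in counts_list),
        TN=sum(c.TN for c in counts_list),
        FP=sum(c.FP for c in counts_list),
        FN=sum(c.FN for c in counts_list),
        n=sum(c.n for c in counts_list),
        label=label,
    )


# ----------------------------------------------------------------------
# reference table IO
# ----------------------------------------------------------------------
def load_reference_counts() -> pd.DataFrame:
    """The published FADAR/human evaluation counts, one row per
    station-classifier (columns: station, classifier, sample_size, n,
    TP, TN, FP, FN)."""
    with importlib.resources.files("aasarray.data").joinpath("fadar_eval_counts.csv").open() as fh:
        return pd.read_csv(fh)


def counts_from_row(row) -> ConfusionCounts:
    return ConfusionCounts(
        TP=int(row["TP"]),
        TN=int(row["TN"]),
        FP=int(row["FP"]),
        FN=int(row["FN"]),
        n=int(row["n"]),
        label=f"{row['station']} {row['classifier']}",
    )


def counts_table(counts_list) -> pd.DataFrame:
    """Confusion counts with marginals, mirroring the reference table."""
    rows = []
    for c in counts_list:
        rows.append(
            {
                "label": c.label,
                "n": c.n,
                "TP": c.TP,
                "TN": c.TN,
                "FP": c.FP,
                "FN": c.FN,
                "act_pres": c.act_pres,
                "act_abs": c.act_abs,
                "pred_pres": c.pred_pres,
                "pred_abs": c.pred_abs,
                "consistent": c.consistent,
            }
        )
    return pd.DataFrame(rows)


def metrics_table(counts_list) -> pd.DataFrame:
    """Metric rows (kappa, accuracy, mcr, tpr, tnr, fpr, fnr)."""
    return pd.DataFrame([metrics(c).to_dict() for c in counts_list])
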