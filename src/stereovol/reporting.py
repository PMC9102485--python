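"""Per-food trial aggregation: mean +/- SD volume, percent error, overall MAE.

The validation protocol behind these tables: five plastic food replicas
(banana, chocolate brownie, chickpeas, French fries, popcorn) whose true
volumes were measured by water displacement, each imaged at several random
tray positions with four captures per position.  Per food the summary is the
mean and SD of the predicted volumes over all trials and the percent error of
the mean against ground truth; across foods the headline number is the
unweighted mean of the absolute per-food percent errors.

Two packaged fixture tables transcribe the published per-trial volumes: one
for the structured-light stereo device (``sl_stereo``) and one for a
time-of-flight comparison camera (``tof_picoflexx``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FoodSummary",
    "summarize_food",
    "summarize_table",
    "mean_absolute_error",
    "load_trials",
]

_FIXTURES = {
    "sl_stereo": "trials_sl_stereo.csv",
    "tof_picoflexx": "trials_tof_picoflexx.csv",
}


@dataclass(frozen=True)
class FoodSummary:
    """Mean/SD predicted volume and percent error for one food."""

    food: str
    n_trials: int
    mean_ml: float
    sd_ml: float
    ground_truth_ml: float
    mean_error_pct: float
    sd_error_pct: float


def summarize_food(predicted_ml, ground_truth_ml: float, food: str = "") -> FoodSummary:
    """Aggregate one food's trials.

    The SD uses the population divisor ``n`` (matching the published
    summaries).  The percent error is computed from the mean volume,
    ``(mean - GT) / GT * 100``; its SD is ``SD(volume) / GT * 100``.
    """
    v = np.asarray(predicted_ml, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one trial")
    if ground_truth_ml <= 0:
        raise ValueError("ground truth volume must be > 0")
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    return FoodSummary(
        food=food,
        n_trials=int(v.size),
        mean_ml=mean,
        sd_ml=sd,
        ground_truth_ml=float(ground_truth_ml),
        mean_error_pct=(mean - ground_truth_ml) / ground_truth_ml * 100.0,
        sd_error_pct=sd / ground_truth_ml * 100.0,
    )


def summarize_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-food summaries for a trial table.

    Expects columns ``food``, ``predicted_ml``, ``ground_truth_ml`` (one
    ground truth per food); preserves first-appearance food order.
    """
    required = {"food", "predicted_ml", "ground_truth_ml"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    rows = []
    for food in trials["food"].drop_duplicates():
        sub = trials[trials["food"] == food]
        gts = sub["ground_truth_ml"].unique()
        if len(gts) != 1:
            raise ValueError(f"food {food!r} has inconsistent ground truths {gts}")
        s = summarize_food(sub["predicted_ml"].to_numpy(), float(gts[0]), food=food)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def mean_absolute_error(summaries: pd.DataFrame | list[FoodSummary]) -> float:
    """Unweighted mean of |per-food percent error| across foods."""
    if isinstance(summaries, pd.DataFrame):
        errs = summaries["mean_error_pct"].to_numpy(dtype=float)
    else:
        errs = np.array([s.mean_error_pct for s in summaries], dtype=float)
    if errs.size == 0:
        raise ValueError("need at least one food summary")
    return float(np.abs(errs).mean())


def load_trials(which: str = "sl_stereo") -> pd.DataFrame:
    """Load a packaged per-trial fixture table.

    ``which`` is ``"sl_stereo"`` (structured-light stereo rig) or
    ``"tof_picoflexx"`` (time-of-flight comparison camera).
    """
    if which not in _FIXTURES:
        raise ValueError(f"unknown table {which!r}; expected one of {sorted(_FIXTURES)}")
    with resources.files("stereovol.data").joinpath(_FIXTURES[which]).open() as f:
        return pd.read_csv(f)
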