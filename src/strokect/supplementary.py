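"""Recompute published summary statistics from deposited datapoints.

The reference clinical evaluation deposited per-subject prediction/ground-truth
datapoints (and per-volume Dice scores of the region-proposal stage) as
supplementary material. Given a local copy of those files, the
functions here recompute the summary numbers printed in the study —
confusion counts at the 0.3 operating threshold, test-set sizes, mean
per-volume proposal Dice, and ROC AUCs — so they can be checked against
the published tables.

Expected on-disk layout (``root`` directory):

* ``<experiment>.csv`` with columns ``prediction`` and ``groundtruth``
  (one row per test subject), e.g. ``unstratified.csv``,
  ``scanner_stratified.csv``, ``age_stratified.csv``;
* ``dice_<tag>.csv`` with column ``dice`` (one row per volume), e.g.
  ``dice_masking_enabled.csv``, ``dice_masking_disabled.csv``.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import DataError
from .evalstat import confusion_at_threshold, roc_auc

__all__ = ["load_datapoints", "recompute_confusion", "recompute_auc",
           "recompute_mean_dice", "summarize"]


def load_datapoints(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise DataError(f"datapoints file not found: {path}")
    df = pd.read_csv(path)
    missing = {"prediction", "groundtruth"} - set(df.columns)
    if missing:
        raise DataError(f"{path} lacks columns {sorted(missing)}")
    return df


def recompute_confusion(df: pd.DataFrame, threshold: float = 0.3) -> dict[str, int]:
    return confusion_at_threshold(df["prediction"].to_numpy(),
                                  df["groundtruth"].astype(int).to_numpy(),
                                  t=threshold)


def recompute_auc(df: pd.DataFrame) -> float:
    return roc_auc(df["prediction"].to_numpy(),
                   df["groundtruth"].astype(int).to_numpy()).auc


def recompute_mean_dice(path) -> tuple[float, float]:
    if not os.path.exists(path):
        raise DataError(f"dice file not found: {path}")
    df = pd.read_csv(path)
    if "dice" not in df.columns:
        raise DataError(f"{path} lacks a 'dice' column")
    vals = df["dice"].to_numpy(dtype=float)
    return float(np.mean(vals)), float(np.std(vals))


def summarize(root, threshold: float = 0.3) -> dict:
    """Recompute every deposited-datapoint statistic found under ``root``."""
    out: dict = {}
    for name in sorted(os.listdir(root)):
        path = os.path.join(root, name)
        stem, ext = os.path.splitext(name)
        if ext != ".csv":
            continue
        if stem.startswith("dice_"):
            mean, sd = recompute_mean_dice(path)
            out[stem] = {"mean_dice": mean, "sd": sd}
        else:
            df = load_datapoints(path)
            out[stem] = {"n": int(len(df)),
                         "auc": recompute_auc(df),
                         "confusion": recompute_confusion(df, threshold)}
    if not out:
        raise DataError(f"no datapoint CSVs found under {root}")
    return out
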