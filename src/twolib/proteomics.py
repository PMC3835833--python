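"""Differential protein calls from replicate 2-DE spot volumes.

A spot's abundance per gel is its volume percentage (vol.%, spot volume
over total gel spot volume). A spot is a DEP when the infected/control
ratio of replicate-mean vol.% is at least ``min_fold`` (or at most its
inverse) AND a two-sample unequal-variance t-test across replicate gels
gives p <= alpha. The test runs on log-transformed volumes when all
replicates are positive (making every call invariant to rescaling all
volumes) and falls back to raw volumes when a condition mixes zero and
positive replicates.

Spots detected in only one condition (all replicates zero on the other
side) are presence/absence calls -- ``infected_only`` / ``control_only``
-- with infinite fold; they bypass the t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["dep_call", "call_deps", "summarize_deps"]

DEFAULT_MIN_FOLD = 2.0
DEFAULT_ALPHA = 0.05

CALLS = ("up", "down", "infected_only", "control_only", "none")


def dep_call(
    vol_control,
    vol_infected,
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[str, float, float]:
    """Classify one spot; returns (call, mean_ratio, p_value).

    ``vol_control`` / ``vol_infected`` are replicate vol.% vectors.
    mean_ratio is mean(infected)/mean(control) (inf or 0 for
    presence/absence spots); p_value is NaN when the test is bypassed.
    """
    c = np.asarray(vol_control, dtype=float)
    i = np.asarray(vol_infected, dtype=float)
    if np.any(c < 0) or np.any(i < 0):
        raise ValueError("spot volumes must be non-negative")
    c_absent, i_absent = not np.any(c > 0), not np.any(i > 0)
    if c_absent and i_absent:
        raise ValueError("spot has zero volume in every replicate of both conditions")
    if c_absent:
        return "infected_only", float("inf"), float("nan")
    if i_absent:
        return "control_only", 0.0, float("nan")
    if min(c.size, i.size) < 2:
        raise ValueError("at least two replicates per condition are required")
    ratio = float(i.mean() / c.mean())
    if np.all(c > 0) and np.all(i > 0):
        p = stats.ttest_ind(np.log(i), np.log(c), equal_var=False).pvalue
    else:  # zeros mixed with signal: log undefined, test raw volumes
        p = stats.ttest_ind(i, c, equal_var=False).pvalue
    p = float(p)
    if not np.isnan(p) and p <= alpha:
        if ratio >= min_fold:
            return "up", ratio, p
        if ratio <= 1.0 / min_fold:
            return "down", ratio, p
    return "none", ratio, p


def call_deps(
    spots: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Call every spot in a long-format replicate table.

    ``spots`` columns: spot_id, accession, condition ("control" /
    "infected"), replicate, vol_percent, protein_name. Returns one row
    per spot with mean volumes, fold ratio, p and dep_call.
    """
    required = {"spot_id", "accession", "condition", "replicate", "vol_percent"}
    if not required <= set(spots.columns):
        raise ValueError(f"spot table must have columns {sorted(required)}")
    rows = []
    for spot_id, grp in spots.groupby("spot_id", sort=True):
        c = grp.loc[grp["condition"] == "control", "vol_percent"].to_numpy()
        i = grp.loc[grp["condition"] == "infected", "vol_percent"].to_numpy()
        call, ratio, p = dep_call(c, i, min_fold=min_fold, alpha=alpha)
        rows.append(
            {
                "spot_id": spot_id,
                "accession": grp["accession"].iloc[0],
                "protein_name": (grp["protein_name"].iloc[0]
                                 if "protein_name" in grp.columns else ""),
                "mean_vol_control": float(c.mean()),
                "mean_vol_infected": float(i.mean()),
                "mean_ratio": ratio,
                "p_value": p,
                "dep_call": call,
            }
        )
    return pd.DataFrame(rows)


def summarize_deps(called: pd.DataFrame, min_fold: float = DEFAULT_MIN_FOLD) -> dict:
    """Tally detected spots, fold-changed spots and full DEP calls.

    n_changed counts spots whose mean ratio passes the fold threshold
    alone (presence/absence included); n_called additionally requires
    the significance test, i.e. dep_call != none.
    """
    if called.empty:
        return {"n_detected": 0, "n_changed": 0, "n_called": 0,
                "n_up": 0, "n_down": 0, "n_infected_only": 0, "n_control_only": 0}
    ratio = called["mean_ratio"].to_numpy(dtype=float)
    changed = (~np.isfinite(ratio)) | (ratio >= min_fold) | (ratio <= 1.0 / min_fold)
    tally = called["dep_call"].value_counts()
    return {
        "n_detected": int(len(called)),
        "n_changed": int(changed.sum()),
        "n_called": int((called["dep_call"] != "none").sum()),
        "n_up": int(tally.get("up", 0)),
        "n_down": int(tally.get("down", 0)),
        "n_infected_only": int(tally.get("infected_only", 0)),
        "n_control_only": int(tally.get("control_only", 0)),
    }
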