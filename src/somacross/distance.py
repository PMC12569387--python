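"""Tactile-distance judgement (TDJT) summaries and perceptual-bias tests.

Each trial applies two rods 15 mm apart (within one phalanx) or 30 mm
apart (across adjacent phalanges), starting from the base or the tip of
the finger; the participant matches a visual bar to the felt distance.
Judged lengths are averaged per participant x intervention x session x
position x distance cell, and the baseline perceptual bias (judged vs
real distance) is tested on data collapsed across interventions and
sessions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize_distance", "distance_bias_tests"]

_CELL = ["participant", "intervention", "session", "position", "true_distance"]


def summarize_distance(table: pd.DataFrame) -> pd.DataFrame:
    """Mean judged length per design cell.

    Rows with non-positive judged lengths are rejected with a warning;
    cells with no surviving trials are simply absent.
    """
    bad = table["judged_length"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} non-positive judged lengths",
                      stacklevel=2)
        table = table[~bad]
    out = (
        table.groupby(_CELL, observed=True)["judged_length"]
        .agg(mean_judged="mean", n="size")
        .reset_index()
    )
    return out


def distance_bias_tests(summary: pd.DataFrame) -> pd.DataFrame:
    """Baseline distance-perception bias tests.

    Collapses the cell means across interventions, sessions and
    positions so each participant contributes one mean judged length per
    true distance, then runs three two-tailed tests: judged-vs-real at
    15 mm, judged-vs-real at 30 mm (one-sample t on the paired
    differences), and a paired t comparing the two biases.
    Positive mean difference = overestimation.
    """
    per = (
        summary.groupby(["participant", "true_distance"], observed=True)["mean_judged"]
        .mean()
        .unstack("true_distance")
    )
    if len(per) < 2:
        raise ValueError("need >= 2 participants for bias tests")
    distances = sorted(per.columns)
    rows = []
    biases = {}
    for d in distances:
        diff = per[d].to_numpy(float) - float(d)
        biases[d] = diff
        res = stats.ttest_1samp(diff, 0.0)
        sd = diff.std(ddof=1)
        rows.append(
            {
                "comparison": f"judged_vs_real_{d:g}mm",
                "mean_diff": float(diff.mean()),
                "t": float(res.statistic),
                "df": len(diff) - 1,
                "p": float(res.pvalue),
                "cohens_d": float(diff.mean() / sd) if sd > 0 else 0.0,
                "direction": "over" if diff.mean() > 0 else "under",
            }
        )
    if len(distances) == 2:
        near, far = (biases[d] for d in distances)
        diff = far - near
        res = stats.ttest_rel(far, near)
        sd = diff.std(ddof=1)
        rows.append(
            {
                "comparison": f"bias_{distances[1]:g}mm_vs_{distances[0]:g}mm",
                "mean_diff": float(diff.mean()),
                "t": float(res.statistic),
                "df": len(diff) - 1,
                "p": float(res.pvalue),
                "cohens_d": float(diff.mean() / sd) if sd > 0 else 0.0,
                "direction": "larger_bias_at_far" if diff.mean() > 0 else "larger_bias_at_near",
            }
        )
    return pd.DataFrame(rows)
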