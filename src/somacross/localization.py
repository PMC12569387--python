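"""Tactile-localization error decomposition.

Each pointing trial records the real touch location R and the judged
location J on a real-sized finger image, in a common mm frame with +y
along the proximo-distal axis (distal positive) and +x along the
ulnar-radial axis (radial, i.e. thumb-ward, positive). After
normalizing both axes to the participant's finger length, localization
performance at each target is decomposed into

* constant error — the mean magnitude of the J-R displacement,
  delta_jr = mean(sqrt(dx^2 + dy^2)), and its direction,
  theta_jr = atan2(mean dy, mean dx), the polar angle of the mean
  displacement vector;
* variable error — the area of the 95% confidence ellipse of the
  judged locations, from the eigendecomposition of their sample
  covariance.

Both axes share the finger-length scale, so angles are preserved by the
normalization. The trial- and group-level filtering rules (missed
trials, the 3-SD outlier screen, the 7-of-10 floor) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_coordinates",
    "constant_error",
    "confidence_ellipse",
    "Ellipse",
    "filter_tlt",
    "FilterReport",
    "localization_summary",
    "axis_bias_tests",
]

_CELL = ["participant", "intervention", "session"]
_CONDITION = _CELL + ["phalanx", "position"]


def normalize_coordinates(table: pd.DataFrame) -> pd.DataFrame:
    """Finger-length-normalized displacement of judged from real locations.

    Adds ``dx``/``dy`` = (judged - real) / finger_length; rows with
    missing coordinates are dropped (their count is available through
    :func:`filter_tlt`).
    """
    if (table["finger_length"] <= 0).any():
        raise ValueError("finger_length must be positive for every trial")
    out = table.dropna(subset=["judged_x", "judged_y", "real_x", "real_y"]).copy()
    out["dx"] = (out["judged_x"] - out["real_x"]) / out["finger_length"]
    out["dy"] = (out["judged_y"] - out["real_y"]) / out["finger_length"]
    return out


def constant_error(points: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Constant localization error of a set of displacement vectors.

    Returns ``(delta_jr, theta_jr)``: the mean Euclidean displacement
    magnitude, and the direction of the mean displacement vector in
    degrees within (-180, 180] (0 = radial, 90 = distal). The direction
    is NaN when the mean vector vanishes.
    """
    arr = (
        points[["dx", "dy"]].to_numpy(float)
        if isinstance(points, pd.DataFrame)
        else np.asarray(points, dtype=float)
    )
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("expected an (n, 2) array of displacement vectors")
    delta = float(np.hypot(arr[:, 0], arr[:, 1]).mean())
    mx, my = arr.mean(axis=0)
    if np.hypot(mx, my) == 0.0:
        return delta, float("nan")
    theta = float(np.degrees(np.arctan2(my, mx)))
    if theta <= -180.0:  # atan2 returns (-180, 180]; keep the closed end at +180
        theta += 360.0
    return delta, theta


def circular_mean_direction(points: pd.DataFrame | np.ndarray) -> float:
    """Alternative direction summary: circular mean of per-trial angles."""
    arr = (
        points[["dx", "dy"]].to_numpy(float)
        if isinstance(points, pd.DataFrame)
        else np.asarray(points, dtype=float)
    )
    ang = np.arctan2(arr[:, 1], arr[:, 0])
    return float(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())))


@dataclass(frozen=True)
class Ellipse:
    """A confidence ellipse of judged locations."""

    center: tuple[float, float]  # mean judged location
    semi_axes: tuple[float, float]  # major, minor
    angle: float  # degrees of the major axis from +x, in (-90, 90]
    area: float
    level: float


def confidence_ellipse(points: pd.DataFrame | np.ndarray, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of a 2-D point cloud.

    Centered on the sample mean; axes from the eigendecomposition of the
    sample covariance S (denominator n-1), semi-axis i = sqrt(k * l_i)
    with k the chi-square(2 df) quantile at ``level``; area =
    pi * k * sqrt(det S). Requires >= 3 non-collinear points.
    """
    if isinstance(points, pd.DataFrame):
        cols = ["judged_x", "judged_y"] if "judged_x" in points.columns else ["dx", "dy"]
        arr = points[cols].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 points for a confidence ellipse")
    S = np.cov(arr.T, ddof=1)
    det = float(np.linalg.det(S))
    if det <= 0 or not np.isfinite(det):
        raise ValueError("degenerate point cloud: singular sample covariance")
    k = float(stats.chi2.ppf(level, df=2))
    eigval, eigvec = np.linalg.eigh(S)  # ascending
    major, minor = np.sqrt(k * eigval[1]), np.sqrt(k * eigval[0])
    vx, vy = eigvec[:, 1]
    angle = float(np.degrees(np.arctan2(vy, vx)))
    if angle <= -90.0:  # an axis is a line: fold into (-90, 90]
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    cx, cy = arr.mean(axis=0)
    return Ellipse(
        center=(float(cx), float(cy)),
        semi_axes=(float(major), float(minor)),
        angle=angle,
        area=float(np.pi * k * np.sqrt(det)),
        level=level,
    )


@dataclass
class FilterReport:
    """Tally of the TLT cleaning steps."""

    n_input: int
    n_missing_removed: int
    n_trial_outliers_removed: int
    missing_by_cell: pd.Series
    group_outliers: list[str]

    @property
    def removal_fraction(self) -> float:
        return (self.n_missing_removed + self.n_trial_outliers_removed) / max(
            self.n_input, 1
        )


def filter_tlt(
    table: pd.DataFrame, sd_criterion: float = 3.0, min_reps: int = 7
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the TLT cleaning rules.

    1. Missed trials (missing coordinates) are removed and tallied per
       intervention x session cell.
    2. Intra-subject trial outliers — trials beyond ``sd_criterion``
       SDs of their own condition's mean on either normalized axis —
       are screened out.
    3. Every (participant, cell, location) condition must retain at
       least ``min_reps`` trials, else a hard error names the cell.
    4. Inter-subject (group-level) outliers — participants whose mean
       displacement magnitude lies beyond ``sd_criterion`` group SDs —
       are flagged in a ``group_outlier`` column but retained, so
       downstream analyses can run both with and without them.
    """
    n_input = len(table)
    missing = table[["judged_x", "judged_y"]].isna().any(axis=1)
    missing_by_cell = (
        table[missing].groupby(["intervention", "session"], observed=True).size()
    )
    clean = normalize_coordinates(table[~missing])

    grp = clean.groupby(_CONDITION, observed=True)
    trial_out = pd.Series(False, index=clean.index)
    for axis in ("dx", "dy"):
        mean = grp[axis].transform("mean")
        sd = grp[axis].transform("std")
        trial_out |= (clean[axis] - mean).abs() > sd_criterion * sd.fillna(np.inf)
    clean = clean[~trial_out]

    counts = clean.groupby(_CONDITION, observed=True).size()
    if (counts < min_reps).any():
        bad = counts[counts < min_reps].index[0]
        raise ValueError(f"condition {bad} retains fewer than {min_reps} trials")

    per_participant = (
        clean.assign(mag=np.hypot(clean["dx"], clean["dy"]))
        .groupby("participant", observed=True)["mag"]
        .mean()
    )
    # leave-one-out z: an extreme participant must not mask itself by
    # inflating the group SD it is screened against
    flagged = []
    for pid, value in per_participant.items():
        others = per_participant.drop(pid)
        sd_o = others.std(ddof=1)
        if sd_o > 0 and abs(value - others.mean()) > sd_criterion * sd_o:
            flagged.append(pid)
    flagged = sorted(flagged)
    clean = clean.copy()
    clean["group_outlier"] = clean["participant"].isin(flagged)

    report = FilterReport(
        n_input=n_input,
        n_missing_removed=int(missing.sum()),
        n_trial_outliers_removed=int(trial_out.sum()),
        missing_by_cell=missing_by_cell,
        group_outliers=flagged,
    )
    return clean.reset_index(drop=True), report


def localization_summary(normalized: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per (cell x location) constant- and variable-error summary.

    One row per participant x intervention x session x phalanx x
    position with delta_jr, theta_jr, mean dx/dy, and the confidence-
    ellipse parameters of the judged scatter (in normalized units).
    """
    rows = []
    for key, g in normalized.groupby(_CONDITION, observed=True):
        delta, theta = constant_error(g)
        try:
            ell = confidence_ellipse(g[["dx", "dy"]].to_numpy(), level=level)
            area, angle = ell.area, ell.angle
        except ValueError:
            area, angle = np.nan, np.nan
        rows.append(
            dict(
                zip(_CONDITION, key),
                delta_jr=delta,
                theta_jr=theta,
                mean_dx=float(g["dx"].mean()),
                mean_dy=float(g["dy"].mean()),
                ellipse_area=area,
                ellipse_angle=angle,
                n=len(g),
            )
        )
    return pd.DataFrame(rows)


def axis_bias_tests(
    summary: pd.DataFrame, alpha_family: int = 3
) -> pd.DataFrame:
    """One-sample t-tests of the per-phalanx axis biases against zero.

    Input is the per-location summary; values are first averaged across
    interventions, sessions and within-phalanx positions so each
    participant contributes one mean dx and one mean dy per phalanx.
    The Bonferroni family is the number of phalanges per axis (default
    3, alpha_bonf ~ 0.017). Negative dx = ulnar bias, negative dy =
    proximal bias; the table names the significant direction.
    """
    per = (
        summary.groupby(["participant", "phalanx"], observed=True)[["mean_dx", "mean_dy"]]
        .mean()
        .reset_index()
    )
    alpha_bonf = 0.05 / alpha_family
    rows = []
    for (phalanx,), g in per.groupby(["phalanx"], observed=True):
        if len(g) < 2:
            raise ValueError("need >= 2 participants for bias tests")
        for axis, col, neg, pos in (
            ("x", "mean_dx", "ulnar", "radial"),
            ("y", "mean_dy", "proximal", "distal"),
        ):
            v = g[col].to_numpy(float)
            res = stats.ttest_1samp(v, 0.0)
            d = float(v.mean() / v.std(ddof=1)) if v.std(ddof=1) > 0 else 0.0
            rows.append(
                {
                    "phalanx": phalanx,
                    "axis": axis,
                    "mean": float(v.mean()),
                    "t": float(res.statistic),
                    "df": len(v) - 1,
                    "p": float(res.pvalue),
                    "alpha_bonf": alpha_bonf,
                    "cohens_d": d,
                    "significant": bool(res.pvalue < alpha_bonf),
                    "direction": neg if v.mean() < 0 else pos,
                }
            )
    return pd.DataFrame(rows)
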