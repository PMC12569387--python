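"""Binary-logistic psychometric fitting and PSE extraction.

For the two binary tasks (2PDT, TMT) the percentage of "two"/"larger"
responses as a function of stimulus level is modelled by a binary
logistic regression on per-trial outcomes,

    P(response = 1 | x) = logistic(beta0 + beta1 * x),

and the point of subjective equality (PSE) — the level at which the
observer responds at chance — is the 50% crossing, pse = -beta0/beta1.
No lapse parameter is estimated (the generative observers may lapse;
fitting without a lapse term is the analysis model, and its robustness
to small lapse rates is covered by the recovery tests).

Cells in which the regression cannot be fitted (complete separation,
constant responses, non-convergence) are returned with
``converged=False`` and an undefined PSE; :func:`pse_table` then drops
the affected participant from the task, mirroring participant-level
exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = ["PsychometricFit", "fit_logistic", "pse_table", "curve_points"]

_RESPONSE_POSITIVE = {"two", "larger", "1", "yes"}
_STIM_COLUMNS = ("separation", "distortion", "level")

#: |beta1| below this is treated as a flat (unfittable) curve.
_MIN_SLOPE = 1e-8
#: |coef| above this signals divergence toward separation.
_MAX_COEF = 1e3


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted logistic psychometric function for one design cell."""

    beta0: float  # intercept, logit units
    beta1: float  # slope, logit per mm (2PDT) or per % (TMT)
    converged: bool
    n_trials: int
    deviance: float

    @property
    def pse(self) -> float:
        """Stimulus level of the 50% point; NaN when the fit failed."""
        if not self.converged or abs(self.beta1) < _MIN_SLOPE:
            return float("nan")
        return -self.beta0 / self.beta1

    @property
    def slope_at_pse(self) -> float:
        """Probability change per stimulus unit at the PSE (beta1/4)."""
        return self.beta1 / 4.0


def _binary_response(trials: pd.DataFrame) -> np.ndarray:
    resp = trials["response"]
    if resp.dtype == object or isinstance(resp.dtype, pd.CategoricalDtype):
        return resp.astype(str).str.lower().isin(_RESPONSE_POSITIVE).to_numpy(float)
    return resp.to_numpy(float)


def _stimulus_column(trials: pd.DataFrame) -> str:
    for col in _STIM_COLUMNS:
        if col in trials.columns:
            return col
    raise KeyError(f"no stimulus column among {_STIM_COLUMNS} in table")


def fit_logistic(trials: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood logistic fit of response on stimulus level.

    ``trials`` is one cell's slice of a long trial table with a stimulus
    column (``separation`` or ``distortion``) and a binary-codable
    ``response`` column. Requires at least two distinct stimulus levels.
    """
    x = trials[_stimulus_column(trials)].to_numpy(float)
    y = _binary_response(trials)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct stimulus levels to fit")
    n = int(len(y))
    if y.min() == y.max():  # all responses identical: flat likelihood in beta1
        return PsychometricFit(np.nan, np.nan, False, n, np.nan)
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception:
        return PsychometricFit(np.nan, np.nan, False, n, np.nan)
    b0, b1 = (float(v) for v in res.params)
    ok = (
        bool(res.converged)
        and np.isfinite([b0, b1]).all()
        and max(abs(b0), abs(b1)) < _MAX_COEF
        and abs(b1) >= _MIN_SLOPE
        # a binary GLM fitting its data perfectly means the classes are
        # completely separated and the ML slope is unbounded
        and res.deviance > 1e-6
    )
    if ok:
        # a 50% point far outside the tested range means the threshold is
        # not measurable from this cell (near-flat response profile)
        span = float(x.max() - x.min())
        pse = -b0 / b1
        ok = (x.min() - span) <= pse <= (x.max() + span)
    return PsychometricFit(b0, b1, ok, n, float(res.deviance))


def fit_cells(table: pd.DataFrame) -> dict[tuple[str, str, str], PsychometricFit]:
    """Fit every (participant, intervention, session) cell of a task table."""
    return {
        key: fit_logistic(cell)
        for key, cell in table.groupby(
            ["participant", "intervention", "session"], observed=True
        )
    }


def pse_table(
    fits: dict[tuple[str, str, str], PsychometricFit]
) -> pd.DataFrame:
    """Long PSE/slope table for the inference layer.

    Participants with any unfittable cell are excluded from the task
    entirely (all four cells dropped) and reported via a warning, so the
    crossover models only see complete cases.
    """
    if not fits:
        return pd.DataFrame(
            columns=["participant", "intervention", "session", "pse",
                     "slope", "slope_at_pse", "converged"]
        )
    bad = {pid for (pid, _, _), fit in fits.items() if not fit.converged}
    incomplete = {
        pid
        for pid in {k[0] for k in fits}
        if sum(k[0] == pid for k in fits) < 4
    }
    excluded = bad | incomplete
    if excluded:
        warnings.warn(
            f"excluding {sorted(excluded)} (unfittable or incomplete cells)",
            stacklevel=2,
        )
    rows = [
        {
            "participant": pid,
            "intervention": intervention,
            "session": session,
            "pse": fit.pse,
            "slope": fit.beta1,
            "slope_at_pse": fit.slope_at_pse,
            "converged": fit.converged,
        }
        for (pid, intervention, session), fit in sorted(fits.items())
        if pid not in excluded
    ]
    return pd.DataFrame(
        rows,
        columns=["participant", "intervention", "session", "pse",
                 "slope", "slope_at_pse", "converged"],
    )


def curve_points(fit: PsychometricFit, levels: np.ndarray) -> np.ndarray:
    """Predicted P(response=1) on a stimulus grid, for curve plots."""
    if not fit.converged:
        raise ValueError("cannot predict from an unconverged fit")
    levels = np.asarray(levels, dtype=float)
    return expit(fit.beta0 + fit.beta1 * levels)
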