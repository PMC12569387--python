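"""Crossover statistical inference.

The measures produced by the task modules (PSEs, cell-mean distances,
localization errors) are analysed with linear mixed-effects models
(LMMs) whose fixed part always contains session (pre/post),
intervention (sham/RSS) and their interaction, plus task-specific
factors (position/distance for the TDJT; phalanx/position for the TLT),
and whose random part is a per-participant intercept optionally
augmented with session and intervention slopes. On the fitted models
this module computes

* type-II Wald chi-square tests per fixed term (each term tested in the
  model containing all other terms except its higher-order relatives),
* estimated-marginal-mean (EMM) contrasts with Bonferroni-corrected
  alpha levels and Cohen's-d-like effect sizes standardized by the
  residual SD,
* post-minus-pre slopes per intervention with Wald 95% CIs (a CI
  excluding zero marks an intervention effect),
* JZS Bayes factors for paired comparisons (Cauchy prior, width 0.707;
  BF10 < 1/3 read as support for the null),
* the Harrison-Kanji two-factor ANOVA for circular data (constant-error
  directions), with the concentration-dependent variant switch.

Degrees of freedom for EMM t-tests use the residual-df approximation
(n_obs - n_fixed_coefficients).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices
from scipy import integrate, special, stats

__all__ = [
    "LmmSpec",
    "LmmFit",
    "fit_lmm",
    "wald_type2",
    "emm_contrasts",
    "postpre_family",
    "pairwise_family",
    "postpre_slopes",
    "jzs_bf10",
    "jzs_bf_paired",
    "harrison_kanji",
    "one_sample_t",
    "paired_t",
    "pearson_r",
]

_BASELINES = {"session": "pre", "intervention": "sham"}

#: random-structure fallback ladder, widest first
_LADDER = (
    ("intercept", "session", "intervention"),
    ("intercept", "intervention"),
    ("intercept",),
)


def _coded(factor: str, data: pd.DataFrame) -> str:
    """Patsy code for a factor with a fixed baseline level."""
    base = _BASELINES.get(factor)
    if base is None:
        base = sorted(data[factor].astype(str).unique())[0]
    return f"C({factor}, Treatment('{base}'))"


@dataclass
class LmmSpec:
    """Declaration of one crossover mixed model."""

    response: str
    fixed: tuple[str, ...] = ("session", "intervention")
    random: tuple[str, ...] = ("intercept", "intervention")
    reml: bool = True

    def __post_init__(self) -> None:
        extras = set(self.random) - {"intercept", "session", "intervention"}
        if extras:
            raise ValueError(f"unsupported random terms: {sorted(extras)}")
        if not {"session", "intervention"} <= set(self.fixed):
            raise ValueError("fixed part must include session and intervention")

    def fixed_formula(self, data: pd.DataFrame) -> str:
        return f"{self.response} ~ " + " * ".join(_coded(f, data) for f in self.fixed)

    def re_formula(self, data: pd.DataFrame, random: tuple[str, ...]) -> str:
        slopes = [_coded(f, data) for f in random if f != "intercept"]
        return "~" + " + ".join(["1"] + slopes)


@dataclass
class LmmFit:
    """A fitted crossover LMM plus everything needed to re-derive tests."""

    spec: LmmSpec
    data: pd.DataFrame
    result: "sm.regression.mixed_linear_model.MixedLMResults"
    random_structure: tuple[str, ...]
    ladder_record: list[dict] = field(default_factory=list)

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.result.scale))

    @property
    def residual_df(self) -> int:
        return int(self.result.nobs - self.result.k_fe)

    @property
    def design_info(self):
        return self.result.model.data.design_info

    def fixed_cov(self) -> np.ndarray:
        cov = self.result.cov_params()
        cov = np.asarray(cov)
        k = self.result.k_fe
        return cov[:k, :k]


def _fit_mixedlm(model, reml: bool):
    """Fit a MixedLM, trying several optimizers; None if all fail.

    lbfgs is fast but its gradient can hit singular working matrices
    when a variance component sits on the boundary; powell and cg are
    derivative-free/robust fallbacks.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
            if res.converged and np.isfinite(res.fe_params).all():
                return res
    return None


def _try_fit(
    spec: LmmSpec, data: pd.DataFrame, random: tuple[str, ...]
) -> "sm.regression.mixed_linear_model.MixedLMResults | None":
    re_formula = spec.re_formula(data, random)
    try:
        model = sm.MixedLM.from_formula(
            spec.fixed_formula(data),
            data,
            groups=data["participant"],
            re_formula=re_formula,
        )
    except (np.linalg.LinAlgError, ValueError):
        return None
    return _fit_mixedlm(model, spec.reml)


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """Fit the declared LMM by restricted maximum likelihood.

    If the requested random structure fails to converge, the fit falls
    back along the ladder intercept+session+intervention ->
    intercept+intervention -> intercept only, recording each step.
    """
    if data["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    y = data[spec.response]
    if not np.isfinite(y).all():
        raise ValueError(f"non-finite values in response {spec.response!r}")
    if float(y.std()) == 0.0:
        raise ValueError("response is constant")
    start = _LADDER.index(tuple(spec.random)) if tuple(spec.random) in _LADDER else 0
    ladder_record = []
    for random in _LADDER[start:]:
        res = _try_fit(spec, data, random)
        ladder_record.append(
            {"random": random, "converged": res is not None}
        )
        if res is not None:
            return LmmFit(spec, data.reset_index(drop=True), res, random, ladder_record)
    raise RuntimeError("no random structure on the ladder converged")


# ---------------------------------------------------------------------------
# type-II Wald tests


def _term_factors(design_info) -> dict[str, frozenset]:
    out = {}
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        out[name] = frozenset(f.name() for f in term.factors)
    return out


def wald_type2(fit: LmmFit) -> pd.DataFrame:
    """Type-II Wald chi-square table for every fixed term.

    Each term T is tested as it would be in the model containing all
    other terms except T's higher-order relatives (terms whose factor
    set strictly contains T's). The test is expressed as a linear
    hypothesis L*beta = 0 on the full fit: the rows of L select T's
    coefficients and absorb the relatives' columns through the
    projection that aliases them onto T in the reduced model, so no
    refitting is needed and the full model's residual variance is used
    throughout. For the highest-order term this reduces to the plain
    Wald test of its coefficients. The eta^2 column is the partial
    variance-explained analogue chi2 / (chi2 + residual df).
    """
    terms = _term_factors(fit.design_info)
    X = np.asarray(fit.result.model.exog)
    slices = fit.design_info.term_name_slices
    beta = np.asarray(fit.result.fe_params)
    V = fit.fixed_cov()
    k_fe = X.shape[1]
    resid_df = int(fit.result.nobs - k_fe)
    rows = []
    for name, factors in terms.items():
        relatives = [t for t, fs in terms.items() if fs > factors]
        i2 = np.r_[slices[name]]
        i3 = np.concatenate([np.r_[slices[t]] for t in relatives]) if relatives else np.array([], int)
        i1 = np.setdiff1d(np.arange(k_fe), np.concatenate([i2, i3]))
        L = np.zeros((len(i2), k_fe))
        L[:, i2] = np.eye(len(i2))
        if len(i3):
            # residualize T's and its relatives' columns on the rest;
            # the reduced-model estimate of T aliases the relatives via
            # (X2'M1X2)^-1 X2'M1X3
            X1, X2, X3 = X[:, i1], X[:, i2], X[:, i3]
            coef1, *_ = np.linalg.lstsq(X1, np.c_[X2, X3], rcond=None)
            resid = np.c_[X2, X3] - X1 @ coef1
            X2m, X3m = resid[:, : len(i2)], resid[:, len(i2):]
            L[:, i3] = np.linalg.solve(X2m.T @ X2m, X2m.T @ X3m)
        est = L @ beta
        try:
            chi2 = float(est @ np.linalg.solve(L @ V @ L.T, est))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"term {name!r} is aliased (rank-deficient design)"
            ) from exc
        df = len(i2)
        rows.append(
            {
                "term": _plain_term_name(name),
                "chi2": chi2,
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
                "eta2": chi2 / (chi2 + resid_df),
                "resid_df": resid_df,
            }
        )
    return pd.DataFrame(rows)


def _plain_term_name(name: str) -> str:
    out = []
    for part in name.split(":"):
        if part.startswith("C(") and "," in part:
            out.append(part[2:].split(",")[0].strip())
        else:
            out.append(part)
    return ":".join(out)


# ---------------------------------------------------------------------------
# estimated marginal means and contrasts


def _reference_grid(fit: LmmFit) -> pd.DataFrame:
    levels = {
        f: sorted(fit.data[f].astype(str).unique()) for f in fit.spec.fixed
    }
    return pd.DataFrame(
        list(itertools.product(*levels.values())), columns=list(levels)
    )


def _emm_row(fit: LmmFit, at: dict[str, str]) -> np.ndarray:
    """Design-space vector of the EMM at factor settings `at`.

    Cells matching ``at`` receive equal weight; factors not in ``at``
    are averaged over with balanced weights.
    """
    grid = _reference_grid(fit)
    mask = np.ones(len(grid), dtype=bool)
    for f, level in at.items():
        mask &= grid[f].to_numpy() == str(level)
    if not mask.any():
        raise ValueError(f"no reference-grid cell matches {at}")
    X = np.asarray(
        build_design_matrices([fit.design_info], grid[mask])[0]
    )
    return X.mean(axis=0)


def postpre_family(fit: LmmFit) -> list[tuple[str, dict, dict]]:
    """The post-vs-pre contrast within each intervention (family of 2)."""
    return [
        (
            f"post-pre|{i}",
            {"session": "post", "intervention": i},
            {"session": "pre", "intervention": i},
        )
        for i in ("RSS", "sham")
    ]


def pairwise_family(fit: LmmFit, factor: str) -> list[tuple[str, dict, dict]]:
    """All pairwise contrasts among the levels of one factor."""
    levels = sorted(fit.data[factor].astype(str).unique())
    return [
        (f"{a}-{b}|{factor}", {factor: a}, {factor: b})
        for a, b in itertools.combinations(levels, 2)
    ]


def emm_contrasts(
    fit: LmmFit, family: list[tuple[str, dict, dict]]
) -> pd.DataFrame:
    """EMM contrasts with Bonferroni alpha and residual-SD effect sizes.

    Each family entry is (label, cell_a, cell_b); the estimate is
    EMM(a) - EMM(b), tested with a t-statistic on the residual-df
    approximation; alpha_bonf = 0.05 / family size; Cohen's-d-like
    effect size = estimate / residual SD.
    """
    if not family:
        raise ValueError("empty contrast family")
    alpha_bonf = 0.05 / len(family)
    beta = np.asarray(fit.result.fe_params)
    cov = fit.fixed_cov()
    df = fit.residual_df
    rows = []
    for label, a, b in family:
        L = _emm_row(fit, a) - _emm_row(fit, b)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se
        rows.append(
            {
                "contrast": label,
                "estimate": est,
                "se": se,
                "t": t,
                "df": df,
                "p": float(2 * stats.t.sf(abs(t), df)),
                "alpha_bonf": alpha_bonf,
                "cohens_d": est / fit.residual_sd,
            }
        )
    return pd.DataFrame(rows)


def postpre_slopes(fit: LmmFit, level: float = 0.95) -> pd.DataFrame:
    """Post-minus-pre change per intervention with a Wald CI.

    The point estimate is the same linear combination as the post-pre
    EMM contrast; the CI is est +/- z * SE. A CI excluding zero flags an
    intervention effect.
    """
    if "session" not in fit.spec.fixed:
        raise ValueError("model has no session factor")
    z = stats.norm.ppf(0.5 + level / 2)
    beta = np.asarray(fit.result.fe_params)
    cov = fit.fixed_cov()
    rows = []
    for i in ("RSS", "sham"):
        L = _emm_row(fit, {"session": "post", "intervention": i}) - _emm_row(
            fit, {"session": "pre", "intervention": i}
        )
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        lo, hi = est - z * se, est + z * se
        rows.append(
            {
                "intervention": i,
                "estimate": est,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JZS Bayes factors


def jzs_bf10(t: float, n: int, r: float = 0.707, tol: float = 1e-6) -> float:
    """JZS Bayes factor BF10 from a one-sample/paired t statistic.

    The alternative places a Cauchy(0, r) prior on the standardized
    effect delta; the marginal likelihood of t is integrated
    numerically (the integrand is the noncentral-t density of t at
    noncentrality delta*sqrt(n) weighted by the prior) and divided by
    the central-t density under the point null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(delta, 0, r)

    peak = t / sqrt_n
    lo, _ = integrate.quad(integrand, -np.inf, peak, epsabs=tol, epsrel=1e-10,
                           limit=200)
    hi, _ = integrate.quad(integrand, peak, np.inf, epsabs=tol, epsrel=1e-10,
                           limit=200)
    return float((lo + hi) / stats.t.pdf(t, nu))


def jzs_bf_paired(
    x: np.ndarray, y: np.ndarray | None = None, r: float = 0.707
) -> float:
    """BF10 of a paired (or one-sample) comparison against zero.

    ``x`` is either the vector of paired differences or, with ``y``
    given, the first member of each pair.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size < 2:
        raise ValueError("need >= 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in paired differences")
    t = d.mean() / (sd / np.sqrt(d.size))
    return jzs_bf10(float(t), int(d.size), r=r)


# ---------------------------------------------------------------------------
# Harrison-Kanji circular two-way ANOVA


def _circ_r(angles: np.ndarray) -> float:
    return float(np.hypot(np.cos(angles).sum(), np.sin(angles).sum()) / angles.size)


def _circ_kappa(r: float, n: int | None = None) -> float:
    """Maximum-likelihood-style concentration estimate from resultant r."""
    if r >= 1.0:
        return np.inf
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1 / (r**3 - 4 * r**2 + 3 * r)
    if n is not None and 1 < n < 15:
        if k < 2:
            k = max(k - 2 / (n * k), 0.0) if k > 0 else 0.0
        else:
            k = (n - 1) ** 3 * k / (n**3 + n)
    return float(k)


def harrison_kanji(
    angles: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    degrees: bool = True,
) -> pd.DataFrame:
    """Two-factor ANOVA for circular data (Harrison-Kanji procedure).

    Decomposes the resultant lengths of the angle sample over the
    levels of two crossed factors. When the pooled concentration
    estimate kappa exceeds 2, an ANOVA-like F decomposition with a
    kappa-dependent correction is used; otherwise the low-concentration
    chi-square variant (2(p-1)-type dfs with the 2/(1-rbar^2) scaling).
    Returns one row per term (A, B, interaction) with the statistic,
    df, p-value and the variant used.
    """
    angles = np.asarray(angles, dtype=float)
    if degrees:
        angles = np.radians(angles)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (angles.size == fa.size == fb.size):
        raise ValueError("angles and factors must have equal length")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    p, q = len(a_levels), len(b_levels)
    n = angles.size
    for a in a_levels:
        for b in b_levels:
            if np.sum((fa == a) & (fb == b)) < 2:
                raise ValueError(f"cell ({a}, {b}) has fewer than 2 observations")

    tr = n * _circ_r(angles)
    kk = _circ_kappa(tr / n, n)

    def group_rsq_over_n(mask_levels, factor) -> float:
        total = 0.0
        for lev in mask_levels:
            sub = angles[factor == lev]
            total += (sub.size * _circ_r(sub)) ** 2 / sub.size
        return total

    pa = group_rsq_over_n(a_levels, fa)
    pb = group_rsq_over_n(b_levels, fb)
    pc = 0.0
    for a in a_levels:
        for b in b_levels:
            sub = angles[(fa == a) & (fb == b)]
            pc += (sub.size * _circ_r(sub)) ** 2 / sub.size

    terms = ["factor_a", "factor_b", "interaction"]
    effects = [pa - tr**2 / n, pb - tr**2 / n, pc - pa - pb + tr**2 / n]

    if np.isinf(kk) or 1 - tr / n < 1e-12:
        # all angles (near) identical: no dispersion to test against
        return pd.DataFrame(
            {
                "term": terms,
                "statistic": [0.0] * 3,
                "df": [p - 1, q - 1, (p - 1) * (q - 1)],
                "p": [1.0] * 3,
                "variant": ["degenerate"] * 3,
            }
        )

    if kk > 2:
        dfs = [p - 1, q - 1, (p - 1) * (q - 1)]
        df_res = n - p * q
        eff_res = n - pc
        beta = 1 / (1 - 1 / (5 * kk) - 1 / (10 * kk**2))
        rows = []
        for term, eff, df in zip(terms, effects, dfs):
            F = beta * (eff / df) / (eff_res / df_res)
            rows.append(
                {
                    "term": term,
                    "statistic": float(F),
                    "df": df,
                    "p": float(stats.f.sf(F, df, df_res)),
                    "variant": "high_concentration_F",
                }
            )
        return pd.DataFrame(rows)

    rbar = special.i1e(kk) / special.i0e(kk)
    f = 2 / (1 - rbar**2)
    dfs = [2 * (p - 1), 2 * (q - 1), 2 * (p - 1) * (q - 1)]
    rows = []
    for term, eff, df in zip(terms, effects, dfs):
        chi2 = f * eff
        rows.append(
            {
                "term": term,
                "statistic": float(chi2),
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
                "variant": "low_concentration_chi2",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain t-tests and correlation


def _t_record(t: float, df: int, p: float, d: float) -> dict:
    return {"t": float(t), "df": int(df), "p": float(p), "cohens_d": float(d)}


def one_sample_t(values: np.ndarray, popmean: float = 0.0) -> dict:
    """Two-tailed one-sample t-test with Cohen's d."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(v, popmean)
    return _t_record(res.statistic, v.size - 1, res.pvalue, (v.mean() - popmean) / sd)


def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-tailed paired t-test with Cohen's d on the differences."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return one_sample_t(d, 0.0)


def pearson_r(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson correlation (used for change-vs-change comparisons)."""
    r, pval = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return {"r": float(r), "p": float(pval), "n": len(np.asarray(x))}
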