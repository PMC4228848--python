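"""Statistical pipeline for per-patch single-channel measurements.

Open probabilities are proportions confined to (0, 1): raw Po tables are
non-normal and heteroscedastic, so they are logit-transformed before any
parametric modelling; dwell times are log-transformed for the same reason.
Because several measurements come from the same membrane patch, fixed
condition/phase effects are estimated by a linear mixed model with a
per-patch random intercept (REML), and specific hypotheses are tested as
linear contrasts of the fixed effects with family-wise multiplicity
adjustment (single-step max-|t| over the joint normal distribution of the
contrast statistics, or Holm as a deterministic fallback).

Also provided: the star significance coding, percent-of-control summaries
(per-patch ratio convention) and back-transformed group means for plotting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "logit",
    "inverse_logit",
    "transform_table",
    "MixedModelFit",
    "fit_mixed_model",
    "ContrastResult",
    "linear_contrasts",
    "h2s_contrasts",
    "star_code",
    "percent_of_control",
    "back_transformed_means",
]


def logit(p: float) -> float:
    """ln(p / (1 - p)); domain (0, 1), no silent clamping."""
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError(f"logit domain is (0, 1); got {p}")
    return math.log(p / (1.0 - p))


def inverse_logit(x: float) -> float:
    """Exact inverse of :func:`logit`, numerically stable for large |x|."""
    x = float(x)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def transform_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``logit_po`` and ``log_dwell`` columns.

    Rows with po outside (0, 1) or non-positive dwell are flagged in an
    ``untransformable`` column (their transform is NaN) and reported with a
    warning — never silently dropped.
    """
    out = table.copy()
    po = out["po"].astype(float)
    ok_po = (po > 0.0) & (po < 1.0)
    out["logit_po"] = np.where(ok_po, np.log(po / (1.0 - po)), np.nan)
    ok_dwell = pd.Series(True, index=out.index)
    if "dwell_ms" in out.columns:
        dw = out["dwell_ms"].astype(float)
        ok_dwell = dw > 0.0
        out["log_dwell"] = np.where(ok_dwell, np.log(dw), np.nan)
    out["untransformable"] = ~(ok_po & ok_dwell)
    n_bad = int(out["untransformable"].sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} row(s) untransformable (po at 0/1 or dwell <= 0); flagged",
            stacklevel=2,
        )
    return out


_RESPONSE_COLUMNS = {
    "logit-po": "logit_po",
    "logit_po": "logit_po",
    "log-dwell": "log_dwell",
    "log_dwell": "log_dwell",
    "amplitude": "amplitude_pA",
}


@dataclass
class MixedModelFit:
    """REML random-intercept fit: fixed effects, their covariance, variances."""

    params: pd.Series
    cov_params: pd.DataFrame
    random_intercept_sd: float
    residual_sd: float
    reml_loglike: float
    exog_names: list[str]
    formula: str
    n_obs: int
    n_groups: int
    factor_levels: dict[str, list[str]] = field(default_factory=dict)
    result: object = field(repr=False, default=None)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Build a contrast row from {fixed-effect name: weight}."""
        c = np.zeros(len(self.exog_names))
        for name, w in weights.items():
            if name not in self.exog_names:
                raise KeyError(f"unknown fixed effect {name!r}; have {self.exog_names}")
            c[self.exog_names.index(name)] = w
        return c


def fit_mixed_model(
    table: pd.DataFrame,
    response: str = "logit-po",
    fixed: tuple[str, ...] = ("condition", "phase"),
    random: str = "patch_id",
) -> MixedModelFit:
    """Random-intercept mixed model of a transformed response.

    ``fixed`` factors enter as a full-interaction categorical design
    (factors with a single observed level are dropped).  Estimation is REML
    via statsmodels MixedLM; Powell optimization is used because it tracks
    the profiled variance optimum tightly enough for contrast statistics to
    match closed-form paired tests on balanced designs.
    """
    import statsmodels.formula.api as smf

    col = _RESPONSE_COLUMNS.get(response, response)
    if col in ("logit_po", "log_dwell") and col not in table.columns:
        table = transform_table(table)
    if col not in table.columns:
        raise KeyError(f"response column {col!r} not in table")
    data = table.loc[~table[col].isna()].copy()
    groups = data[random]
    if groups.nunique() < 2:
        raise ValueError("need measurements from at least 2 patches")
    terms = [f for f in fixed if f in data.columns and data[f].nunique() > 1]
    if not terms:
        raise ValueError("no estimable fixed factor (all single-level)")

    def _cterm(t: str) -> str:
        # make 'control' the reference level of the phase factor
        if t == "phase" and "control" in set(data[t]):
            return "C(phase, Treatment('control'))"
        return f"C({t})"

    rhs = " * ".join(_cterm(t) for t in terms)
    formula = f"{col} ~ {rhs}"
    # fail early on singular designs, naming the inestimable term
    import patsy

    exog = patsy.dmatrix(rhs, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(exog.values)
    if rank < exog.shape[1]:
        u, s, vt = np.linalg.svd(exog.values)
        bad = exog.columns[int(np.argmax(np.abs(vt[-1])))]
        raise ValueError(f"singular design: term {bad!r} is not estimable")
    model = smf.mixedlm(formula, data, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="powell", maxiter=2000)
        except Exception:
            res = model.fit(reml=True, method="lbfgs", maxiter=2000)
    fe_names = list(res.fe_params.index)
    cov = res.cov_params().loc[fe_names, fe_names]
    var_patch = float(np.squeeze(res.cov_re.values)) if res.cov_re.size else 0.0
    levels = {t: sorted(map(str, data[t].unique())) for t in terms}
    return MixedModelFit(
        params=res.fe_params,
        cov_params=cov,
        random_intercept_sd=math.sqrt(max(var_patch, 0.0)),
        residual_sd=math.sqrt(float(res.scale)),
        reml_loglike=float(res.llf),
        exog_names=fe_names,
        formula=formula,
        n_obs=int(res.nobs),
        n_groups=int(groups.nunique()),
        factor_levels=levels,
        result=res,
    )


@dataclass
class ContrastResult:
    """One tested linear contrast of the fixed effects."""

    label: str
    estimate: float
    se: float
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    stars: str


def _max_t_adjust(
    z: np.ndarray, corr: np.ndarray, df: float = math.inf, seed: int = 0
) -> np.ndarray:
    """Single-step adjusted p: P(max_j |T_j| >= |t_i|), T ~ t_df(0, corr).

    Rectangle probabilities of the equicoordinate box via the (seeded,
    deterministic) multivariate t/normal CDF.
    """
    from scipy.stats import multivariate_normal, multivariate_t, norm, t as t_dist

    k = len(z)
    if k == 1:
        return (
            2.0 * norm.sf(np.abs(z))
            if math.isinf(df)
            else 2.0 * t_dist.sf(np.abs(z), df)
        )
    # regularize in case duplicated contrasts make corr singular
    corr = np.asarray(corr, float)
    corr = 0.5 * (corr + corr.T) + 1e-8 * np.eye(k)
    if math.isinf(df):
        mv = multivariate_normal(
            mean=np.zeros(k), cov=corr, allow_singular=True, seed=seed
        )
    else:
        mv = multivariate_t(loc=np.zeros(k), shape=corr, df=df, seed=seed)
    out = np.empty(k)
    for i, zi in enumerate(np.abs(z)):
        if not np.isfinite(zi):
            out[i] = 0.0
            continue
        box = mv.cdf(np.full(k, zi), lower_limit=np.full(k, -zi))
        out[i] = min(max(1.0 - box, 0.0), 1.0)
    return out


def contrast_df(fit: MixedModelFit) -> int:
    """Within-patch residual degrees of freedom for contrast tests.

    n_obs - n_groups - rank(X) + 1: equals n - 1 for a balanced paired
    two-condition design, matching the paired t-test reference.
    """
    return max(fit.n_obs - fit.n_groups - len(fit.exog_names) + 1, 2)


def linear_contrasts(
    fit: MixedModelFit,
    contrasts: dict[str, np.ndarray | dict[str, float]],
    adjust: str = "max-t",
    seed: int = 0,
    df: float | None = None,
) -> list[ContrastResult]:
    """Estimate and test linear contrasts of the fixed effects.

    ``contrasts`` maps a label to either a weight vector over
    ``fit.exog_names`` or a {name: weight} dict.  ``adjust`` is one of
    ``max-t`` (single-step over the joint t distribution of the
    statistics), ``holm`` or ``none``.  Reference distribution is t with
    the within-patch residual degrees of freedom (``df=math.inf`` selects
    the normal approximation); small-patch-count designs are otherwise
    anti-conservative.
    """
    from scipy.stats import norm, t as t_dist

    if not contrasts:
        raise ValueError("no contrasts supplied")
    labels = list(contrasts)
    rows = []
    for lab in labels:
        c = contrasts[lab]
        c = fit.contrast_vector(c) if isinstance(c, dict) else np.asarray(c, float)
        if c.shape != (len(fit.exog_names),):
            raise ValueError(f"contrast {lab!r} has wrong length")
        rows.append(c)
    cmat = np.vstack(rows)
    # each individual contrast must be testable (nonzero row)
    norms = np.linalg.norm(cmat, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero contrast row supplied")
    beta = fit.params.values
    vmat = fit.cov_params.values
    est = cmat @ beta
    cov_c = cmat @ vmat @ cmat.T
    se = np.sqrt(np.clip(np.diag(cov_c), 0.0, None))
    if np.any(se == 0):
        raise ValueError("contrast with zero standard error (rank-deficient design)")
    z = est / se
    if df is None:
        df = contrast_df(fit)
    p_raw = (
        2.0 * norm.sf(np.abs(z))
        if math.isinf(df)
        else 2.0 * t_dist.sf(np.abs(z), df)
    )
    if adjust in ("max-t", "max_t", "maxt"):
        d = 1.0 / se
        corr = cov_c * np.outer(d, d)
        p_adj = _max_t_adjust(z, corr, df=df, seed=seed)
        # single-step adjustment can never be more significant than raw
        p_adj = np.maximum(p_adj, p_raw)
    elif adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        p_adj = multipletests(p_raw, method="holm")[1]
    elif adjust in ("none", None):
        p_adj = p_raw.copy()
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        ContrastResult(
            label=lab,
            estimate=float(est[i]),
            se=float(se[i]),
            statistic=float(z[i]),
            p_unadjusted=float(p_raw[i]),
            p_adjusted=float(p_adj[i]),
            stars=star_code(float(p_adj[i])),
        )
        for i, lab in enumerate(labels)
    ]


def h2s_contrasts(fit: MixedModelFit) -> dict[str, dict[str, float]]:
    """H2S-vs-control contrast within each condition of a condition*phase fit.

    Works for treatment-coded designs produced by :func:`fit_mixed_model`
    (patsy ``C(condition) * C(phase)``).
    """
    phase_terms = [n for n in fit.exog_names if "phase" in n and ":" not in n]
    if not phase_terms:
        raise ValueError("fit has no phase effect")
    phase_term = phase_terms[0]
    inter = [n for n in fit.exog_names if "phase" in n and ":" in n]
    out: dict[str, dict[str, float]] = {}
    # the phase main effect alone tests H2S in the reference condition
    cond_levels = fit.factor_levels.get("condition", [])
    seen = set()
    for term in inter:
        cond_part = [p for p in term.split(":") if "condition" in p][0]
        seen.add(cond_part.split("[T.")[-1].rstrip("]"))
    ref = [c for c in cond_levels if c not in seen]
    if cond_levels and ref:
        out[f"H2S effect ({ref[0]})"] = {phase_term: 1.0}
    else:
        out["H2S effect"] = {phase_term: 1.0}
    for term in inter:
        cond_part = [p for p in term.split(":") if "condition" in p][0]
        level = cond_part.split("[T.")[-1].rstrip("]")
        out[f"H2S effect ({level})"] = {phase_term: 1.0, term: 1.0}
    return out


def star_code(p: float) -> str:
    """Significance stars: '' (p>=0.05), '*', '**' (p<=0.01), '***' (p<=0.001)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p >= 0.05:
        return ""
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


def percent_of_control(
    table: pd.DataFrame,
    value: str = "po",
    pairing: str = "patch_id",
    condition: str = "condition",
    phase: str = "phase",
    control_label: str = "control",
    treatment_label: str = "H2S",
) -> pd.DataFrame:
    """Per-condition percent-of-control summary (per-patch-ratio convention).

    For each patch the treatment value is divided by its matched control
    (control = 100%); the per-patch percentages are then averaged, giving a
    mean +- s.e.m. across patches.  Patches lacking either phase are
    excluded with a warning.
    """
    out_rows = []
    for cond, sub in table.groupby(condition, sort=True):
        piv = sub.pivot_table(
            index=pairing, columns=phase, values=value, aggfunc="first"
        )
        have = piv.dropna(subset=[control_label, treatment_label], how="any") \
            if {control_label, treatment_label} <= set(piv.columns) else piv.iloc[0:0]
        n_drop = len(piv) - len(have)
        if n_drop:
            warnings.warn(
                f"condition {cond!r}: {n_drop} unpaired patch(es) excluded",
                stacklevel=2,
            )
        if len(have) == 0:
            continue
        ratios = 100.0 * have[treatment_label] / have[control_label]
        n = len(ratios)
        sem = float(ratios.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out_rows.append(
            {
                "condition": cond,
                "mean_percent": float(ratios.mean()),
                "sem_percent": sem,
                "n_patches": n,
            }
        )
    return pd.DataFrame(out_rows)


def back_transformed_means(
    table: pd.DataFrame,
    response: str = "logit-po",
    by: tuple[str, ...] = ("condition", "phase"),
) -> pd.DataFrame:
    """Group means computed on the transform scale, reported back-transformed.

    The s.e.m. is taken on the transform scale and mapped through the
    inverse transform as an asymmetric (lo, hi) band around the mean.
    """
    col = _RESPONSE_COLUMNS.get(response, response)
    if col not in table.columns:
        table = transform_table(table)
    inv = {
        "logit_po": inverse_logit,
        "log_dwell": math.exp,
        "amplitude_pA": lambda x: x,
    }[col]
    rows = []
    for keys, sub in table.groupby(list(by), sort=True):
        vals = sub[col].dropna()
        m = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(
            {
                "mean": inv(m),
                "lo": inv(m - sem),
                "hi": inv(m + sem),
                "n": int(len(vals)),
            }
        )
        rows.append(rec)
    return pd.DataFrame(rows)
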