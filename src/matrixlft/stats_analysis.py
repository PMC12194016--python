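"""Statistical stage: ToT effect, clustering, mediation, regressions.

Implements the analysis battery for the extracted features:

* quadratic time-on-task (ToT) effect — an inverted-U between mean ToT
  and test score, tested against the linear model;
* hierarchical agglomerative clustering (Ward linkage on Euclidean
  distance, Ward.D2 convention) of standardized (score, interrule time)
  with silhouette-based selection of k and a participant bootstrap for
  stability;
* Welch t comparisons with pooled-SD Cohen's d;
* Pearson correlations with Fisher-z confidence intervals;
* a recursive 4-variable path model with two parallel mediators
  (interrule -> {intrarule, rule jumps} -> score) estimated by
  per-equation OLS, with the mediator residual covariance fixed to zero
  (one model df) and ML-discrepancy fit indices (chi^2, CFI, RMSEA,
  SRMR), plus percentile bootstrap CIs for the indirect effects;
* hierarchical regression of the score on ToT alone vs ToT + LFTs with
  unique R^2 (squared semipartials), VIFs and an F-change test;
* a linear mixed model with crossed random intercepts for participant
  and item, predicting a response time from global and current IAP;
* incremental-validity nested model comparison (delta R^2, F-change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.metrics import silhouette_score

__all__ = [
    "QuadraticToTResult",
    "ClusterSolution",
    "MediationResult",
    "RegressionReport",
    "MixedModelReport",
    "quadratic_tot_effect",
    "ward_cluster",
    "compare_clusters",
    "correlation_ci",
    "mediation_path",
    "hierarchical_regression",
    "iap_mixed_model",
    "incremental_r2",
]


def _z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Quadratic ToT effect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticToTResult:
    beta_linear: float  # standardized beta of z(ToT) in the quadratic model
    beta_quadratic: float  # standardized beta of z(ToT)^2
    p_quadratic: float
    r2_linear: float
    r2_quadratic: float
    delta_r2: float
    f_change: float
    p_change: float
    n: int


def quadratic_tot_effect(score, tot) -> QuadraticToTResult:
    """Test the quadratic ToT effect against the linear model.

    Fits ``z(score) ~ z(ToT) + z(ToT)^2`` (all columns standardized, so
    the coefficients are standardized betas) and compares R^2 with the
    linear model via an F-change test on (1, n - 3) df.
    """
    score = np.asarray(score, dtype=float)
    tot = np.asarray(tot, dtype=float)
    n = len(score)
    if n < 10:
        raise ValueError("quadratic ToT effect requires n >= 10")
    y = _z(score)
    zt = _z(tot)
    zt2 = zt**2
    X_full = sm.add_constant(np.column_stack([_z(zt), _z(zt2)]))
    X_lin = sm.add_constant(_z(zt))
    full = sm.OLS(y, X_full).fit()
    lin = sm.OLS(y, X_lin).fit()
    delta = full.rsquared - lin.rsquared
    df_denom = n - 3
    f_change = delta * df_denom / (1.0 - full.rsquared) if full.rsquared < 1 else np.inf
    p_change = float(st.f.sf(f_change, 1, df_denom))
    return QuadraticToTResult(
        beta_linear=float(full.params[1]),
        beta_quadratic=float(full.params[2]),
        p_quadratic=float(full.pvalues[2]),
        r2_linear=float(lin.rsquared),
        r2_quadratic=float(full.rsquared),
        delta_r2=float(delta),
        f_change=float(f_change),
        p_change=p_change,
        n=n,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSolution:
    """Ward clustering result with silhouette-based model selection."""

    linkage: np.ndarray  # scipy linkage matrix (Ward.D2 heights)
    k_selected: int
    labels: np.ndarray  # 1..k
    silhouette_by_k: Mapping[int, float]
    silhouette: float  # average width at k_selected
    weak_structure: bool  # all candidate silhouettes < 0.25
    bootstrap_silhouettes: np.ndarray
    bootstrap_stability: float  # mean pairwise co-assignment agreement
    cluster_sizes: Mapping[int, int]


def ward_cluster(
    features,
    k_range: Sequence[int] = range(1, 11),
    n_boot: int = 100,
    seed: int = 0,
) -> ClusterSolution:
    """Ward/Euclidean agglomerative clustering with silhouette selection.

    Columns are z-standardized internally.  k is chosen to maximize the
    average silhouette width over ``k_range`` intersected with [2, 10];
    if every candidate silhouette falls below 0.25 the solution is
    flagged as weak structure (k = 1 is then admissible if requested).
    ``n_boot`` participant resamples quantify silhouette stability and
    pairwise co-assignment agreement with the full-sample labels.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    ks = sorted(k for k in k_range if 2 <= k <= min(10, n - 1))
    if not ks:
        raise ValueError("k_range must contain a value in [2, min(10, n-1)]")
    if n < max(ks):
        raise ValueError(f"need at least {max(ks)} observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("all points identical; silhouette undefined")
    Xz = np.column_stack([_z(col) if np.ptp(col) > 0 else col for col in X.T])

    link = sch.linkage(Xz, method="ward")
    sil = {}
    for k in ks:
        lab = sch.fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(Xz, lab))
    if not sil:
        raise ValueError("no valid multi-cluster solution in k_range")
    k_best = max(sil, key=lambda k: (sil[k], -k))
    weak = all(v < 0.25 for v in sil.values())
    if weak and 1 in k_range:
        k_selected = 1
        labels = np.ones(n, dtype=int)
        sil_sel = float("nan")
    else:
        k_selected = k_best
        labels = sch.fcluster(link, t=k_best, criterion="maxclust")
        sil_sel = sil[k_best]

    rng = np.random.default_rng(seed)
    boot_sil = []
    agreements = []
    same_full = labels[:, None] == labels[None, :]
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        uniq = np.unique(idx)
        if len(uniq) <= max(2, k_selected):
            continue
        Xb = Xz[uniq]
        if np.all(np.ptp(Xb, axis=0) == 0):
            continue
        link_b = sch.linkage(Xb, method="ward")
        kb = max(k_selected, 2)
        lab_b = sch.fcluster(link_b, t=kb, criterion="maxclust")
        if len(np.unique(lab_b)) >= 2:
            boot_sil.append(float(silhouette_score(Xb, lab_b)))
        same_b = lab_b[:, None] == lab_b[None, :]
        mask = np.triu(np.ones((len(uniq), len(uniq)), bool), 1)
        agreements.append(
            float((same_b == same_full[np.ix_(uniq, uniq)])[mask].mean())
        )
    sizes = dict(zip(*np.unique(labels, return_counts=True)))
    return ClusterSolution(
        linkage=link,
        k_selected=k_selected,
        labels=labels,
        silhouette_by_k=sil,
        silhouette=sil_sel,
        weak_structure=weak,
        bootstrap_silhouettes=np.asarray(boot_sil),
        bootstrap_stability=float(np.mean(agreements)) if agreements else float("nan"),
        cluster_sizes={int(k): int(v) for k, v in sizes.items()},
    )


# ---------------------------------------------------------------------------
# Group comparison and correlation
# ---------------------------------------------------------------------------


def compare_clusters(x1, x2) -> tuple[float, float, float, float]:
    """Welch t-test plus pooled-SD Cohen's d for two groups.

    Returns ``(t, df, p, d)`` where df is the Welch-Satterthwaite
    approximation and d = (mean2 - mean1) / pooled SD (the pooled SD is
    paired with the Welch t by convention in the field).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("both groups need n >= 2")
    if x1.std(ddof=1) == 0 and x2.std(ddof=1) == 0:
        if x1.mean() == x2.mean():
            return 0.0, float(len(x1) + len(x2) - 2), 1.0, 0.0
        raise ValueError("zero variance in both groups")
    res = st.ttest_ind(x2, x1, equal_var=False)
    n1, n2 = len(x1), len(x2)
    sp = np.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    )
    d = (x2.mean() - x1.mean()) / sp if sp > 0 else np.inf
    return float(res.statistic), float(res.df), float(res.pvalue), float(d)


def correlation_ci(
    x, y, conf: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """Pearson r with a Fisher-z confidence interval; returns (r, CI, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("correlation CI requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = st.pearsonr(x, y)
    if abs(r) >= 1.0:
        return float(r), (float(r), float(r)), 0.0
    zcrit = st.norm.ppf(0.5 + conf / 2.0)
    fz = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(fz - zcrit * se), np.tanh(fz + zcrit * se)
    return float(r), (float(lo), float(hi)), float(p)


# ---------------------------------------------------------------------------
# Parallel mediation path model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediationResult:
    """Standardized path estimates, fit indices and bootstrap CIs.

    Variables: x = interrule time, m1 = intrarule time, m2 = rule-jump
    score, y = test score.  ``paths``: a1 (x->m1), a2 (x->m2),
    b1 (m1->y), b2 (m2->y), direct (x->y).  Indirects are a*b products,
    total = direct + indirect1 + indirect2 (an exact OLS identity).
    """

    paths: Mapping[str, float]
    indirect1: float
    indirect2: float
    total: float
    ci: Mapping[str, tuple[float, float]]
    p_boot: Mapping[str, float]
    chi2: float
    df: int
    p_chi2: float
    cfi: float
    rmsea: float
    srmr: float
    n: int
    n_boot: int
    seed: int


def _paths_from_corr(R: np.ndarray) -> dict[str, float]:
    """Standardized path coefficients from a 4x4 correlation matrix.

    Variable order: x, m1, m2, y.  Per-equation OLS: m1 ~ x; m2 ~ x;
    y ~ x + m1 + m2.
    """
    a1 = R[0, 1]
    a2 = R[0, 2]
    Spp = R[:3, :3]
    spy = R[:3, 3]
    w = np.linalg.solve(Spp, spy)
    return {"a1": a1, "a2": a2, "direct": w[0], "b1": w[1], "b2": w[2]}


def _implied_corr(paths: Mapping[str, float], R: np.ndarray, free_cov: bool) -> np.ndarray:
    a1, a2 = paths["a1"], paths["a2"]
    w = np.array([paths["direct"], paths["b1"], paths["b2"]])
    Spp = np.array(
        [
            [1.0, a1, a2],
            [a1, 1.0, R[1, 2] if free_cov else a1 * a2],
            [a2, R[1, 2] if free_cov else a1 * a2, 1.0],
        ]
    )
    # residual variance of y from OLS on the *sample* predictor covariance
    var_ey = 1.0 - w @ R[:3, :3] @ w
    spy = Spp @ w
    syy = w @ Spp @ w + var_ey
    Sigma = np.empty((4, 4))
    Sigma[:3, :3] = Spp
    Sigma[:3, 3] = Sigma[3, :3] = spy
    Sigma[3, 3] = syy
    return Sigma


def _ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma - logdet_s + np.trace(S @ np.linalg.inv(Sigma)) - p)


def mediation_path(
    inter,
    intra,
    jumps,
    score,
    n_boot: int = 1000,
    seed: int = 0,
    free_mediator_cov: bool = False,
) -> MediationResult:
    """Parallel mediation of the interrule-score link via intra and jumps.

    All variables are standardized; paths come from per-equation OLS
    (``intra ~ inter``, ``jumps ~ inter``, ``score ~ inter + intra +
    jumps``).  The mediator residual covariance is fixed to zero, which
    leaves one over-identifying restriction (df = 1) and yields the fit
    indices; ``free_mediator_cov=True`` estimates the saturated model
    (chi^2 = 0, df = 0).  Percentile bootstrap CIs resample participants
    with replacement; point estimates are bootstrap-independent.
    """
    data = np.column_stack(
        [np.asarray(v, dtype=float) for v in (inter, intra, jumps, score)]
    )
    n = data.shape[0]
    if n < 30:
        raise ValueError("mediation model requires n >= 30 complete cases")
    if not np.all(np.isfinite(data)):
        raise ValueError("mediation inputs must be finite (complete cases only)")
    R = np.corrcoef(data, rowvar=False)
    if np.linalg.matrix_rank(R) < 4 or np.any(~np.isfinite(R)):
        raise ValueError("singular covariance among mediation variables")
    paths = _paths_from_corr(R)
    ind1 = paths["a1"] * paths["b1"]
    ind2 = paths["a2"] * paths["b2"]
    total = paths["direct"] + ind1 + ind2

    Sigma = _implied_corr(paths, R, free_mediator_cov)
    df = 0 if free_mediator_cov else 1
    chi2 = (n - 1) * _ml_discrepancy(R, Sigma)
    chi2 = max(chi2, 0.0)
    p_chi2 = float(st.chi2.sf(chi2, df)) if df > 0 else 1.0
    # independence baseline: all correlations zero
    chi2_b = -(n - 1) * float(np.linalg.slogdet(R)[1])
    df_b = 6
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, num, 1e-12)
    cfi = 1.0 - num / den
    rmsea = float(np.sqrt(num / (df * (n - 1)))) if df > 0 else 0.0
    resid = R - Sigma
    tri = np.tril_indices(4)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))

    rng = np.random.default_rng(seed)
    stats = {k: [] for k in ("direct", "indirect1", "indirect2", "total")}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = data[idx]
        if np.any(sample.std(axis=0) == 0):
            continue
        Rb = np.corrcoef(sample, rowvar=False)
        try:
            pb = _paths_from_corr(Rb)
        except np.linalg.LinAlgError:
            continue
        i1 = pb["a1"] * pb["b1"]
        i2 = pb["a2"] * pb["b2"]
        stats["direct"].append(pb["direct"])
        stats["indirect1"].append(i1)
        stats["indirect2"].append(i2)
        stats["total"].append(pb["direct"] + i1 + i2)
    ci = {}
    p_boot = {}
    for key, draws in stats.items():
        if draws:
            arr = np.asarray(draws)
            ci[key] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
            below = float(np.mean(arr < 0))
            p_boot[key] = float(min(1.0, 2 * min(below, 1 - below)))
        else:  # pragma: no cover - only with degenerate bootstrap draws
            ci[key] = (float("nan"), float("nan"))
            p_boot[key] = float("nan")
    return MediationResult(
        paths=paths,
        indirect1=float(ind1),
        indirect2=float(ind2),
        total=float(total),
        ci=ci,
        p_boot=p_boot,
        chi2=float(chi2),
        df=df,
        p_chi2=p_chi2,
        cfi=float(cfi),
        rmsea=rmsea,
        srmr=srmr,
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hierarchical regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionReport:
    """ToT-only vs ToT + LFT hierarchical regression summary."""

    beta: pd.Series  # standardized betas of the full model
    t: pd.Series
    p: pd.Series
    unique_r2: pd.Series  # squared semipartial per predictor
    vif: pd.Series
    beta_base: float  # standardized beta of ToT in the base model
    r2_base: float
    r2_full: float
    delta_r2: float
    f_change: float
    p_change: float
    df_change: tuple[int, int]
    n: int


def hierarchical_regression(score, tot, onset, inter, intra) -> RegressionReport:
    """Nested comparison: ``score ~ ToT`` vs ``score ~ ToT + LFTs``.

    All variables standardized (betas are standardized coefficients).
    Unique R^2 is the drop in model R^2 when the predictor is removed
    from the full model (squared semipartial correlation).  Collinear
    predictors are rejected with an error naming the offender.
    """
    frame = pd.DataFrame(
        {
            "score": np.asarray(score, float),
            "tot": np.asarray(tot, float),
            "onset": np.asarray(onset, float),
            "inter": np.asarray(inter, float),
            "intra": np.asarray(intra, float),
        }
    )
    n = len(frame)
    if n <= 10:
        raise ValueError("hierarchical regression requires n > 10")
    if frame.isna().any().any():
        raise ValueError("complete cases required")
    z = frame.apply(lambda c: _z(c.to_numpy()), axis=0)
    predictors = ["tot", "onset", "inter", "intra"]
    Xf = z[predictors]
    # collinearity screen: VIF per predictor
    vif = {}
    offenders = []
    for j, name in enumerate(predictors):
        others = [q for q in predictors if q != name]
        r2_j = sm.OLS(Xf[name], sm.add_constant(Xf[others])).fit().rsquared
        if r2_j > 1 - 1e-10:
            offenders.append(name)
            continue
        vif[name] = 1.0 / (1.0 - r2_j)
    if offenders:
        raise ValueError(
            "perfect collinearity involving predictor(s) "
            + ", ".join(repr(n) for n in offenders)
        )
    full = sm.OLS(z["score"], sm.add_constant(Xf)).fit()
    base = sm.OLS(z["score"], sm.add_constant(z["tot"])).fit()
    unique = {}
    for name in predictors:
        others = [q for q in predictors if q != name]
        reduced = sm.OLS(z["score"], sm.add_constant(z[others])).fit()
        unique[name] = full.rsquared - reduced.rsquared
    delta = full.rsquared - base.rsquared
    df_num, df_den = 3, n - 5
    f_change = (
        delta / df_num * df_den / (1.0 - full.rsquared)
        if full.rsquared < 1
        else np.inf
    )
    return RegressionReport(
        beta=full.params[predictors],
        t=full.tvalues[predictors],
        p=full.pvalues[predictors],
        unique_r2=pd.Series(unique),
        vif=pd.Series(vif),
        beta_base=float(base.params["tot"]),
        r2_base=float(base.rsquared),
        r2_full=float(full.rsquared),
        delta_r2=float(delta),
        f_change=float(f_change),
        p_change=float(st.f.sf(f_change, df_num, df_den)),
        df_change=(df_num, df_den),
        n=n,
    )


# ---------------------------------------------------------------------------
# IAP mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedModelReport:
    """Crossed random-intercept model of a response time on IAP."""

    b_intercept: float
    b_global: float
    se_global: float
    p_global: float
    b_current: float
    se_current: float
    p_current: float
    var_participant: float
    var_item: float
    var_residual: float
    converged: bool
    n_obs: int


def iap_mixed_model(
    response,
    iap_global,
    iap_current,
    participant_id,
    item_id,
    reml: bool = True,
) -> MixedModelReport:
    """Predict a response time from global and current IAP.

    Linear mixed model with fixed effects (intercept, global IAP,
    current IAP) and crossed random intercepts for participant and item,
    fitted by (restricted) maximum likelihood.  Wald p-values are
    reported for the fixed effects.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(response, float),
            "iap_global": np.asarray(iap_global, float),
            "iap_current": np.asarray(iap_current, float),
            "pid": np.asarray(participant_id).astype(str),
            "item": np.asarray(item_id).astype(str),
        }
    ).dropna()
    if df.empty:
        raise ValueError("empty long-format table")
    model = smf.mixedlm(
        "y ~ iap_global + iap_current",
        df,
        groups=np.ones(len(df)),
        vc_formula={"pid": "0 + C(pid)", "item": "0 + C(item)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=500)
    if not res.converged:
        raise RuntimeError(
            "mixed model did not converge; "
            f"gradient norm around optimum unavailable, params={res.params.to_dict()}"
        )
    fe = res.fe_params
    pv = res.pvalues
    se = res.bse
    vc = res.vcomp
    vc_names = list(model.exog_vc.names)
    var = {name: float(v) for name, v in zip(vc_names, vc)}
    return MixedModelReport(
        b_intercept=float(fe["Intercept"]),
        b_global=float(fe["iap_global"]),
        se_global=float(se["iap_global"]),
        p_global=float(pv["iap_global"]),
        b_current=float(fe["iap_current"]),
        se_current=float(se["iap_current"]),
        p_current=float(pv["iap_current"]),
        var_participant=var.get("pid", float("nan")),
        var_item=var.get("item", float("nan")),
        var_residual=float(res.scale),
        converged=bool(res.converged),
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# Incremental validity
# ---------------------------------------------------------------------------


def incremental_r2(score, covariate, addition) -> tuple[float, float, float, float]:
    """Does ``addition`` explain score variance beyond ``covariate``?

    Nested OLS comparison; returns ``(r2_base, delta_r2, f_change, p)``
    with the F-change on (1, n - 3) df.  A redundant addition (an exact
    linear function of the covariate) gives delta R^2 = 0.
    """
    y = np.asarray(score, float)
    x0 = np.asarray(covariate, float)
    x1 = np.asarray(addition, float)
    n = len(y)
    if n < 5:
        raise ValueError("incremental R^2 requires n >= 5")
    base = sm.OLS(y, sm.add_constant(x0)).fit()
    Xf = sm.add_constant(np.column_stack([x0, x1]))
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        # redundant addition: no extra variance explained by construction
        return float(base.rsquared), 0.0, 0.0, 1.0
    full = sm.OLS(y, Xf).fit()
    delta = max(full.rsquared - base.rsquared, 0.0)
    df_den = n - 3
    f_change = delta * df_den / (1.0 - full.rsquared) if full.rsquared < 1 else np.inf
    return (
        float(base.rsquared),
        float(delta),
        float(f_change),
        float(st.f.sf(f_change, 1, df_den)),
    )
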