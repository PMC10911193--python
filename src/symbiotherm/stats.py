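"""Model selection, Tukey contrasts, PERMANOVA, and PCA.

Every response variable in the experiment is analyzed the same way: fit a
small set of candidate models (linear, linear mixed with a container
random intercept, or a penalized-spline smooth), rank them by
small-sample-corrected AIC, then follow significant effects with
Tukey-HSD-adjusted pairwise contrasts. Multivariate physiology profiles
are compared with a permutation MANOVA (pseudo-F on Euclidean distances of
z-scored variables) and ordinated by PCA.

Candidates are fitted by maximum likelihood so AICc is comparable across
fixed-effect structures; the winning mixed model can be refit by REML for
reporting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .smoothing import fit_penalized_spline

__all__ = [
    "CandidateModel",
    "ModelFit",
    "ContrastTable",
    "PermanovaResult",
    "PcaResult",
    "aicc",
    "fit_candidates",
    "rank_by_aicc",
    "tukey_contrasts",
    "tukey_contrasts_oneway",
    "compact_letter_display",
    "permanova",
    "pca",
]


def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class CandidateModel:
    """One candidate: a formula plus its estimator kind.

    kind "ols"   — ordinary linear model (statsmodels formula API)
    kind "mixed" — linear mixed model with a random intercept for
                   ``groups`` (the anemone container), fitted by ML
    kind "gam"   — penalized-spline smooth of the response on one numeric
                   covariate named in ``smooth``
    """

    formula: str
    kind: str = "ols"
    groups: str | None = None
    smooth: str | None = None
    name: str = ""

    def label(self) -> str:
        return self.name or f"{self.kind}:{self.formula}"


@dataclass
class ModelFit:
    candidate: CandidateModel
    log_lik: float
    k: int
    n: int
    aicc: float
    result: object = field(repr=False, default=None)
    fitted: np.ndarray | None = field(repr=False, default=None)
    residuals: np.ndarray | None = field(repr=False, default=None)


def _fit_one(cand: CandidateModel, data: pd.DataFrame) -> ModelFit:
    if cand.kind == "ols":
        res = smf.ols(cand.formula, data=data).fit()
        k = int(res.df_model + 1) + 1  # coefficients + error variance
        return ModelFit(cand, float(res.llf), k, int(res.nobs),
                        aicc(float(res.llf), k, int(res.nobs)),
                        res, np.asarray(res.fittedvalues), np.asarray(res.resid))
    if cand.kind == "mixed":
        if not cand.groups:
            raise ValueError("mixed candidate needs a grouping column")
        model = smf.mixedlm(cand.formula, data=data, groups=data[cand.groups])
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("bfgs", "lbfgs", "cg"):
                try:
                    res = model.fit(reml=False, method=method)
                    break
                except np.linalg.LinAlgError:
                    continue
        if res is None:
            raise np.linalg.LinAlgError("mixed-model fit singular for all optimizers")
        k_fe = len(res.fe_params)
        k_vc = res.cov_re.shape[0]  # random-intercept variance(s)
        k = k_fe + k_vc + 1  # + residual variance
        n = int(res.nobs)
        return ModelFit(cand, float(res.llf), k, n, aicc(float(res.llf), k, n),
                        res, np.asarray(res.fittedvalues), np.asarray(res.resid))
    if cand.kind == "gam":
        if not cand.smooth:
            raise ValueError("gam candidate needs a smooth covariate name")
        response = cand.formula.split("~")[0].strip()
        y = data[response].to_numpy(dtype=float)
        x = data[cand.smooth].to_numpy(dtype=float)
        smooth = fit_penalized_spline(x, y)
        ll = smooth.loglik_gaussian()
        k = int(np.ceil(smooth.edf)) + 1  # edf (rounded up) + error variance
        n = y.size
        fitted = smooth.predict(x)
        return ModelFit(cand, ll, k, n, aicc(ll, k, n), smooth, fitted, y - fitted)
    raise ValueError(f"unknown candidate kind: {cand.kind!r}")


def fit_candidates(data: pd.DataFrame, candidates: Sequence[CandidateModel]) -> list[ModelFit]:
    """Fit each candidate by ML; singular/failed fits are dropped with a warning."""
    if not candidates:
        raise ValueError("no candidate models supplied")
    fits = []
    for cand in candidates:
        try:
            fits.append(_fit_one(cand, data))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"dropping candidate {cand.label()}: {exc}")
    if not fits:
        raise ValueError("all candidate fits failed")
    return fits


def rank_by_aicc(fits: Sequence[ModelFit]) -> tuple[ModelFit, pd.DataFrame]:
    """Ascending-AICc ranking; ties break toward fewer parameters."""
    if not fits:
        raise ValueError("no fits to rank")
    order = sorted(fits, key=lambda f: (f.aicc, f.k))
    table = pd.DataFrame(
        {
            "model": [f.candidate.label() for f in order],
            "log_lik": [f.log_lik for f in order],
            "k": [f.k for f in order],
            "n": [f.n for f in order],
            "aicc": [f.aicc for f in order],
            "delta_aicc": [f.aicc - order[0].aicc for f in order],
        }
    )
    return order[0], table


@dataclass(frozen=True)
class ContrastTable:
    factor: str
    table: pd.DataFrame  # pair, estimate, se, q, p_adj
    letters: dict
    alpha: float


def tukey_contrasts_oneway(
    values: np.ndarray,
    labels: np.ndarray,
    df_resid: float | None = None,
    mse: float | None = None,
    alpha: float = 0.05,
    factor: str = "group",
) -> pd.DataFrame:
    """All pairwise Tukey-HSD contrasts of group means.

    By default the error variance is the pooled within-group MSE with its
    one-way residual df; callers with a richer model pass that model's
    residual df and MSE instead (a containment-style approximation for
    mixed models). p-values use the studentized range with k = number of
    group means.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    groups = {g: values[labels == g] for g in levels}
    ns = {g: v.size for g, v in groups.items()}
    means = {g: float(v.mean()) for g, v in groups.items()}
    if mse is None or df_resid is None:
        n_tot = values.size
        df_resid = n_tot - len(levels)
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        sse = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
        mse = sse / df_resid
    k = len(levels)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        rows.append({"pair": f"{a}-{b}", "estimate": diff, "se": se, "q": q,
                     "p_adj": min(max(p, 0.0), 1.0)})
    return pd.DataFrame(rows)


def tukey_contrasts(
    data: pd.DataFrame,
    response: str,
    factor: str,
    fit: ModelFit | None = None,
    alpha: float = 0.05,
) -> ContrastTable:
    """Tukey contrasts of ``response`` over ``factor`` levels.

    When ``fit`` is given, its residual df and error variance replace the
    one-way pooled estimates (so contrasts respect the selected model's
    error structure, approximately for mixed models).
    """
    df_resid = mse = None
    if fit is not None:
        res = fit.result
        if hasattr(res, "df_resid") and hasattr(res, "mse_resid"):
            df_resid, mse = float(res.df_resid), float(res.mse_resid)
        elif hasattr(res, "scale"):  # MixedLM: residual variance, containment df
            df_resid = float(fit.n - fit.k)
            mse = float(res.scale)
    table = tukey_contrasts_oneway(
        data[response].to_numpy(dtype=float),
        data[factor].to_numpy(),
        df_resid=df_resid,
        mse=mse,
        alpha=alpha,
        factor=factor,
    )
    means = data.groupby(factor)[response].mean().to_dict()
    letters = compact_letter_display(table, means, alpha=alpha)
    return ContrastTable(factor=factor, table=table, letters=letters, alpha=alpha)


def compact_letter_display(contrasts: pd.DataFrame, means: dict, alpha: float = 0.05) -> dict:
    """Letters such that two levels share a letter iff not significantly different.

    Letter classes are the maximal cliques of the non-significance graph
    (enumerated directly; factor counts here are small), lettered in order
    of descending best member mean.
    """
    levels = sorted(means, key=lambda g: -means[g])
    sig = set()
    for _, row in contrasts.iterrows():
        a, b = row["pair"].split("-", 1)
        if row["p_adj"] < alpha:
            sig.add(frozenset((a, b)))

    def compatible(subset):
        return all(frozenset(p) not in sig for p in itertools.combinations(subset, 2))

    cliques = []
    for r in range(len(levels), 0, -1):
        for combo in itertools.combinations(levels, r):
            if compatible(combo) and not any(set(combo) <= set(c) for c in cliques):
                cliques.append(combo)
    cliques.sort(key=lambda c: min(levels.index(g) for g in c))
    letters = {g: "" for g in levels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return letters


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_perm: float
    n_perm: int
    seed: int | None


def _permanova_ss(d2: np.ndarray, idx_by_group: list[np.ndarray], n: int):
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for idx in idx_by_group:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total - ss_within, ss_within


def permanova(
    X: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = 0,
    standardize: bool = True,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances of (optionally z-scored) data.

    pseudo-F partitions the squared-distance matrix into among- and
    within-group sums of squares; the p-value counts free label
    permutations whose pseudo-F meets or exceeds the observed one,
    with the observed labeling included (p >= 1/(n_perm+1)).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n = X.shape[0]
    if groups.shape[0] != n:
        raise ValueError("groups length must match rows of X")
    levels = pd.unique(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = [int((groups == lv).sum()) for lv in levels]
    if min(counts) < 2:
        raise ValueError("each group needs at least 2 members")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    idx_by_group = [np.nonzero(groups == lv)[0] for lv in levels]
    ss_among, ss_within = _permanova_ss(d2, idx_by_group, n)
    if ss_within <= 0:
        f_obs = np.inf
    else:
        f_obs = (ss_among / (g - 1)) / (ss_within / (n - g))
    ss_total = ss_among + ss_within
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    sizes = [idx.size for idx in idx_by_group]
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        idx_perm = []
        for sz in sizes:
            idx_perm.append(perm[start : start + sz])
            start += sz
        ss_a, ss_w = _permanova_ss(d2, idx_perm, n)
        f_p = np.inf if ss_w <= 0 else (ss_a / (g - 1)) / (ss_w / (n - g))
        if f_p >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs), r_squared=float(r2), p_perm=float(p),
        n_perm=n_perm, seed=seed,
    )


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray  # columns orthonormal
    explained_variance_ratio: np.ndarray


def pca(X: np.ndarray, scale: bool = True) -> PcaResult:
    """PCA by SVD of the centered (and by default unit-variance) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >=3 observations and >=2 variables")
    Z = X - X.mean(axis=0)
    if scale:
        sd = Z.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant variable cannot be scaled to unit variance")
        Z = Z / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        explained_variance_ratio=var / var.sum(),
    )
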