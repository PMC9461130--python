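"""Trait-metabolite/lipid association layer.

This module builds the first layer of the multi-dimensional genetic network:

* per-line trait values across environments (BLUP from a random-line model),
* sparse trait ~ omics regressions with the nonconvex MCP and SCAD penalties,
  lambda chosen by seeded k-fold cross-validation, followed by an OLS refit
  with overall F- and per-variable t-tests,
* genetic correlations from replicated measurements via two-way ANOVA
  method-of-moments components: r_G(i,j) = COV_G(i,j) / sqrt(s2_G(i) s2_G(j)),
* Gaussian graphical model edges from shrinkage partial correlations with a
  Bonferroni family-wise cut,
* maximal cliques around trait nodes in the resulting association network.

MCP and SCAD are solved by cyclic coordinate descent on standardized
predictors; both thresholding operators reduce to closed forms per coordinate,
so for orthonormal designs the solution equals the per-coordinate threshold of
the OLS estimates (a property the test-suite checks against brute-force
minimization of the penalized objective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from sklearn.covariance import LedoitWolf


# ---------------------------------------------------------------------------
# elementwise transforms
# ---------------------------------------------------------------------------

def log2_transform(table: pd.DataFrame) -> pd.DataFrame:
    """log2-transform the ``value`` column of a long phenotype table.

    Raises ``ValueError`` naming the first offending cell if any value is
    non-positive (the measurements are abundances and must be > 0).
    """
    bad = table.loc[~(table["value"] > 0)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"non-positive value {row['value']!r} for line={row['line']} "
            f"variable={row['variable']} ({len(bad)} offending cells)"
        )
    out = table.copy()
    out["value"] = np.log2(out["value"].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# BLUP across environments
# ---------------------------------------------------------------------------

def compute_blup(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-line BLUPs from a balanced random-line model, per trait.

    Model: y_ij = mu + env_j (fixed) + line_i (random) + e_ij.  Variance
    components come from the ANOVA method of moments,
    s2_g = (MS_line - MS_err) / n_env floored at 0, and the BLUP is the
    shrunken centered line mean, k = n_env s2_g / (n_env s2_g + s2_e).
    Returns a lines x traits DataFrame (environment means removed).
    """
    envs = traits["environment"].unique()
    if len(envs) < 2:
        raise ValueError("BLUP requires >= 2 environments")
    out = {}
    for trait, sub in traits.groupby("variable"):
        wide = sub.pivot(index="line", columns="environment", values="value")
        wide = wide.dropna(axis=0)
        n_env = wide.shape[1]
        if n_env < 2:
            raise ValueError(f"trait {trait}: fewer than 2 environments after pivot")
        centered = wide - wide.mean(axis=0)  # remove env fixed effects
        line_mean = centered.mean(axis=1)
        n = len(wide)
        ms_line = n_env * line_mean.pow(2).sum() / (n - 1)
        resid = centered.sub(line_mean, axis=0)
        ms_err = resid.pow(2).to_numpy().sum() / ((n - 1) * (n_env - 1))
        s2_g = max((ms_line - ms_err) / n_env, 0.0)
        k = 0.0 if s2_g == 0 else n_env * s2_g / (n_env * s2_g + ms_err)
        out[trait] = k * line_mean
    return pd.DataFrame(out).sort_index()


# ---------------------------------------------------------------------------
# MCP / SCAD penalized regression
# ---------------------------------------------------------------------------

@dataclass
class PenalizedFit:
    coefficients: pd.Series
    intercept: float
    lam: float
    gamma: float
    objective: float
    selected: list = field(default_factory=list)
    method: str = "MCP"


def soft_threshold(z: float, lam: float) -> float:
    return math.copysign(max(abs(z) - lam, 0.0), z)


def mcp_threshold(z: float, lam: float, gamma: float) -> float:
    """Univariate MCP solution for an orthonormal coordinate."""
    if abs(z) <= gamma * lam:
        return soft_threshold(z, lam) / (1.0 - 1.0 / gamma)
    return z


def scad_threshold(z: float, lam: float, a: float) -> float:
    """Univariate SCAD solution (Fan & Li three-regime rule)."""
    if abs(z) <= 2.0 * lam:
        return soft_threshold(z, lam)
    if abs(z) <= a * lam:
        return soft_threshold(z, a * lam / (a - 1.0)) / (1.0 - 1.0 / (a - 1.0))
    return z


def mcp_penalty(beta: np.ndarray, lam: float, gamma: float) -> float:
    b = np.abs(beta)
    small = b <= gamma * lam
    pen = np.where(small, lam * b - b * b / (2.0 * gamma), 0.5 * gamma * lam * lam)
    return float(pen.sum())


def scad_penalty(beta: np.ndarray, lam: float, a: float) -> float:
    b = np.abs(beta)
    pen = np.where(
        b <= lam,
        lam * b,
        np.where(
            b <= a * lam,
            (2.0 * a * lam * b - b * b - lam * lam) / (2.0 * (a - 1.0)),
            lam * lam * (a + 1.0) / 2.0,
        ),
    )
    return float(pen.sum())


def penalized_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                        lam: float, gamma: float, method: str) -> float:
    n = len(y)
    rss = float(np.sum((y - X @ beta) ** 2))
    pen = mcp_penalty(beta, lam, gamma) if method == "MCP" else scad_penalty(beta, lam, gamma)
    return rss / (2.0 * n) + pen


def _check_design(X: np.ndarray, y: np.ndarray) -> None:
    n = len(y)
    var = (X * X).sum(axis=0) / n - (X.sum(axis=0) / n) ** 2
    if np.any(np.abs(var - 1.0) > 1e-6):
        raise ValueError("columns of X must be standardized to unit variance")


def _coordinate_descent(X: np.ndarray, y: np.ndarray, lam: float, gamma: float,
                        threshold, beta0: np.ndarray | None = None,
                        tol: float = 1e-8, max_iter: int = 10_000,
                        gram: tuple | None = None) -> np.ndarray:
    """Cyclic coordinate descent on the Gram system (exact for cyclic updates).

    With unit-variance columns the per-coordinate update is
    z_j = x_j'(r + x_j b_j)/n and b_j <- threshold(z_j); maintaining
    s = X'X b makes each update O(p) instead of O(n).
    """
    n, p = X.shape
    if gram is None:
        G = X.T @ X
        xty = X.T @ y
    else:
        G, xty = gram
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    s = G @ beta if beta0 is not None else np.zeros(p)
    diag = np.diag(G)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            z = (xty[j] - s[j] + diag[j] * bj) / n
            new = threshold(z, lam, gamma)
            if new != bj:
                s += G[:, j] * (new - bj)
                beta[j] = new
                delta = max(delta, abs(new - bj))
        if delta < tol:
            break
    return beta


def fit_mcp(X: np.ndarray, y: np.ndarray, lam: float, gamma: float = 3.0,
            names=None) -> PenalizedFit:
    """MCP-penalized least squares by cyclic coordinate descent.

    ``X`` must have unit-variance columns and ``y`` is centered internally;
    loss is RSS/(2n) + sum_j P_MCP(beta_j; lambda, gamma).
    """
    if gamma <= 1.0:
        raise ValueError("MCP requires gamma > 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(X, y)
    intercept = float(y.mean())
    yc = y - intercept
    beta = _coordinate_descent(X, yc, lam, gamma, mcp_threshold)
    return _make_fit(X, yc, beta, intercept, lam, gamma, "MCP", names)


def fit_scad(X: np.ndarray, y: np.ndarray, lam: float, a: float = 3.7,
             names=None) -> PenalizedFit:
    """SCAD-penalized least squares by cyclic coordinate descent (a > 2)."""
    if a <= 2.0:
        raise ValueError("SCAD requires a > 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(X, y)
    intercept = float(y.mean())
    yc = y - intercept
    beta = _coordinate_descent(X, yc, lam, a, scad_threshold)
    return _make_fit(X, yc, beta, intercept, lam, a, "SCAD", names)


def _make_fit(X, yc, beta, intercept, lam, gamma, method, names) -> PenalizedFit:
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    coef = pd.Series(beta, index=list(names))
    selected = [nm for nm, b in coef.items() if b != 0.0]
    obj = penalized_objective(X, yc, beta, lam, gamma, method)
    return PenalizedFit(coef, intercept, lam, gamma, obj, selected, method)


def lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from lambda_max = max_j |x_j'y|/n downward."""
    n = len(y)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ yc)) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def cv_select_lambda(X: np.ndarray, y: np.ndarray, method: str = "MCP",
                     gamma: float | None = None, n_folds: int = 10,
                     seed: int = 0, n_lambda: int = 100,
                     rule: str = "1se") -> tuple[float, PenalizedFit]:
    """Pick lambda by seeded k-fold cross-validation.

    ``rule='min'`` takes the CV-error minimizer; the default ``'1se'`` takes
    the largest (sparsest) lambda whose CV error is within one standard error
    of the minimum, which keeps null selections rare ahead of the OLS refit
    tests.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if gamma is None:
        gamma = 3.0 if method == "MCP" else 3.7
    threshold = mcp_threshold if method == "MCP" else scad_threshold
    lams = lambda_path(_standardize(X), y, n_lambda=n_lambda)
    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % n_folds)
    fold_mse = np.zeros((n_folds, len(lams)))
    for k in range(n_folds):
        test = fold == k
        Xt, yt = X[~test], y[~test]
        mu = yt.mean()
        sd = Xt.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (Xt - Xt.mean(axis=0)) / sd
        gram = (Xs.T @ Xs, Xs.T @ (yt - mu))
        beta = None
        for i, lam in enumerate(lams):  # warm starts down the path
            beta = _coordinate_descent(
                Xs, yt - mu, lam, gamma, threshold, beta0=beta, gram=gram
            )
            b_orig = beta / sd
            pred = mu + (X[test] - Xt.mean(axis=0)) @ b_orig
            fold_mse[k, i] = float(np.mean((y[test] - pred) ** 2))
    cv = fold_mse.mean(axis=0)
    if rule == "min":
        best = lams[int(np.argmin(cv))]
    elif rule == "1se":
        i_min = int(np.argmin(cv))
        se = fold_mse[:, i_min].std(ddof=1) / np.sqrt(n_folds)
        within = np.nonzero(cv <= cv[i_min] + se)[0]
        best = lams[int(within.min())]  # path is decreasing: smallest index = largest lam
    else:
        raise ValueError("rule must be 'min' or '1se'")
    fitter = fit_mcp if method == "MCP" else fit_scad
    fit = fitter(_standardize(X), y, best, gamma)
    return float(best), fit


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# association edges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationEdge:
    node_a: str
    node_b: str
    edge_class: str
    statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValueError("self-association is not an edge")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def select_trait_associations(trait: pd.Series, omics: pd.DataFrame,
                              categories: dict | None = None,
                              trait_category: str = "trait",
                              n_folds: int = 10, seed: int = 0,
                              alpha: float = 0.05) -> list[AssociationEdge]:
    """Trait ~ omics variable selection with MCP + SCAD, then OLS tests.

    Lambda for each penalty is chosen by seeded k-fold CV; the union of the
    MCP- and SCAD-selected variables is refit by OLS, and an edge is kept only
    if the overall regression F-test and the per-variable t-test both reach
    ``alpha``.  ``categories`` maps variable id -> compound category used to
    label the edge class (e.g. trait-metabolite vs trait-lipid).
    """
    common = trait.index.intersection(omics.index)
    if len(common) < 10:
        raise ValueError("need at least 10 lines for association selection")
    y = trait.loc[common].to_numpy(dtype=float)
    Xdf = omics.loc[common]
    keep = Xdf.std(axis=0) > 0
    Xdf = Xdf.loc[:, keep]
    X = Xdf.to_numpy(dtype=float)
    _, fit_m = cv_select_lambda(X, y, "MCP", n_folds=n_folds, seed=seed)
    _, fit_s = cv_select_lambda(X, y, "SCAD", n_folds=n_folds, seed=seed)
    cols = list(Xdf.columns)
    sel_idx = sorted(
        {j for j, b in enumerate(fit_m.coefficients) if b != 0.0}
        | {j for j, b in enumerate(fit_s.coefficients) if b != 0.0}
    )
    if not sel_idx:
        return []
    Xs = np.column_stack([np.ones(len(y)), X[:, sel_idx]])
    beta, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
    resid = y - Xs @ beta
    n, k = len(y), len(sel_idx)
    df_res = n - k - 1
    if df_res <= 0:
        return []
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    f_stat = ((tss - rss) / k) / (rss / df_res) if rss > 0 else np.inf
    f_p = float(stats.f.sf(f_stat, k, df_res))
    if f_p >= alpha:
        return []
    sigma2 = rss / df_res
    xtx_inv = np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 1e-300))
    edges = []
    categories = categories or {}
    for pos, j in enumerate(sel_idx, start=1):
        t_stat = beta[pos] / se[pos]
        t_p = float(2.0 * stats.t.sf(abs(t_stat), df_res))
        if t_p < alpha:
            var = cols[j]
            cat = categories.get(var, "metabolite")
            edges.append(
                AssociationEdge(
                    str(trait.name), var, f"{trait_category}-{cat}",
                    float(t_stat), t_p, "MCP+SCAD",
                )
            )
    return edges


# ---------------------------------------------------------------------------
# genetic correlation from replicated measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCorrelation:
    var_i: str
    var_j: str
    cov_g: float
    var_g_i: float
    var_g_j: float
    r_g: float
    defined: bool = True


def genetic_correlation(table: pd.DataFrame, var_i: str, var_j: str) -> GeneticCorrelation:
    """Genetic correlation between two replicated variables.

    Two-way (line, replicate) ANOVA mean squares / cross-products give
    method-of-moments genetic components: COV_G = (MCP_line - MCP_err)/r and
    likewise for the variances; r_G = COV_G / sqrt(s2_G(i) s2_G(j)).  If
    either genetic variance is non-positive the result is flagged undefined
    (``defined=False``, r_g = nan) rather than propagating a NaN silently.
    """
    wide_i = table.loc[table["variable"] == var_i].pivot(
        index="line", columns="environment", values="value"
    )
    wide_j = table.loc[table["variable"] == var_j].pivot(
        index="line", columns="environment", values="value"
    )
    common = wide_i.dropna().index.intersection(wide_j.dropna().index)
    wide_i, wide_j = wide_i.loc[common], wide_j.loc[common]
    n, r = wide_i.shape
    if r < 2:
        raise ValueError("genetic correlation requires >= 2 replicates per line")

    def components(a: pd.DataFrame, b: pd.DataFrame) -> float:
        am, bm = a.mean(axis=1), b.mean(axis=1)
        mcp_line = r * float(((am - am.mean()) * (bm - bm.mean())).sum()) / (n - 1)
        ra = a.sub(am, axis=0).to_numpy()
        rb = b.sub(bm, axis=0).to_numpy()
        mcp_err = float((ra * rb).sum()) / (n * (r - 1))
        return (mcp_line - mcp_err) / r

    cov_g = components(wide_i, wide_j)
    s2_i = components(wide_i, wide_i)
    s2_j = components(wide_j, wide_j)
    if s2_i <= 0 or s2_j <= 0:
        return GeneticCorrelation(var_i, var_j, cov_g, s2_i, s2_j, float("nan"), False)
    r_g = cov_g / math.sqrt(s2_i * s2_j)
    return GeneticCorrelation(var_i, var_j, cov_g, s2_i, s2_j, r_g, True)


# ---------------------------------------------------------------------------
# Gaussian graphical model
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha_family: float, family_size: int) -> float:
    """Per-test p-value cut for a family-wise error rate over ``family_size`` tests."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha_family / family_size


@dataclass
class GGMResult:
    pcor: pd.DataFrame
    p_values: pd.DataFrame
    threshold: float
    shrinkage: float
    edges: list


def ggm_edges(omics: pd.DataFrame, alpha_family: float = 0.05,
              shrinkage: float | None = None, family_size: int | None = None,
              categories: dict | None = None) -> GGMResult:
    """Partial-correlation (GGM) edges with a Bonferroni family-wise cut.

    The covariance of the standardized variables is shrunk toward the identity
    with a Ledoit-Wolf analytic intensity (or a caller-fixed ``shrinkage``),
    inverted, and converted to partial correlations
    rho_ij = -w_ij / sqrt(w_ii w_jj).  P-values use the normal approximation
    of the Fisher z-transform with effective df = n - p - 1 (floored at 3);
    an edge is kept when p < alpha_family / C(p, 2) (or a caller-supplied
    ``family_size``, e.g. the published 119,316-test family).
    """
    omics = omics.dropna(axis=0)
    n, p = omics.shape
    if p < 3:
        raise ValueError("GGM requires at least 3 variables")
    if n <= 3:
        raise ValueError("GGM requires n > 3 observations")
    Z = _standardize(omics.to_numpy(dtype=float))
    if shrinkage is None:
        lw = LedoitWolf(assume_centered=True).fit(Z)
        shrink = float(lw.shrinkage_)
    else:
        shrink = float(shrinkage)
    R = (Z.T @ Z) / n
    S = (1.0 - shrink) * R + shrink * np.eye(p)
    omega = np.linalg.inv(S)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    df = max(n - p - 1, 3)
    z = np.arctanh(np.clip(pcor, -1 + 1e-12, 1 - 1e-12))
    pvals = 2.0 * stats.norm.sf(np.abs(z) * math.sqrt(df))
    np.fill_diagonal(pvals, 1.0)
    fam = family_size if family_size is not None else p * (p - 1) // 2
    cut = bonferroni_threshold(alpha_family, fam)
    cols = list(omics.columns)
    categories = categories or {}
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if pvals[i, j] < cut:
                ca = categories.get(cols[i], "metabolite")
                cb = categories.get(cols[j], "metabolite")
                cls = "-".join(sorted([ca, cb]))
                edges.append(
                    AssociationEdge(
                        cols[i], cols[j], cls, float(pcor[i, j]),
                        float(pvals[i, j]), "GGM",
                    )
                )
    pcor_df = pd.DataFrame(pcor, index=cols, columns=cols)
    pval_df = pd.DataFrame(pvals, index=cols, columns=cols)
    return GGMResult(pcor_df, pval_df, cut, shrink, edges)


# ---------------------------------------------------------------------------
# cliques around trait nodes
# ---------------------------------------------------------------------------

def trait_cliques(edges: list, node_types: dict) -> list[dict]:
    """All maximal cliques of the association graph containing >= 1 trait node.

    Uses Bron-Kerbosch with pivoting (via networkx).  Cliques are reported
    with members in lexicographic order, and the clique list itself sorted,
    for reproducibility.
    """
    G = nx.Graph()
    for e in edges:
        G.add_edge(e.node_a, e.node_b)
    cliques = []
    for clique in nx.find_cliques(G):
        members = sorted(clique)
        types = [node_types.get(m, "metabolite") for m in members]
        if "trait" in types:
            cliques.append({"members": members, "types": types})
    cliques.sort(key=lambda c: (len(c["members"]), c["members"]))
    return cliques


def edges_to_frame(edges: list) -> pd.DataFrame:
    rows = [
        {
            "node_a": e.node_a, "node_b": e.node_b, "class": e.edge_class,
            "method": e.method, "statistic": e.statistic, "p": e.p_value,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "class", "method", "statistic", "p"]
    )
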