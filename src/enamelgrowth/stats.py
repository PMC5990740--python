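"""Phylogenetically corrected multi-group comparison of growth rates.

The chain mirrors standard comparative practice: log₁₀ growth rates are
regressed on log₁₀ body mass by phylogenetic generalized least squares
(PGLS) under a Brownian-motion covariance, the residuals are the
mass-corrected rates, each residual vector is Box-Cox transformed toward
normality, and the transformed pair (DSR, CER) is compared across groups
with a Wilks'-lambda MANOVA plus pairwise two-group MANOVAs, univariate
one-way ANOVAs with pairwise contrasts, and a Kruskal-Wallis test with
Dunn post-hocs — every pairwise family Benjamini-Hochberg adjusted.

For two response variables the Wilks statistic converts exactly to an F:
F = ((1-√Λ)/√Λ)·((ν_e-1)/ν_h) on (2ν_h, 2(ν_e-1)) degrees of freedom, and
the multivariate partial η² is 1-Λ^(1/s) with s = min(q, ν_h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "phylo_covariance", "PGLSResult", "pgls_fit", "BoxCoxResult", "boxcox",
    "ManovaResult", "wilks_to_f", "manova_wilks", "pairwise_manova",
    "AnovaResult", "anova_oneway", "pairwise_anova", "kruskal_wallis",
    "dunn_pairwise", "bh_fdr", "GroupComparisonResult",
    "run_group_comparison",
]


# ---------------------------------------------------------------------------
# phylogeny

def phylo_covariance(tree: dendropy.Tree,
                     tip_order: Sequence[str]) -> np.ndarray:
    """Brownian-motion trait covariance structure C from a tree.

    ``C[i, j]`` is the shared branch length from the root down to the most
    recent common ancestor of tips i and j; the diagonal holds root-to-tip
    path lengths.  Branch lengths must be present and non-negative.
    """
    labels = {t.label for t in tree.taxon_namespace}
    missing = [t for t in tip_order if t not in labels]
    if missing:
        raise ValueError(f"tips absent from the tree: {missing}")
    depth: dict = {}
    anc_depth: dict[str, dict[int, float]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            bl = node.edge.length
            if bl is None:
                raise ValueError("branch length absent; Brownian covariance "
                                 "is undefined")
            if bl < 0:
                raise ValueError("negative branch length")
            depth[node] = depth[node.parent_node] + bl
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        d = {}
        node = leaf
        while node is not None:
            d[id(node)] = depth[node]
            node = node.parent_node
        anc_depth[label] = d
    n = len(tip_order)
    C = np.zeros((n, n))
    leaf_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for i, a in enumerate(tip_order):
        C[i, i] = depth[leaf_nodes[a]]
        da = anc_depth[a]
        for j in range(i + 1, n):
            db = anc_depth[tip_order[j]]
            shared = [v for k, v in da.items() if k in db]
            C[i, j] = C[j, i] = max(shared)
    return C


# ---------------------------------------------------------------------------
# PGLS

@dataclass
class PGLSResult:
    """GLS fit of a trait on log body mass under covariance V."""

    beta: np.ndarray           # (intercept, slope)
    residuals: np.ndarray      # observed - fitted, log scale
    covariance_V: np.ndarray


def pgls_fit(y: np.ndarray, x: np.ndarray, C: np.ndarray) -> PGLSResult:
    """β = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with X = [1, x]; residuals are y - Xβ."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance; check branch "
                         "lengths") from exc
    CiX = cho_solve(cf, X)
    Ciy = cho_solve(cf, y)
    beta = np.linalg.solve(X.T @ CiX, X.T @ Ciy)
    resid = y - X @ beta
    return PGLSResult(beta=beta, residuals=resid, covariance_V=C)


# ---------------------------------------------------------------------------
# Box-Cox

@dataclass
class BoxCoxResult:
    """Grid-search profile-likelihood Box-Cox transform."""

    lambda_bc: float
    transformed: np.ndarray
    log_likelihood: float
    shift: float = 0.0         # added to the input to reach positivity


def boxcox(values: np.ndarray, grid: tuple[float, float, float] = (-3.0, 3.0,
           0.01)) -> BoxCoxResult:
    """Box-Cox transform with λ maximizing the profile likelihood.

    Residuals can be negative, so inputs with min(v) <= 0 are first shifted
    by (-min + 1).  The transform is (v^λ - 1)/λ for λ != 0 and log v at
    λ = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least three values")
    if np.ptp(v) == 0:
        raise ValueError("constant input has no Box-Cox optimum")
    shift = 0.0
    if v.min() <= 0:
        shift = -v.min() + 1.0
        v = v + shift
    lams = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])
    logv = np.log(v)
    n = v.size
    # transformed values for every grid λ at once: (n_lam, n)
    with np.errstate(over="ignore", invalid="ignore"):
        W = np.where(np.abs(lams[:, None]) < 1e-8, logv[None, :],
                     (np.power(v[None, :], lams[:, None]) - 1.0)
                     / np.where(np.abs(lams[:, None]) < 1e-8, 1.0,
                                lams[:, None]))
    var = W.var(axis=1)
    with np.errstate(divide="ignore"):
        llf = (lams - 1.0) * logv.sum() - n / 2.0 * np.log(var)
    llf[~np.isfinite(llf)] = -np.inf
    k = int(np.argmax(llf))
    lam = float(lams[k])
    return BoxCoxResult(lambda_bc=lam, transformed=W[k],
                        log_likelihood=float(llf[k]), shift=shift)


# ---------------------------------------------------------------------------
# MANOVA

@dataclass
class ManovaResult:
    wilks_lambda: float
    F_stat: float
    df1: float
    df2: float
    p_value: float
    partial_eta_sq_mv: float


def wilks_to_f(lam: float, nu_h: int, nu_e: int,
               q: int) -> tuple[float, float, float]:
    """Rao's F approximation for Wilks' Λ (exact when q <= 2 or ν_h <= 2).

    With q = 2 responses it reduces to the closed form
    F = ((1-√Λ)/√Λ)·((ν_e-1)/ν_h) on (2ν_h, 2(ν_e-1)) df.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("Wilks lambda must lie in [0, 1]")
    pq = q * nu_h
    if q ** 2 + nu_h ** 2 - 5 > 0:
        t = np.sqrt((q ** 2 * nu_h ** 2 - 4) / (q ** 2 + nu_h ** 2 - 5))
    else:
        t = 1.0
    df1 = pq
    df2 = (nu_e + nu_h - (q + nu_h + 1) / 2.0) * t - (pq - 2) / 2.0
    lam_t = lam ** (1.0 / t) if lam > 0 else 0.0
    if lam_t == 0.0:
        return float("inf"), df1, df2
    F = (1.0 - lam_t) / lam_t * (df2 / df1)
    return float(F), float(df1), float(df2)


def manova_wilks(Y: np.ndarray, groups: Sequence) -> ManovaResult:
    """One-way MANOVA via Wilks' Λ = det(E)/det(E+H).

    E and H are the within- and between-group cross-product matrices of the
    (n, q) response matrix Y.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    g, n, q = len(labels), len(groups), Y.shape[1]
    if g < 2:
        raise ValueError("need at least two groups")
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than two members: "
                         f"{list(small)}")
    if n <= g + q:
        raise ValueError("too few observations for the group/response "
                         "count")
    grand = Y.mean(axis=0)
    E = np.zeros((q, q))
    H = np.zeros((q, q))
    for lab in labels:
        sub = Y[groups == lab]
        m = sub.mean(axis=0)
        d = sub - m
        E += d.T @ d
        dm = (m - grand)[:, None]
        H += len(sub) * (dm @ dm.T)
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    lam = min(max(lam, 0.0), 1.0)
    nu_h, nu_e = g - 1, n - g
    F, df1, df2 = wilks_to_f(lam, nu_h, nu_e, q)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    s = min(q, nu_h)
    eta = 1.0 - lam ** (1.0 / s)
    return ManovaResult(wilks_lambda=lam, F_stat=F, df1=df1, df2=df2,
                        p_value=p, partial_eta_sq_mv=float(eta))


def _pair_matrix(labels: Sequence[str], raw: dict[tuple[str, str], float]
                 ) -> pd.DataFrame:
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for (a, b), v in raw.items():
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def pairwise_manova(Y: np.ndarray, groups: Sequence) -> pd.DataFrame:
    """Two-group Wilks tests for every unordered pair, BH-adjusted."""
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    labels = list(np.unique(groups))
    raw: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sel = (groups == a) | (groups == b)
            try:
                raw[(a, b)] = manova_wilks(Y[sel], groups[sel]).p_value
            except ValueError as exc:
                warnings.warn(f"pairwise MANOVA {a} vs {b} failed: {exc}",
                              stacklevel=2)
    keys = list(raw)
    adj = bh_fdr([raw[k] for k in keys]) if keys else []
    return _pair_matrix(labels, dict(zip(keys, adj)))


# ---------------------------------------------------------------------------
# univariate tests

@dataclass
class AnovaResult:
    F_stat: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


def anova_oneway(y: np.ndarray, groups: Sequence) -> AnovaResult:
    """One-way ANOVA; partial η² = SS_effect/(SS_effect + SS_error)."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    grand = y.mean()
    ss_eff = sum((y[groups == lab].mean() - grand) ** 2
                 * (groups == lab).sum() for lab in labels)
    ss_err = sum(((y[groups == lab] - y[groups == lab].mean()) ** 2).sum()
                 for lab in labels)
    df1, df2 = len(labels) - 1, len(y) - len(labels)
    if ss_err == 0:
        if ss_eff == 0:
            return AnovaResult(0.0, df1, df2, 1.0, 0.0, 0.0, 0.0)
        warnings.warn("zero within-group variance with unequal means; "
                      "F is infinite", stacklevel=2)
        return AnovaResult(float("inf"), df1, df2, 0.0, 1.0,
                           float(ss_eff), 0.0)
    F = (ss_eff / df1) / (ss_err / df2)
    p = float(sps.f.sf(F, df1, df2))
    eta = ss_eff / (ss_eff + ss_err)
    return AnovaResult(float(F), df1, df2, p, float(eta), float(ss_eff),
                       float(ss_err))


def partial_eta_sq_from_f(F: float, df1: int, df2: int) -> float:
    """η² recovered from a published F and its degrees of freedom."""
    return F * df1 / (F * df1 + df2)


def pairwise_anova(y: np.ndarray, groups: Sequence) -> pd.DataFrame:
    """Two-group one-way ANOVAs for every pair, BH-adjusted."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = list(np.unique(groups))
    raw = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sel = (groups == a) | (groups == b)
            raw[(a, b)] = anova_oneway(y[sel], groups[sel]).p_value
    keys = list(raw)
    adj = bh_fdr([raw[k] for k in keys])
    return _pair_matrix(labels, dict(zip(keys, adj)))


def kruskal_wallis(y: np.ndarray, groups: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [y[groups == lab] for lab in labels]
    if np.ptp(y) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def dunn_pairwise(y: np.ndarray, groups: Sequence
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's rank-based post-hoc z and BH-adjusted two-sided p matrices.

    z_ij = (R̄_i - R̄_j) / sqrt[(N(N+1)/12 - T)·(1/n_i + 1/n_j)] with the
    standard tie term T = Σ(t³ - t) / (12(N - 1)) over tied sets.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = list(np.unique(groups))
    if any((groups == lab).sum() == 0 for lab in labels):
        raise ValueError("empty group")
    N = len(y)
    ranks = sps.rankdata(y)
    _, tie_counts = np.unique(y, return_counts=True)
    T = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base = N * (N + 1) / 12.0 - T
    zraw, praw = {}, {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ra = ranks[groups == a].mean()
            rb = ranks[groups == b].mean()
            na, nb = (groups == a).sum(), (groups == b).sum()
            se = np.sqrt(base * (1.0 / na + 1.0 / nb))
            z = 0.0 if se == 0 else (ra - rb) / se
            zraw[(a, b)] = float(z)
            praw[(a, b)] = float(2.0 * sps.norm.sf(abs(z)))
    keys = list(praw)
    adj = bh_fdr([praw[k] for k in keys])
    return (_pair_matrix(labels, zraw),
            _pair_matrix(labels, dict(zip(keys, adj))))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class GroupComparisonResult:
    """Everything the comparative chain produces, with provenance."""

    pgls: dict[str, PGLSResult]
    boxcox: dict[str, BoxCoxResult]
    manova: ManovaResult
    pairwise_manova_p: Optional[pd.DataFrame]
    anova_per_variable: dict[str, AnovaResult]
    pairwise_anova_p: dict[str, pd.DataFrame]
    kw_per_variable: dict[str, tuple[float, float]]
    dunn_z: dict[str, pd.DataFrame]
    dunn_p: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)


RESPONSES = ("dsr", "cer")


def run_group_comparison(table, tree: dendropy.Tree,
                         exclude: Sequence[str] = (),
                         reassign: Optional[dict[str, str]] = None,
                         posthoc: bool = True,
                         boxcox_grid: tuple = (-3.0, 3.0, 0.01)
                         ) -> GroupComparisonResult:
    """Run the full comparative chain on a species table and a tree.

    ``exclude`` drops species (outliers such as taxa with aberrant growth);
    ``reassign`` overrides group labels (to probe taxa of uncertain
    affinity by moving them between groups).  Species labelled
    ``unassigned`` after reassignment are dropped.
    """
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else \
        table.copy()
    reassign = reassign or {}
    df = df[~df.species.isin(list(exclude))].copy()
    df["group"] = [reassign.get(s, g)
                   for s, g in zip(df.species, df.group)]
    df = df[df.group != "unassigned"].reset_index(drop=True)
    if df.species.duplicated().any():
        raise ValueError("duplicate species in table")
    species = list(df.species)
    C = phylo_covariance(tree, species)
    logm = np.log10(df.body_mass_g.to_numpy())
    pgls, bc, cols = {}, {}, {}
    for resp in RESPONSES:
        yv = np.log10(df[f"{resp}_um_d"].to_numpy())
        fit = pgls_fit(yv, logm, C)
        pgls[resp] = fit
        bc[resp] = boxcox(fit.residuals, grid=boxcox_grid)
        cols[resp] = bc[resp].transformed
    Y = np.column_stack([cols[r] for r in RESPONSES])
    groups = df.group.to_numpy()
    manova = manova_wilks(Y, groups)
    pw_manova = None
    anovas, pw_anova, kw, dunn_z, dunn_p = {}, {}, {}, {}, {}
    for resp in RESPONSES:
        anovas[resp] = anova_oneway(cols[resp], groups)
    if posthoc:
        pw_manova = pairwise_manova(Y, groups)
        for resp in RESPONSES:
            pw_anova[resp] = pairwise_anova(cols[resp], groups)
            kw[resp] = kruskal_wallis(cols[resp], groups)
            z, p = dunn_pairwise(cols[resp], groups)
            dunn_z[resp], dunn_p[resp] = z, p
    prov = {"n_species": len(df), "excluded": list(exclude),
            "reassigned": dict(reassign),
            "groups": {g: int((groups == g).sum())
                       for g in np.unique(groups)},
            "boxcox_lambda": {r: bc[r].lambda_bc for r in RESPONSES}}
    return GroupComparisonResult(pgls=pgls, boxcox=bc, manova=manova,
                                 pairwise_manova_p=pw_manova,
                                 anova_per_variable=anovas,
                                 pairwise_anova_p=pw_anova,
                                 kw_per_variable=kw, dunn_z=dunn_z,
                                 dunn_p=dunn_p, provenance=prov)
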