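"""Phylogenetic expression-divergence testing with an Ornstein-Uhlenbeck
model (the "expression variance and evolution" framework).

Expression of each gene is treated as a quantitative trait evolving on a
population tree under a stationary Ornstein-Uhlenbeck process with optimum
``mu``, pull strength ``alpha`` and stationary between-population variance
``v`` = sigma^2/(2 alpha). Samples from population p and q covary as
``v * exp(-alpha * d(p, q))`` with d the patristic distance; each sample
additionally carries independent within-population variance ``beta * v``,
so ``beta`` is literally the ratio of within- to between-population
variance.

Divergent expression is detected by the beta-shared likelihood-ratio test:
the null shares one beta across all genes, the alternative frees beta for
the tested gene; 2*(ll_free - ll_shared) is referred to chi-square with one
degree of freedom. A gene whose beta falls below the shared value has more
between-population (divergent) variance than its within-population noise
predicts; -log10(beta_hat) is reported as the divergence metric.

The likelihood is evaluated in O(K^3) per gene (K = number of populations)
using the exchangeability of samples within a population: within-population
contrasts have variance ``beta*v`` and contribute only through per-population
sums of squares, while population means follow a K-variate normal with
covariance ``v * (exp(-alpha D) + beta * diag(1/n_k))``. ``mu`` and ``v``
are profiled out analytically, leaving a 2-D search over (alpha, beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2, shapiro

from . import stats
from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

LOG10_ALPHA_BOUNDS = (-4.0, 3.0)
LOG10_BETA_BOUNDS = (-4.0, 4.0)
_BOUND_TOL = 1e-6
DEFAULT_MIN_MEAN = 10.0
DEFAULT_P_CUT = 0.05
DEFAULT_EVE_FDR = 0.1


# ---------------------------------------------------------------------------
# tree and dataset containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationTree:
    """Tip names and the patristic distance matrix of a population tree."""

    tips: list[str]
    dist: np.ndarray  # (K, K), symmetric, zero diagonal

    @classmethod
    def from_newick(cls, source: str, is_path: bool = False) -> "PopulationTree":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        tips = [t.label for t in taxa]
        k = len(tips)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return cls(tips, d)

    def distance(self, p: str, q: str) -> float:
        i, j = self.tips.index(p), self.tips.index(q)
        return float(self.dist[i, j])


@dataclass
class ExpressionDataset:
    """Counts (genes x samples), a sample -> population map, and the tree."""

    counts: pd.DataFrame
    sample_pops: dict[str, str]
    tree: PopulationTree

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.sample_pops)
        if missing:
            raise ConfigurationError(f"samples without population: {sorted(missing)[:3]}")
        bad = set(self.sample_pops.values()) - set(self.tree.tips)
        if bad:
            raise ConfigurationError(f"populations not in tree: {sorted(bad)}")


def read_counts(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    return df


def read_sample_map(path) -> dict[str, str]:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if not {"sample", "population"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns sample, population")
    return dict(zip(df["sample"], df["population"]))


@dataclass
class OUGeneParams:
    """Per-gene OU parameters: optimum, pull strength, stationary
    between-population variance, within/between variance ratio."""

    mu: float
    alpha: float
    v: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.mu) and self.alpha > 0 and self.v > 0 and self.beta > 0):
            raise ValueError("alpha, v, beta must be positive and mu finite")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference over genes
    expressed in every sample)."""
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    usable = ref.notna() & np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    ratios = logc.loc[usable].sub(ref[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf


def preprocess_counts(counts: pd.DataFrame,
                      min_mean: float = DEFAULT_MIN_MEAN) -> pd.DataFrame:
    """Filter low-expression genes and variance-stabilize.

    Genes with mean raw count below ``min_mean`` (across all samples) are
    removed; remaining counts are divided by median-of-ratios size factors
    and shifted-log transformed, log2(x + 1).
    """
    keep = counts.mean(axis=1) >= min_mean
    sf = size_factors(counts)
    norm = counts.loc[keep].div(sf, axis=1)
    return np.log2(norm + 1.0)


def residual_normality(norm: pd.DataFrame, sample_pops: dict[str, str]) -> pd.Series:
    """Shapiro-Wilk p per gene on within-population-centered residuals
    (quality control, reported not enforced)."""
    pops = pd.Series({s: sample_pops[s] for s in norm.columns})
    centered = norm.sub(norm.T.groupby(pops).transform("mean").T)
    out = {}
    for g, row in centered.iterrows():
        vals = row.to_numpy(dtype=float)
        out[g] = float(shapiro(vals).pvalue) if np.ptp(vals) > 0 else np.nan
    return pd.Series(out, name="shapiro_p")


# ---------------------------------------------------------------------------
# OU covariance and likelihood
# ---------------------------------------------------------------------------

def ou_covariance(tree: PopulationTree, sample_pops: list[str] | dict[str, str],
                  params: OUGeneParams) -> np.ndarray:
    """Full sample-by-sample OU covariance matrix.

    Off-diagonal: ``v * exp(-alpha d(pop_i, pop_j))`` (same-population pairs
    have d = 0, hence covariance v); diagonal: ``v * (1 + beta)``.
    """
    if isinstance(sample_pops, dict):
        pops = list(sample_pops.values())
    else:
        pops = list(sample_pops)
    idx = np.array([tree.tips.index(p) for p in pops])
    d = tree.dist[np.ix_(idx, idx)]
    cov = params.v * np.exp(-params.alpha * d)
    cov[np.diag_indices_from(cov)] = params.v * (1.0 + params.beta)
    return cov


@dataclass
class _GeneStats:
    """Sufficient statistics of one gene: per-population sample counts,
    means and the pooled within-population sum of squares."""

    n_k: np.ndarray
    ybar: np.ndarray
    sse: float
    n: int


def _gene_stats(y: np.ndarray, pop_index: np.ndarray, n_pops: int) -> _GeneStats:
    n_k = np.bincount(pop_index, minlength=n_pops).astype(float)
    sums = np.bincount(pop_index, weights=y, minlength=n_pops)
    ybar = sums / n_k
    sse = float(np.sum((y - ybar[pop_index]) ** 2))
    return _GeneStats(n_k, ybar, sse, y.size)


def _profile_loglik(log10_alpha: float, log10_beta: float, gs: _GeneStats,
                    dist: np.ndarray) -> tuple[float, float, float]:
    """Log-likelihood maximized analytically over mu and v at fixed
    (alpha, beta). Returns (ll, mu_hat, v_hat)."""
    alpha = 10.0 ** log10_alpha
    beta = 10.0 ** log10_beta
    k = gs.n_k.size
    m = np.exp(-alpha * dist)
    m[np.diag_indices_from(m)] = 1.0 + beta / gs.n_k
    try:
        cf = cho_factor(m, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    one = np.ones(k)
    w = cho_solve(cf, one)
    u = cho_solve(cf, gs.ybar)
    mu = float(one @ u) / float(one @ w)
    r = gs.ybar - mu
    quad = float(r @ cho_solve(cf, r))
    s = gs.sse / beta + quad
    if s <= 0:
        return -np.inf, mu, np.nan
    n = gs.n
    v = s / n
    logdet_m = 2.0 * np.sum(np.log(np.diag(cf[0])))
    # the final term is the Jacobian of the (contrasts, means) transform
    ll = -0.5 * (n * np.log(2 * np.pi * v) + (n - k) * np.log(beta)
                 + logdet_m + n + np.sum(np.log(gs.n_k)))
    return float(ll), mu, float(v)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _prepare(tree: PopulationTree, sample_pops: dict[str, str],
             columns) -> np.ndarray:
    pops = [sample_pops[s] for s in columns]
    counts = pd.Series(pops).value_counts()
    if (counts < 2).all():
        raise ConfigurationError(
            "need >=2 samples in at least one population for within-population variance"
        )
    return np.array([tree.tips.index(p) for p in pops])


def _free_starts(gs: _GeneStats) -> list[tuple[float, float]]:
    # moment-based start for beta: within-variance / between-variance
    within = gs.sse / max(gs.n - gs.n_k.size, 1)
    between = float(np.var(gs.ybar))
    b0 = np.clip(np.log10(max(within, 1e-12) / max(between, 1e-12)),
                 LOG10_BETA_BOUNDS[0] + 1, LOG10_BETA_BOUNDS[1] - 1)
    return [(0.0, 0.0), (0.0, b0), (-1.0, 1.0), (1.0, -1.0), (-2.0, 0.0)]


def fit_gene_free(y: np.ndarray, tree: PopulationTree, pop_index: np.ndarray,
                  extra_starts: list[tuple[float, float]] = ()) -> tuple[OUGeneParams | None, float, bool]:
    """Maximum-likelihood fit of (mu, alpha, v, beta) for one gene by
    deterministic multi-start L-BFGS-B over (log10 alpha, log10 beta).

    Returns (params, ll, converged); a constant expression vector or a
    solution pinned at a parameter bound is flagged non-converged.
    """
    gs = _gene_stats(np.asarray(y, dtype=float), pop_index, tree.dist.shape[0])
    if np.ptp(y) == 0:
        return None, -np.inf, False

    def nll(x):
        ll, _, _ = _profile_loglik(x[0], x[1], gs, tree.dist)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [LOG10_ALPHA_BOUNDS, LOG10_BETA_BOUNDS]
    best = None
    ok = False
    for x0 in list(_free_starts(gs)) + list(extra_starts):
        res = optimize.minimize(nll, np.asarray(x0, dtype=float), method="L-BFGS-B",
                                bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    ll, mu, v = _profile_loglik(best.x[0], best.x[1], gs, tree.dist)
    at_bound = (
        abs(best.x[1] - LOG10_BETA_BOUNDS[0]) < _BOUND_TOL
        or abs(best.x[1] - LOG10_BETA_BOUNDS[1]) < _BOUND_TOL
    )
    converged = ok and np.isfinite(ll) and not at_bound
    if not np.isfinite(ll):
        return None, -np.inf, False
    params = OUGeneParams(mu=mu, alpha=10.0 ** best.x[0], v=v, beta=10.0 ** best.x[1])
    return params, ll, converged


def _conditional_ll(gs: _GeneStats, dist: np.ndarray, log10_beta: float) -> tuple[float, float]:
    """Max over alpha (mu, v profiled) at fixed beta; returns (ll, log10_alpha)."""
    res = optimize.minimize_scalar(
        lambda a: -_profile_loglik(a, log10_beta, gs, dist)[0],
        bounds=LOG10_ALPHA_BOUNDS, method="bounded",
        options={"xatol": 1e-4},
    )
    return -float(res.fun), float(res.x)


@dataclass
class SharedBetaFit:
    beta_shared: float
    total_ll: float
    gene_ll: pd.Series       # per-gene conditional ll at beta_shared
    gene_alpha: pd.Series    # per-gene conditional alpha at beta_shared

    def __post_init__(self):
        assert np.isclose(self.total_ll, float(self.gene_ll.sum()))


def fit_shared_beta(Y: pd.DataFrame, tree: PopulationTree,
                    sample_pops: dict[str, str]) -> SharedBetaFit:
    """Estimate the genome-shared beta by maximizing the summed per-gene
    profile likelihood over a single beta (bounded 1-D optimization; each
    gene re-optimizes alpha, mu, v at every candidate beta).

    Constant genes are excluded; if no gene is usable a ValueError is raised.
    """
    pop_index = _prepare(tree, sample_pops, Y.columns)
    usable = {}
    for g in Y.index:
        y = Y.loc[g].to_numpy(dtype=float)
        if np.ptp(y) > 0:
            usable[g] = _gene_stats(y, pop_index, tree.dist.shape[0])
    if not usable:
        raise ValueError("no gene with non-constant expression")

    def neg_total(log10_beta: float) -> float:
        return -sum(_conditional_ll(gs, tree.dist, log10_beta)[0]
                    for gs in usable.values())

    res = optimize.minimize_scalar(neg_total, bounds=LOG10_BETA_BOUNDS,
                                   method="bounded", options={"xatol": 1e-4})
    b = float(res.x)
    lls, alphas = {}, {}
    for g, gs in usable.items():
        ll, a = _conditional_ll(gs, tree.dist, b)
        lls[g] = ll
        alphas[g] = 10.0 ** a
    gene_ll = pd.Series(lls)
    return SharedBetaFit(10.0 ** b, float(gene_ll.sum()), gene_ll, pd.Series(alphas))


def lrt_divergence(free: pd.DataFrame, shared: SharedBetaFit,
                   p_cut: float = DEFAULT_P_CUT,
                   fdr: float = DEFAULT_EVE_FDR) -> pd.DataFrame:
    """Beta-shared likelihood-ratio test per gene.

    ``free`` must carry columns ll_free, beta, converged (the per-gene free
    fits). LRT = max(0, 2*(ll_free - ll_shared)) is referred to chi-square
    with 1 df; BH q-values are computed across converged genes; the
    divergence metric is -log10 of the free beta estimate.
    """
    df = free.copy()
    df["ll_shared"] = shared.gene_ll.reindex(df.index)
    df["lrt"] = np.clip(2.0 * (df["ll_free"] - df["ll_shared"]), 0.0, None)
    df["p_value"] = chi2.sf(df["lrt"], df=1)
    df.loc[df["lrt"] == 0.0, "p_value"] = 1.0
    df["q_value"] = np.nan
    conv = df.index[df["converged"] & df["p_value"].notna()]
    if len(conv):
        df.loc[conv, "q_value"] = stats.bh_fdr(df.loc[conv, "p_value"].to_numpy())
    df["divergence"] = -np.log10(df["beta"])
    df["significant_p"] = df["converged"] & (df["p_value"] < p_cut)
    df["significant_fdr"] = df["converged"] & (df["q_value"] < fdr)
    return df


def run_eve(Y: pd.DataFrame, tree: PopulationTree, sample_pops: dict[str, str],
            p_cut: float = DEFAULT_P_CUT, fdr: float = DEFAULT_EVE_FDR) -> tuple[pd.DataFrame, SharedBetaFit]:
    """Fit the shared-beta null and per-gene free models on an already
    normalized matrix and run the beta-shared LRT.

    Nesting (ll_free >= ll_shared per gene) is enforced by re-polishing the
    free fit from the shared solution whenever the first multi-start misses
    it. Returns (per-gene results, shared fit).
    """
    pop_index = _prepare(tree, sample_pops, Y.columns)
    shared = fit_shared_beta(Y, tree, sample_pops)
    log10_b_shared = np.log10(shared.beta_shared)
    rows = {}
    for g in Y.index:
        y = Y.loc[g].to_numpy(dtype=float)
        extra = []
        if g in shared.gene_alpha.index:
            extra = [(np.log10(shared.gene_alpha[g]), log10_b_shared)]
        params, ll, converged = fit_gene_free(y, tree, pop_index, extra_starts=extra)
        rows[g] = {
            "mu": params.mu if params else np.nan,
            "alpha": params.alpha if params else np.nan,
            "v": params.v if params else np.nan,
            "beta": params.beta if params else np.nan,
            "ll_free": ll,
            "converged": converged,
        }
    free = pd.DataFrame.from_dict(rows, orient="index")
    free.index.name = "gene_id"
    results = lrt_divergence(free, shared, p_cut=p_cut, fdr=fdr)
    return results, shared


# ---------------------------------------------------------------------------
# class-level comparisons
# ---------------------------------------------------------------------------

def class_comparison(divergence: pd.Series, class_of: pd.Series) -> stats.AnovaTukeyResult:
    """One-way ANOVA with Tukey-Kramer HSD of the divergence metric across
    homology classes (e.g. ohnolog / paralog / singleton)."""
    joined = pd.DataFrame({"d": divergence, "cls": class_of}).dropna()
    groups = {c: g["d"].to_numpy() for c, g in joined.groupby("cls")}
    return stats.anova_tukey(groups)


def class_representation(significant: set[str], class_of: dict[str, str],
                         universe: set[str], focal_class: str = "ohnolog") -> tuple[float, float]:
    """Fisher test of whether ``focal_class`` genes are over/underrepresented
    among significant genes relative to the universe. Returns (odds ratio, p)."""
    if not significant:
        raise ValueError("significant gene set is empty")
    if not significant <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    a = sum(1 for g in significant if class_of.get(g) == focal_class)
    b = len(significant) - a
    rest = universe - significant
    c = sum(1 for g in rest if class_of.get(g) == focal_class)
    d = len(rest) - c
    table = [[a, b], [c, d]]
    p = stats.fisher_exact_2x2(table)
    or_, _, _ = stats.odds_ratio_ci(table)
    return or_, p
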