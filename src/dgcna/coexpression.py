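"""Per-group weighted gene co-expression analysis.

The chain follows the WGCNA recipe: an unsupervised inverse-gamma variance
filter, automatic soft-threshold (beta) selection against the scale-free
topology criterion, unsigned adjacency ``|cor|^beta``, topological overlap
(TOM) similarity, average-linkage clustering of ``1 - TOM`` with a
minimum-size tree cut, intramodular-connectivity hubs, and subsample-based
module stability scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import CountMatrix, ExpressionMatrix, ParameterError
from .simulate import substream

logger = logging.getLogger(__name__)

DEFAULT_BETAS = tuple(range(1, 21))
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_MIN_GAP = 0.02


# ---------------------------------------------------------------------------
# variance filter

def filter_genes_invgamma(
    expr: ExpressionMatrix | pd.DataFrame, p_threshold: float = 0.1
) -> list[str]:
    """Unsupervised gene filter on sample variances via an inverse-gamma fit.

    Per-gene sample variances are fit by maximum likelihood to an
    inverse-gamma distribution (location fixed at zero); each gene's p-value
    is the upper-tail probability of its variance under the fit, and genes
    with ``p <= p_threshold`` — the most variable tail — are kept.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 2:
        raise ParameterError("variance filter needs >= 2 samples")
    variances = values.var(axis=1, ddof=1).to_numpy()
    if np.ptp(variances) < 1e-12:
        raise ParameterError(
            "all gene variances are (near-)identical; the inverse-gamma fit is "
            "degenerate — skip variance filtering for this matrix"
        )
    positive = variances[variances > 0]
    shape, _, scale = stats.invgamma.fit(positive, floc=0)
    p = stats.invgamma.sf(variances, shape, loc=0, scale=scale)
    keep = p <= p_threshold
    return list(values.index[keep])


# ---------------------------------------------------------------------------
# adjacency / soft threshold

def _correlation_matrix(values: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    """Gene-gene correlation with zero-variance genes forced to r = 0."""
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes; correlations set to 0",
            stacklevel=2,
        )
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def adjacency_from_correlation(corr: np.ndarray, beta: int) -> np.ndarray:
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def adjacency(
    expr: ExpressionMatrix | pd.DataFrame, beta: int, method: str = "pearson"
) -> pd.DataFrame:
    """Unsigned WGCNA adjacency ``a_gh = |cor(g, h)|^beta`` with unit diagonal."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    corr = _correlation_matrix(values, method)
    adj = adjacency_from_correlation(corr, beta)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index.

    Connectivities are binned (equal width), per-bin mean connectivity is
    regressed against log-frequency on log10 scales, and the squared
    correlation is returned, negated when the slope is positive so that
    ascending degree distributions can never satisfy the criterion.
    Returns ``(signed_r2, slope)``.
    """
    k = np.asarray(k, dtype=float)
    if k.size < 2 or np.ptp(k) < 1e-12 or k.max() <= 0:
        return 0.0, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mean_k = k[mask].mean()
            if mean_k > 0:
                dk.append(mean_k)
                freq.append(mask.mean())
    if len(dk) < 2:
        return 0.0, np.nan
    log_dk, log_p = np.log10(dk), np.log10(freq)
    if np.ptp(log_dk) < 1e-12:
        return 0.0, np.nan
    fit = stats.linregress(log_dk, log_p)
    r2 = fit.rvalue**2
    return (-r2 if fit.slope > 0 else r2), fit.slope


@dataclass
class SoftThresholdResult:
    beta: int
    fit_table: pd.DataFrame  # columns: beta, r_squared, slope, mean_connectivity
    criterion_met: bool


def select_soft_threshold(
    expr: ExpressionMatrix | pd.DataFrame,
    betas: tuple[int, ...] = DEFAULT_BETAS,
    r2_target: float = 0.8,
    method: str = "pearson",
    min_mean_connectivity: float = 1.0,
) -> SoftThresholdResult:
    """Pick the smallest beta whose scale-free fit R^2 reaches the target.

    A candidate only satisfies the criterion while the network retains some
    density (mean connectivity >= ``min_mean_connectivity``): at extreme
    powers every adjacency collapses toward zero and the degenerate degree
    distribution fits a line trivially.  Falls back to the argmax-R^2 beta
    (``criterion_met=False``) when no candidate qualifies.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 3:
        raise ParameterError("soft-threshold selection needs >= 3 genes")
    corr = _correlation_matrix(values, method)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    rows = []
    for beta in betas:
        k = (abs_corr**beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append(
            {"beta": beta, "r_squared": r2, "slope": slope, "mean_connectivity": k.mean()}
        )
    table = pd.DataFrame(rows)
    hits = table.index[
        (table["r_squared"] >= r2_target)
        & (table["mean_connectivity"] >= min_mean_connectivity)
    ]
    if len(hits):
        best = int(table.loc[hits[0], "beta"])
        met = True
    else:
        best = int(table.loc[table["r_squared"].idxmax(), "beta"])
        met = False
    return SoftThresholdResult(beta=best, fit_table=table, criterion_met=met)


# ---------------------------------------------------------------------------
# TOM + modules

def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: shared-neighbor-weighted similarity.

    ``TOM_gh = (L_gh + a_gh) / (min(k_g, k_h) + 1 - a_gh)`` with
    ``L_gh = sum_{u != g,h} a_gu a_uh`` and ``k_g = sum_{u != g} a_gu``;
    unit diagonal.
    """
    index = adj.index if isinstance(adj, pd.DataFrame) else None
    a = np.asarray(adj, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ParameterError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ParameterError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # with zeroed diagonal the u == g and u == h terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return tom


@dataclass
class ModuleAssignment:
    """Per-gene module labels (0 = unassigned) plus per-module hub lists."""

    module_of_gene: pd.Series  # gene id -> int label
    module_sizes: dict[int, int] = field(default_factory=dict)
    hubs: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.module_sizes:
            counts = self.module_of_gene[self.module_of_gene > 0].value_counts()
            self.module_sizes = {int(m): int(c) for m, c in counts.items()}

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def members(self, label: int) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == label])

    def labels_for(self, gene_ids) -> np.ndarray:
        return self.module_of_gene.reindex(gene_ids, fill_value=0).to_numpy()


def detect_modules(
    tom: pd.DataFrame | np.ndarray,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    gene_ids=None,
    min_gap: float = DEFAULT_MIN_GAP,
) -> ModuleAssignment:
    """Average-linkage clustering of ``1 - TOM`` with a dynamic tree cut.

    The cut height is chosen adaptively from the dendrogram itself: tight
    modules complete their internal merges low in the tree while background
    genes and inter-module "glue" join near the top, so the sorted merge
    heights show a wide gap between the two regimes.  The tree is cut at the
    midpoint of the largest such gap (only gaps deep enough in the tree to
    leave room for a full module below them are considered); when no
    eligible gap reaches ``min_gap`` the tree has no module structure and
    every gene is left unassigned.  Clusters smaller than
    ``min_module_size`` are assigned label 0 ("not correlated"); the rest
    are relabeled 1..K by decreasing size.
    """
    if isinstance(tom, pd.DataFrame):
        if gene_ids is None:
            gene_ids = tom.index
        tom = tom.to_numpy()
    n = tom.shape[0]
    if gene_ids is None:
        gene_ids = pd.Index([f"g{i}" for i in range(n)])
    gene_ids = pd.Index(gene_ids)
    if n < max(2, min_module_size):
        return ModuleAssignment(pd.Series(0, index=gene_ids, name="module"))
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip((dissim + dissim.T) / 2.0, 0.0, None), checks=False)
    tree = linkage(condensed, method="average")
    heights = np.sort(tree[:, 2])
    gaps = np.diff(heights)
    # A module of m genes needs m-1 merges below the cut, so only gaps with
    # at least that many merges underneath can separate modules from glue.
    eligible = np.arange(len(gaps)) + 1 >= min_module_size - 1
    gaps = np.where(eligible, gaps, 0.0)
    if len(gaps) == 0 or gaps.max() < min_gap:
        labels = np.zeros(n, dtype=int)
    else:
        best = int(np.argmax(gaps))
        cut_height = (heights[best] + heights[best + 1]) / 2.0
        raw = fcluster(tree, t=cut_height, criterion="distance")
        labels = _relabel_by_size(raw, min_module_size)
    return ModuleAssignment(pd.Series(labels, index=gene_ids, name="module"))


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    """Small clusters -> 0; survivors -> 1..K by decreasing size (stable ties)."""
    labels = np.zeros_like(raw)
    uniq, counts = np.unique(raw, return_counts=True)
    keep = [(int(c), int(u)) for u, c in zip(uniq, counts) if c >= min_size]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new, (_, old) in enumerate(keep, start=1):
        labels[raw == old] = new
    return labels


def find_hubs(
    adj: pd.DataFrame, modules: ModuleAssignment, n_hubs: int = 5
) -> dict[int, list[str]]:
    """Top genes per module by intramodular connectivity.

    ``k_within(g) = sum_{h in module(g), h != g} a_gh``; ties broken
    lexicographically by gene id.
    """
    hubs: dict[int, list[str]] = {}
    for label in sorted(modules.module_sizes):
        members = modules.members(label)
        members = [g for g in members if g in adj.index]
        block = adj.loc[members, members].to_numpy()
        k_within = block.sum(axis=1) - 1.0  # drop the unit self-adjacency
        order = sorted(range(len(members)), key=lambda i: (-k_within[i], members[i]))
        hubs[label] = [members[i] for i in order[:n_hubs]]
    return hubs


def intramodular_connectivity(adj: pd.DataFrame, modules: ModuleAssignment) -> pd.Series:
    k = pd.Series(0.0, index=adj.index)
    for label in modules.module_sizes:
        members = [g for g in modules.members(label) if g in adj.index]
        block = adj.loc[members, members].to_numpy()
        k.loc[members] = block.sum(axis=1) - 1.0
    return k


# ---------------------------------------------------------------------------
# full chain + stability

def fallback_beta(n_samples: int) -> int:
    """Recommended unsigned-network power when the scale-free fit fails.

    The standard WGCNA guidance by sample size: 6 for n > 40, 7 for 31-40,
    8 for 21-30, 9 otherwise.
    """
    if n_samples > 40:
        return 6
    if n_samples > 30:
        return 7
    if n_samples > 20:
        return 8
    return 9


@dataclass
class CoexpressionResult:
    assignment: ModuleAssignment
    soft_threshold: SoftThresholdResult
    adjacency: pd.DataFrame
    analyzed_genes: list[str]
    beta_used: int = 0


def run_coexpression_chain(
    expr: ExpressionMatrix | pd.DataFrame,
    var_filter_p: float | None = 0.1,
    betas: tuple[int, ...] = DEFAULT_BETAS,
    r2_target: float = 0.8,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    n_hubs: int = 5,
    method: str = "pearson",
    min_gap: float = DEFAULT_MIN_GAP,
) -> CoexpressionResult:
    """Variance filter -> beta selection -> adjacency -> TOM -> modules -> hubs.

    Genes removed by the variance filter keep label 0 in the returned
    assignment, so the label vector always covers the input genes.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    all_genes = values.index
    if var_filter_p is not None:
        kept = filter_genes_invgamma(values, var_filter_p)
        analyzed = values.loc[kept]
    else:
        analyzed = values
    soft = select_soft_threshold(analyzed, betas, r2_target, method)
    # When no candidate reaches the scale-free target, the argmax beta is
    # arbitrary; follow the standard practice of the sample-size default.
    beta = soft.beta if soft.criterion_met else fallback_beta(analyzed.shape[1])
    adj = adjacency(analyzed, beta, method)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, min_module_size, min_gap=min_gap)
    full = assignment.module_of_gene.reindex(all_genes, fill_value=0)
    full.name = "module"
    assignment = ModuleAssignment(full)
    assignment.hubs = find_hubs(adj, assignment, n_hubs)
    return CoexpressionResult(assignment, soft, adj, list(analyzed.index), beta)


@dataclass
class StabilityReport:
    n_reps: int
    sample_fraction: float
    module_count_distribution: dict[int, float]
    modal_count: int
    modal_count_accuracy: float
    module_size_mean_sd: dict[int, tuple[float, float]]
    hub_recovery: pd.Series  # gene -> fraction of reps as a hub


def module_stability(
    counts: CountMatrix,
    sample_fraction: float = 0.7,
    n_reps: int = 100,
    seed: int = 0,
    **chain_params,
) -> StabilityReport:
    """Module stability under repeated subsampling of samples.

    Each rep draws ``floor(fraction * n)`` samples without replacement, reruns
    the whole co-expression chain from counts (VST included), and records the
    module count, per-rank module sizes and the hub set.  The headline
    ``modal_count_accuracy`` is the frequency of the modal module count.
    """
    from .preprocess import vst

    n = counts.n_samples
    m = int(np.floor(sample_fraction * n))
    if m < 4:
        raise ParameterError(
            f"subsample of {m} samples is too small (need >= 4)"
        )
    if n_reps < 1:
        raise ParameterError("n_reps must be positive")
    counts_per_rep: list[int] = []
    sizes_per_rep: list[list[int]] = []
    hub_hits = pd.Series(0.0, index=counts.gene_ids)
    for rep in range(n_reps):
        rng = substream(seed, "module_stability", rep)
        chosen = counts.sample_ids[
            np.sort(rng.choice(n, size=m, replace=False))
        ]
        sub = counts.subset_samples(chosen)
        expr = vst(sub)
        result = run_coexpression_chain(expr, **chain_params)
        sizes = [
            result.assignment.module_sizes[k]
            for k in sorted(result.assignment.module_sizes)
        ]
        counts_per_rep.append(len(sizes))
        sizes_per_rep.append(sizes)
        for genes in result.assignment.hubs.values():
            hub_hits.loc[genes] += 1.0
    dist_counts = pd.Series(counts_per_rep).value_counts(normalize=True)
    distribution = {int(k): float(v) for k, v in dist_counts.items()}
    modal = int(dist_counts.idxmax())
    size_stats: dict[int, tuple[float, float]] = {}
    max_rank = max(counts_per_rep) if counts_per_rep else 0
    for rank in range(1, max_rank + 1):
        observed = [s[rank - 1] for s in sizes_per_rep if len(s) >= rank]
        arr = np.asarray(observed, dtype=float)
        size_stats[rank] = (float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
    return StabilityReport(
        n_reps=n_reps,
        sample_fraction=sample_fraction,
        module_count_distribution=distribution,
        modal_count=modal,
        modal_count_accuracy=float(dist_counts.max()),
        module_size_mean_sd=size_stats,
        hub_recovery=hub_hits / n_reps,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator

class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Co-expression module detection as a sklearn clustering estimator.

    Parameters
    ----------
    var_filter_p : float or None, default=0.1
        Upper-tail p threshold of the inverse-gamma variance filter; ``None``
        disables filtering (appropriate when gene variances are homogeneous).
    betas : tuple of int
        Candidate soft-threshold powers.
    r2_target : float
        Scale-free topology fit target for automatic beta selection.
    min_module_size : int
        Clusters below this size are left unassigned (label 0).
    n_hubs : int
        Hub genes reported per module.
    method : {"pearson", "spearman"}
        Correlation flavor for the adjacency.

    Attributes
    ----------
    labels_ : ndarray of shape (n_features,)
        Module label per gene (0 = unassigned), in input column order.
    hubs_ : dict[int, list[str]]
        Ranked hub genes per module.
    beta_ : int
        Selected soft-threshold power.
    fit_table_ : DataFrame
        Scale-free fit diagnostics per candidate beta.
    """

    def __init__(
        self,
        var_filter_p: float | None = 0.1,
        betas: tuple[int, ...] = DEFAULT_BETAS,
        r2_target: float = 0.8,
        min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
        n_hubs: int = 5,
        method: str = "pearson",
        min_gap: float = DEFAULT_MIN_GAP,
    ):
        self.var_filter_p = var_filter_p
        self.betas = betas
        self.r2_target = r2_target
        self.min_module_size = min_module_size
        self.n_hubs = n_hubs
        self.method = method
        self.min_gap = min_gap

    def fit(self, X, y=None):
        """Fit on a samples x genes matrix (DataFrame columns = gene ids)."""
        if isinstance(X, pd.DataFrame):
            values = X.T
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ParameterError("X must be 2-dimensional (samples x genes)")
            values = pd.DataFrame(
                X.T, index=[f"g{i}" for i in range(X.shape[1])]
            )
        result = run_coexpression_chain(
            values,
            var_filter_p=self.var_filter_p,
            betas=tuple(self.betas),
            r2_target=self.r2_target,
            min_module_size=self.min_module_size,
            n_hubs=self.n_hubs,
            method=self.method,
            min_gap=self.min_gap,
        )
        self.assignment_ = result.assignment
        self.labels_ = result.assignment.labels_for(values.index)
        self.hubs_ = result.assignment.hubs
        self.beta_ = result.beta_used
        self.criterion_met_ = result.soft_threshold.criterion_met
        self.fit_table_ = result.soft_threshold.fit_table
        self.analyzed_genes_ = result.analyzed_genes
        self.n_modules_ = result.assignment.n_modules
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
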