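"""Differential co-expression between two conditions.

Gene pairs co-expressed in at least one condition are tested for a
correlation difference with Fisher's Z (``z = atanh(r)``, variance
``1/(n-3)``); significant pairs after BH correction are differential
co-expressed links (DCLs).  Genes carrying more incident DCLs than a
binomial model at the global DCL rate predicts are differential co-expressed
genes (DCGs).  A subsample-based stability score measures how reliably each
gene is re-identified as a DCG.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConditionedExpression, ParameterError
from .simulate import substream

R_CLAMP = 1.0 - 1e-15

DCL_CLASSES = ("same-signed", "diff-signed", "switched-opposite")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# correlations

def correlation_p_values(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    r = np.asarray(r, dtype=float)
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[interior] * np.sqrt((n - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum(p, 1.0)


def pairwise_correlations(
    expr: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-gene correlation matrix and two-sided p-value matrix.

    Zero-variance genes get r = 0 and p = 1 with a warning.
    """
    n = expr.shape[1]
    if n < 4:
        raise ParameterError("pairwise correlations need >= 4 samples")
    x = expr.to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes; r set to 0, p to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    p = correlation_p_values(corr, n)
    p[degenerate, :] = 1.0
    p[:, degenerate] = 1.0
    np.fill_diagonal(p, 0.0)
    idx = expr.index
    return (
        pd.DataFrame(corr, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def coexpressed_pairs(
    cond: ConditionedExpression,
    rth: float = 0.5,
    q_coexp: float = 0.1,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairs co-expressed (|r| >= rth and BH q <= q_coexp) in >= 1 condition.

    Returns one row per retained pair (``gene_i < gene_j`` in matrix order)
    with per-condition r, p, q and co-expression flags.
    """
    r1m, p1m = pairwise_correlations(cond.expr1, method)
    r2m, p2m = pairwise_correlations(cond.expr2, method)
    genes = cond.gene_ids.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    r1, p1 = r1m.to_numpy()[iu], p1m.to_numpy()[iu]
    r2, p2 = r2m.to_numpy()[iu], p2m.to_numpy()[iu]
    q1, q2 = bh_adjust(p1), bh_adjust(p2)
    coexp1 = (np.abs(r1) >= rth) & (q1 <= q_coexp)
    coexp2 = (np.abs(r2) >= rth) & (q2 <= q_coexp)
    keep = coexp1 | coexp2
    return pd.DataFrame(
        {
            "gene_i": genes[iu[0][keep]],
            "gene_j": genes[iu[1][keep]],
            "r1": r1[keep],
            "p1": p1[keep],
            "q1": q1[keep],
            "r2": r2[keep],
            "p2": p2[keep],
            "q2": q2[keep],
            "coexp1": coexp1[keep],
            "coexp2": coexp2[keep],
        }
    )


# ---------------------------------------------------------------------------
# Fisher-Z difference test

def fisher_z_diff_test(r1, n1: int, r2, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-Z test for a difference between two independent correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided standard-normal p.  Accepts scalars or arrays; correlations at
    |r| = 1 are clamped to keep atanh finite.
    """
    if n1 <= 3 or n2 <= 3:
        raise ParameterError("Fisher-Z needs n > 3 in both conditions")
    r1 = np.clip(np.asarray(r1, dtype=float), -R_CLAMP, R_CLAMP)
    r2 = np.clip(np.asarray(r2, dtype=float), -R_CLAMP, R_CLAMP)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def classify_dcl(r1, r2, coexp1, coexp2) -> np.ndarray:
    """DCL class from per-condition co-expression flags and correlation signs."""
    coexp1 = np.asarray(coexp1, dtype=bool)
    coexp2 = np.asarray(coexp2, dtype=bool)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(~coexp1 & ~coexp2):
        raise ParameterError("a DCL must be co-expressed in at least one condition")
    both = coexp1 & coexp2
    same_sign = np.sign(r1) == np.sign(r2)
    return np.select(
        [both & same_sign, both & ~same_sign],
        ["same-signed", "switched-opposite"],
        default="diff-signed",
    )


def call_dcls(
    pairs: pd.DataFrame,
    cond: ConditionedExpression,
    q_dcl: float = 0.1,
) -> pd.DataFrame:
    """Fisher-Z test every retained pair; BH over retained pairs; q <= q_dcl.

    Returns the significant pairs with ``z``, ``p_diff``, ``q_diff`` and
    ``dcl_class`` columns appended.
    """
    pairs = pairs.copy()
    if len(pairs) == 0:
        for col in ("z", "p_diff", "q_diff", "dcl_class"):
            pairs[col] = []
        return pairs
    z, p = fisher_z_diff_test(
        pairs["r1"].to_numpy(), cond.n1, pairs["r2"].to_numpy(), cond.n2
    )
    pairs["z"] = z
    pairs["p_diff"] = p
    pairs["q_diff"] = bh_adjust(p)
    dcls = pairs[pairs["q_diff"] <= q_dcl].copy()
    if len(dcls):
        dcls["dcl_class"] = classify_dcl(
            dcls["r1"], dcls["r2"], dcls["coexp1"], dcls["coexp2"]
        )
    else:
        dcls["dcl_class"] = pd.Series([], dtype=str)
    return dcls


# ---------------------------------------------------------------------------
# DCGs

def call_dcgs(
    dcls: pd.DataFrame, pairs: pd.DataFrame, q_dcg: float = 0.1
) -> pd.DataFrame:
    """Binomial enrichment of incident DCLs per gene.

    The global rate ``p_hat = #DCLs / #retained pairs`` gives the null; for a
    gene with ``n_links`` incident retained pairs of which ``n_dcls`` are
    DCLs, ``p_binom = P(X >= n_dcls), X ~ Binomial(n_links, p_hat)``.  BH runs
    over every gene with at least one link; the ``dcg`` column marks
    ``q_binom <= q_dcg``.
    """
    if len(pairs) == 0:
        raise ParameterError("no retained pairs; cannot estimate the DCL rate")
    p_hat = len(dcls) / len(pairs)
    genes = pd.unique(np.concatenate([pairs["gene_i"], pairs["gene_j"]]))
    code = {g: i for i, g in enumerate(genes)}
    n_links = np.zeros(len(genes), dtype=int)
    n_dcls = np.zeros(len(genes), dtype=int)
    for col in ("gene_i", "gene_j"):
        np.add.at(n_links, [code[g] for g in pairs[col]], 1)
        if len(dcls):
            np.add.at(n_dcls, [code[g] for g in dcls[col]], 1)
    p_binom = stats.binom.sf(n_dcls - 1, n_links, p_hat)
    out = pd.DataFrame(
        {
            "gene": genes,
            "n_links": n_links,
            "n_dcls": n_dcls,
            "p_binom": p_binom,
            "q_binom": bh_adjust(p_binom),
        }
    )
    out["dcg"] = out["q_binom"] <= q_dcg
    return out.sort_values(["q_binom", "gene"], kind="stable").reset_index(drop=True)


@dataclass
class DiffCoexpNetwork:
    """The differential co-expression network: DCL edges and DCG nodes."""

    genes: list[str]
    pairs: pd.DataFrame  # retained (tested) pairs
    dcls: pd.DataFrame
    dcgs: pd.DataFrame  # all linked genes with binomial stats; `dcg` column
    thresholds: dict = field(default_factory=dict)

    @property
    def dcg_genes(self) -> list[str]:
        return sorted(self.dcgs.loc[self.dcgs["dcg"], "gene"])

    @property
    def node_genes(self) -> list[str]:
        return sorted(set(self.dcls["gene_i"]) | set(self.dcls["gene_j"]))

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "thresholds": self.thresholds,
            "pairs": self.pairs.to_dict(orient="list"),
            "dcls": self.dcls.to_dict(orient="list"),
            "dcgs": self.dcgs.to_dict(orient="list"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=_json_scalar)

    @classmethod
    def from_dict(cls, data: dict) -> "DiffCoexpNetwork":
        return cls(
            genes=list(data["genes"]),
            pairs=pd.DataFrame(data["pairs"]),
            dcls=pd.DataFrame(data["dcls"]),
            dcgs=pd.DataFrame(data["dcgs"]),
            thresholds=dict(data.get("thresholds", {})),
        )

    @classmethod
    def from_json(cls, path) -> "DiffCoexpNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for _, row in self.dcls.iterrows():
                fh.write(f"{row['gene_i']}\tdcl\t{row['gene_j']}\n")


def _json_scalar(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def differential_coexpression(
    cond: ConditionedExpression,
    rth: float = 0.5,
    q_coexp: float = 0.1,
    q_dcl: float = 0.1,
    q_dcg: float = 0.1,
    method: str = "pearson",
) -> DiffCoexpNetwork:
    """Full chain: co-expressed pair gating -> DCL calling -> DCG calling."""
    pairs = coexpressed_pairs(cond, rth, q_coexp, method)
    dcls = call_dcls(pairs, cond, q_dcl)
    if len(pairs):
        dcgs = call_dcgs(dcls, pairs, q_dcg)
    else:
        dcgs = pd.DataFrame(
            columns=["gene", "n_links", "n_dcls", "p_binom", "q_binom", "dcg"]
        )
    return DiffCoexpNetwork(
        genes=list(cond.gene_ids),
        pairs=pairs,
        dcls=dcls,
        dcgs=dcgs,
        thresholds={
            "rth": rth,
            "q_coexp": q_coexp,
            "q_dcl": q_dcl,
            "q_dcg": q_dcg,
            "method": method,
        },
    )


def dcg_stability(
    cond: ConditionedExpression,
    sample_fraction: float = 0.7,
    n_reps: int = 100,
    seed: int = 0,
    joint: bool = False,
    **thresholds,
) -> pd.Series:
    """Fraction of subsample reps in which each gene is re-called a DCG.

    Each rep subsamples the two conditions independently (preserving the
    group ratio) at ``sample_fraction`` without replacement and reruns the
    whole DCG chain.  ``joint=True`` instead subsamples the pooled sample
    list once and splits it by condition.
    """
    n1, n2 = cond.n1, cond.n2
    m1, m2 = int(np.floor(sample_fraction * n1)), int(np.floor(sample_fraction * n2))
    if m1 < 4 or m2 < 4:
        raise ParameterError("subsampled group sizes must be >= 4")
    hits = pd.Series(0.0, index=cond.gene_ids)
    for rep in range(n_reps):
        rng = substream(seed, "dcg_stability", rep)
        if joint:
            pooled = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
            chosen = rng.choice(n1 + n2, size=m1 + m2, replace=False)
            idx1 = np.sort(chosen[pooled[chosen] == 0])
            idx2 = np.sort(chosen[pooled[chosen] == 1] - n1)
            if len(idx1) < 4 or len(idx2) < 4:
                continue
        else:
            idx1 = np.sort(rng.choice(n1, size=m1, replace=False))
            idx2 = np.sort(rng.choice(n2, size=m2, replace=False))
        sub = ConditionedExpression(cond.expr1.iloc[:, idx1], cond.expr2.iloc[:, idx2])
        net = differential_coexpression(sub, **thresholds)
        dcg = net.dcg_genes
        if dcg:
            hits.loc[dcg] += 1.0
    return hits / n_reps


# ---------------------------------------------------------------------------
# sklearn-style estimator

from sklearn.base import BaseEstimator  # noqa: E402


class DifferentialCoexpression(BaseEstimator):
    """Differential co-expression as a paired-condition sklearn estimator.

    ``fit(X, y)`` takes a samples x genes matrix ``X`` (DataFrame columns are
    gene ids) and a binary condition vector ``y``; condition order follows
    sorted unique labels unless ``conditions`` is given.

    Attributes
    ----------
    pairs_ : DataFrame
        Pairs co-expressed in at least one condition (the tested universe).
    dcls_ : DataFrame
        Differential co-expressed links (q_diff <= q_dcl) with classes.
    dcgs_ : DataFrame
        Per-gene binomial statistics; boolean ``dcg`` column.
    network_ : DiffCoexpNetwork
        The assembled differential network.
    """

    def __init__(
        self,
        rth: float = 0.5,
        q_coexp: float = 0.1,
        q_dcl: float = 0.1,
        q_dcg: float = 0.1,
        method: str = "pearson",
        conditions: tuple | None = None,
    ):
        self.rth = rth
        self.q_coexp = q_coexp
        self.q_dcl = q_dcl
        self.q_dcg = q_dcg
        self.method = method
        self.conditions = conditions

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, dtype=float),
                columns=[f"g{i}" for i in range(np.asarray(X).shape[1])],
            )
        y = np.asarray(y)
        if len(y) != len(X):
            raise ParameterError("y must label every sample (row) of X")
        levels = self.conditions or tuple(sorted(pd.unique(y)))
        if len(levels) != 2:
            raise ParameterError(f"need exactly 2 condition labels, got {levels}")
        expr = X.T
        cond = ConditionedExpression(
            expr.loc[:, y == levels[0]], expr.loc[:, y == levels[1]]
        )
        net = differential_coexpression(
            cond,
            rth=self.rth,
            q_coexp=self.q_coexp,
            q_dcl=self.q_dcl,
            q_dcg=self.q_dcg,
            method=self.method,
        )
        self.condition_levels_ = levels
        self.conditioned_ = cond
        self.network_ = net
        self.pairs_ = net.pairs
        self.dcls_ = net.dcls
        self.dcgs_ = net.dcgs
        self.dcg_genes_ = net.dcg_genes
        return self
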