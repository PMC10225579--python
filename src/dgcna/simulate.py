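"""Two-condition RNA-seq count simulator with planted co-expression structure.

The generator emulates the study design every downstream stage assumes:

* latent-factor co-expression modules — gene ``g`` in module ``m`` carries the
  log-scale signal ``x = sqrt(rho) * f_m + sqrt(1 - rho) * eps`` with a shared
  per-sample module factor ``f_m ~ N(0, 1)``, so any two module co-members have
  Pearson correlation ``rho`` on the latent scale;
* planted differential pairs — gene pairs drawn bivariate-normal with
  correlation ``r1`` in condition 1 and ``r2`` in condition 2, overriding the
  background for those genes (pairs may share a gene: the partner is then drawn
  conditionally, ``x_j = r x_i + sqrt(1 - r^2) eta``, which reduces to the
  bivariate construction for disjoint pairs);
* negative-binomial counts with log-normal library-size variation —
  ``counts ~ NB(mean = L_s * exp(mu + x), dispersion = alpha)``.

Randomness is hierarchical: every gene, module factor and sample draws from a
named substream of the one top-level seed, so enlarging the gene set never
perturbs the draws of earlier genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, ParameterError

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "generate_dataset",
    "generate_null_correlation_pairs",
]

CONDITIONS = ("cond1", "cond2")


def substream(seed: int, *tags) -> np.random.Generator:
    """Deterministic named child stream of a top-level seed."""
    key = tuple(
        t if isinstance(t, (int, np.integer)) else zlib.crc32(str(t).encode())
        for t in tags
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass
class SimulationParams:
    """Study-design knobs for :func:`generate_dataset`.

    ``planted_pairs`` entries are ``(gene_i, gene_j, r1, r2)`` with 0-based
    gene indices; by default these genes must be background (outside every
    module) so module-recovery and differential-link tests stay independent.
    """

    n_genes: int = 200
    n_samples_per_condition: tuple[int, int] = (70, 70)
    module_sizes: list[int] = field(default_factory=list)
    within_module_cor: float = 0.8
    planted_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    nb_dispersion: float = 0.01
    mean_log_expression: float = 6.5
    library_size_log_sd: float = 0.2
    seed: int = 0
    allow_module_overlap: bool = False

    def validate(self) -> None:
        n1, n2 = self.n_samples_per_condition
        if n1 < 4 or n2 < 4:
            raise ParameterError(
                "n_samples_per_condition: both groups need >= 4 samples "
                f"(got {n1}, {n2})"
            )
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ParameterError(
                "module_sizes: total module membership exceeds n_genes"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ParameterError("module_sizes entries must be positive")
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ParameterError("within_module_cor must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")
        if self.library_size_log_sd < 0:
            raise ParameterError("library_size_log_sd must be non-negative")
        n_module = sum(self.module_sizes)
        for i, j, r1, r2 in self.planted_pairs:
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes) or i == j:
                raise ParameterError(f"planted_pairs: invalid gene pair ({i}, {j})")
            if abs(r1) >= 1 or abs(r2) >= 1:
                raise ParameterError(
                    f"planted_pairs: |r| must be < 1 (pair {i},{j}: {r1}, {r2})"
                )
            if not self.allow_module_overlap and (i < n_module or j < n_module):
                raise ParameterError(
                    f"planted_pairs: genes ({i}, {j}) overlap module genes; "
                    "set allow_module_overlap=True to permit"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth: module labels (0 = background) and pairs."""

    module_of_gene: dict[str, int]
    differential_pairs: list[tuple[str, str, float, float]]

    def module_labels(self, gene_ids) -> np.ndarray:
        return np.array([self.module_of_gene[g] for g in gene_ids])

    @property
    def planted_hub_genes(self) -> list[str]:
        """Genes appearing in more than one planted pair (star centers)."""
        counts: dict[str, int] = {}
        for gi, gj, _, _ in self.differential_pairs:
            counts[gi] = counts.get(gi, 0) + 1
            counts[gj] = counts.get(gj, 0) + 1
        return sorted(g for g, c in counts.items() if c > 1)


def gene_id(i: int) -> str:
    return f"G{i + 1:06d}"


def _module_index(params: SimulationParams) -> np.ndarray:
    labels = np.zeros(params.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(params.module_sizes, start=1):
        labels[start : start + size] = m
        start += size
    return labels


def _latent_signals(params: SimulationParams, n_total: int) -> np.ndarray:
    """Latent log-scale signal matrix (genes x all samples)."""
    seed = params.seed
    labels = _module_index(params)
    rho = params.within_module_cor
    factors = {
        m: substream(seed, "factor", m).standard_normal(n_total)
        for m in range(1, len(params.module_sizes) + 1)
    }
    x = np.empty((params.n_genes, n_total))
    for g in range(params.n_genes):
        eps = substream(seed, "gene_noise", g).standard_normal(n_total)
        m = labels[g]
        if m > 0:
            x[g] = np.sqrt(rho) * factors[m] + np.sqrt(1.0 - rho) * eps
        else:
            x[g] = eps

    n1, _ = params.n_samples_per_condition
    # Planted pairs: per condition, partner = r * base + sqrt(1-r^2) * noise.
    planted: set[int] = set()
    for i, j, r1, r2 in params.planted_pairs:
        if i in planted and j in planted:
            raise ParameterError(
                f"planted_pairs: both genes of pair ({i}, {j}) already "
                "constrained by earlier pairs"
            )
        if j in planted:  # keep the already-constrained gene as the base
            i, j = j, i
        eta = substream(seed, "pair_noise", j).standard_normal(n_total)
        for r, sl in ((r1, slice(0, n1)), (r2, slice(n1, n_total))):
            x[j, sl] = r * x[i, sl] + np.sqrt(1.0 - r * r) * eta[sl]
        planted.update((i, j))
    return x


def generate_dataset(params: SimulationParams) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a two-condition count matrix with planted structure.

    Returns the counts (genes x samples, integer) together with the planted
    truth.  Same ``params.seed`` -> bit-identical output.
    """
    params.validate()
    n1, n2 = params.n_samples_per_condition
    n_total = n1 + n2
    x = _latent_signals(params, n_total)

    log_lib = substream(params.seed, "library").standard_normal(n_total)
    lib = np.exp(params.library_size_log_sd * log_lib)

    mu = lib[None, :] * np.exp(params.mean_log_expression + x)
    size = 1.0 / params.nb_dispersion  # NB variance = mu + alpha * mu^2
    p = size / (size + mu)
    counts = np.empty((params.n_genes, n_total), dtype=np.int64)
    for g in range(params.n_genes):
        rng = substream(params.seed, "counts", g)
        counts[g] = rng.negative_binomial(size, p[g])

    genes = [gene_id(i) for i in range(params.n_genes)]
    samples = [f"{CONDITIONS[0]}_s{k + 1:04d}" for k in range(n1)] + [
        f"{CONDITIONS[1]}_s{k + 1:04d}" for k in range(n2)
    ]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    conditions = pd.Series(
        [CONDITIONS[0]] * n1 + [CONDITIONS[1]] * n2, index=frame.columns, name="condition"
    )
    labels = _module_index(params)
    truth = SyntheticTruth(
        module_of_gene={genes[g]: int(labels[g]) for g in range(params.n_genes)},
        differential_pairs=[
            (genes[i], genes[j], r1, r2) for i, j, r1, r2 in params.planted_pairs
        ],
    )
    return CountMatrix(frame, conditions), truth


def star_pairs(
    center: int, leaves: list[int], r1: float, r2: float
) -> list[tuple[int, int, float, float]]:
    """Planted pairs wiring one hub gene to each leaf (a planted DCG)."""
    return [(center, leaf, r1, r2) for leaf in leaves]


def generate_null_correlation_pairs(
    n1: int, n2: int, r_common: float, reps: int, seed: int
) -> list[tuple[float, float]]:
    """Sample-correlation pairs under a shared true correlation.

    Each rep draws two independent bivariate-normal samples (sizes ``n1`` and
    ``n2``) with the same true correlation ``r_common`` and returns the two
    sample Pearson correlations — the calibration harness for the Fisher-Z
    difference test's type-I error.
    """
    if n1 < 4 or n2 < 4:
        raise ParameterError("n1 and n2 must both be >= 4")
    if abs(r_common) >= 1:
        raise ParameterError("|r_common| must be < 1")
    if reps < 0:
        raise ParameterError("reps must be non-negative")
    if reps == 0:
        return []
    rng = substream(seed, "null_pairs")
    out = []
    for n in (n1, n2):
        z = rng.standard_normal((reps, n, 2))
        y = r_common * z[:, :, 0] + np.sqrt(1.0 - r_common**2) * z[:, :, 1]
        a = z[:, :, 0] - z[:, :, 0].mean(axis=1, keepdims=True)
        b = y - y.mean(axis=1, keepdims=True)
        r = (a * b).sum(axis=1) / np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
        out.append(r)
    return list(zip(out[0].tolist(), out[1].tolist()))
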