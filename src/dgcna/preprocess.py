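"""Count-matrix normalization and filtering.

The rules mirror standard bulk RNA-seq quality control for co-expression
work: counts-per-million scaling, removal of transcripts whose total count
falls below the global per-transcript average, removal of shallow samples
(default floor 10 million reads), restriction to protein-coding biotypes, and
a log2(CPM + 1) variance-stabilizing transform before any correlation-based
analysis.  Every operation returns a new object and records itself in the
result's provenance.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    UNANNOTATED,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    ParameterError,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10_000_000


def cpm_normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: scale every sample to a library size of 1e6."""
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ParameterError(f"zero-depth samples cannot be CPM-normalized: {zero.tolist()}")
    cpm = counts.counts / totals * 1e6
    return ExpressionMatrix(
        cpm,
        transform_tag="cpm",
        provenance=[{"op": "cpm_normalize"}],
        conditions=counts.conditions,
    )


def filter_transcripts_global_average(
    counts: CountMatrix, per_sample: bool = False
) -> tuple[CountMatrix, dict]:
    """Drop transcripts whose total count is below the global average.

    With ``T_g = sum_s counts_gs`` and ``A = mean_g(T_g)``, genes with
    ``T_g < A`` are removed; ties (``T_g == A``) are retained.  The
    ``per_sample`` variant compares each transcript against each sample's own
    average instead: a gene survives if ``counts_gs >= mean_g(counts_gs)`` in
    at least one sample.
    """
    if counts.n_genes == 0:
        raise ParameterError("empty count matrix")
    totals = counts.counts.sum(axis=1)
    if per_sample:
        per_sample_avg = counts.counts.mean(axis=0)
        keep = (counts.counts >= per_sample_avg).any(axis=1)
        threshold = float(per_sample_avg.mean())
    else:
        threshold = float(totals.mean())
        keep = totals >= threshold
    record = {
        "op": "filter_transcripts_global_average",
        "global_average": threshold,
        "per_sample": per_sample,
        "n_removed": int((~keep).sum()),
    }
    return counts.subset_genes(counts.gene_ids[keep]), record


def filter_samples_by_depth(
    counts: CountMatrix, min_reads: int = DEFAULT_MIN_READS
) -> tuple[CountMatrix, dict]:
    """Drop samples with fewer than ``min_reads`` total counts (strict)."""
    totals = counts.counts.sum(axis=0)
    keep = totals >= min_reads
    dropped = counts.sample_ids[~keep].tolist()
    if not keep.any():
        raise ParameterError(f"all samples fall below {min_reads} reads")
    if dropped:
        logger.info("depth filter removed %d samples: %s", len(dropped), dropped)
    record = {
        "op": "filter_samples_by_depth",
        "min_reads": int(min_reads),
        "dropped_samples": dropped,
    }
    return counts.subset_samples(counts.sample_ids[keep]), record


def filter_by_biotype(
    counts: CountMatrix,
    annot: GeneAnnotation,
    keep: set[str] = frozenset({"protein_coding"}),
) -> tuple[CountMatrix, dict]:
    """Restrict to genes whose biotype is in ``keep``.

    Unannotated genes resolve to the sentinel label and are removed unless the
    sentinel itself is in ``keep``.
    """
    biotypes = np.array([annot.biotype(g) for g in counts.gene_ids])
    mask = np.isin(biotypes, list(keep))
    if not mask.any():
        raise ParameterError("biotype filter removed every gene")
    record = {
        "op": "filter_by_biotype",
        "keep": sorted(keep),
        "n_removed": int((~mask).sum()),
        "sentinel": UNANNOTATED,
    }
    return counts.subset_genes(counts.gene_ids[mask]), record


def vst(counts: CountMatrix) -> ExpressionMatrix:
    """Variance-stabilizing transform: log2(CPM + 1).

    CPM is recomputed from the current matrix, so library sizes always
    reflect the retained genes.
    """
    cpm = cpm_normalize(counts)
    values = np.log2(cpm.values + 1.0)
    return ExpressionMatrix(
        values,
        transform_tag="log2cpm1",
        provenance=cpm.provenance + [{"op": "vst", "formula": "log2(cpm + 1)"}],
        conditions=counts.conditions,
    )


def preprocess_counts(
    counts: CountMatrix,
    annot: GeneAnnotation | None = None,
    keep_biotypes: set[str] = frozenset({"protein_coding"}),
    min_reads: int = DEFAULT_MIN_READS,
    apply_vst: bool = True,
    apply_global_average: bool = True,
) -> tuple[CountMatrix, ExpressionMatrix | None, list[dict]]:
    """Full filtering chain: biotype -> global-average -> depth -> VST.

    ``apply_global_average=False`` skips the abundance filter — appropriate
    when every transcript is known to be expressed (e.g. simulated data with
    a common baseline), where a mean-count threshold would drop an arbitrary
    half of the genes.
    """
    provenance: list[dict] = []
    if annot is not None:
        counts, rec = filter_by_biotype(counts, annot, keep_biotypes)
        provenance.append(rec)
    if apply_global_average:
        counts, rec = filter_transcripts_global_average(counts)
        provenance.append(rec)
    counts, rec = filter_samples_by_depth(counts, min_reads)
    provenance.append(rec)
    expr = None
    if apply_vst:
        expr = vst(counts)
        expr.provenance = provenance + expr.provenance
    return counts, expr, provenance
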