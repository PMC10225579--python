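"""Readers and writers for the pipeline's plain-text formats.

Counts TSV: first column ``gene_id``, one column per sample.
Metadata TSV: ``sample_id`` and ``condition`` columns.
Annotation TSV: ``gene_id`` and ``biotype`` columns.
Gene lists: one gene id per line.  Networks travel as JSON (and SIF).
"""

from __future__ import annotations

import json

import pandas as pd

from .containers import CountMatrix, GeneAnnotation, ParameterError
from .simulate import SyntheticTruth


def read_counts(counts_path, metadata_path) -> CountMatrix:
    frame = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("sample_id", "condition"):
        if col not in meta.columns:
            raise ParameterError(f"metadata is missing the {col!r} column")
    conditions = pd.Series(
        meta["condition"].to_numpy(), index=meta["sample_id"], name="condition"
    )
    return CountMatrix(frame, conditions)


def write_counts(counts: CountMatrix, counts_path, metadata_path) -> None:
    counts.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    meta = pd.DataFrame(
        {"sample_id": counts.sample_ids, "condition": counts.conditions.to_numpy()}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotation:
    frame = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "biotype"):
        if col not in frame.columns:
            raise ParameterError(f"annotation is missing the {col!r} column")
    return GeneAnnotation.from_frame(frame)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "module_of_gene": truth.module_of_gene,
                "differential_pairs": [list(p) for p in truth.differential_pairs],
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        data = json.load(fh)
    return SyntheticTruth(
        module_of_gene={g: int(m) for g, m in data["module_of_gene"].items()},
        differential_pairs=[
            (i, j, float(r1), float(r2)) for i, j, r1, r2 in data["differential_pairs"]
        ],
    )
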