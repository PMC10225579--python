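"""Config-driven orchestration of the full analysis.

``run_all`` chains preprocess → per-group co-expression (with stability) →
two-condition differential co-expression (with DCG stability) → optional
over-representation analysis → optional boosted-tree prediction, mirroring a
case/control transcriptomics study that analyses each condition and the
pooled samples separately.  Every output file's SHA-256 lands in a run
manifest so a rerun with an identical config can be checked for
bit-reproducibility stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, ParameterError
from .coexpression import CoexpressionResult, module_stability, run_coexpression_chain
from .diffcoexp import DiffCoexpNetwork, dcg_stability, differential_coexpression
from .enrichment import ora_hypergeom, read_gmt
from .io import read_annotation, read_counts, read_gene_list, write_counts, write_truth
from .preprocess import preprocess_counts, vst
from .prediction import FeatureSetSpec, evaluate_feature_sets
from .simulate import SimulationParams, generate_dataset

logger = logging.getLogger(__name__)

MIN_SAMPLES_PER_GROUP = 20  # best-practice floor for co-expression work


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for one pipeline run."""

    output_dir: str = "dgcna_run"
    seed: int = 0
    counts: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    simulate: dict | None = None
    conditions: tuple[str, str] = ("cond1", "cond2")
    groups: list[str] = field(default_factory=lambda: ["cond1", "cond2", "pooled"])
    preprocess: dict = field(default_factory=dict)
    coexpression: dict = field(default_factory=dict)
    diffcoexp: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.conditions = tuple(cfg.conditions)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if self.counts is None or self.metadata is None:
                raise ParameterError(
                    "config needs either a 'simulate' block or 'counts' + 'metadata'"
                )
            for label, path in (
                ("counts", self.counts),
                ("metadata", self.metadata),
                ("annotation", self.annotation),
            ):
                if path is not None and not Path(path).exists():
                    raise ParameterError(f"{label} file does not exist: {path}")
        gmt = self.enrichment.get("gmt")
        if gmt is not None and not Path(gmt).exists():
            raise ParameterError(f"gene-set file does not exist: {gmt}")
        for name, path in self.prediction.get("feature_lists", {}).items():
            if not Path(path).exists():
                raise ParameterError(f"feature list {name!r} does not exist: {path}")

    def snapshot(self) -> dict:
        data = dataclasses.asdict(self)
        data["conditions"] = list(data["conditions"])
        return data


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def exclusive_elements(a, b) -> set:
    """Elements of ``a`` absent from ``b`` (set difference)."""
    return set(a) - set(b)


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        params = SimulationParams(seed=config.seed, **config.simulate)
        counts, truth = generate_dataset(params)
        write_counts(counts, out / "counts.tsv", out / "metadata.tsv")
        write_truth(truth, out / "truth.json")
        return counts, truth
    counts = read_counts(config.counts, config.metadata)
    return counts, None


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.snapshot(),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "hashes": {},
    }
    stage = "load"
    try:
        counts, _truth = _load_inputs(config, out)

        stage = "preprocess"
        pp = dict(config.preprocess)
        annot = read_annotation(config.annotation) if config.annotation else None
        counts_f, _, provenance = preprocess_counts(
            counts,
            annot=annot,
            keep_biotypes=set(pp.get("keep_biotypes", ["protein_coding"]))
            if annot
            else frozenset(),
            min_reads=pp.get("min_reads", 10_000_000),
            apply_vst=False,
            apply_global_average=pp.get("global_average", True),
        )
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)
        manifest["hashes"]["preprocess"] = {
            "provenance.json": sha256_file(out / "provenance.json")
        }
        manifest["stages"].append("preprocess")

        c1, c2 = config.conditions
        group_counts: dict[str, CountMatrix] = {}
        for group in config.groups:
            if group == "pooled":
                group_counts[group] = counts_f
            else:
                samples = counts_f.sample_ids[counts_f.conditions == group]
                if len(samples) == 0:
                    raise ParameterError(f"no samples for group {group!r}")
                group_counts[group] = counts_f.subset_samples(samples)
            if group_counts[group].n_samples < MIN_SAMPLES_PER_GROUP:
                logger.warning(
                    "group %r has %d samples, below the best-practice floor of "
                    "20 or more samples per group",
                    group,
                    group_counts[group].n_samples,
                )

        stage = "coexpression"
        cx = dict(config.coexpression)
        stability_cfg = cx.pop("stability", {})
        chain_params = {
            k: cx[k]
            for k in (
                "var_filter_p",
                "betas",
                "r2_target",
                "min_module_size",
                "n_hubs",
                "method",
                "min_gap",
            )
            if k in cx
        }
        if "betas" in chain_params:
            chain_params["betas"] = tuple(chain_params["betas"])
        group_results: dict[str, CoexpressionResult] = {}
        coexpr_hashes = {}
        for group, gcounts in group_counts.items():
            expr = vst(gcounts)
            result = run_coexpression_chain(expr, **chain_params)
            group_results[group] = result
            modules_path = out / f"modules_{group}.tsv"
            _write_tsv(
                result.assignment.module_of_gene.to_frame(),
                modules_path,
                index_label="gene_id",
            )
            hub_rows = [
                {"module": m, "rank": r + 1, "gene_id": g}
                for m, hub_list in sorted(result.assignment.hubs.items())
                for r, g in enumerate(hub_list)
            ]
            hubs_path = out / f"hubs_{group}.tsv"
            _write_tsv(pd.DataFrame(hub_rows), hubs_path, index=False)
            fit_path = out / f"soft_threshold_{group}.tsv"
            _write_tsv(result.soft_threshold.fit_table, fit_path, index=False)
            coexpr_hashes[modules_path.name] = sha256_file(modules_path)
            coexpr_hashes[hubs_path.name] = sha256_file(hubs_path)
            coexpr_hashes[fit_path.name] = sha256_file(fit_path)
            if stability_cfg.get("enabled", False):
                report = module_stability(
                    gcounts,
                    sample_fraction=stability_cfg.get("sample_fraction", 0.7),
                    n_reps=stability_cfg.get("n_reps", 100),
                    seed=config.seed,
                    **chain_params,
                )
                stab_path = out / f"module_stability_{group}.json"
                with open(stab_path, "w") as fh:
                    json.dump(
                        {
                            "n_reps": report.n_reps,
                            "sample_fraction": report.sample_fraction,
                            "module_count_distribution": {
                                str(k): v
                                for k, v in sorted(
                                    report.module_count_distribution.items()
                                )
                            },
                            "modal_count": report.modal_count,
                            "modal_count_accuracy": report.modal_count_accuracy,
                            "module_size_mean_sd": {
                                str(k): list(v)
                                for k, v in sorted(report.module_size_mean_sd.items())
                            },
                            "hub_recovery": {
                                g: f
                                for g, f in report.hub_recovery.items()
                                if f > 0
                            },
                        },
                        fh,
                        indent=1,
                        sort_keys=True,
                    )
                coexpr_hashes[stab_path.name] = sha256_file(stab_path)
        manifest["hashes"]["coexpression"] = coexpr_hashes
        manifest["stages"].append("coexpression")

        # exclusive genes / hubs between the two condition groups
        if c1 in group_results and c2 in group_results:
            a1 = group_results[c1].assignment
            a2 = group_results[c2].assignment
            genes1 = set(a1.module_of_gene.index[a1.module_of_gene > 0])
            genes2 = set(a2.module_of_gene.index[a2.module_of_gene > 0])
            hubs1 = {g for hub_list in a1.hubs.values() for g in hub_list}
            hubs2 = {g for hub_list in a2.hubs.values() for g in hub_list}
            excl = {
                f"{c1}_exclusive_module_genes": sorted(
                    exclusive_elements(genes1, genes2)
                ),
                f"{c2}_exclusive_module_genes": sorted(
                    exclusive_elements(genes2, genes1)
                ),
                f"{c1}_exclusive_hubs": sorted(exclusive_elements(hubs1, hubs2)),
                f"{c2}_exclusive_hubs": sorted(exclusive_elements(hubs2, hubs1)),
            }
            with open(out / "exclusive_elements.json", "w") as fh:
                json.dump(excl, fh, indent=1, sort_keys=True)
            manifest["hashes"]["exclusive"] = {
                "exclusive_elements.json": sha256_file(out / "exclusive_elements.json")
            }

        stage = "diffcoexp"
        dc = dict(config.diffcoexp)
        dcg_stab_cfg = dc.pop("stability", {})
        from .containers import ConditionedExpression

        expr_all = vst(counts_f)
        cond = ConditionedExpression.from_expression(expr_all, c1, c2)
        network = differential_coexpression(
            cond,
            rth=dc.get("rth", 0.5),
            q_coexp=dc.get("q_coexp", 0.1),
            q_dcl=dc.get("q_dcl", 0.1),
            q_dcg=dc.get("q_dcg", 0.1),
            method=dc.get("method", "pearson"),
        )
        _write_tsv(network.dcls, out / "dcls.tsv", index=False)
        _write_tsv(network.dcgs, out / "dcgs.tsv", index=False)
        network.to_json(out / "network.json")
        network.to_sif(out / "network.sif")
        dcx_hashes = {
            name: sha256_file(out / name)
            for name in ("dcls.tsv", "dcgs.tsv", "network.json", "network.sif")
        }
        if dcg_stab_cfg.get("enabled", False):
            recovery = dcg_stability(
                cond,
                sample_fraction=dcg_stab_cfg.get("sample_fraction", 0.7),
                n_reps=dcg_stab_cfg.get("n_reps", 100),
                seed=config.seed,
                rth=dc.get("rth", 0.5),
                q_coexp=dc.get("q_coexp", 0.1),
                q_dcl=dc.get("q_dcl", 0.1),
                q_dcg=dc.get("q_dcg", 0.1),
            )
            _write_tsv(
                recovery[recovery > 0].to_frame("recovery"),
                out / "dcg_stability.tsv",
                index_label="gene_id",
            )
            dcx_hashes["dcg_stability.tsv"] = sha256_file(out / "dcg_stability.tsv")
        manifest["hashes"]["diffcoexp"] = dcx_hashes
        manifest["stages"].append("diffcoexp")

        stage = "enrichment"
        gmt_path = config.enrichment.get("gmt")
        if gmt_path:
            collection = read_gmt(gmt_path)
            universe = set(expr_all.gene_ids)
            queries = {"dcgs": set(network.dcg_genes)}
            for group, result in group_results.items():
                assignment = result.assignment
                for label in sorted(assignment.module_sizes):
                    queries[f"{group}_module{label}"] = set(assignment.members(label))
            tables = []
            for name, query in queries.items():
                if not query:
                    continue
                table = ora_hypergeom(
                    query & universe or query,
                    universe,
                    collection,
                    q_threshold=config.enrichment.get("q_threshold", 0.05),
                )
                table.insert(0, "query", name)
                tables.append(table)
            if tables:
                ora_table = pd.concat(tables, ignore_index=True)
                _write_tsv(ora_table, out / "ora.tsv", index=False)
                manifest["hashes"]["enrichment"] = {
                    "ora.tsv": sha256_file(out / "ora.tsv")
                }
                manifest["stages"].append("enrichment")

        stage = "prediction"
        pred = dict(config.prediction)
        if pred.get("enabled", True):
            feature_sets: list[FeatureSetSpec] = []
            if pred.get("use_derived", True):
                hubs_all = sorted(
                    {
                        g
                        for grp in (c1, c2)
                        if grp in group_results
                        for hub_list in group_results[grp].assignment.hubs.values()
                        for g in hub_list
                    }
                )
                candidates = {
                    "coexp_hubs": hubs_all,
                    "dcgs": network.dcg_genes,
                    "dcgs_plus_hubs": sorted(set(hubs_all) | set(network.dcg_genes)),
                    "diffcoexp_network": network.node_genes,
                }
                for name, genes in candidates.items():
                    genes = [g for g in genes if g in expr_all.gene_ids]
                    if genes:
                        feature_sets.append(FeatureSetSpec(name, genes))
            for name, path in pred.get("feature_lists", {}).items():
                feature_sets.append(FeatureSetSpec(name, read_gene_list(path)))
            if feature_sets:
                labels = expr_all.conditions
                summary = evaluate_feature_sets(
                    expr_all,
                    labels,
                    feature_sets,
                    rounds=pred.get("rounds", 10),
                    folds=pred.get("folds", 5),
                    seed=config.seed,
                    n_estimators=pred.get("n_estimators", 100),
                    max_depth=pred.get("max_depth", 4),
                    learning_rate=pred.get("learning_rate", 0.1),
                )
                _write_tsv(summary, out / "prediction.tsv", index=False)
                manifest["hashes"]["prediction"] = {
                    "prediction.tsv": sha256_file(out / "prediction.tsv")
                }
                manifest["stages"].append("prediction")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
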