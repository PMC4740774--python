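"""End-to-end orchestration: simulate/ingest -> filter -> trees -> signal.

A run is described by a YAML-serializable :class:`PipelineConfig` holding
either input paths (VCF + metadata TSV) or a simulation block, plus the
analysis knobs.  Every stage writes its artifact to the output directory and
the run manifest records the resolved configuration (defaults included), a
config hash, package versions, and per-stage counts, so a run is
self-describing and exactly reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .matrix import (
    drop_uninformative,
    filter_by_completeness,
    filter_samples_by_completeness,
    harmonize,
    read_vcf,
    write_nexus,
    write_phylip,
    write_vcf,
)
from .metadata import read_metadata
from .report import render_report
from .signal import results_table, run_signal_suite
from .simulate import SimulationConfig, simulate
from .trees import (
    build_stratified_trees,
    hamming_distances,
    neighbor_joining,
    write_newick,
)

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Full description of one analysis run (YAML-loadable)."""

    vcf: Optional[str] = None
    metadata: Optional[str] = None
    multilabel: list[str] = Field(default_factory=list)
    simulation: Optional[SimulationConfig] = None
    min_call_fraction: float = Field(default=0.9, gt=0.0, le=1.0)
    min_sample_call_fraction: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    stratify_by: Optional[str] = None
    variables: list[str]
    n_reps: int = Field(default=9999, ge=1)
    seed: int
    outdir: str
    min_stratum_size: int = Field(default=4, ge=3)
    normalize_distances: bool = True

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        has_paths = self.vcf is not None and self.metadata is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError(
                "config must contain exactly one of (vcf+metadata) or simulation"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON).

    Rerunning with an identical config (seed included) reproduces
    byte-identical numeric outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "config_hash": _config_hash(config),
        "snpsignal_version": __version__,
        "counts": {},
    }

    if config.simulation is not None:
        matrix, metadata = simulate(config.simulation)
        write_vcf(matrix, out / "simulated.vcf")
        metadata.write_tsv(out / "simulated_metadata.tsv")
    else:
        matrix = read_vcf(config.vcf)
        metadata = read_metadata(config.metadata, multilabel=config.multilabel)
        matrix, metadata = harmonize(matrix, metadata)
    n_samples_in = matrix.n_samples
    manifest["counts"]["samples"] = n_samples_in
    manifest["counts"]["variants_in"] = matrix.n_variants

    filtered, report = filter_by_completeness(matrix, config.min_call_fraction)
    report.to_json(out / "filter_report.json")
    manifest["counts"]["variants_kept"] = report.n_variants_kept
    manifest["counts"]["variants_filtered"] = (
        report.n_variants_in - report.n_variants_kept
    )
    if config.min_sample_call_fraction is not None:
        filtered = filter_samples_by_completeness(
            filtered, config.min_sample_call_fraction
        )
        metadata = metadata.subset(filtered.sample_ids)
    manifest["counts"]["samples_analyzed"] = filtered.n_samples

    informative = drop_uninformative(filtered)
    manifest["counts"]["variants_informative"] = informative.n_variants
    write_vcf(informative, out / "filtered.vcf")
    write_phylip(informative, out / "matrix.phy")
    write_nexus(informative, out / "matrix.nex")

    dm = hamming_distances(informative, config.normalize_distances)
    dm.to_tsv(out / "distances.tsv")
    trees = {"global": neighbor_joining(dm)}
    if config.stratify_by is not None:
        trees.update(
            build_stratified_trees(
                informative,
                metadata,
                config.stratify_by,
                min_call_fraction=config.min_call_fraction,
                min_stratum_size=config.min_stratum_size,
                normalize=config.normalize_distances,
            )
        )
    for tree_id, tree in trees.items():
        write_newick(tree, out / f"tree_{tree_id.replace('/', '_')}.nwk")
    manifest["counts"]["trees"] = len(trees)

    results = run_signal_suite(
        trees, metadata, config.variables, n_reps=config.n_reps, seed=config.seed
    )
    table = results_table(results, bh_adjust=True)
    table.to_csv(out / "signal_results.tsv", sep="\t", index=False,
                 float_format="%.10g")
    manifest["counts"]["signal_tests"] = len(results)
    manifest["significant"] = (
        table.loc[table["p_value"] <= 0.05, ["variable", "tree_id"]]
        .to_dict("records")
        if len(table)
        else []
    )

    render_report(results, trees, metadata, out / "figures")

    summary = {
        "results": table.to_dict("records"),
        "config_hash": manifest["config_hash"],
    }
    with open(out / "signal_results.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
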