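"""End-to-end pipeline driver: io → structure → trends → maturity → sites.

A single master seed determines every stochastic stage; the output
directory receives one tsv/json file per stage plus ``manifest.json``
recording the configuration hash, package version, derived seeds and a
sha256 digest of every output file (no timestamps, so identical runs
produce byte-identical manifests).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import core_io, maturity, site_dynamics, structure, synthetic, trends

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("normalize", "structure", "trends", "maturity", "sites")


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of inputs / simulate."""

    out_dir: str = "rhizochron_out"
    seed: int = 0
    inputs: dict | None = None      # {"otu_table":…, "metadata":…, "taxonomy":…}
    simulate: dict | None = None    # kwargs for synthetic.simulate_dataset
    stages: tuple = DEFAULT_STAGES
    min_prevalence: float = 0.05
    pseudocount: float = 1.0
    n_perm: int = 199
    n_trees: int = 100
    cv_trees: int = 50
    n_sparse: int | None = None
    alpha: float = 0.05
    split_day: float = 84.0
    maturity_compartment: str = "endosphere"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "provide exactly one of input paths or a simulation spec")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    # out_dir is a deployment detail, not part of the run's identity:
    # the same seed and settings must yield byte-identical manifests
    # wherever the results land
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(config).items() if k != "out_dir"}
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index=True):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)
        return path

    stage = "load"
    try:
        if config.simulate is not None:
            sim = dict(config.simulate)
            design_kwargs = sim.pop("design", {})
            design = synthetic.SimulationDesign(
                **{**design_kwargs, "seed": stage_seed(config.seed,
                                                       "simulate")})
            dataset = synthetic.simulate_dataset(design, **sim)
            synthetic.write_fixture(dataset, out / "simulated")
            written += sorted((out / "simulated").iterdir())
            table, metadata = dataset.table, dataset.metadata
            taxonomy = dataset.taxonomy
        else:
            table = core_io.read_otu_table(config.inputs["otu_table"])
            metadata = core_io.read_metadata(config.inputs["metadata"])
            taxonomy = (core_io.read_taxonomy(config.inputs["taxonomy"])
                        if config.inputs.get("taxonomy") else None)

        norm = None
        if "normalize" in config.stages or set(config.stages) & {
                "structure", "trends", "maturity", "sites"}:
            stage = "normalize"
            filtered, n_removed = core_io.filter_prevalence(
                table, config.min_prevalence)
            norm = core_io.normalize_per_mille(filtered)
            save_df(norm.data, "per_mille.tsv")
            logger.info("prevalence filter removed %d OTUs", n_removed)

        dist = None
        if "structure" in config.stages:
            stage = "structure"
            dist = structure.bray_curtis(norm, transform="log2_pseudocount",
                                         pseudocount=config.pseudocount)
            ord_res = structure.pcoa(dist)
            save_df(ord_res.coordinates, "pcoa_coordinates.tsv")
            save_df(pd.DataFrame({"eigenvalue": ord_res.eigenvalues}),
                    "pcoa_eigenvalues.tsv")
            perm = structure.permanova(
                dist, metadata, ["compartment", "site", "age_days"],
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "permanova"))
            save_df(perm, "permanova.tsv")

        if "trends" in config.stages and taxonomy is not None:
            stage = "trends"
            phyla = core_io.aggregate_taxonomy(
                norm, taxonomy, rank="phylum", split_proteobacteria=True)
            spatial = trends.spatial_phylum_trends(phyla, metadata,
                                                   alpha=config.alpha)
            save_df(spatial, "phylum_spatial_trends.tsv")
            calls = trends.classify_colonizers(norm, metadata,
                                               alpha=config.alpha)
            save_df(calls, "colonizer_calls.tsv", index=False)
            markers = maturity.aggregate_marker_abundance(norm, calls)
            save_df(markers, "marker_class_abundance.tsv")

        if "maturity" in config.stages:
            stage = "maturity"
            model, split, ranking, cv_curve, preds = \
                maturity.fit_maturity_pipeline(
                    norm, metadata, response="age_days",
                    compartment=config.maturity_compartment,
                    n_sparse=config.n_sparse, n_trees=config.n_trees,
                    cv_trees=config.cv_trees,
                    seed=stage_seed(config.seed, "maturity"))
            save_df(ranking, "importance_ranking.tsv")
            save_df(cv_curve, "cv_curve.tsv", index=False)
            save_df(preds, "maturity_predictions.tsv", index=False)
            maturity.save_model(model, out / "maturity_model.json")
            written.append(out / "maturity_model.json")

        if "sites" in config.stages and metadata["site"].nunique() == 2:
            stage = "sites"
            if dist is None:
                dist = structure.bray_curtis(
                    norm, transform="log2_pseudocount",
                    pseudocount=config.pseudocount)
            pairs = site_dynamics.between_site_distances(dist, metadata)
            save_df(site_dynamics.convergence_slopes(pairs),
                    "convergence_slopes.tsv")
            calls = site_dynamics.site_specific_otus(
                table.select_otus(norm.otu_ids), metadata,
                alpha=config.alpha)
            save_df(calls, "site_skew_calls.tsv", index=False)
            frac, trend = site_dynamics.site_specific_fraction(
                norm, calls, metadata)
            save_df(trend, "site_specific_fraction_trend.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "rhizochron",
        "version": __version__,
        "config": _config_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seeds": {s: stage_seed(config.seed, s)
                  for s in ("simulate", "permanova", "maturity")},
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
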