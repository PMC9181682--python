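"""End-to-end orchestration: preprocess -> differential -> network ->
module-trait/hubs -> (two-region) overlap -> enrichment.

A :class:`RunConfig` names the input files (per-region protein and
metabolite TSVs, a trait table, optionally a GMT) and every stage parameter.
``run_pipeline`` writes each intermediate table under the output directory
and finishes with a JSON manifest listing every output with its SHA-256
content hash: identical config + seed reproduce identical hashes.

Stage-level randomness (the permutation null) is seeded with the global
seed plus a stage-name salt so stages can be rerun independently yet
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, io, network, overlap, preprocess, traits as traits_mod
from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config", "stage_seed"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class RunConfig:
    """Paths and parameters for one full run.

    ``regions`` maps a region name to ``{"proteins": path, "metabolites":
    path}``; one region runs the single-network pipeline, two regions add
    the cross-region module overlap analysis.
    """

    regions: dict
    traits: str
    out_dir: str
    gmt: str | None = None
    # preprocessing
    log_offset: float = 0.0
    quantile_proteins: bool = False
    quantile_metabolites: bool = True
    max_missing: float = 0.3
    outlier_k_sd: float = 3.0
    remove_outliers: bool = False
    # differential
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    # network
    beta: float = 1.0
    signed: bool = False
    min_module_size: int = 10
    cut_height_quantile: float = 0.85
    # enrichment
    n_perm: int = 1000
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Global seed + stage-name salt, kept below 2^31."""
    return (seed + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(config: RunConfig) -> None:
    paths = [config.traits]
    for region, layers in config.regions.items():
        paths += [layers["proteins"], layers["metabolites"]]
    if config.gmt:
        paths.append(config.gmt)
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineError("preflight", "missing-input", f"paths not found: {missing}")


def _write(df: pd.DataFrame, path: Path, outputs: dict, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=io.FLOAT_FORMAT, index_label=index_label)
    outputs[path.name] = _sha256(path)


def _region_pipeline(region: str, layers: dict, traits: pd.DataFrame,
                     config: RunConfig, out: Path, outputs: dict) -> dict:
    prot = io.read_matrix_tsv(layers["proteins"], layer="protein")
    met = io.read_matrix_tsv(layers["metabolites"], layer="metabolite")
    shared = [s for s in prot.samples if s in set(met.samples) and s in traits.index]
    if len(shared) < 4:
        raise PipelineError(region, "too-few-samples",
                            f"only {len(shared)} samples shared across inputs")
    prot, met = prot.subset_samples(shared), met.subset_samples(shared)
    groups = pd.Series(
        np.where(traits.loc[shared, "strain"] > 0, "case", "control"), index=shared
    )

    def normalized(p: OmicsMatrix, m: OmicsMatrix) -> OmicsMatrix:
        np_ = preprocess.normalize_layer(
            p, config.log_offset, config.quantile_proteins, config.max_missing
        )
        nm = preprocess.normalize_layer(
            m, config.log_offset, config.quantile_metabolites, config.max_missing
        )
        return preprocess.concatenate_layers([np_, nm])

    combined = normalized(prot, met)
    flags = preprocess.detect_outliers(combined, k_sd=config.outlier_k_sd)
    _write(flags.to_frame(), out / f"{region}_outlier_flags.tsv", outputs,
           index_label="sample")
    if config.remove_outliers and flags.any():
        keep = flags.index[~flags].tolist()
        logger.warning("%s: removing %d outlier samples and re-running",
                       region, int(flags.sum()))
        prot, met = prot.subset_samples(keep), met.subset_samples(keep)
        groups = groups.loc[keep]
        combined = normalized(prot, met)

    # differential abundance on log2 (pre-scaling) data, per layer
    diff_frames = []
    for m, method in ((prot, "moderated"), (met, "welch")):
        logm = preprocess.log_transform(
            preprocess.drop_high_missing(m, config.max_missing), config.log_offset
        )
        d = differential.differential_table(
            logm, groups, method=method,
            fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold,
        )
        diff_frames.append(d)
        layer = m.layers.iloc[0]
        _write(d, out / f"{region}_diff_{layer}.tsv", outputs, index_label="feature")
    diff_all = pd.concat(diff_frames)

    # network and modules
    net = network.correlation_matrix(combined)
    network.adjacency(net, beta=config.beta, signed=config.signed)
    partition = network.cluster_modules(
        net, combined, min_size=config.min_module_size,
        cut_height_quantile=config.cut_height_quantile,
    )
    part_df = pd.DataFrame(
        {"layer": combined.layers, "module": partition.assignments}
    )
    _write(part_df, out / f"{region}_modules.tsv", outputs, index_label="feature")

    egenes = network.eigengene_set(combined, partition)
    _write(egenes, out / f"{region}_eigengenes.tsv", outputs, index_label="module")

    mt = traits_mod.module_trait_matrix(egenes, traits.loc[combined.samples])
    mt.to_csv(out / f"{region}_module_trait.tsv", sep="\t",
              float_format=io.FLOAT_FORMAT, index=False)
    outputs[f"{region}_module_trait.tsv"] = _sha256(out / f"{region}_module_trait.tsv")

    hubs = traits_mod.find_hub(net, partition, egenes, combined)
    _write(hubs, out / f"{region}_hubs.tsv", outputs, index_label="module")

    result = {
        "partition": partition,
        "eigengenes": egenes,
        "module_trait": mt,
        "diff": diff_all,
        "combined": combined,
        "groups": groups,
        "n_features": combined.n_features,
        "n_samples": combined.n_samples,
    }

    if config.gmt:
        db = io.read_gmt(config.gmt)
        universe = set(combined.features)
        strain_rows = mt[mt["trait"] == "strain"].dropna(subset=["r"])
        if not strain_rows.empty:
            top = strain_rows.loc[strain_rows["r"].abs().idxmax(), "module"]
            query = partition.members(top)
            ora = enrichment.ora_hypergeometric(query, db, universe)
            _write(ora, out / f"{region}_ora_{top}.tsv", outputs, index_label="set")
        padog = enrichment.padog_like_score(
            combined, groups, db, n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"padog:{region}"),
        )
        padog["mean_log2FC"] = enrichment.pathway_direction(diff_all, db).reindex(
            padog.index
        )
        _write(padog, out / f"{region}_padog.tsv", outputs, index_label="set")
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    _preflight(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traits = io.read_traits_tsv(config.traits)
    outputs: dict = {}
    regions = {}
    for region, layers in config.regions.items():
        try:
            regions[region] = _region_pipeline(region, layers, traits, config, out, outputs)
        except PipelineError:
            raise
        except Exception as exc:  # surface the failing stage
            raise PipelineError(region, "stage-failure", str(exc)) from exc

    if len(regions) == 2:
        (ra, resa), (rb, resb) = regions.items()
        tab = overlap.cross_tabulate(resa["partition"], resb["partition"])
        _write(tab.counts, out / f"overlap_{ra}_{rb}_counts.tsv", outputs)
        _write(tab.neg_log10_p, out / f"overlap_{ra}_{rb}_neglog10p.tsv", outputs)
        long = (
            tab.counts.stack()
            .rename("count")
            .to_frame()
            .join(tab.p.stack().rename("p"))
            .reset_index()
        )
        long.to_csv(out / f"overlap_{ra}_{rb}_long.tsv", sep="\t",
                    float_format=io.FLOAT_FORMAT, index=False)
        outputs[f"overlap_{ra}_{rb}_long.tsv"] = _sha256(
            out / f"overlap_{ra}_{rb}_long.tsv"
        )

    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
        "stages": {
            r: {"n_features": res["n_features"], "n_samples": res["n_samples"],
                "n_modules": len(res["partition"].modules())}
            for r, res in regions.items()
        },
        "outputs": dict(sorted(outputs.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
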