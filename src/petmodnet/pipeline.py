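"""End-to-end orchestration: imaging -> radiomics -> DE -> modules -> pathways.

A YAML config names the inputs (cohort manifest, raw arrays, annotation,
GMT + hierarchy) and the stage parameters; ``run_pipeline`` executes the
four workflow stages, writing each stage's outputs as TSV/JSON into the
output directory. Stages are resumable: each stage records a content hash
of its inputs and config section, and is skipped on rerun when the hash and
outputs are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import RawArraySet, paired_log_ratios, run_paired_de
from .imaging import (
    Box,
    read_volume,
    segment_fixed_fraction,
    segment_fuzzy_adaptive,
)
from .modnet import ModuleNetwork, ScorePrior
from .pathways import load_pathway_db, summarize_modules
from .radiomics import DiscretizationConfig, extract_cohort_features, normalize_cohort_features

log = logging.getLogger("petmodnet")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    manifest: str
    arrays_intensities: str
    arrays_samples: str
    annotation: str
    gmt: str
    hierarchy: str
    outdir: str
    segmentation_method: str = "fuzzy"  # fuzzy | fixed41
    n_bins: int = 64
    de_alpha: float = 0.01
    de_fc: float = 2.0
    modnet_K: int = 50
    modnet_max_iter: int = 30
    modnet_max_depth: int = 2
    modnet_min_leaf: int = 4
    modnet_seed: int = 0
    prior: dict = field(default_factory=lambda: {"mu0": 0.0, "lam0": 1.0, "a0": 1.0, "b0": 1.0})
    enrichment_alpha: float = 0.05

    def section_hash(self, name: str, *input_paths: str) -> str:
        h = hashlib.sha256()
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        h.update(json.dumps({"section": name, "config": payload}, sort_keys=True).encode())
        for p in input_paths:
            with open(p, "rb") as fh:
                h.update(fh.read())
        return h.hexdigest()


def validate_config(path: str) -> PipelineConfig:
    """Load, default and validate a YAML config; aggregate all violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    paths = raw.get("paths", {})
    params = raw.get("params", {})
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    errors: list[str] = []
    required = ["manifest", "arrays_intensities", "arrays_samples", "annotation", "gmt", "hierarchy", "outdir"]
    resolved: dict[str, str] = {}
    for key in required:
        if key not in paths:
            errors.append(f"paths.{key} is missing")
            continue
        resolved[key] = resolve(str(paths[key]))
        if key != "outdir" and not os.path.exists(resolved[key]):
            errors.append(f"paths.{key}: file not found: {resolved[key]}")

    cfg_kwargs = dict(resolved)
    for key, value in params.items():
        cfg_kwargs[key] = value
    try:
        cfg = PipelineConfig(**cfg_kwargs)  # type: ignore[arg-type]
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc

    if cfg.segmentation_method not in ("fuzzy", "fixed41"):
        errors.append("params.segmentation_method must be 'fuzzy' or 'fixed41'")
    if cfg.n_bins < 2:
        errors.append("params.n_bins must be >= 2")
    if not (0 < cfg.de_alpha <= 1):
        errors.append("params.de_alpha must be in (0, 1]")
    if cfg.de_fc < 1:
        errors.append("params.de_fc must be >= 1")
    if cfg.modnet_K < 1:
        errors.append("params.modnet_K must be >= 1")
    if cfg.modnet_max_depth not in (1, 2):
        errors.append("params.modnet_max_depth must be 1 or 2")
    if errors:
        raise ValueError("config validation failed:\n  " + "\n  ".join(errors))
    return cfg


def _stage(cfg: PipelineConfig, name: str, outputs: list[str], inputs: list[str]):
    """Decorator-free cache gate: returns True when the stage may be skipped."""
    hash_path = os.path.join(cfg.outdir, f".{name}.hash")
    digest = cfg.section_hash(name, *inputs)
    if os.path.exists(hash_path) and all(os.path.exists(o) for o in outputs):
        with open(hash_path) as fh:
            if fh.read().strip() == digest:
                log.info("stage %s: cached, skipping", name)
                return True, digest, hash_path
    return False, digest, hash_path


def _finish(digest: str, hash_path: str) -> None:
    with open(hash_path, "w") as fh:
        fh.write(digest)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a report dict of output paths and key numbers."""
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict[str, object] = {"version": __version__, "outdir": cfg.outdir}

    # ---- stage 1: segmentation + radiomics ------------------------------
    features_path = os.path.join(cfg.outdir, "features.tsv")
    features_norm_path = os.path.join(cfg.outdir, "features_normalized.tsv")
    skip, digest, hpath = _stage(cfg, "imaging", [features_path, features_norm_path], [cfg.manifest])
    if not skip:
        manifest = pd.read_csv(cfg.manifest, sep="\t")
        base = os.path.dirname(os.path.abspath(cfg.manifest))
        volumes, masks = [], []
        for _, row in manifest.iterrows():
            pid = str(row["patient_id"])
            vol = read_volume(os.path.join(base, row["volume_path"]), calibrated=True, patient_id=pid)
            box: Box = (
                (int(row["box_i0"]), int(row["box_i1"])),
                (int(row["box_j0"]), int(row["box_j1"])),
                (int(row["box_k0"]), int(row["box_k1"])),
            )
            if cfg.segmentation_method == "fixed41":
                mask = segment_fixed_fraction(vol, box, 0.41)
            else:
                mask = segment_fuzzy_adaptive(vol, box, n_classes=2, seed=cfg.modnet_seed)
            mask.patient_id = pid
            volumes.append(vol)
            masks.append(mask)
        table = extract_cohort_features(volumes, masks, DiscretizationConfig(cfg.n_bins))
        table.rename_axis("patient_id").to_csv(features_path, sep="\t")
        normalize_cohort_features(table).rename_axis("patient_id").to_csv(features_norm_path, sep="\t")
        _finish(digest, hpath)
        log.info("stage imaging: %d patients, %d features", *table.shape)
    report["features"] = features_path
    report["features_normalized"] = features_norm_path

    # ---- stage 2: differential expression -------------------------------
    de_path = os.path.join(cfg.outdir, "de_results.tsv")
    ratios_path = os.path.join(cfg.outdir, "paired_log_ratios.tsv")
    skip, digest, hpath = _stage(cfg, "diffexpr", [de_path, ratios_path],
                                 [cfg.arrays_intensities, cfg.arrays_samples])
    if not skip:
        raw = RawArraySet.from_tsv(cfg.arrays_intensities, cfg.arrays_samples)
        de = run_paired_de(raw, alpha=cfg.de_alpha, fc=cfg.de_fc)
        de.to_tsv(de_path)
        paired_log_ratios(raw).rename_axis("probe_id").to_csv(ratios_path, sep="\t")
        _finish(digest, hpath)
        log.info("stage diffexpr: %s", de.summary())
    report["de_results"] = de_path

    # ---- stage 3: module network ----------------------------------------
    model_path = os.path.join(cfg.outdir, "module_network.json")
    table_path = os.path.join(cfg.outdir, "module_table.tsv")
    assign_path = os.path.join(cfg.outdir, "module_assignment.tsv")
    skip, digest, hpath = _stage(cfg, "modnet", [model_path, table_path, assign_path],
                                 [de_path, ratios_path, features_norm_path])
    if not skip:
        de_table = pd.read_csv(de_path, sep="\t", index_col="probe_id")
        retained = list(de_table.index[de_table["retained"]])
        if not retained:
            raise RuntimeError("stage modnet: no probes retained by the DE filter")
        ratios = pd.read_csv(ratios_path, sep="\t", index_col="probe_id").loc[retained]
        reg = pd.read_csv(features_norm_path, sep="\t", index_col="patient_id")
        reg.index = reg.index.astype(str)
        ratios.columns = ratios.columns.astype(str)
        model = ModuleNetwork(
            ratios, reg.loc[list(ratios.columns)],
            K=cfg.modnet_K, max_iter=cfg.modnet_max_iter, max_depth=cfg.modnet_max_depth,
            min_leaf=cfg.modnet_min_leaf, prior=ScorePrior(**cfg.prior),
        )
        res = model.fit(seed=cfg.modnet_seed)
        res.to_json(model_path)
        res.module_table().to_csv(table_path, sep="\t")
        res.assignment.rename_axis("probe_id").to_csv(assign_path, sep="\t")
        _finish(digest, hpath)
        log.info("stage modnet: %d modules, score %.2f", res.n_modules, res.score)
    report["module_network"] = model_path
    report["module_table"] = table_path

    # ---- stage 4: functional annotation ---------------------------------
    summary_path = os.path.join(cfg.outdir, "module_summary.tsv")
    skip, digest, hpath = _stage(cfg, "annotate", [summary_path],
                                 [assign_path, cfg.annotation, cfg.gmt, cfg.hierarchy])
    if not skip:
        assignment = pd.read_csv(assign_path, sep="\t", index_col="probe_id")["module"]
        annotation = pd.read_csv(cfg.annotation, sep="\t")
        db = load_pathway_db(cfg.gmt, cfg.hierarchy)
        module_probes = {
            int(m): [str(p) for p in assignment.index[assignment == m]]
            for m in sorted(assignment.unique())
        }
        summary = summarize_modules(module_probes, annotation, db, alpha=cfg.enrichment_alpha)
        summary.to_csv(summary_path, sep="\t")
        _finish(digest, hpath)
        log.info("stage annotate: %d modules summarized", len(summary))
    report["module_summary"] = summary_path

    run_log = os.path.join(cfg.outdir, "run_report.json")
    with open(run_log, "w") as fh:
        json.dump({**report, "seed": cfg.modnet_seed}, fh, indent=2)
    report["run_report"] = run_log
    return report
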