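"""End-to-end orchestration: cohort -> blocks -> scores -> markers -> models
-> plasma transfer -> survival, with one seed fanned out to every stage and a
manifest of outputs.

Input is either a synthetic cohort specification or a directory produced by
:meth:`methylhap.simulate.SyntheticCohort.write` (sites.tsv, haplotypes/,
metadata.tsv, optionally regions.bed). Every intermediate artefact is written
in the package's text formats, so each stage can be re-run in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .blocks import partition_blocks
from .classify import (
    ModelConfig,
    auc,
    cross_validate,
    fit_model,
    predict_mvi,
    transfer_predict,
)
from .errors import PipelineError
from .load import LoadParams, score_cohort
from .markers import FilterConfig, scaled_min_detected, select_markers, write_markers
from .simulate import CohortSpec, simulate_cohort
from .survival import survival_by_group

log = logging.getLogger("methylhap.pipeline")


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` drives every stochastic stage."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None        # ingest mode when set
    seed: int = 0
    regions_from: str = "discover"      # "discover" | "given" (generator/file)
    r2_threshold: float = 0.5
    min_pairs: int = 10
    max_gap: int = 500
    load: LoadParams = field(default_factory=LoadParams)
    min_detection_fraction: float = 2.0 / 3.0
    min_sd: float = 0.02
    hcc_test: str = "signed_rank"
    hcc_fdr: float = 0.05
    mvi_fdr: float = 0.05
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortSpec(**d["cohort"])
        if "load" in d and isinstance(d["load"], dict):
            d["load"] = LoadParams(**d["load"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; returns (and writes) the manifest dictionary."""
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    metrics: dict[str, object] = {}
    try:
        return _run(config, outdir, outputs, metrics)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir, outputs, metrics) -> dict:
    # --- stage 0: cohort -----------------------------------------------------
    stage = "cohort"
    try:
        if config.input_dir is None:
            cohort = simulate_cohort(config.cohort, seed=_stage_seed(config.seed, 0))
            paths = cohort.write(outdir)
            outputs.update(
                {k: v for k, v in paths.items() if k != "haplotypes"}
            )
            index, haplotypes, metadata = cohort.index, cohort.haplotypes, cohort.metadata
            given_regions = cohort.regions
        else:
            index = mio.read_sites(os.path.join(config.input_dir, "sites.tsv"))
            haplotypes = mio.read_cohort_haplotypes(
                os.path.join(config.input_dir, "haplotypes"), index
            )
            metadata = mio.read_metadata(os.path.join(config.input_dir, "metadata.tsv"))
            # keep the metadata's sample order so results do not depend on
            # directory listing order
            haplotypes = {
                s: haplotypes[s] for s in list(metadata.index) + sorted(
                    set(haplotypes) - set(metadata.index)
                ) if s in haplotypes
            }
            bed = os.path.join(config.input_dir, "regions.bed")
            given_regions = mio.read_regions(bed, index) if os.path.exists(bed) else None
        log.info("cohort: %d samples", len(haplotypes))

        # --- stage 1: blocks -------------------------------------------------
        stage = "blocks"
        if config.regions_from == "discover":
            regions = partition_blocks(
                haplotypes, index, config.r2_threshold, config.min_pairs, config.max_gap
            )
        elif given_regions is not None:
            regions = given_regions
        else:
            raise PipelineError("regions_from='given' but no region set available")
        if not regions:
            raise PipelineError("no blocks discovered")
        bed_out = os.path.join(outdir, "regions_used.bed")
        mio.write_regions(regions, bed_out)
        outputs["regions_used"] = bed_out
        metrics["n_regions"] = len(regions)
        log.info("blocks: %d regions", len(regions))

        # --- stage 2: scoring ------------------------------------------------
        stage = "score"
        matrices = {}
        for kind in ("MHL", "UMHL"):
            m = score_cohort(haplotypes, regions, config.load, kind)
            path = os.path.join(outdir, f"{kind.lower()}.tsv")
            mio.write_matrix(m, path)
            outputs[f"matrix_{kind.lower()}"] = path
            matrices[kind] = m

        # --- stage 3: markers ------------------------------------------------
        stage = "markers"
        floor = scaled_min_detected(len(regions))
        hcc_cfg = FilterConfig(
            min_detected_per_sample=floor,
            min_detection_fraction=config.min_detection_fraction,
            min_sd=config.min_sd,
            fdr_threshold=config.hcc_fdr,
            test=config.hcc_test,
        )
        hcc_markers = select_markers(
            matrices["MHL"], metadata, hcc_cfg, contrast="tumor_vs_normal"
        )
        mvi_cfg = dataclasses.replace(
            hcc_cfg, test="rank_sum", fdr_threshold=config.mvi_fdr
        )
        mvi_markers = select_markers(matrices, metadata, mvi_cfg, contrast="mvi")
        for name, mk in [("markers_hcc", hcc_markers), ("markers_mvi", mvi_markers)]:
            path = os.path.join(outdir, f"{name}.tsv")
            write_markers(mk, path)
            outputs[name] = path
        metrics["n_markers_hcc"] = int(len(hcc_markers))
        metrics["n_markers_mvi"] = int(len(mvi_markers))
        log.info("markers: %d HCC, %d MVI", len(hcc_markers), len(mvi_markers))
        if len(hcc_markers) == 0:
            raise PipelineError("no HCC markers retained")

        # --- stage 4: tissue classification ----------------------------------
        stage = "classify_tissue"
        tissue = metadata[
            (metadata["specimen"] == "tissue")
            & metadata["tumor_status"].isin(["tumor", "normal"])
        ]
        hcc_ids = hcc_markers["mhb_id"].unique().tolist()
        feats = matrices["MHL"].data.loc[tissue.index, hcc_ids]
        model_cfg = dataclasses.replace(config.model, seed=_stage_seed(config.seed, 4))
        cv_tissue = cross_validate(
            feats, tissue["tumor_status"], model_cfg, positive_label="tumor"
        )
        _write_cv(cv_tissue, os.path.join(outdir, "cv_tissue.json"))
        outputs["cv_tissue"] = os.path.join(outdir, "cv_tissue.json")
        metrics["tissue_mean_auc"] = cv_tissue.mean_auc
        metrics["tissue_auc_ci"] = [cv_tissue.ci_lower, cv_tissue.ci_upper]

        # --- stage 5: plasma transfer ----------------------------------------
        stage = "plasma_transfer"
        plasma = metadata[metadata["specimen"] == "plasma"]
        if len(plasma):
            model = fit_model(
                feats, tissue["tumor_status"], model_cfg, positive_label="tumor"
            )
            plasma_feats = matrices["MHL"].data.loc[plasma.index, hcc_ids]
            scores = transfer_predict(model, plasma_feats)
            pred = pd.DataFrame(
                {"score": scores, "tumor_status": plasma["tumor_status"]}
            )
            path = os.path.join(outdir, "plasma_predictions.tsv")
            pred.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
            outputs["plasma_predictions"] = path
            labels = plasma["tumor_status"] == "tumor"
            if labels.any() and not labels.all():
                metrics["plasma_auc"] = auc(scores, labels)

        # --- stage 6: MVI classification --------------------------------------
        stage = "classify_mvi"
        tumors = metadata[
            (metadata["specimen"] == "tissue") & (metadata["tumor_status"] == "tumor")
        ]
        if len(mvi_markers):
            cols = []
            for kind in ("MHL", "UMHL"):
                ids = mvi_markers.loc[
                    mvi_markers["score_kind"] == kind, "mhb_id"
                ].unique()
                sub = matrices[kind].data.loc[tumors.index, list(ids)]
                sub.columns = [f"{kind}:{c}" for c in sub.columns]
                cols.append(sub)
            mvi_feats = pd.concat(cols, axis=1)
            mvi_model_cfg = dataclasses.replace(
                config.model, seed=_stage_seed(config.seed, 6)
            )
            cv_mvi, calls = predict_mvi(mvi_feats, tumors["mvi_status"], mvi_model_cfg)
            _write_cv(cv_mvi, os.path.join(outdir, "cv_mvi.json"))
            outputs["cv_mvi"] = os.path.join(outdir, "cv_mvi.json")
            path = os.path.join(outdir, "mvi_calls.tsv")
            calls.to_frame().to_csv(path, sep="\t", index_label="sample_id")
            outputs["mvi_calls"] = path
            metrics["mvi_mean_auc"] = cv_mvi.mean_auc
            metrics["mvi_auc_ci"] = [cv_mvi.ci_lower, cv_mvi.ci_upper]

            # --- stage 7: survival validation ---------------------------------
            stage = "survival"
            if calls.nunique() == 2:
                km, lr = survival_by_group(metadata, calls)
                path = os.path.join(outdir, "km_curves.tsv")
                km.to_csv(path, sep="\t", index=False, float_format="%.10g")
                outputs["km_curves"] = path
                surv = {"logrank_statistic": lr.statistic, "logrank_p": lr.p_value}
                with open(os.path.join(outdir, "survival.json"), "w") as fh:
                    json.dump(surv, fh, sort_keys=True, indent=2)
                outputs["survival"] = os.path.join(outdir, "survival.json")
                metrics.update(surv)
            else:
                log.info("survival skipped: predicted MVI has a single group")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- manifest -------------------------------------------------------------
    from . import __version__

    manifest = {
        "package": "methylhap",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {f"stage_{k}": _stage_seed(config.seed, k) for k in range(8)},
        "config": config.to_dict(),
        "outputs": {
            name: {"path": os.path.relpath(p, outdir), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
        "metrics": metrics,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    log.info("pipeline complete: %s", json.dumps(metrics, sort_keys=True))
    return manifest


def _write_cv(cv, path) -> None:
    payload = {
        "repeat_aucs": [float(a) for a in cv.repeat_aucs],
        "mean_auc": cv.mean_auc,
        "ci": [cv.ci_lower, cv.ci_upper],
        "seed": cv.seed,
        "oof_scores": {
            s: [float(v) for v in row]
            for s, row in cv.oof_scores.iterrows()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
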