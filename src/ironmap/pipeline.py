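"""End-to-end orchestration: preprocess -> fuse -> segment -> extract ->
select -> classify, as one reproducible, resumable run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification_eval import DISEASE_PAIRS, run_task
from .feature_selection import FeatureTable, fisher_score, select_top_k
from .hybrid_contrast import build_system, fuse, solve_weights
from .io_preproc import (
    LabelMask,
    RegistrationConfig,
    Volume,
    normalize_t1w_wm,
    read_mask,
    read_volume,
    register_affine,
    resample,
    write_mask,
    write_volume,
)
from .radiomics import ExtractionConfig, extract_all
from .segmentation import DeformationProvider, propagate_labels
from .synthetic_data import LEGEND, generate_template

log = logging.getLogger("ironmap")

__all__ = ["RunConfig", "run_all", "preprocess_subject", "StageError"]

MANIFEST_COLUMNS = (
    "subject_id", "class", "t1w_path", "swi_path", "wm_mask_path", "init_dgm_mask_path"
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject ID."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject


@dataclass
class RunConfig:
    manifest: str = ""
    out_dir: str = "ironmap_run"
    template_path: str | None = None  # None -> built-in synthetic template
    template_mask_path: str | None = None
    wm_target: float = 110.0
    bin_width: float = 25.0
    distances: tuple[int, ...] = (1, 4, 7)
    structure: str = "putamen"
    pairs: tuple[tuple[str, str], ...] = DISEASE_PAIRS
    classifiers: tuple[str, ...] | None = None
    n_repeats: int = 100
    k_features: int = 10
    master_seed: int = 0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "registration" in raw:
            raw["registration"] = RegistrationConfig(**raw["registration"])
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        if "distances" in raw:
            raw["distances"] = tuple(raw["distances"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_template(config: RunConfig) -> tuple[Volume, LabelMask]:
    if config.template_path:
        template = read_volume(config.template_path, modality="template")
        tmask = read_mask(config.template_mask_path, LEGEND, grid=template)
        return template, tmask
    return generate_template()


def preprocess_subject(
    t1w: Volume, swi: Volume, wm_mask: LabelMask, config: RunConfig
) -> tuple[Volume, Volume]:
    """WM-anchored T1w normalization and affine SWI-to-T1w alignment."""
    t1w_n = normalize_t1w_wm(t1w, wm_mask, target=config.wm_target)
    t = register_affine(moving=swi, fixed=t1w_n, config=config.registration)
    swi_r = resample(swi, t, t1w_n, interp="linear")
    return t1w_n, swi_r


def run_all(config: RunConfig) -> dict:
    """Execute every stage for every manifest subject; returns the run manifest.

    Per-stage artifacts are written under ``out_dir`` and stages are skipped
    when their outputs already exist (resume support). Any failure halts with
    the stage name and subject ID.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    manifest = pd.read_csv(config.manifest)
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest lacks columns {sorted(missing_cols)}")

    template, template_mask = _load_template(config)
    extraction = ExtractionConfig(distances=config.distances, bin_width=config.bin_width)

    features_path = out / "features.csv"
    rows = {}
    for _, rec in manifest.iterrows():
        sid = str(rec["subject_id"])
        subject_dir = out / "subjects" / sid
        subject_dir.mkdir(parents=True, exist_ok=True)
        try:
            for key in ("t1w_path", "swi_path", "wm_mask_path", "init_dgm_mask_path"):
                if not Path(str(rec[key])).exists():
                    raise FileNotFoundError(f"{key} = {rec[key]}")
        except FileNotFoundError as exc:
            raise StageError("inputs", sid, exc) from exc

        try:
            t1w = read_volume(rec["t1w_path"], "T1w")
            swi = read_volume(rec["swi_path"], "SWI")
            wm_mask = read_mask(rec["wm_mask_path"], LEGEND, grid=t1w)
            init_mask = read_mask(rec["init_dgm_mask_path"], LEGEND, grid=t1w)
            t1w_n, swi_r = preprocess_subject(t1w, swi, wm_mask, config)
            write_volume(t1w_n, subject_dir / "t1w_norm.nii.gz")
            write_volume(swi_r, subject_dir / "swi_reg.nii.gz")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("preprocess", sid, exc) from exc

        try:
            system = build_system(t1w_n, swi_r, init_mask, template, template_mask)
            weights = solve_weights(system)
            hc = fuse(t1w_n, swi_r, weights)
            weights.to_json(subject_dir / "weights.json")
            write_volume(hc, subject_dir / "hc.nii.gz")
        except Exception as exc:
            raise StageError("fuse", sid, exc) from exc

        try:
            provider = DeformationProvider.from_registration(
                hc, template, config.registration
            )
            dgm = propagate_labels(hc, template, template_mask, provider)
            write_mask(dgm, subject_dir / "dgm_mask.nii.gz")
        except Exception as exc:
            raise StageError("segment", sid, exc) from exc

        try:
            fv = extract_all(swi_r, dgm, config.structure, extraction)
        except Exception as exc:
            raise StageError("extract", sid, exc) from exc
        rows[sid] = fv.to_series()
        log.info("subject %s: %d features extracted", sid, len(fv))

    matrix = pd.DataFrame(rows).T
    matrix.index.name = "subject_id"
    labels = manifest.set_index(manifest["subject_id"].astype(str))["class"]
    table_out = matrix.copy()
    table_out.insert(0, "class", labels)
    table_out.to_csv(features_path)

    table = FeatureTable(matrix, labels.rename("class"))

    # whole-cohort ranking for reporting; per-repeat selection happens inside run_task
    reports = []
    selected_summary = {}
    for pair in config.pairs:
        if not set(pair) <= set(table.labels.unique()):
            log.info("skipping pair %s: classes absent from manifest", pair)
            continue
        sub = table.pair(*pair)
        ranking = fisher_score(sub)
        selected_summary["%s vs %s" % pair] = select_top_k(ranking, config.k_features)
        task_reports = run_task(
            table,
            pair,
            classifiers=config.classifiers,
            n_repeats=config.n_repeats,
            k_features=config.k_features,
            master_seed=config.master_seed,
        )
        reports.extend(r.summary() for r in task_reports.values())
    with open(out / "selected.json", "w") as fh:
        json.dump(selected_summary, fh, indent=2)
    report = pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
    report.to_csv(out / "report.csv", index=False)

    run_manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_subjects": int(len(manifest)),
        "outputs": {
            "features": str(features_path),
            "selected": str(out / "selected.json"),
            "report": str(out / "report.csv"),
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=str)
    return run_manifest
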