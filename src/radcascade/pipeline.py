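"""End-to-end orchestration: cohort -> features -> split -> screen -> mRMR ->
cascade fits (clinical and clinical-radiomic) -> evaluation.

Every random step consumes a sub-seed derived deterministically from the
master seed (named sub-streams: cohort generation, train/validation split,
CV folds), so a run with a fixed seed is byte-reproducible and individual
stages can be reproduced in isolation.  Validation subjects never enter
screening, ranking, normalization, lambda selection, or threshold choice.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeModel, fit_cascade, predict_cascade
from .cohort import CohortSpec, Subject, cohort_to_feature_table, sample_cohort
from .evaluation import evaluate_cascade, format_metrics_table
from .features import ExtractionConfig
from .selection import SelectionResult, mrmr_rank, stratified_split, univariate_screen
from .volume_io import read_mask, read_volume

__all__ = ["PipelineConfig", "run_pipeline", "run_from_table", "load_directory_cohort", "derive_subseeds"]

log = logging.getLogger("radcascade")

_SUBSTREAMS = ("cohort", "split", "folds")


def derive_subseeds(master_seed: int) -> dict[str, int]:
    """Named integer sub-seeds (< 2^31) derived from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_SUBSTREAMS))
    return {
        name: int(child.generate_state(1, np.uint32)[0] % (2**31))
        for name, child in zip(_SUBSTREAMS, children)
    }


@dataclass
class PipelineConfig:
    """Study configuration; defaults mirror the modeled protocol:
    0.5 x 0.5 x 5 mm resampling, bin width 20, 3:1 split, p < 0.05 screen,
    top-10 mRMR features, 5-fold CV."""

    mode: str = "synthetic"                      # "synthetic" | "directory"
    input_dir: str | None = None                 # directory mode: volumes + masks
    clinical_csv: str | None = None              # directory mode: clinical table
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 5.0)
    bin_width: float = 20.0
    wavelet: str = "haar"
    train_ratio: float = 0.75
    screen_alpha: float = 0.05
    mrmr_k: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    cv_folds: int = 5
    threshold_rule: str = "youden"               # "youden" | "half"
    seed: int = 0
    output_dir: str = "radcascade_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(bin_width=self.bin_width, wavelet=self.wavelet)


def load_directory_cohort(input_dir, clinical_csv) -> list[Subject]:
    """Load ``<id>_image`` / ``<id>_mask`` NIfTI or NRRD pairs listed in a clinical CSV.

    The CSV needs columns subject_id, age, gender, label; every row must have
    a matching volume and mask file.
    """
    input_dir = Path(input_dir)
    clin = pd.read_csv(clinical_csv)
    required = {"subject_id", "age", "gender", "label"}
    missing_cols = required - set(clin.columns)
    if missing_cols:
        raise ValueError(f"clinical CSV missing column(s): {sorted(missing_cols)}")
    subjects = []
    for _, row in clin.iterrows():
        sid = str(row["subject_id"])
        img_path = mask_path = None
        for ext in (".nii.gz", ".nii", ".nrrd"):
            if (input_dir / f"{sid}_image{ext}").exists():
                img_path = input_dir / f"{sid}_image{ext}"
            if (input_dir / f"{sid}_mask{ext}").exists():
                mask_path = input_dir / f"{sid}_mask{ext}"
        if img_path is None or mask_path is None:
            raise FileNotFoundError(f"missing volume or mask for subject {sid}")
        label = str(row["label"])
        if label not in ("GN", "GNB", "NB"):
            raise ValueError(f"unknown class label {label!r} for subject {sid}")
        subjects.append(
            Subject(
                subject_id=sid,
                volume=read_volume(img_path),
                mask=read_mask(mask_path),
                age=float(row["age"]),
                gender=int(row["gender"]),
                label=label,
            )
        )
    return subjects


def run_from_table(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Split/screen/rank/fit/evaluate on a pre-extracted feature table.

    The table holds 851 radiomic columns + age + gender + label.  Returns a
    dict with the split table, the SelectionResult, both fitted CascadeModels
    and their train/validation evaluation reports.
    """
    seeds = derive_subseeds(config.seed)
    split_table = stratified_split(table, ratio=config.train_ratio, seed=seeds["split"])
    train = split_table[split_table["split"] == "train"]

    t0 = time.perf_counter()
    selection = univariate_screen(train, alpha=config.screen_alpha)
    log.info(
        "screen: %d/%d features survive p < %g (%.1fs)",
        len(selection.survivors),
        len(selection.pvalues),
        config.screen_alpha,
        time.perf_counter() - t0,
    )
    pool = selection.survivors + ["age", "gender"]
    selection.ranked = mrmr_rank(
        train[pool], train["label"], k=min(config.mrmr_k, len(pool))
    )
    log.info("mRMR top-%d: %s", config.mrmr_k, [n for n, _ in selection.ranked])

    models: dict[str, CascadeModel] = {}
    reports: dict[str, dict] = {}
    for tag in ("clinical_radiomic", "clinical"):
        models[tag] = fit_cascade(
            train,
            feature_set=tag,
            ranked_features=selection.ranked_names(),
            seed=seeds["folds"],
            n_folds=config.cv_folds,
            n_lambdas=config.n_lambdas,
            min_ratio=config.lambda_min_ratio,
            threshold_rule=config.threshold_rule,
        )
        reports[tag] = {
            split: evaluate_cascade(models[tag], split_table[split_table["split"] == split])
            for split in ("train", "validation")
            if (split_table["split"] == split).any()
        }
    return {
        "table": split_table,
        "selection": selection,
        "models": models,
        "reports": reports,
        "subseeds": seeds,
    }


def _selection_to_dict(sel: SelectionResult, split_table: pd.DataFrame) -> dict:
    return {
        "pvalues": sel.pvalues,
        "survivors": sel.survivors,
        "ranked": [{"feature": n, "importance": s} for n, s in sel.ranked],
        "split": {
            str(i): s for i, s in zip(split_table.index, split_table["split"])
        },
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study and write all artifacts into ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        seeds = derive_subseeds(config.seed)
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            spec = config.cohort
            spec.seed = seeds["cohort"]
            cohort = sample_cohort(spec)
        elif config.mode == "directory":
            cohort = load_directory_cohort(config.input_dir, config.clinical_csv)
        else:
            raise ValueError(f"unknown pipeline mode {config.mode!r}")
        log.info("cohort: %d subjects (%.1fs)", len(cohort), time.perf_counter() - t0)

        t0 = time.perf_counter()
        table = cohort_to_feature_table(
            cohort, config.extraction_config(), target_spacing=config.target_spacing
        )
        log.info(
            "extraction: %d x %d feature table (%.1fs)",
            table.shape[0],
            table.shape[1],
            time.perf_counter() - t0,
        )
        table.to_csv(outdir / "features.csv")
        with open(outdir / "extraction_config.json", "w") as fh:
            json.dump(
                {"bin_width": config.bin_width, "wavelet": config.wavelet,
                 "target_spacing": list(config.target_spacing)},
                fh, indent=2, sort_keys=True,
            )

        result = run_from_table(table, config)

        with open(outdir / "selection.json", "w") as fh:
            json.dump(
                _selection_to_dict(result["selection"], result["table"]),
                fh, indent=2, sort_keys=True,
            )
        for tag, model in result["models"].items():
            model.to_json(outdir / f"model_{tag}.json")
            for split in ("train", "validation"):
                sub = result["table"][result["table"]["split"] == split]
                if len(sub):
                    predict_cascade(model, sub).to_csv(
                        outdir / f"predictions_{tag}_{split}.csv"
                    )
        with open(outdir / "eval_report.json", "w") as fh:
            json.dump(result["reports"], fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            cfg = asdict(config)
            cfg["cohort"] = config.cohort.to_manifest()
            json.dump({"config": cfg, "subseeds": result["subseeds"]},
                      fh, indent=2, sort_keys=True, default=str)
        for tag in result["reports"]:
            log.info("%s:\n%s", tag,
                     format_metrics_table(result["reports"][tag]["validation"]))
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
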