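"""End-to-end orchestration: images → habitats → features → model → report.

Stages run in a fixed order — load, habitat segmentation, validity-index
features, 7:3 stratified split, per-feature screening, z-score, feature
selection, GP fit, evaluation — under one master seed that fixes the split,
selection CV, GP optimizer restarts and any subsampling.  Cases whose ROI
is degenerate (constant intensity) are excluded and counted, mirroring the
exclusion of unanalyzable images in a real cohort.

A run with an ``out_dir`` writes the feature table, screening report,
model artifact, train/test evaluation reports, plots and a log, each output
stamped with the config hash and seed; ``out_dir=None`` runs fully
in memory (used by the power analyses).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateInputError, FormatError, TumorHabitatError
from .evaluation import (
    EvalReport,
    evaluate_model,
    plot_calibration,
    plot_decision_curve,
    plot_roc,
)
from .io import TumorROI, load_case, load_case_table
from .metrics import FEATURE_NAMES, HeterogeneityExtractor
from .model import (
    PAPER_FEATURE_SET,
    GradeClassifier,
    SplitCohort,
    predict_proba,
    save_model,
    split_cohort,
)
from .screening import screen_cohort, screen_results_to_frame
from .synthetic import PhantomSpec, SyntheticCohortSpec, cohort_rois, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "extract_features"]

logger = logging.getLogger("tumorhabitat")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    mode: str = "synthetic"  # "synthetic" | "directory"
    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    k: int = 3
    n_restarts: int = 10
    standardize: bool = True
    split_ratio: float = 0.7
    features: tuple[str, ...] | None = PAPER_FEATURE_SET
    selection_chain: tuple[str, ...] | None = None
    threshold_policy: str = "youden"
    make_plots: bool = True
    # synthetic-mode cohort parameters
    n_low: int = 60
    n_high: int = 60
    habitat_contrast: float = 3.0
    grid_size: int = 48
    noise_sd: float = 10.0
    rim_fraction: float = 0.25
    tumor_radii: tuple[float, float, float] = (10.0, 12.0, 14.0)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise FormatError(f"unknown mode {self.mode!r}")
        if self.mode == "directory" and not self.input_dir:
            raise FormatError("directory mode requires input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("features", "selection_chain", "tumor_radii"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        # output location and plotting do not affect the computation
        payload.pop("out_dir", None)
        payload.pop("make_plots", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory outputs of one run."""

    features: pd.DataFrame  # indexed by case_id; includes 'grade' column
    screening: pd.DataFrame
    split: SplitCohort
    model: GradeClassifier
    train_report: EvalReport
    test_report: EvalReport
    n_excluded: int
    config_hash: str
    seed: int


def _load_directory(input_dir: Path) -> tuple[list[TumorROI], np.ndarray, list[str]]:
    records = load_case_table(input_dir / "cases.csv")
    rois, labels, ids = [], [], []
    for rec in records:
        img = input_dir / f"{rec.case_id}_image.nii.gz"
        msk = input_dir / f"{rec.case_id}_mask.nii.gz"
        for p in (img, msk):
            if not p.exists():
                raise FormatError(f"case {rec.case_id}: missing file {p.name}")
        rois.append(load_case(img, msk, case_id=rec.case_id))
        labels.append(rec.grade)
        ids.append(rec.case_id)
    return rois, np.asarray(labels), ids


def extract_features(
    rois: list[TumorROI],
    labels: np.ndarray,
    case_ids: list[str],
    config: RunConfig,
) -> tuple[pd.DataFrame, int]:
    """Per-case habitat features; degenerate cases excluded with a count."""
    extractor = HeterogeneityExtractor(
        k=config.k,
        standardize=config.standardize,
        n_restarts=config.n_restarts,
        random_state=config.seed,
    )
    rows, kept_labels, kept_ids = [], [], []
    n_excluded = 0
    for roi, lab, cid in zip(rois, labels, case_ids):
        try:
            rows.append(extractor.transform([roi])[0])
        except (DegenerateInputError, TumorHabitatError) as err:
            n_excluded += 1
            logger.warning("excluding case %s: %s", cid, err)
            continue
        kept_labels.append(lab)
        kept_ids.append(cid)
        logger.info(
            "case %s: N=%d voxels, silhouette subsample %s",
            cid,
            roi.n_voxels,
            "on" if roi.n_voxels > 10_000 else "off",
        )
    feats = pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=kept_ids)
    feats.index.name = "case_id"
    feats["grade"] = kept_labels
    return feats, n_excluded


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage; write artifacts when ``config.out_dir`` is set."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    chash = config.config_hash()
    try:
        if config.mode == "synthetic":
            cohort = generate_cohort(
                SyntheticCohortSpec(
                    n_low=config.n_low,
                    n_high=config.n_high,
                    phantom=PhantomSpec(
                        grid_size=config.grid_size,
                        tumor_radii=config.tumor_radii,
                        habitat_contrast=config.habitat_contrast,
                        rim_fraction=config.rim_fraction,
                        noise_sd=config.noise_sd,
                    ),
                    master_seed=config.seed,
                )
            )
            rois, labels, ids = cohort_rois(cohort)
        else:
            rois, labels, ids = _load_directory(Path(config.input_dir))

        feature_cache = out_dir / "features.csv" if out_dir else None
        cache_meta = out_dir / "features.hash" if out_dir else None
        if (
            feature_cache
            and feature_cache.exists()
            and cache_meta is not None
            and cache_meta.exists()
            and cache_meta.read_text().strip() == chash
        ):
            feats = pd.read_csv(feature_cache, index_col="case_id")
            n_excluded = 0
            logger.info("reusing cached feature table (config hash %s)", chash)
        else:
            feats, n_excluded = extract_features(rois, labels, ids, config)
            if out_dir:
                feats.to_csv(feature_cache)
                cache_meta.write_text(chash)
        if n_excluded:
            logger.warning("%d case(s) excluded for degenerate input", n_excluded)

        X = feats[list(FEATURE_NAMES)]
        y = feats["grade"].to_numpy()
        split = split_cohort(X, y, ratio=config.split_ratio, seed=config.seed)

        screen = screen_results_to_frame(
            screen_cohort(split.train_features, split.train_labels)
        )

        model = GradeClassifier(
            features=config.features,
            selection_chain=config.selection_chain,
            threshold_policy=config.threshold_policy,
            random_state=config.seed,
        ).fit(split.train_features, split.train_labels)

        p_train = predict_proba(model, split.train_features)
        p_test = predict_proba(model, split.test_features)
        train_report = evaluate_model(p_train, split.train_labels)
        test_report = evaluate_model(p_test, split.test_labels)

        if out_dir:
            screen.to_csv(out_dir / "screening.csv", index=False)
            save_model(model, out_dir / "model.json")
            train_report.to_json(out_dir / "eval_train.json")
            test_report.to_json(out_dir / "eval_test.json")
            (out_dir / "provenance.json").write_text(
                json.dumps(
                    {"config_hash": chash, "seed": config.seed,
                     "n_excluded": n_excluded, "config": asdict(config)},
                    indent=1, default=str,
                )
            )
            if config.make_plots:
                import matplotlib

                matplotlib.use("Agg", force=True)
                import matplotlib.pyplot as plt

                for name, probs, labs in (
                    ("train", p_train, split.train_labels),
                    ("test", p_test, split.test_labels),
                ):
                    ax = plot_roc(probs, labs)
                    ax.figure.savefig(out_dir / f"roc_{name}.png", dpi=120)
                    plt.close(ax.figure)
                    ax = plot_calibration(probs, labs)
                    ax.figure.savefig(out_dir / f"calibration_{name}.png", dpi=120)
                    plt.close(ax.figure)
                ax = plot_decision_curve(p_test, split.test_labels)
                ax.figure.savefig(out_dir / "dca_test.png", dpi=120)
                plt.close(ax.figure)

        return PipelineResult(
            features=feats,
            screening=screen,
            split=split,
            model=model,
            train_report=train_report,
            test_report=test_report,
            n_excluded=n_excluded,
            config_hash=chash,
            seed=config.seed,
        )
    finally:
        if out_dir:
            logger.removeHandler(handler)
            handler.close()
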