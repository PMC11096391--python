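"""End-to-end orchestration: configuration, logging, and the full pipeline.

``run_synthetic_study`` generates a cohort and runs
preprocess -> coregister -> train -> predict -> evaluate, writing the
intermediary images (ion image, PC1 projection, coregistration overlay,
prediction) and the pooled evaluation report.  ``run_on_imzml`` runs the same
pipeline on user-supplied imzML + mask pairs.  Everything is deterministic
given the configuration; the only stochastic element is the generator seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from sccmsi import classify, coregister, evaluate, msi_io, preprocess, synthetic
from sccmsi.msi_io import BACKGROUND, AnnotationMask, MsiDataset

logger = logging.getLogger("sccmsi")


class ConfigError(ValueError):
    """Unknown keys or invalid values in a run configuration."""


@dataclass
class PreprocessConfig:
    ref_mzs: tuple[float, ...] = preprocess.DEFAULT_REF_MZS
    tol_ppm: float = 30.0
    tissue_ref_mz: float = 885.5493
    noise_floor: float = 0.0
    axis_step_ppm: float = 2.0
    sg_order: int = 2
    sg_window: int = 21
    min_rel_intensity: float = 0.001
    min_sep_ppm: float = 20.0
    window_ppm: float = 10.0


@dataclass
class CoregisterConfig:
    rotation_range_deg: float = 15.0
    rotation_step_deg: float = 3.0
    scale_min: float = 0.5
    scale_max: float = 2.0
    scale_step: float = 0.05
    max_translation_frac: float = 0.25
    min_dice: float = 0.7
    n_starts: int = 5


@dataclass
class ClassifyConfig:
    l2_lambda: float = 1e-2
    threshold: float = 0.5
    top_n: int = 50


@dataclass
class RunConfig:
    """One block per pipeline stage; every default is echoed into the run log."""

    n_datasets: int = 10
    seed: int = 7
    log_level: str = "INFO"
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    coregister: CoregisterConfig = field(default_factory=CoregisterConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def __post_init__(self) -> None:
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["synthetic"]["ref_mzs"] = list(out["synthetic"]["ref_mzs"])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs: dict = {}
        blocks = {"synthetic": synthetic.SyntheticConfig, "preprocess": PreprocessConfig, "coregister": CoregisterConfig, "classify": ClassifyConfig}
        for key, value in data.items():
            if key in blocks:
                block_cls = blocks[key]
                names = {f.name for f in dataclasses.fields(block_cls)}
                unknown = set(value) - names
                if unknown:
                    raise ConfigError(f"unknown keys in {key!r} block: {sorted(unknown)}")
                if "ref_mzs" in value:
                    value = {**value, "ref_mzs": tuple(value["ref_mzs"])}
                for tup in ("drift_plane", "mask_offset"):
                    if tup in value:
                        value = {**value, tup: tuple(value[tup])}
                kwargs[key] = block_cls(**value)
            elif key in {"n_datasets", "seed", "log_level"}:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown top-level config key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class DatasetResult:
    name: str
    tissue_flags: np.ndarray
    recalibration: preprocess.RecalibrationModel
    features: preprocess.FeatureMatrix
    pca: coregister.PcaProjection
    msi_tissue_mask: np.ndarray
    transform: coregister.RegistrationTransform
    coreg_report: coregister.CoregistrationReport
    label_image: np.ndarray
    labels: np.ndarray
    prediction: classify.PredictionImage | None = None


@dataclass
class StudyResult:
    config: RunConfig
    peaks: preprocess.PeakList
    datasets: list[DatasetResult]
    eval_report: evaluate.EvalReport | None
    classifier: classify.OvrClassifier
    coefficients: pd.DataFrame
    run_dir: Path | None = None


def _grey_png(values: np.ndarray, path: Path) -> None:
    v = np.asarray(values, float)
    rng = np.ptp(v)
    scaled = np.zeros_like(v) if rng == 0 else (v - v.min()) / rng
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)


def analyze_cohort(
    pairs: list[tuple[MsiDataset, AnnotationMask]],
    config: RunConfig,
) -> StudyResult:
    """Run the full pipeline on (dataset, annotation mask) pairs.

    Peak picking happens once on the cohort-pooled tissue mean spectrum so
    every dataset shares one feature space; registration failures (Dice below
    the configured floor) abort with :class:`coregister.RegistrationError`.
    """
    pc = config.preprocess
    if not pairs:
        raise ValueError("empty cohort")

    recalibrated: list[MsiDataset] = []
    tissue_flags_list: list[np.ndarray] = []
    recal_models: list[preprocess.RecalibrationModel] = []
    mz_min = min(ds.mz_min for ds, _ in pairs)
    mz_max = max(ds.mz_max for ds, _ in pairs)
    axis = preprocess.make_mz_axis(mz_min, mz_max, pc.axis_step_ppm)
    total = np.zeros(len(axis))
    n_tissue_total = 0
    for ds, _mask in pairs:
        flags = preprocess.detect_tissue_pixels(ds, ref_mz=pc.tissue_ref_mz, tol_ppm=pc.tol_ppm, noise_floor=pc.noise_floor)
        model = preprocess.fit_recalibration(ds, ref_mzs=pc.ref_mzs, tol_ppm=pc.tol_ppm)
        cal = preprocess.apply_recalibration(ds, model)
        _, mean = preprocess.mean_spectrum(cal, flags, pc.axis_step_ppm, axis=axis)
        n = int(flags.sum())
        total += mean * n
        n_tissue_total += n
        recalibrated.append(cal)
        tissue_flags_list.append(flags)
        recal_models.append(model)
        logger.info("dataset %s: %d tissue pixels, drift plane %s", ds.source_id, n, np.round(model.plane, 3))
    cohort_mean = total / max(n_tissue_total, 1)
    smoothed = preprocess.smooth_spectrum(cohort_mean, order=pc.sg_order, window=pc.sg_window)
    peaks = preprocess.pick_peaks(axis, smoothed, pc.min_rel_intensity, pc.min_sep_ppm, pc.window_ppm)
    logger.info("picked %d consensus peaks", len(peaks))

    cc = config.coregister
    ds_results: list[DatasetResult] = []
    for (ds, mask), cal, flags, model in zip(pairs, recalibrated, tissue_flags_list, recal_models):
        feats = preprocess.extract_features(cal, peaks)
        feats.tissue_flags = flags
        grid = cal.grid_shape
        pca = coregister.pca_projection(feats, grid)
        total_int = cal.image_from_values(np.array([float(np.sum(i)) for i in cal.intensities]))
        msi_mask = coregister.tissue_mask_from_pca(pca.score_images[..., 0], total_int)
        transform = coregister.register_mask(
            mask.tissue_mask(),
            msi_mask,
            rotation_range_deg=cc.rotation_range_deg,
            rotation_step_deg=cc.rotation_step_deg,
            scale_min=cc.scale_min,
            scale_max=cc.scale_max,
            scale_step=cc.scale_step,
            max_translation_frac=cc.max_translation_frac,
            min_dice=cc.min_dice,
            n_starts=cc.n_starts,
        )
        report = coregister.coregistration_report(mask.tissue_mask(), msi_mask, transform)
        label_image = coregister.transfer_labels(mask, transform, grid)
        labels = label_image[feats.coords[:, 1], feats.coords[:, 0]]
        ds_results.append(
            DatasetResult(
                name=ds.source_id,
                tissue_flags=flags,
                recalibration=model,
                features=feats,
                pca=pca,
                msi_tissue_mask=msi_mask,
                transform=transform,
                coreg_report=report,
                label_image=label_image,
                labels=labels,
            )
        )
        logger.info(
            "dataset %s: registration Dice %.3f (both %d / hne-only %d / msi-only %d)",
            ds.source_id,
            transform.overlap_score,
            report.n_both,
            report.n_hne_only,
            report.n_msi_only,
        )

    cohort = [
        evaluate.LabelledDataset(features=r.features, labels=r.labels, grid_shape=cal.grid_shape, name=r.name)
        for r, cal in zip(ds_results, recalibrated)
    ]
    cl = config.classify
    report = None
    if len(cohort) >= 2:
        report = evaluate.logo_cv(cohort, l2_lambda=cl.l2_lambda, threshold=cl.threshold)
        logger.info(
            "LOGO: sensitivity %.3f specificity %.3f accuracy %.3f",
            report.sensitivity,
            report.specificity,
            report.accuracy,
        )
    else:
        logger.warning("single dataset: skipping leave-one-group-out cross-validation")

    x_all = np.vstack([c.features.values for c in cohort])
    y_all = np.concatenate([c.labels for c in cohort])
    final = classify.train_ovr(x_all, y_all, feature_mzs=peaks.mzs, l2_lambda=cl.l2_lambda, threshold=cl.threshold)
    coefficients = classify.rank_coefficients(final, top_n=cl.top_n)
    for r, cal in zip(ds_results, recalibrated):
        r.prediction = classify.predict_image(final, r.features, cal.grid_shape)
    return StudyResult(
        config=config,
        peaks=peaks,
        datasets=ds_results,
        eval_report=report,
        classifier=final,
        coefficients=coefficients,
    )


def _write_outputs(result: StudyResult, pairs, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(result.config.to_dict(), sort_keys=True))
    pd.DataFrame({"mz": result.peaks.mzs, "window_ppm": result.peaks.window_ppm}).to_csv(run_dir / "peaks.csv", index=False)
    result.coefficients.to_csv(run_dir / "coefficients.csv", index=False)
    result.classifier.to_json(run_dir / "classifier.json")
    transforms = {r.name: r.transform.to_dict() for r in result.datasets}
    (run_dir / "transforms.json").write_text(json.dumps(transforms, indent=2, sort_keys=True))
    if result.eval_report is not None:
        result.eval_report.to_json(run_dir / "eval_report.json")
        result.eval_report.confusion_table().to_csv(run_dir / "confusion_pooled.csv")
    for idx, ((ds, _mask), r) in enumerate(zip(pairs, result.datasets)):
        tag = f"ds{idx:02d}"
        ion = np.zeros(ds.grid_shape)
        for (x, y), mz, inten in zip(ds.coords, ds.mzs, ds.intensities):
            j = preprocess.match_mz(mz, np.array([885.5493]), tol_ppm=30.0)[0]
            if j >= 0:
                ion[y, x] = inten[j]
        _grey_png(ion, run_dir / f"{tag}_ion885.png")
        _grey_png(r.pca.score_images[..., 0], run_dir / f"{tag}_pc1.png")
        Image.fromarray(r.coreg_report.image).save(run_dir / f"{tag}_coreg.png")
        msi_io.write_prediction_image(r.prediction, run_dir / f"{tag}_prediction.png")
    result.run_dir = run_dir


def run_synthetic_study(config: RunConfig, run_dir: str | Path) -> StudyResult:
    """Generate a synthetic cohort and run the full pipeline into ``run_dir``."""
    logging.basicConfig(level=config.log_level)
    logger.info("run configuration: %s", json.dumps(config.to_dict(), sort_keys=True))
    cohort = synthetic.generate_cohort(config.n_datasets, config.synthetic)
    pairs = [(ds, mask) for ds, mask, _truth in cohort]
    result = analyze_cohort(pairs, config)
    run_dir = Path(run_dir)
    _write_outputs(result, pairs, run_dir)
    for idx, (_ds, _mask, truth) in enumerate(cohort):
        truth.to_json(run_dir / f"ds{idx:02d}_truth.json")
    return result


def run_on_imzml(
    imzml_paths: list[str | Path],
    mask_paths: list[str | Path],
    config: RunConfig,
    run_dir: str | Path,
) -> StudyResult:
    """Run the pipeline on user-supplied imzML + annotation-mask pairs."""
    logging.basicConfig(level=config.log_level)
    if len(imzml_paths) != len(mask_paths):
        raise ConfigError("need one mask per imzML dataset")
    if not imzml_paths:
        raise ConfigError("no input datasets")
    pairs = []
    for ip, mp in zip(imzml_paths, mask_paths):
        if not Path(mp).exists():
            raise ConfigError(f"missing mask: {mp}")
        pairs.append((msi_io.read_imzml(ip), msi_io.read_mask(mp)))
    result = analyze_cohort(pairs, config)
    _write_outputs(result, pairs, Path(run_dir))
    return result


def write_cohort(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Materialize a synthetic cohort as imzML + mask + ground-truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, (ds, mask, truth) in enumerate(synthetic.generate_cohort(config.n_datasets, config.synthetic)):
        tag = f"ds{idx:02d}"
        msi_io.write_imzml(ds, out_dir / f"{tag}.imzML")
        msi_io.write_mask(mask, out_dir / f"{tag}_mask.png")
        truth.to_json(out_dir / f"{tag}_truth.json")
        paths.append(out_dir / f"{tag}.imzML")
    return paths
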