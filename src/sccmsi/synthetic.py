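"""Synthetic MALDI-MSI cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: centroided
negative-mode spectra on m/z 300-1000, two always-present reference ions
(m/z 311.2950 and 885.5493), class-dependent intensity shifts on a planted
subset of lipid-range ions (m/z 600-900 up in tumor; a cholesterol-sulphate-
like ion near m/z 465.3 down in tumor), a smooth ppm-scale mass-drift plane,
multiplicative intensity noise, and a deliberately misaligned, partially
Unlabeled annotation mask to exercise coregistration.

Intensities are log-normal per ion; the class effect is an additive shift in
log10 space, matching the pipeline's log10 normalization so the effect size
is directly interpretable as a log10 fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from sccmsi.geometry import TransformParams, grid_center, invert_params, params_to_matrix
from sccmsi.msi_io import BACKGROUND, NONTUMOR, TUMOR, UNLABELED, AnnotationMask, MsiDataset

REF_MZS = (311.2950, 885.5493)
CHOLESTEROL_SULPHATE_MZ = 465.304  # strongest tumor-downregulated ion

# log10 intensity scale of the simulation
_BASELINE_LO, _BASELINE_HI = 1.5, 3.5
_REF_LOG10 = 4.0
_MIN_PEAK_SEP_PPM = 100.0


class ConfigError(ValueError):
    """Raised when a SyntheticConfig violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic MSI dataset.

    ``seed`` drives geometry and noise; ``peak_seed`` independently drives
    the identity of the true peaks (their m/z positions and baseline
    intensities), so cohorts share one peak panel while varying everything
    else and changing the base seed re-rolls the noise, not the panel.
    """

    grid_width: int = 32
    grid_height: int = 32
    n_peaks: int = 200
    mz_min: float = 300.0
    mz_max: float = 1000.0
    ref_mzs: tuple[float, ...] = REF_MZS
    n_tumor_up: int = 5
    n_nontumor_up: int = 1
    effect_log10: float = 1.0
    noise_cv: float = 0.2
    mz_jitter_ppm: float = 1.0
    drift_plane: tuple[float, float, float] = (0.1, -0.05, 5.0)
    mask_offset: tuple[float, float, float, float] = (2.0, -3.0, 4.0, 1.1)
    tumor_fraction: float = 0.4
    unlabeled_fraction: float = 0.3
    pixel_size_um: float = 50.0
    seed: int = 0
    peak_seed: int = 1729

    def validate(self) -> None:
        if self.grid_width < 4 or self.grid_height < 4:
            raise ConfigError("grid_width/grid_height must be >= 4")
        if not self.mz_min < self.mz_max:
            raise ConfigError("mz_min must be < mz_max")
        for ref in self.ref_mzs:
            if not self.mz_min <= ref <= self.mz_max:
                raise ConfigError(f"ref_mzs entry {ref} outside [mz_min, mz_max]")
        if self.n_tumor_up + self.n_nontumor_up > self.n_peaks - len(self.ref_mzs):
            raise ConfigError("n_tumor_up + n_nontumor_up exceeds n_peaks - len(ref_mzs)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not 0 < self.tumor_fraction < 1:
            raise ConfigError("tumor_fraction must be in (0, 1)")
        if not 0 <= self.unlabeled_fraction < 1:
            raise ConfigError("unlabeled_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    class_map: np.ndarray  # (H, W) codes in {BACKGROUND, TUMOR, NONTUMOR}
    true_peak_mzs: np.ndarray
    tumor_up_mzs: np.ndarray
    nontumor_up_mzs: np.ndarray
    drift_plane: tuple[float, float, float]
    true_transform: TransformParams  # mask frame -> MSI frame
    mask_offset: TransformParams = field(default_factory=TransformParams)  # MSI -> mask frame

    def tissue_mask(self) -> np.ndarray:
        return self.class_map != BACKGROUND

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "class_map": self.class_map.tolist(),
                    "true_peak_mzs": self.true_peak_mzs.tolist(),
                    "tumor_up_mzs": self.tumor_up_mzs.tolist(),
                    "nontumor_up_mzs": self.nontumor_up_mzs.tolist(),
                    "drift_plane": list(self.drift_plane),
                    "true_transform": self.true_transform.to_dict(),
                    "mask_offset": self.mask_offset.to_dict(),
                },
                sort_keys=True,
            )
        )
        return path


def _sample_peak_panel(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the shared peak panel: m/z positions, baselines, planted subsets.

    Peaks keep >= 100 ppm mutual separation so consensus peak picking on the
    cohort mean spectrum is well-posed.
    """
    rng = np.random.default_rng(config.peak_seed)
    taken = list(config.ref_mzs)

    def draw(lo: float, hi: float) -> float:
        for _ in range(10_000):
            mz = float(rng.uniform(lo, hi))
            if all(abs(mz - t) / t * 1e6 > _MIN_PEAK_SEP_PPM for t in taken):
                taken.append(mz)
                return mz
        raise ConfigError("could not place peaks with the required separation; reduce n_peaks")

    margin = (config.mz_max - config.mz_min) * 0.005
    lo, hi = config.mz_min + margin, config.mz_max - margin

    tumor_up = [draw(max(lo, 600.0), min(hi, 900.0)) for _ in range(config.n_tumor_up)]
    nontumor_up: list[float] = []
    if config.n_nontumor_up > 0 and lo < CHOLESTEROL_SULPHATE_MZ < hi:
        taken.append(CHOLESTEROL_SULPHATE_MZ)
        nontumor_up.append(CHOLESTEROL_SULPHATE_MZ)
    while len(nontumor_up) < config.n_nontumor_up:
        nontumor_up.append(draw(lo, hi))
    n_rest = config.n_peaks - len(config.ref_mzs) - len(tumor_up) - len(nontumor_up)
    rest = [draw(lo, hi) for _ in range(n_rest)]

    mzs = np.sort(np.array(list(config.ref_mzs) + tumor_up + nontumor_up + rest))
    baselines = rng.uniform(_BASELINE_LO, _BASELINE_HI, size=len(mzs))
    baselines[np.isin(mzs, config.ref_mzs)] = _REF_LOG10
    return mzs, baselines, np.sort(np.array(tumor_up)), np.sort(np.array(nontumor_up))


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi: tuple[float, float],
    rot_deg: float,
    lobes: tuple[tuple[int, float, float], ...] = (),
) -> np.ndarray:
    """Elliptical blob, optionally with low-order radial lobes.

    ``lobes`` entries are (harmonic, amplitude, phase_rad); they perturb the
    boundary radius, producing the irregular outline of a real tissue section
    (and making the section's orientation geometrically identifiable).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    th = np.deg2rad(rot_deg)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    rho = np.sqrt((u / semi[0]) ** 2 + (v / semi[1]) ** 2)
    boundary = np.ones_like(rho)
    if lobes:
        ang = np.arctan2(v / semi[1], u / semi[0])
        for k, amp, phase in lobes:
            boundary = boundary + amp * np.cos(k * ang + phase)
    return rho <= boundary


def _class_map(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Irregular tissue blob containing a tumor sub-blob of ~tumor_fraction area."""
    h, w = config.grid_height, config.grid_width
    cx = (w - 1) / 2 + rng.uniform(-0.05, 0.05) * w
    cy = (h - 1) / 2 + rng.uniform(-0.05, 0.05) * h
    rx = rng.uniform(0.30, 0.36) * w
    ry = rng.uniform(0.30, 0.36) * h
    rot = rng.uniform(0, 180)
    lobes = tuple(
        (k, rng.uniform(0.08, 0.15), rng.uniform(0, 2 * np.pi)) for k in (2, 3)
    )
    tissue = _ellipse_mask((h, w), (cx, cy), (rx, ry), rot, lobes=lobes)

    s = np.sqrt(config.tumor_fraction)
    # offset the tumor blob inside the tissue, scale slightly up to compensate
    # for clipping at the tissue boundary
    off = rng.uniform(-0.25, 0.25, size=2) * np.array([rx, ry])
    tumor = _ellipse_mask((h, w), (cx + off[0], cy + off[1]), (1.15 * s * rx, 1.15 * s * ry), rot) & tissue

    cmap = np.full((h, w), BACKGROUND, dtype=np.uint8)
    cmap[tissue] = NONTUMOR
    cmap[tumor] = TUMOR
    if not (cmap == TUMOR).any() or not (cmap == NONTUMOR).any():
        # extremely small grids: force one pixel of each class
        ys, xs = np.nonzero(tissue)
        cmap[ys[0], xs[0]] = TUMOR
        cmap[ys[-1], xs[-1]] = NONTUMOR
    return cmap


def _misaligned_mask(class_map: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> tuple[AnnotationMask, TransformParams, TransformParams]:
    """Export the class map into a misaligned 'histology' frame.

    The forward offset maps MSI coordinates into the mask frame; each mask
    pixel therefore samples the class map at the inverse-transformed position
    (nearest neighbor).  A fraction of tissue pixels is relabelled Unlabeled
    to mimic partial annotation.
    """
    h, w = class_map.shape
    dx, dy, rot, scale = config.mask_offset
    offset = TransformParams(scale_x=scale, scale_y=scale, rotation_deg=rot, translate_x=dx, translate_y=dy)
    center = grid_center((h, w))
    inv = np.linalg.inv(params_to_matrix(offset, center))

    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = pts @ inv[:2, :2].T + inv[:2, 2]
    sx = np.rint(src[:, 0]).astype(int)
    sy = np.rint(src[:, 1]).astype(int)
    inside = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
    labels = np.full(h * w, BACKGROUND, dtype=np.uint8)
    labels[inside] = class_map[sy[inside], sx[inside]]
    labels = labels.reshape(h, w)

    tissue_idx = np.flatnonzero(labels.ravel() != BACKGROUND)
    n_unlab = int(round(config.unlabeled_fraction * len(tissue_idx)))
    if n_unlab:
        chosen = rng.choice(tissue_idx, size=n_unlab, replace=False)
        flat = labels.ravel()
        flat[chosen] = UNLABELED
        labels = flat.reshape(h, w)

    mask = AnnotationMask(labels=labels, frame="hne")
    return mask, offset, invert_params(offset, center)


def generate_dataset(config: SyntheticConfig) -> tuple[MsiDataset, AnnotationMask, GroundTruth]:
    """Generate one synthetic dataset: spectra, misaligned mask, ground truth.

    Deterministic: identical configs (including seed) give bit-identical
    output.
    """
    config.validate()
    peak_mzs, baselines, tumor_up, nontumor_up = _sample_peak_panel(config)
    rng = np.random.default_rng(config.seed)
    class_map = _class_map(config, rng)
    h, w = class_map.shape
    a, b, c = config.drift_plane
    sigma_ln = np.sqrt(np.log1p(config.noise_cv**2))

    shift = np.zeros(len(peak_mzs))
    shift[np.isin(peak_mzs, tumor_up)] = 1.0  # +effect in tumor
    shift_nt = np.zeros(len(peak_mzs))
    shift_nt[np.isin(peak_mzs, nontumor_up)] = 1.0  # +effect in non-tumor

    coords, mz_list, int_list = [], [], []
    for y in range(h):
        for x in range(w):
            label = class_map[y, x]
            ppm = a * x + b * y + c
            if label == BACKGROUND:
                # sparse low-intensity noise peaks, none near the reference
                # ions; at least one so every pixel has a recorded spectrum
                n_noise = 1 + rng.poisson(7)
                mz = rng.uniform(config.mz_min + 1, config.mz_max - 1, size=n_noise)
                keep = np.ones(len(mz), bool)
                for ref in config.ref_mzs:
                    keep &= np.abs(mz - ref) / ref * 1e6 > 200.0
                if not keep.any():
                    keep[np.argmin(np.abs(mz - config.mz_min - 1))] = True
                mz = np.sort(mz[keep])
                if len(mz) > 1:
                    mz = mz[np.concatenate([[True], np.diff(mz) > 1e-6])]
                inten = 10 ** rng.uniform(0.0, 1.0, size=len(mz))
            else:
                log10_mu = baselines + config.effect_log10 * (shift if label == TUMOR else shift_nt)
                inten = 10**log10_mu * np.exp(rng.normal(0.0, sigma_ln, size=len(peak_mzs)))
                jitter = rng.normal(0.0, config.mz_jitter_ppm, size=len(peak_mzs))
                mz = peak_mzs * (1.0 + (ppm + jitter) * 1e-6)
                order = np.argsort(mz)
                mz, inten = mz[order], inten[order]
            coords.append((x, y))
            mz_list.append(np.clip(mz, config.mz_min, config.mz_max))
            int_list.append(np.asarray(inten, dtype=float))

    dataset = MsiDataset(
        coords=np.asarray(coords, dtype=int),
        mzs=mz_list,
        intensities=int_list,
        pixel_size_um=config.pixel_size_um,
        mz_min=config.mz_min,
        mz_max=config.mz_max,
        source_id=f"synthetic-seed{config.seed}",
    )
    mask, offset, true_transform = _misaligned_mask(class_map, config, rng)
    truth = GroundTruth(
        class_map=class_map,
        true_peak_mzs=peak_mzs,
        tumor_up_mzs=tumor_up,
        nontumor_up_mzs=nontumor_up,
        drift_plane=config.drift_plane,
        true_transform=true_transform,
        mask_offset=offset,
    )
    return dataset, mask, truth


def generate_cohort(
    n_datasets: int, base_config: SyntheticConfig
) -> list[tuple[MsiDataset, AnnotationMask, GroundTruth]]:
    """Generate a cohort sharing one peak panel but differing in geometry/noise.

    Dataset i uses seed = base seed + i; the peak panel is pinned to the base
    seed so a model trained on some datasets transfers to the others.
    """
    if n_datasets < 2:
        raise ConfigError("a cohort needs n_datasets >= 2 (leave-one-group-out is undefined otherwise)")
    base_config.validate()
    out = []
    for i in range(n_datasets):
        out.append(generate_dataset(replace(base_config, seed=base_config.seed + i)))
    return out
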