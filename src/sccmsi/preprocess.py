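"""Spectral preprocessing.

Tissue-pixel detection from the ubiquitous lipid ion at m/z 885.5493,
two-reference-ion ppm recalibration with a least-squares drift plane filling
in pixels whose calibrant peaks are missing, mean-spectrum construction on a
log-spaced (constant-ppm) axis, Gaussian-weighted Savitzky-Golay smoothing,
peak picking with parabolic centroid refinement, and per-pixel feature
extraction into a pixels x peaks matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from sccmsi.msi_io import MsiDataset

DEFAULT_REF_MZS = (311.2950, 885.5493)


class RecalibrationError(RuntimeError):
    """Too few reference-ion matches to fit a drift plane."""


@dataclass
class RecalibrationModel:
    """Per-pixel ppm shifts plus the fitted linear drift surface.

    ppm(x, y) = a*x + b*y + c; pixels where no reference ion matched carry the
    plane's prediction instead of a direct estimate.
    """

    per_pixel_ppm: np.ndarray  # aligned with the dataset's pixel order
    plane: tuple[float, float, float]
    ref_mzs: tuple[float, ...] = DEFAULT_REF_MZS
    tol_ppm: float = 30.0
    matched: np.ndarray | None = None  # bool, pixels with >= 1 matched ref

    def plane_ppm(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b, c = self.plane
        return a * np.asarray(x, float) + b * np.asarray(y, float) + c


@dataclass
class PeakList:
    """Consensus centroid m/z values with the half-width used for extraction."""

    mzs: np.ndarray
    window_ppm: float = 10.0

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        if len(self.mzs) > 1:
            if np.any(np.diff(self.mzs) <= 0):
                raise ValueError("peak m/z values must be strictly ascending")
            sep_ppm = np.diff(self.mzs) / self.mzs[:-1] * 1e6
            if np.any(sep_ppm <= 2 * self.window_ppm):
                raise ValueError("adjacent peaks closer than 2*window_ppm; shrink window_ppm")

    def __len__(self) -> int:
        return len(self.mzs)


@dataclass
class FeatureMatrix:
    """pixels x peaks intensity table with pixel coordinates attached."""

    coords: np.ndarray  # (n, 2) int (x, y)
    mzs: np.ndarray  # peak m/z, ascending
    values: np.ndarray  # (n, p) non-negative
    tissue_flags: np.ndarray | None = None
    zero_rows: np.ndarray | None = None  # set by classify.normalize

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def image_stack(self, grid_shape: tuple[int, int]) -> np.ndarray:
        """(H, W, p) stack of ion images."""
        out = np.zeros((*grid_shape, self.values.shape[1]))
        out[self.coords[:, 1], self.coords[:, 0]] = self.values
        return out


def ppm_diff(observed: np.ndarray | float, reference: float) -> np.ndarray | float:
    return (observed - reference) / reference * 1e6


def detect_tissue_pixels(
    dataset: MsiDataset,
    ref_mz: float = 885.5493,
    tol_ppm: float = 30.0,
    noise_floor: float = 0.0,
) -> np.ndarray:
    """Flag pixels carrying signal at the reference lipid ion.

    A pixel is tissue iff it has at least one centroid within +/- tol_ppm of
    ``ref_mz`` with intensity above ``noise_floor`` (default 0: any recorded
    centroid counts).
    """
    if dataset.n_pixels == 0:
        raise ValueError("empty dataset")
    tol = ref_mz * tol_ppm * 1e-6
    flags = np.zeros(dataset.n_pixels, dtype=bool)
    for i, (mz, inten) in enumerate(zip(dataset.mzs, dataset.intensities)):
        lo, hi = np.searchsorted(mz, [ref_mz - tol, ref_mz + tol])
        flags[i] = hi > lo and np.max(inten[lo:hi]) > noise_floor
    if not flags.any():
        warnings.warn("no tissue pixels detected", stacklevel=2)
    return flags


def _match_ref(mz: np.ndarray, ref: float, tol_ppm: float) -> float | None:
    """ppm error of the centroid nearest to ``ref``, or None outside tolerance."""
    if len(mz) == 0:
        return None
    i = np.searchsorted(mz, ref)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(mz):
            err = ppm_diff(mz[j], ref)
            if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best)):
                best = float(err)
    return best


def fit_recalibration(
    dataset: MsiDataset,
    ref_mzs: tuple[float, ...] = DEFAULT_REF_MZS,
    tol_ppm: float = 30.0,
) -> RecalibrationModel:
    """Estimate per-pixel ppm shifts from the reference ions and fit a plane.

    The per-pixel shift is the mean observed ppm error over the matched
    reference ions; a least-squares plane over (x, y) supplies shifts for
    pixels where no reference ion was found.
    """
    shifts = np.full(dataset.n_pixels, np.nan)
    for i, mz in enumerate(dataset.mzs):
        errs = [e for ref in ref_mzs if (e := _match_ref(mz, ref, tol_ppm)) is not None]
        if errs:
            shifts[i] = float(np.mean(errs))
    matched = np.isfinite(shifts)
    if matched.sum() < 3:
        raise RecalibrationError(
            f"only {int(matched.sum())} pixels matched a reference ion; "
            "consider increasing tol_ppm"
        )
    x = dataset.coords[matched, 0].astype(float)
    y = dataset.coords[matched, 1].astype(float)
    design = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise RecalibrationError("matched pixels are collinear; cannot fit a drift plane")
    coeffs, *_ = np.linalg.lstsq(design, shifts[matched], rcond=None)
    plane = (float(coeffs[0]), float(coeffs[1]), float(coeffs[2]))
    filled = shifts.copy()
    miss = ~matched
    filled[miss] = coeffs[0] * dataset.coords[miss, 0] + coeffs[1] * dataset.coords[miss, 1] + coeffs[2]
    return RecalibrationModel(per_pixel_ppm=filled, plane=plane, ref_mzs=tuple(ref_mzs), tol_ppm=tol_ppm, matched=matched)


def apply_recalibration(dataset: MsiDataset, model: RecalibrationModel) -> MsiDataset:
    """Correct each pixel's m/z axis by its estimated ppm shift.

    ppm errors are multiplicative, so the axis is divided by
    (1 + ppm * 1e-6); intensities are untouched and ascending order is
    preserved.
    """
    if len(model.per_pixel_ppm) != dataset.n_pixels:
        raise ValueError("model does not match dataset pixel count")
    new_mzs = [mz / (1.0 + p * 1e-6) for mz, p in zip(dataset.mzs, model.per_pixel_ppm)]
    lo = min((float(m[0]) for m in new_mzs if len(m)), default=dataset.mz_min)
    hi = max((float(m[-1]) for m in new_mzs if len(m)), default=dataset.mz_max)
    return MsiDataset(
        coords=dataset.coords.copy(),
        mzs=new_mzs,
        intensities=[i.copy() for i in dataset.intensities],
        pixel_size_um=dataset.pixel_size_um,
        mz_min=min(dataset.mz_min, lo),
        mz_max=max(dataset.mz_max, hi),
        source_id=dataset.source_id,
    )


def make_mz_axis(mz_min: float, mz_max: float, step_ppm: float = 2.0) -> np.ndarray:
    """Log-spaced m/z axis with constant ppm bin width (Orbitrap-like)."""
    ratio = np.log(mz_max / mz_min) / np.log1p(step_ppm * 1e-6)
    n = int(np.floor(ratio)) + 1
    return mz_min * (1.0 + step_ppm * 1e-6) ** np.arange(n)


def _axis_index(mz: np.ndarray, mz_min: float, step_ppm: float, n_bins: int) -> np.ndarray:
    idx = np.rint(np.log(np.asarray(mz, float) / mz_min) / np.log1p(step_ppm * 1e-6)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def mean_spectrum(
    dataset: MsiDataset,
    tissue_flags: np.ndarray,
    axis_step_ppm: float = 2.0,
    axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average the tissue-pixel spectra on a common log-spaced axis.

    Each centroid is accumulated into its nearest bin and bin totals are
    divided by the number of tissue pixels.  Returns (axis, mean_values).
    """
    if not np.any(tissue_flags):
        raise ValueError("mean_spectrum requires at least one tissue pixel")
    if axis is None:
        axis = make_mz_axis(dataset.mz_min, dataset.mz_max, axis_step_ppm)
    total = np.zeros(len(axis))
    mz_min = float(axis[0])
    for i in np.flatnonzero(tissue_flags):
        mz, inten = dataset.mzs[i], dataset.intensities[i]
        if len(mz) == 0:
            continue
        idx = _axis_index(mz, mz_min, axis_step_ppm, len(axis))
        np.add.at(total, idx, inten)
    return axis, total / int(np.sum(tissue_flags))


def _sg_kernel(order: int, window: int, sigma: float) -> np.ndarray:
    """Savitzky-Golay smoothing kernel with Gaussian point weights.

    The kernel evaluates the weighted local polynomial fit at the window
    center; with symmetric weights it is symmetric.
    """
    half = window // 2
    t = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (t / sigma) ** 2)
    a = np.vander(t, order + 1, increasing=True)
    awa = a.T @ (w[:, None] * a)
    # row of the hat matrix at t = 0
    e0 = np.zeros(order + 1)
    e0[0] = 1.0
    beta = np.linalg.solve(awa, e0)
    return (w[:, None] * a) @ beta


def smooth_spectrum(
    values: np.ndarray,
    order: int = 2,
    window: int = 21,
    sigma: float | None = None,
) -> np.ndarray:
    """Gaussian-weighted Savitzky-Golay smoothing (default 2nd order, 21 points).

    ``sigma`` defaults to (window - 1) / 6 so the Gaussian weight profile
    spans the window at three standard deviations.  Edges are handled by
    truncating the window; polynomials up to ``order`` are reproduced exactly
    at interior points.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if len(values) < window:
        return values.copy()
    if sigma is None:
        sigma = (window - 1) / 6.0
    kernel = _sg_kernel(order, window, sigma)
    half = window // 2
    out = np.convolve(values, kernel, mode="same")
    # truncated-window weighted fits at the edges
    t_full = np.arange(-half, half + 1, dtype=float)
    w_full = np.exp(-0.5 * (t_full / sigma) ** 2)
    for i in range(half):
        for idx, sl in ((i, slice(0, i + half + 1)), (len(values) - 1 - i, slice(len(values) - i - half - 1, len(values)))):
            t = np.arange(sl.start, sl.stop, dtype=float) - idx
            w = np.interp(t, t_full, w_full)
            a = np.vander(t, order + 1, increasing=True)
            beta, *_ = np.linalg.lstsq(a * np.sqrt(w)[:, None], values[sl] * np.sqrt(w), rcond=None)
            out[idx] = beta[0]
    return out


def pick_peaks(
    axis: np.ndarray,
    values: np.ndarray,
    min_rel_intensity: float = 0.001,
    min_sep_ppm: float = 20.0,
    window_ppm: float = 10.0,
) -> PeakList:
    """Pick local maxima from a (smoothed) binned spectrum.

    Maxima above ``min_rel_intensity`` times the global maximum are kept
    greedily in descending intensity order subject to a minimum mutual
    separation; centroids are refined by 3-point parabolic interpolation on
    the log-spaced axis.
    """
    values = np.asarray(values, dtype=float)
    vmax = values.max(initial=0.0)
    if vmax <= 0 or np.ptp(values) == 0:
        warnings.warn("flat spectrum: no peaks picked", stacklevel=2)
        return PeakList(mzs=np.array([]), window_ppm=window_ppm)
    cand = np.flatnonzero((values[1:-1] > values[:-2]) & (values[1:-1] >= values[2:])) + 1
    cand = cand[values[cand] >= min_rel_intensity * vmax]
    order = cand[np.argsort(values[cand])[::-1]]
    kept_logmz: list[float] = []
    kept_idx: list[int] = []
    log_axis = np.log(axis)
    min_sep = min_sep_ppm * 1e-6
    for i in order:
        lm = log_axis[i]
        if all(abs(lm - k) > min_sep for k in kept_logmz):
            kept_logmz.append(lm)
            kept_idx.append(i)
    mzs = []
    step = log_axis[1] - log_axis[0]
    for i in kept_idx:
        if 0 < i < len(values) - 1:
            denom = values[i - 1] - 2 * values[i] + values[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (values[i - 1] - values[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        mzs.append(float(np.exp(log_axis[i] + delta * step)))
    return PeakList(mzs=np.sort(np.array(mzs)), window_ppm=window_ppm)


def extract_features(dataset: MsiDataset, peaks: PeakList) -> FeatureMatrix:
    """Build the pixels x peaks matrix: max centroid intensity per ppm window.

    value(pixel, peak) = maximum centroid intensity within +/- window_ppm of
    the peak m/z, or 0 when the window is empty.
    """
    p = len(peaks)
    lo = peaks.mzs * (1.0 - peaks.window_ppm * 1e-6)
    hi = peaks.mzs * (1.0 + peaks.window_ppm * 1e-6)
    values = np.zeros((dataset.n_pixels, p))
    for i, (mz, inten) in enumerate(zip(dataset.mzs, dataset.intensities)):
        if len(mz) == 0:
            continue
        a = np.searchsorted(mz, lo)
        b = np.searchsorted(mz, hi)
        for j in np.flatnonzero(b > a):
            values[i, j] = inten[a[j] : b[j]].max()
    return FeatureMatrix(coords=dataset.coords.copy(), mzs=peaks.mzs.copy(), values=values)


def match_mz(mzs: np.ndarray, targets: np.ndarray, tol_ppm: float = 3.0) -> np.ndarray:
    """Index of the nearest entry of ``mzs`` within tol_ppm per target, else -1.

    Helper for tentative metabolite annotation by exact mass.
    """
    mzs = np.asarray(mzs, float)
    out = np.full(len(np.atleast_1d(targets)), -1, dtype=int)
    for k, t in enumerate(np.atleast_1d(targets)):
        i = np.searchsorted(mzs, t)
        best, best_err = -1, tol_ppm
        for j in (i - 1, i):
            if 0 <= j < len(mzs):
                err = abs(ppm_diff(mzs[j], float(t)))
                if err <= best_err:
                    best, best_err = j, err
        out[k] = best
    return out
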