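"""Histology-mask to MSI-grid coregistration.

PCA score images summarize the feature matrix; Otsu thresholding of the PC1
image yields the MSI tissue mask; a deterministic similarity-transform search
(coarse grid plus local refinement, maximizing the Dice coefficient of the
tissue masks) aligns the histology-frame annotation mask onto the MSI grid;
labels are then transferred by nearest neighbor, and matched/unmatched pixel
counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.decomposition import PCA

from sccmsi.geometry import TransformParams, apply_matrix, grid_center, params_to_matrix
from sccmsi.msi_io import UNLABELED, AnnotationMask
from sccmsi.preprocess import FeatureMatrix


class DegenerateInputError(ValueError):
    """Input without enough variation to process (e.g. a constant image)."""


class RegistrationError(RuntimeError):
    """Best achievable mask overlap fell below the acceptance floor."""


@dataclass
class RegistrationTransform:
    """Similarity transform mapping histology-frame pixels to MSI pixels."""

    scale_x: float = 1.0
    scale_y: float = 1.0
    rotation_deg: float = 0.0
    translate_x: float = 0.0
    translate_y: float = 0.0
    overlap_score: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.overlap_score <= 1.0:
            raise ValueError("overlap_score must lie in [0, 1]")

    @property
    def params(self) -> TransformParams:
        return TransformParams(self.scale_x, self.scale_y, self.rotation_deg, self.translate_x, self.translate_y)

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        return params_to_matrix(self.params, grid_center(shape))

    def to_dict(self) -> dict:
        return {**self.params.to_dict(), "overlap_score": self.overlap_score}


@dataclass
class CoregistrationReport:
    """Pixel bookkeeping after registration: both / H&E-only / MSI-only."""

    n_both: int
    n_hne_only: int
    n_msi_only: int
    image: np.ndarray | None = None  # (H, W, 3) grey/white/black rendering


@dataclass
class PcaProjection:
    score_images: np.ndarray  # (H, W, k)
    loadings: np.ndarray  # (p, k)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_pixels, k), aligned with feature rows


def pca_projection(features: FeatureMatrix, grid_shape: tuple[int, int], n_components: int = 3) -> PcaProjection:
    """Mean-centered PCA of the log-intensity feature matrix as score images.

    Intensities enter as log10(v + 1) so the tissue/background contrast —
    present across every ion — dominates PC1 instead of a handful of
    high-intensity ions; this is what makes PC1 usable as the tissue
    outline.  Component signs follow a deterministic convention: the loading
    of largest magnitude is made positive.
    """
    x = np.log10(np.asarray(features.values, dtype=float) + 1.0)
    if x.shape[0] < n_components or x.shape[1] < n_components:
        raise ValueError("need at least n_components pixels and peaks")
    if np.allclose(x.var(axis=0), 0):
        raise DegenerateInputError("feature matrix has zero variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    images = np.zeros((*grid_shape, n_components))
    images[features.coords[:, 1], features.coords[:, 0]] = scores
    return PcaProjection(
        score_images=images,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores,
    )


def tissue_mask_from_pca(pc1_image: np.ndarray, total_intensity_image: np.ndarray) -> np.ndarray:
    """Two-class Otsu threshold of the PC1 score image.

    The mask is oriented so the tissue class is the side with the higher mean
    total ion intensity, making the result invariant to the PC1 sign.
    """
    pc1 = np.asarray(pc1_image, dtype=float)
    if np.ptp(pc1) == 0:
        raise DegenerateInputError("constant PC1 image: cannot threshold")
    tot = np.asarray(total_intensity_image, dtype=float)
    # canonicalize the PC1 sign against total intensity so the result is
    # exactly invariant to the arbitrary sign of the component
    corr = np.corrcoef(pc1.ravel(), tot.ravel())[0, 1]
    if np.isfinite(corr) and corr < 0:
        pc1 = -pc1
    thr = threshold_otsu(pc1)
    high = pc1 > thr
    if not high.any() or high.all():
        raise DegenerateInputError("degenerate Otsu split")
    if tot[high].mean() >= tot[~high].mean():
        return high
    return ~high


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _warp_mask(hne_mask: np.ndarray, matrix: np.ndarray, out_shape: tuple[int, int], grid_pts: np.ndarray) -> np.ndarray:
    """Warp a histology-frame mask onto the MSI grid by inverse nearest-
    neighbor sampling (hole-free for any scale)."""
    inv = np.linalg.inv(matrix)
    src = np.rint(apply_matrix(inv, grid_pts)).astype(int)
    mh, mw = hne_mask.shape
    inside = (src[:, 0] >= 0) & (src[:, 0] < mw) & (src[:, 1] >= 0) & (src[:, 1] < mh)
    warped = np.zeros(out_shape[0] * out_shape[1], dtype=bool)
    warped[inside] = hne_mask[src[inside, 1], src[inside, 0]]
    return warped.reshape(out_shape)


def _grid_points(shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def _transformed_dice(hne_mask: np.ndarray, params: TransformParams, center, msi_mask: np.ndarray, grid_pts: np.ndarray) -> float:
    warped = _warp_mask(hne_mask, params_to_matrix(params, center), msi_mask.shape, grid_pts)
    return dice(warped, msi_mask)


def _candidate_key(p: TransformParams) -> tuple:
    # deterministic tie-break: smallest |rotation|, then |translation|, then
    # scale nearest 1, then lexicographic — equal-Dice ties resolve to the
    # least aggressive transform
    return (
        abs(p.rotation_deg),
        float(np.hypot(p.translate_x, p.translate_y)),
        abs(p.scale_x - 1.0) + abs(p.scale_y - 1.0),
        p.rotation_deg,
        p.scale_x,
        p.scale_y,
        p.translate_x,
        p.translate_y,
    )


def _local_candidates(seed: TransformParams, rot_span, scale_span, trans_span) -> list[TransformParams]:
    out = [seed]
    for rot in seed.rotation_deg + rot_span:
        for s in seed.scale_x + scale_span:
            if s <= 0:
                continue
            for dx in trans_span:
                for dy in trans_span:
                    out.append(
                        TransformParams(
                            scale_x=float(s),
                            scale_y=float(s),
                            rotation_deg=float(rot),
                            translate_x=seed.translate_x + float(dx),
                            translate_y=seed.translate_y + float(dy),
                        )
                    )
    return out


def register_mask(
    hne_tissue_mask: np.ndarray,
    msi_tissue_mask: np.ndarray,
    rotation_range_deg: float = 15.0,
    rotation_step_deg: float = 3.0,
    scale_min: float = 0.5,
    scale_max: float = 2.0,
    scale_step: float = 0.05,
    max_translation_frac: float = 0.25,
    min_dice: float = 0.7,
    n_starts: int = 5,
) -> RegistrationTransform:
    """Find the similarity transform maximizing tissue-mask overlap.

    A coarse grid over rotation and isotropic scale (translation seeded by
    centroid alignment, then searched locally) is followed by two rounds of
    local refinement around each of the ``n_starts`` best coarse candidates
    — the Dice landscape of quantized masks is multi-modal, so a single
    basin is not trusted.  Ties break deterministically in favor of the
    smaller rotation, then translation, then scale nearest 1.  Raises
    :class:`RegistrationError` when the best Dice falls below ``min_dice``.
    """
    hne = np.asarray(hne_tissue_mask, bool)
    msi = np.asarray(msi_tissue_mask, bool)
    if not hne.any() or not msi.any():
        raise ValueError("both masks must contain tissue pixels")
    h, w = msi.shape
    center = grid_center(hne.shape)
    ys, xs = np.nonzero(hne)
    c_hne = np.array([xs.mean(), ys.mean()])
    ys_m, xs_m = np.nonzero(msi)
    c_msi = np.array([xs_m.mean(), ys_m.mean()])
    grid_pts = _grid_points(msi.shape)
    t_max = max_translation_frac * max(h, w)

    def evaluate(cands: list[TransformParams]) -> list[tuple[float, TransformParams]]:
        """Score candidates; return them sorted best-first, deterministically."""
        scored = []
        for p in sorted(cands, key=_candidate_key):
            if abs(p.translate_x) > t_max or abs(p.translate_y) > t_max:
                continue
            scored.append((_transformed_dice(hne, p, center, msi, grid_pts), p))
        if not scored:
            raise RegistrationError("no admissible transform candidate")
        # stable sort: equal-Dice ties keep the candidate-key order
        scored.sort(key=lambda t: -t[0])
        return scored

    rotations = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, rotation_step_deg)
    scales = np.arange(scale_min, scale_max + 1e-9, scale_step)
    coarse: list[TransformParams] = [TransformParams()]
    for rot in rotations:
        for s in scales:
            base = TransformParams(scale_x=float(s), scale_y=float(s), rotation_deg=float(rot))
            m = params_to_matrix(base, center)
            t0 = c_msi - apply_matrix(m, c_hne[None, :])[0]
            for dx in (-2.0, -1.0, 0.0, 1.0, 2.0):
                for dy in (-2.0, -1.0, 0.0, 1.0, 2.0):
                    coarse.append(
                        TransformParams(
                            scale_x=float(s),
                            scale_y=float(s),
                            rotation_deg=float(rot),
                            translate_x=float(t0[0] + dx),
                            translate_y=float(t0[1] + dy),
                        )
                    )
    ranked = evaluate(coarse)

    # keep the best candidate from each of the n_starts best (rotation, scale)
    # cells so the refinement explores distinct basins
    seeds: list[TransformParams] = []
    seen_cells = set()
    for _d, p in ranked:
        cell = (round(p.rotation_deg, 6), round(p.scale_x, 6))
        if cell not in seen_cells:
            seen_cells.add(cell)
            seeds.append(p)
        if len(seeds) >= n_starts:
            break

    best_d, best = ranked[0]
    for seed in seeds:
        cand = seed
        for rot_span, scale_span, trans_span in (
            (np.arange(-2.5, 2.51, 0.5), np.arange(-0.04, 0.041, 0.02), np.arange(-1.0, 1.01, 0.5)),
            (np.arange(-0.5, 0.51, 0.25), np.arange(-0.02, 0.021, 0.01), np.arange(-0.5, 0.51, 0.25)),
        ):
            d, cand = evaluate(_local_candidates(cand, rot_span, scale_span, trans_span))[0]
        if d > best_d + 1e-12 or (
            abs(d - best_d) <= 1e-12 and _candidate_key(cand) < _candidate_key(best)
        ):
            best_d, best = d, cand
    if best_d < min_dice:
        raise RegistrationError(
            f"registration failed: best Dice {best_d:.3f} below the acceptance floor {min_dice}"
        )
    return RegistrationTransform(
        scale_x=best.scale_x,
        scale_y=best.scale_y,
        rotation_deg=best.rotation_deg,
        translate_x=best.translate_x,
        translate_y=best.translate_y,
        overlap_score=float(best_d),
    )


def transfer_labels(
    mask: AnnotationMask,
    transform: RegistrationTransform,
    grid_shape: tuple[int, int],
) -> np.ndarray:
    """Pull annotation labels onto the MSI grid (nearest neighbor).

    Each MSI pixel inherits the label at its inverse-transformed coordinate
    in the mask frame; coordinates falling outside the mask become Unlabeled.
    """
    h, w = grid_shape
    inv = np.linalg.inv(transform.matrix(mask.shape))
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = np.rint(apply_matrix(inv, pts)).astype(int)
    mh, mw = mask.shape
    inside = (src[:, 0] >= 0) & (src[:, 0] < mw) & (src[:, 1] >= 0) & (src[:, 1] < mh)
    labels = np.full(h * w, UNLABELED, dtype=np.uint8)
    labels[inside] = mask.labels[src[inside, 1], src[inside, 0]]
    return labels.reshape(h, w)


def coregistration_report(
    hne_tissue_mask: np.ndarray,
    msi_tissue_mask: np.ndarray,
    transform: RegistrationTransform,
) -> CoregistrationReport:
    """Count pixels in both / H&E-only / MSI-only after transforming the
    H&E mask, and render the grey/white/black overlay."""
    hne = np.asarray(hne_tissue_mask, bool)
    msi = np.asarray(msi_tissue_mask, bool)
    h, w = msi.shape
    warped = _warp_mask(hne, transform.matrix(hne.shape), (h, w), _grid_points((h, w)))
    both = warped & msi
    image = np.zeros((h, w, 3), dtype=np.uint8)
    image[both] = (128, 128, 128)  # grey: in both
    image[warped & ~msi] = (255, 255, 255)  # white: H&E only
    image[msi & ~warped] = (0, 0, 0)  # black: MSI only (on black background)
    return CoregistrationReport(
        n_both=int(both.sum()),
        n_hne_only=int((warped & ~msi).sum()),
        n_msi_only=int((msi & ~warped).sum()),
        image=image,
    )
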