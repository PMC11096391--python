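"""Reading and writing the formats the pipeline touches.

imzML/ibd pairs (via pyimzml), indexed-PNG annotation masks with a JSON
sidecar mapping palette index to class name, rendered prediction images, and
tabular reports.  Internal pixel coordinates are 0-based with origin top-left
(x = column, y = row); imzML's 1-based convention is converted here and
nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

# Fixed class vocabulary.  Tumor/Non-tumor/Background are annotation classes;
# Unlabeled marks mask pixels without annotation; Unclassified is the
# prediction-only fallback state when no scaled probability exceeds 0.5.
BACKGROUND = 0
TUMOR = 1
NONTUMOR = 2
UNLABELED = 3
UNCLASSIFIED = 4

CLASS_NAMES = {
    BACKGROUND: "Background",
    TUMOR: "Tumor",
    NONTUMOR: "Non-tumor",
    UNLABELED: "Unlabeled",
    UNCLASSIFIED: "Unclassified",
}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

# Display palette: Tumor red, Non-tumor green, Background blue (masks) /
# black (predictions), Unlabeled grey, Unclassified white.
MASK_PALETTE = {
    BACKGROUND: (0, 0, 255),
    TUMOR: (255, 0, 0),
    NONTUMOR: (0, 255, 0),
    UNLABELED: (128, 128, 128),
}
PREDICTION_PALETTE = {
    BACKGROUND: (0, 0, 0),
    TUMOR: (255, 0, 0),
    NONTUMOR: (0, 255, 0),
    UNCLASSIFIED: (255, 255, 255),
    UNLABELED: (128, 128, 128),
}


class FormatError(ValueError):
    """Raised when a file violates the declared format contract."""


@dataclass
class MsiDataset:
    """Pixel-indexed collection of centroided spectra on an integer grid.

    Parameters
    ----------
    coords
        (n_pixels, 2) integer array of (x, y) positions, 0-based,
        origin top-left.
    mzs, intensities
        Per-pixel parallel arrays; each ``mzs[i]`` is strictly ascending and
        ``intensities[i]`` is non-negative with the same length.
    """

    coords: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    pixel_size_um: float = 50.0
    mz_min: float = 300.0
    mz_max: float = 1000.0
    source_id: str = ""

    @property
    def n_pixels(self) -> int:
        return len(self.mzs)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid."""
        return int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1

    def validate(self) -> None:
        coords = np.asarray(self.coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise FormatError("coords must be an (n, 2) array")
        if len({(int(x), int(y)) for x, y in coords}) != len(coords):
            raise FormatError("pixel coordinates are not unique")
        if not (len(self.mzs) == len(self.intensities) == len(coords)):
            raise FormatError("coords, mzs and intensities must be parallel")
        for i, (mz, inten) in enumerate(zip(self.mzs, self.intensities)):
            if len(mz) != len(inten):
                raise FormatError(f"pixel {i}: mz/intensity length mismatch")
            if len(mz) and np.any(np.diff(mz) <= 0):
                raise FormatError(f"pixel {i}: m/z axis not strictly ascending")
            if len(mz) and (mz[0] < self.mz_min - 1e-6 or mz[-1] > self.mz_max + 1e-6):
                raise FormatError(f"pixel {i}: m/z outside [{self.mz_min}, {self.mz_max}]")
            if len(inten) and np.any(np.asarray(inten) < 0):
                raise FormatError(f"pixel {i}: negative intensity")

    def image_from_values(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-pixel value vector onto the (H, W) grid."""
        img = np.full(self.grid_shape, fill, dtype=float)
        img[self.coords[:, 1], self.coords[:, 0]] = values
        return img


@dataclass
class AnnotationMask:
    """Label image over the fixed class vocabulary.

    ``frame`` records whether the mask lives in the histology ("hne") frame or
    on the MSI grid ("msi").
    """

    labels: np.ndarray  # (H, W) integer codes
    frame: str = "hne"
    class_palette: dict = field(default_factory=lambda: dict(MASK_PALETTE))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise FormatError("mask label image must be 2-D")
        known = set(MASK_PALETTE)
        if not set(np.unique(self.labels)) <= known:
            raise FormatError("mask contains labels outside the fixed vocabulary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of non-Background pixels (Unlabeled counts as tissue)."""
        return self.labels != BACKGROUND


def write_imzml(dataset: MsiDataset, path: str | Path) -> Path:
    """Write a processed-mode imzML/ibd pair (m/z float64, intensity float32)."""
    if dataset.n_pixels == 0:
        raise FormatError("refusing to write an empty dataset")
    dataset.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(
        str(path),
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        mode="processed",
        spec_type="centroid",
        polarity="negative",
    ) as writer:
        for (x, y), mz, inten in zip(dataset.coords, dataset.mzs, dataset.intensities):
            if len(mz) == 0:
                raise FormatError(f"pixel ({int(x)}, {int(y)}): cannot write an empty spectrum")
            # imzML coordinates are 1-based
            writer.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (int(x) + 1, int(y) + 1))
    return path


def read_imzml(path: str | Path) -> MsiDataset:
    """Read an imzML/ibd pair (continuous or processed mode) into an MsiDataset."""
    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing ibd file for {path}")
    parser = ImzMLParser(str(path))
    coords, mzs, intens = [], [], []
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if len(mz) and np.any(np.diff(mz) <= 0):
            raise FormatError(f"pixel at imzML coordinate ({x}, {y}): non-ascending m/z")
        coords.append((x - 1, y - 1))
        mzs.append(mz)
        intens.append(inten)
    coords = np.asarray(coords, dtype=int)
    pix = parser.imzmldict.get("pixel size x", 50.0) or 50.0
    all_mz = [m for m in mzs if len(m)]
    mz_lo = min((m[0] for m in all_mz), default=0.0)
    mz_hi = max((m[-1] for m in all_mz), default=0.0)
    ds = MsiDataset(
        coords=coords,
        mzs=mzs,
        intensities=intens,
        pixel_size_um=float(pix),
        mz_min=float(mz_lo),
        mz_max=float(mz_hi),
        source_id=path.stem,
    )
    ds.validate()
    return ds


def write_mask(mask: AnnotationMask, path: str | Path) -> Path:
    """Write an indexed PNG plus a JSON sidecar mapping index -> class name."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(mask.labels, mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    for code, rgb in mask.class_palette.items():
        palette[code] = rgb
    img.putpalette(palette.flatten().tolist())
    img.save(path)
    sidecar = {
        "frame": mask.frame,
        "classes": {str(code): CLASS_NAMES[code] for code in mask.class_palette},
        "palette": {str(code): list(rgb) for code, rgb in mask.class_palette.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_mask(path: str | Path) -> AnnotationMask:
    """Read a mask written by :func:`write_mask` (lossless round-trip)."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar JSON for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    for code in np.unique(labels):
        if str(int(code)) not in sidecar["classes"]:
            raise FormatError(f"mask index {int(code)} not declared in sidecar")
        if sidecar["classes"][str(int(code))] not in CLASS_CODES:
            raise FormatError(f"unknown class name {sidecar['classes'][str(int(code))]!r}")
    palette = {int(c): tuple(rgb) for c, rgb in sidecar.get("palette", {}).items()}
    return AnnotationMask(labels=labels, frame=sidecar.get("frame", "hne"), class_palette=palette or dict(MASK_PALETTE))


def render_class_image(class_image: np.ndarray, palette: dict | None = None) -> np.ndarray:
    """Render an (H, W) class-code image to (H, W, 3) uint8 RGB."""
    palette = palette or PREDICTION_PALETTE
    rgb = np.zeros((*class_image.shape, 3), dtype=np.uint8)
    for code, color in palette.items():
        rgb[class_image == code] = color
    return rgb


def write_prediction_image(pred, path: str | Path) -> Path:
    """Render a prediction to PNG: Tumor red, Non-tumor green, Background
    black, Unclassified white; dimensions equal the MSI grid."""
    class_image = pred.class_image if hasattr(pred, "class_image") else np.asarray(pred)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(render_class_image(class_image)).save(path)
    return path
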