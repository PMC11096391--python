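"""Similarity transforms on pixel grids.

A transform is parameterized by (scale_x, scale_y, rotation_deg, translate_x,
translate_y) and acts about a fixed center point, conventionally the grid
center ((W-1)/2, (H-1)/2).  Internally everything is a 3x3 homogeneous
matrix in (x, y) = (column, row) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TransformParams:
    """Similarity-transform parameters acting about a grid center."""

    scale_x: float = 1.0
    scale_y: float = 1.0
    rotation_deg: float = 0.0
    translate_x: float = 0.0
    translate_y: float = 0.0

    def is_identity(self, atol: float = 1e-12) -> bool:
        return (
            abs(self.scale_x - 1.0) <= atol
            and abs(self.scale_y - 1.0) <= atol
            and abs(self.rotation_deg) <= atol
            and abs(self.translate_x) <= atol
            and abs(self.translate_y) <= atol
        )

    def to_dict(self) -> dict:
        return {
            "scale_x": self.scale_x,
            "scale_y": self.scale_y,
            "rotation_deg": self.rotation_deg,
            "translate_x": self.translate_x,
            "translate_y": self.translate_y,
        }


def grid_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Center (cx, cy) of an (H, W) grid in x=column, y=row coordinates."""
    h, w = shape
    return (w - 1) / 2.0, (h - 1) / 2.0


def params_to_matrix(params: TransformParams, center: tuple[float, float]) -> np.ndarray:
    """Homogeneous matrix: p -> S R (p - c) + c + t."""
    cx, cy = center
    th = np.deg2rad(params.rotation_deg)
    ct, st = np.cos(th), np.sin(th)
    sr = np.array([[params.scale_x * ct, -params.scale_x * st], [params.scale_y * st, params.scale_y * ct]])
    offset = np.array([cx + params.translate_x, cy + params.translate_y]) - sr @ np.array([cx, cy])
    m = np.eye(3)
    m[:2, :2] = sr
    m[:2, 2] = offset
    return m


def matrix_to_params(m: np.ndarray, center: tuple[float, float]) -> TransformParams:
    """Decompose a similarity matrix (possibly anisotropic) back to parameters.

    Rotation is taken from the first column; anisotropic scale + rotation is
    recovered exactly for matrices built by :func:`params_to_matrix`.
    """
    a = m[:2, :2]
    rot = np.arctan2(a[1, 0], a[0, 0])
    ct, st = np.cos(rot), np.sin(rot)
    # a = [[sx ct, -sx st], [sy st, sy ct]]
    if abs(ct) >= abs(st):
        sx, sy = a[0, 0] / ct, a[1, 1] / ct
    else:
        sx, sy = a[1, 0] / st, -a[0, 1] / st
    cx, cy = center
    c = np.array([cx, cy])
    t = a @ c + m[:2, 2] - c
    return TransformParams(
        scale_x=float(sx),
        scale_y=float(sy),
        rotation_deg=float(np.rad2deg(rot)),
        translate_x=float(t[0]),
        translate_y=float(t[1]),
    )


def apply_matrix(m: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Apply a homogeneous matrix to an (n, 2) array of (x, y) points."""
    xy = np.asarray(xy, dtype=float)
    return xy @ m[:2, :2].T + m[:2, 2]


def invert_params(params: TransformParams, center: tuple[float, float]) -> TransformParams:
    return matrix_to_params(np.linalg.inv(params_to_matrix(params, center)), center)
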