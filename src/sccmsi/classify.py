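"""One-vs-rest logistic classification with a scaled-probability decision rule.

Feature vectors are normalized by log10(v + 1) followed by division by the
spectrum's Euclidean (L2) norm.  Three binary L2-penalized logistic problems
are trained by Newton iteration (IRLS): Tumor vs rest, Tissue vs Background,
and Non-tumor vs rest.  Their scores are fused into per-class scaled
probabilities that sum to one; a pixel is assigned the class whose scaled
probability exceeds 0.5 and remains Unclassified when none does.  The Tumor
problem's coefficients, oriented so negative means tumor-upregulated, rank
the ions by importance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sccmsi.msi_io import BACKGROUND, CLASS_NAMES, NONTUMOR, TUMOR, UNCLASSIFIED, UNLABELED
from sccmsi.preprocess import FeatureMatrix

# the three classification problems, each named by its positive class(es)
PROBLEM_TUMOR = "tumor_vs_rest"  # Tumor vs Non-tumor + Background
PROBLEM_TISSUE = "tissue_vs_background"  # Tumor + Non-tumor vs Background
PROBLEM_NONTUMOR = "nontumor_vs_rest"  # Non-tumor vs Tumor + Background
PROBLEM_POSITIVES = {
    PROBLEM_TUMOR: (TUMOR,),
    PROBLEM_TISSUE: (TUMOR, NONTUMOR),
    PROBLEM_NONTUMOR: (NONTUMOR,),
}


class TrainingError(ValueError):
    """Raised when the labelled data cannot support the requested fit."""


@dataclass
class LogisticModel:
    weights: np.ndarray
    intercept: float
    positive_classes: tuple[int, ...] = ()
    converged: bool = True
    n_iter: int = 0

    def decision(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weights + self.intercept

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(x))


@dataclass
class OvrClassifier:
    """Three binary logistic models plus the scaled-probability fusion rule."""

    feature_mzs: np.ndarray
    problems: dict[str, LogisticModel]
    l2_lambda: float = 1e-2
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for name, model in self.problems.items():
            if len(model.weights) != len(self.feature_mzs):
                raise ValueError(f"problem {name}: weight length != number of features")

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "feature_mzs": np.asarray(self.feature_mzs).tolist(),
            "l2_lambda": self.l2_lambda,
            "threshold": self.threshold,
            "problems": {
                name: {
                    "weights": m.weights.tolist(),
                    "intercept": m.intercept,
                    "positive_classes": [CLASS_NAMES[c] for c in m.positive_classes],
                }
                for name, m in self.problems.items()
            },
        }
        path = Path(path)
        path.write_text(json.dumps(payload, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "OvrClassifier":
        payload = json.loads(Path(path).read_text())
        name_to_code = {v: k for k, v in CLASS_NAMES.items()}
        problems = {
            name: LogisticModel(
                weights=np.asarray(m["weights"], float),
                intercept=float(m["intercept"]),
                positive_classes=tuple(name_to_code[c] for c in m["positive_classes"]),
            )
            for name, m in payload["problems"].items()
        }
        return cls(
            feature_mzs=np.asarray(payload["feature_mzs"], float),
            problems=problems,
            l2_lambda=float(payload["l2_lambda"]),
            threshold=float(payload["threshold"]),
        )


@dataclass
class PredictionImage:
    """Per-pixel class map plus the scaled class probabilities."""

    class_image: np.ndarray  # (H, W) codes incl. UNCLASSIFIED
    scaled_probabilities: np.ndarray  # (H, W, 3): Tumor, Non-tumor, Background

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_image.shape


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def normalize(features):
    """log10(v + 1) then division by each spectrum's Euclidean norm.

    Accepts a raw array or a :class:`FeatureMatrix`; all-zero rows are left
    as zeros and flagged.  Returns (normalized, zero_row_mask) for arrays, or
    a new FeatureMatrix with ``zero_rows`` set.
    """
    if isinstance(features, FeatureMatrix):
        values, zero = normalize(features.values)
        return FeatureMatrix(
            coords=features.coords.copy(),
            mzs=features.mzs.copy(),
            values=values,
            tissue_flags=None if features.tissue_flags is None else features.tissue_flags.copy(),
            zero_rows=zero,
        )
    v = np.asarray(features, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative intensities cannot be normalized")
    logged = np.log10(v + 1.0)
    norms = np.linalg.norm(logged, axis=-1, keepdims=True)
    zero = norms[..., 0] == 0
    safe = np.where(norms == 0, 1.0, norms)
    return logged / safe, zero


def penalized_loss(x: np.ndarray, y: np.ndarray, weights: np.ndarray, intercept: float, l2_lambda: float) -> float:
    """L2-penalized binomial negative log-likelihood (intercept unpenalized)."""
    z = x @ weights + intercept
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    return nll + 0.5 * l2_lambda * float(weights @ weights)


def train_logistic(
    x: np.ndarray,
    y: np.ndarray,
    l2_lambda: float = 1e-2,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
) -> LogisticModel:
    """Newton / IRLS fit of an L2-penalized logistic model from zero start.

    Minimizes the penalized binomial negative log-likelihood with the
    intercept unpenalized; converged when the gradient's max-norm drops below
    ``grad_tol``.  Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or len(y) != x.shape[0]:
        raise ValueError("x must be (n, p) with matching y")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    n, p = x.shape
    beta = np.zeros(p + 1)  # [weights..., intercept]
    xe = np.column_stack([x, np.ones(n)])
    pen = np.full(p + 1, l2_lambda)
    pen[-1] = 0.0
    loss = penalized_loss(x, y, beta[:p], beta[p], l2_lambda)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = xe @ beta
        prob = _sigmoid(z)
        grad = xe.T @ (prob - y) + pen * beta
        if np.max(np.abs(grad)) < grad_tol:
            n_iter -= 1
            break
        s = np.clip(prob * (1.0 - prob), 1e-12, None)
        hess = xe.T @ (xe * s[:, None]) + np.diag(pen)
        step = np.linalg.solve(hess + 1e-12 * np.eye(p + 1), grad)
        # damped Newton: halve until the penalized loss does not increase
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            cand_loss = penalized_loss(x, y, cand[:p], cand[p], l2_lambda)
            if cand_loss <= loss + 1e-12:
                break
            t *= 0.5
        beta, loss = cand, cand_loss
    z = xe @ beta
    grad = xe.T @ (_sigmoid(z) - y) + pen * beta
    converged = bool(np.max(np.abs(grad)) < grad_tol)
    if not converged:
        warnings.warn(
            f"logistic fit did not converge: max|grad| = {np.max(np.abs(grad)):.3g}",
            stacklevel=2,
        )
    return LogisticModel(weights=beta[:p], intercept=float(beta[p]), converged=converged, n_iter=n_iter)


def train_ovr(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    feature_mzs: np.ndarray | None = None,
    l2_lambda: float = 1e-2,
    threshold: float = 0.5,
) -> OvrClassifier:
    """Train the three one-vs-rest problems on normalized labelled pixels.

    ``labels`` are class codes aligned with the feature rows; Unlabeled rows
    are dropped.  All three classes must be present.
    """
    if isinstance(features, FeatureMatrix):
        raw = features.values
        feature_mzs = features.mzs
    else:
        raw = np.asarray(features, float)
        if feature_mzs is None:
            feature_mzs = np.arange(raw.shape[1], dtype=float)
    labels = np.asarray(labels).ravel()
    keep = labels != UNLABELED
    raw, labels = raw[keep], labels[keep]
    for cls in (TUMOR, NONTUMOR, BACKGROUND):
        if not np.any(labels == cls):
            raise TrainingError(f"class {CLASS_NAMES[cls]!r} missing from the labelled data")
    x, _ = normalize(raw)
    problems = {}
    for name, positives in PROBLEM_POSITIVES.items():
        y = np.isin(labels, positives).astype(float)
        model = train_logistic(x, y, l2_lambda=l2_lambda)
        model.positive_classes = positives
        problems[name] = model
    return OvrClassifier(feature_mzs=np.asarray(feature_mzs, float), problems=problems, l2_lambda=l2_lambda, threshold=threshold)


def fuse_scores(s_tumor: np.ndarray, s_nontumor: np.ndarray, s_background: np.ndarray) -> np.ndarray:
    """Renormalize raw per-class scores into scaled probabilities summing to 1.

    A degenerate all-zero triple maps to the uniform distribution (and hence
    to Unclassified under the 0.5 rule).
    """
    raw = np.stack(np.broadcast_arrays(s_tumor, s_nontumor, s_background), axis=-1).astype(float)
    if np.any(raw < 0):
        raise ValueError("raw scores must be non-negative")
    total = raw.sum(axis=-1, keepdims=True)
    out = np.where(total > 0, raw / np.where(total == 0, 1.0, total), 1.0 / 3.0)
    return out


def scaled_probabilities(classifier: OvrClassifier, x_norm: np.ndarray) -> np.ndarray:
    """Scaled (Tumor, Non-tumor, Background) probabilities for normalized rows.

    Raw scores: sigma from the Tumor and Non-tumor problems; Background's
    score is the complement of the Tissue-vs-Background sigma.
    """
    x_norm = np.atleast_2d(np.asarray(x_norm, float))
    s_t = classifier.problems[PROBLEM_TUMOR].predict_proba(x_norm)
    s_n = classifier.problems[PROBLEM_NONTUMOR].predict_proba(x_norm)
    s_b = 1.0 - classifier.problems[PROBLEM_TISSUE].predict_proba(x_norm)
    return fuse_scores(s_t, s_n, s_b)


def decide(scaled: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Class decision: argmax class iff its scaled probability exceeds the
    threshold, otherwise Unclassified."""
    scaled = np.asarray(scaled, float)
    codes = np.array([TUMOR, NONTUMOR, BACKGROUND], dtype=np.uint8)
    arg = scaled.argmax(axis=-1)
    out = codes[arg]
    out = np.where(np.take_along_axis(scaled, arg[..., None], axis=-1)[..., 0] > threshold, out, UNCLASSIFIED)
    return out.astype(np.uint8)


def predict_image(
    classifier: OvrClassifier,
    features: FeatureMatrix,
    grid_shape: tuple[int, int] | None = None,
) -> PredictionImage:
    """Classify every pixel and render the result onto the MSI grid."""
    if grid_shape is None:
        grid_shape = (int(features.coords[:, 1].max()) + 1, int(features.coords[:, 0].max()) + 1)
    x, _ = normalize(features.values)
    scaled = scaled_probabilities(classifier, x)
    classes = decide(scaled, classifier.threshold)
    class_image = np.full(grid_shape, BACKGROUND, dtype=np.uint8)
    prob_image = np.zeros((*grid_shape, 3))
    class_image[features.coords[:, 1], features.coords[:, 0]] = classes
    prob_image[features.coords[:, 1], features.coords[:, 0]] = scaled
    return PredictionImage(class_image=class_image, scaled_probabilities=prob_image)


def rank_coefficients(classifier: OvrClassifier, top_n: int = 50) -> pd.DataFrame:
    """Rank ions by Tumor-problem coefficient magnitude.

    Reported coefficients are oriented from the stored class coding so that a
    negative value means upregulated in tumor regions.  Ties are broken by
    ascending m/z.
    """
    model = classifier.problems[PROBLEM_TUMOR]
    # internal coding: positive class = Tumor, so positive weight = tumor-up;
    # flip sign for the reporting convention (negative => tumor-up)
    sign = -1.0 if model.positive_classes == (TUMOR,) else 1.0
    coefs = sign * np.asarray(model.weights, float)
    if np.allclose(coefs, 0):
        warnings.warn("all coefficients are zero: empty ranking", stacklevel=2)
        return pd.DataFrame(columns=["mz", "coefficient", "direction"])
    df = pd.DataFrame({"mz": classifier.feature_mzs, "coefficient": coefs})
    df["direction"] = np.where(df["coefficient"] < 0, "tumor-up", "tumor-down")
    df = df.sort_values(["mz"]).sort_values("coefficient", key=np.abs, ascending=False, kind="stable")
    return df.head(top_n).reset_index(drop=True)
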