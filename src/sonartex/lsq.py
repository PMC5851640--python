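"""Linear least-squares unmixing classifier.

Each window's observed texture vector ``o`` is modelled as a non-negative
mixture of the calibrated class signatures (columns of C, features as rows):

    u* = argmin_u || C_z u - o_z ||^2   subject to u >= 0, sum(u) = 1

where the ``_z`` subscript denotes z-scoring by the per-feature spread of the
calibration signatures, so entropy, H' and GLCM variance contribute on
comparable scales.  ``u_q`` is read as the proportion of variance explained
by substrate ``q``; the simplex constraint makes the fractions identifiable
even though the class signatures are nearly collinear in (E, H') — without
it any window could be "explained" by a scaled copy of a single signature.  The confidence of substrate ``q`` is

    alpha_q = u_q / sum_{n != q} (1 - u_n)

which, since sum(u) = 1, equals ``u_q / (q - 2 + u_q)`` for q classes.  For
three classes a uniform ``u`` gives alpha = 0.25 for every class, and a pure
end-member gives alpha = 0.5 — alpha never reaches 1 for q >= 3.  A window is
indeterminate (null substrate) when every alpha lies strictly inside the open
band (0.15, 0.25).

Per-class weights ``w`` (sum 1) bias the mixture, ``u'_q`` proportional to
``w_q u_q`` renormalised; they are fitted by exhaustive search of the weight
simplex in fixed increments, maximising balanced (mean per-class) accuracy.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from sonartex.maps import NODATA, NULL, ClassificationMap
from sonartex.raster_io import SubstratePolygonSet
from sonartex.signatures import CalibrationMatrix, windows_by_class
from sonartex.texture import TextureGrid

INDETERMINATE_BAND = (0.15, 0.25)


class ConditioningWarning(UserWarning):
    """Calibration matrix is rank-deficient after standardization."""


@dataclass
class LsqModel:
    calibration: CalibrationMatrix
    weights: np.ndarray | None = None
    indeterminate_band: tuple[float, float] = INDETERMINATE_BAND

    def __post_init__(self) -> None:
        q = len(self.calibration.class_names)
        if self.weights is None:
            self.weights = np.full(q, 1.0 / q)
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != (q,) or (self.weights < 0).any():
            raise ValueError("weights must be non-negative, one per class")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        lo, hi = self.indeterminate_band
        if not lo < hi:
            raise ValueError("indeterminate band must have lower < upper")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "calibration": json.loads(
                        json.dumps(
                            {
                                "class_names": list(self.calibration.class_names),
                                "feature_names": list(self.calibration.feature_names),
                                "C": self.calibration.C.tolist(),
                                "ci_low": np.asarray(self.calibration.ci_low).tolist(),
                                "ci_high": np.asarray(self.calibration.ci_high).tolist(),
                                "B": self.calibration.B,
                                "seed": self.calibration.seed,
                            }
                        )
                    ),
                    "weights": self.weights.tolist(),
                    "indeterminate_band": list(self.indeterminate_band),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LsqModel":
        d = json.loads(Path(path).read_text())
        c = d["calibration"]
        cal = CalibrationMatrix(
            C=np.array(c["C"]),
            ci_low=np.array(c["ci_low"]),
            ci_high=np.array(c["ci_high"]),
            class_names=tuple(c["class_names"]),
            feature_names=tuple(c["feature_names"]),
            B=c["B"],
            seed=c.get("seed"),
        )
        return cls(
            calibration=cal,
            weights=np.array(d["weights"]),
            indeterminate_band=tuple(d["indeterminate_band"]),
        )


@dataclass(frozen=True)
class LsqResult:
    o: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    label: int  # index into class names, or NULL


def lsq_unmix(o: np.ndarray, calibration: CalibrationMatrix) -> np.ndarray:
    """Variance-explained fractions ``u`` of one observed feature vector.

    Solves the simplex-constrained least-squares mixing problem by NNLS on a
    penalty-augmented system (a sum-to-one row weighted far above the data
    rows), then renormalises exactly.
    """
    o = np.asarray(o, float)
    scale = calibration.feature_scale()
    A = (calibration.C / scale).T  # features x classes, z-scored
    b = o / scale
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn(
            "calibration signatures are linearly dependent after scaling",
            ConditioningWarning,
        )
    rho = 1e4 * max(1.0, float(np.abs(A).max()))
    A_aug = np.vstack([A, rho * np.ones(A.shape[1])])
    b_aug = np.append(b, rho)
    f, _ = nnls(A_aug, b_aug)
    s = f.sum()
    if s == 0:
        return np.full(A.shape[1], 1.0 / A.shape[1])
    return f / s


def lsq_confidence(u: np.ndarray) -> np.ndarray:
    """Confidence ``alpha_q = u_q / sum_{n != q} (1 - u_n)``, literally."""
    u = np.asarray(u, float)
    q = u.size
    if q < 2:
        raise ValueError("confidence undefined for fewer than 2 classes")
    denom = np.array([(1.0 - np.delete(u, k)).sum() for k in range(q)])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(denom > 0, u / denom, np.where(u > 0, np.inf, 0.0))
    return alpha


def _apply_weights(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    uw = w * u
    s = uw.sum()
    return uw / s if s > 0 else np.full_like(u, 1.0 / u.size)


def _classify_u(u: np.ndarray, band: tuple[float, float]) -> tuple[int, float]:
    # the band is an open interval: alpha exactly at 0.25 (uniform u) is NOT
    # indeterminate; the epsilon guards the boundary against float round-off.
    # For u exactly on the simplex max(alpha) >= 0.25 always, so the null
    # label can only fire when upstream confidences are perturbed off it.
    alpha = lsq_confidence(u)
    lo, hi = band
    eps = 1e-9
    if bool(np.all((alpha > lo + eps) & (alpha < hi - eps))):
        return NULL, float(alpha.max())
    k = int(np.argmax(alpha))
    return k, float(alpha[k])


def classify_lsq(tex: TextureGrid, model: LsqModel) -> ClassificationMap:
    """Classify every defined window by weighted unmixing.

    Labels are the argmax-alpha class, or null when every alpha falls
    strictly inside the indeterminate band; undefined windows are nodata.
    """
    cal = model.calibration
    X, idx = tex.feature_matrix(cal.feature_names)
    labels = np.full(tex.shape, NODATA, int).ravel()
    conf = np.full(tex.shape, np.nan).ravel()
    for o, flat in zip(X, idx):
        u = _apply_weights(lsq_unmix(o, cal), model.weights)
        labels[flat], conf[flat] = _classify_u(u, model.indeterminate_band)
    return ClassificationMap(
        labels=labels.reshape(tex.shape),
        confidence=conf.reshape(tex.shape),
        class_names=cal.class_names,
        grid=tex,
        null_name="null",
    )


def _simplex_grid(q: int, increment: float) -> list[tuple[float, ...]]:
    steps = int(round(1.0 / increment))
    pts = []
    for combo in itertools.product(range(steps + 1), repeat=q - 1):
        if sum(combo) <= steps:
            last = steps - sum(combo)
            pts.append(tuple(c / steps for c in combo) + (last / steps,))
    return sorted(pts)


def optimize_weights(
    tex: TextureGrid,
    polys: SubstratePolygonSet,
    model: LsqModel,
    increment: float = 0.1,
    roles: Sequence[str] = ("calibration",),
) -> np.ndarray:
    """Exhaustive weight search maximising balanced accuracy.

    Evaluates every weight vector on the simplex at the given increment
    against the labeled windows.  Ties are broken deterministically in favour
    of the maximiser closest (L2) to uniform weights, then by lexicographic
    order — so when equal weighting already attains the maximum it is the
    vector returned.
    """
    cal = model.calibration
    truth = windows_by_class(tex, polys, roles=roles).ravel()
    X, idx = tex.feature_matrix(cal.feature_names)
    keep = truth[idx] >= 0
    if not keep.any():
        raise ValueError("no labeled windows to optimise against")
    X, y = X[keep], truth[idx][keep]
    U = np.array([lsq_unmix(o, cal) for o in X])

    q = len(cal.class_names)
    classes = np.unique(y)
    uniform = np.full(q, 1.0 / q)
    scored = []
    for w in _simplex_grid(q, increment):
        w_arr = np.asarray(w)
        pred = np.array(
            [_classify_u(_apply_weights(u, w_arr), model.indeterminate_band)[0] for u in U]
        )
        accs = [np.mean(pred[y == c] == c) for c in classes]
        scored.append((float(np.mean(accs)), w))
    best = max(s for s, _ in scored)
    ties = [w for s, w in scored if s >= best - 1e-12]
    ties.sort(key=lambda w: (float(np.sum((np.asarray(w) - uniform) ** 2)), w))
    return np.asarray(ties[0])
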