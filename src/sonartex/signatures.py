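"""Substrate signatures: zonal first-order statistics and the texture
calibration matrix.

The calibration matrix C has one column per substrate class and one row per
texture feature, each entry the bootstrapped median (B replicates, percentile
CI) of that feature over the class's windows.  Homogeneity is stored as
H' = 1 - H when requested so that every calibrated feature increases with
grain size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sonartex.raster_io import IntensityRaster, SubstratePolygonSet
from sonartex.texture import TextureGrid


class MissingClassError(ValueError):
    """A declared substrate class has no valid cells/windows."""


def zonal_first_order(
    raster: IntensityRaster,
    polys: SubstratePolygonSet,
    roles: Sequence[str] = ("calibration", "validation"),
) -> pd.DataFrame:
    """Per-class summary statistics of pooled intensity values.

    Values are aggregated across all patches of a class before computing
    statistics (never per-patch means of means).  CV is sigma/mean, kurtosis
    is Fisher (excess), skewness the standardized third moment.  Columns
    mirror the conventional substrate summary table: mean, sigma, cv, q25,
    q50, q75, kurtosis, skewness, n_patches.
    """
    ee, nn = raster.cell_centers()
    labels = polys.label_points(ee, nn, roles=roles)
    labels[~raster.valid_mask] = -1
    rows = []
    for ci, cname in enumerate(polys.vocabulary):
        vals = raster.values[labels == ci].astype(float)
        n_patches = sum(
            1
            for p in polys.polygons
            if p.role in roles and p.class_label == cname
        )
        if n_patches == 0:
            continue
        if vals.size == 0:
            raise MissingClassError(f"class {cname!r} covers no valid cells")
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        mean = vals.mean()
        sigma = vals.std(ddof=1) if vals.size > 1 else 0.0
        if sigma > 0:
            kurt = stats.kurtosis(vals, fisher=True, bias=True)
            skew = stats.skew(vals, bias=True)
        else:  # shape moments are undefined for a constant zone
            kurt = 0.0
            skew = 0.0
        rows.append(
            {
                "class": cname,
                "mean": mean,
                "sigma": sigma,
                "cv": sigma / mean if mean != 0 else np.nan,
                "q25": q25,
                "q50": q50,
                "q75": q75,
                "kurtosis": kurt,
                "skewness": skew,
                "n_patches": n_patches,
            }
        )
    if not rows:
        raise MissingClassError("no class has any patch")
    return pd.DataFrame(rows).set_index("class")


def bootstrap_median(
    values: np.ndarray,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap of the sample median.

    Returns ``(median, ci_low, ci_high)`` where the point estimate is the
    median of the B resampled medians and the CI the matching percentile
    interval.  Reproducible for a given seed.
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    if v.size < 2:
        return float(v[0]), float(v[0]), float(v[0])
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    meds = np.median(rng.choice(v, size=(B, v.size), replace=True), axis=1)
    lo, hi = np.percentile(meds, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(np.median(meds)), float(lo), float(hi)


@dataclass
class CalibrationMatrix:
    """Bootstrapped-median texture signatures per substrate class.

    ``C[k, f]`` is the signature of class ``class_names[k]`` for feature
    ``feature_names[f]``; ``ci_low``/``ci_high`` bound its 95 % interval.
    """

    C: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    B: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        if self.C.shape != (len(self.class_names), len(self.feature_names)):
            raise ValueError("C shape must be (classes, features)")
        if not np.isfinite(self.C).all():
            raise ValueError("calibration matrix must be finite")
        if not ((self.ci_low <= self.C + 1e-12) & (self.C <= self.ci_high + 1e-12)).all():
            raise ValueError("medians must lie within their CIs")

    def feature_scale(self) -> np.ndarray:
        """Per-feature spread across class signatures, used for z-scoring.

        Features with zero spread get scale 1 so they pass through unchanged.
        """
        s = self.C.std(axis=0, ddof=0)
        s[s == 0] = 1.0
        return s

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "class_names": list(self.class_names),
                    "feature_names": list(self.feature_names),
                    "C": self.C.tolist(),
                    "ci_low": np.asarray(self.ci_low).tolist(),
                    "ci_high": np.asarray(self.ci_high).tolist(),
                    "B": self.B,
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationMatrix":
        d = json.loads(Path(path).read_text())
        return cls(
            C=np.array(d["C"]),
            ci_low=np.array(d["ci_low"]),
            ci_high=np.array(d["ci_high"]),
            class_names=tuple(d["class_names"]),
            feature_names=tuple(d["feature_names"]),
            B=d["B"],
            seed=d.get("seed"),
        )


def windows_by_class(
    tex: TextureGrid,
    polys: SubstratePolygonSet,
    roles: Sequence[str] = ("calibration",),
) -> np.ndarray:
    """Class index per window by centroid containment; -1 where unlabeled
    or undefined."""
    ee, nn = tex.window_centers()
    labels = polys.label_points(ee, nn, roles=roles)
    labels[~tex.defined] = -1
    return labels


def build_calibration(
    tex: TextureGrid,
    polys: SubstratePolygonSet,
    features: Sequence[str] = ("E", "H_prime", "var_G"),
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    roles: Sequence[str] = ("calibration",),
) -> CalibrationMatrix:
    """Build the calibration matrix from labeled texture windows.

    A window belongs to a class iff its centroid lies in one of that class's
    polygons; each ``C`` entry is the bootstrap median of the feature over
    the class's windows.
    """
    labels = windows_by_class(tex, polys, roles=roles)
    classes = tuple(polys.vocabulary)
    rng = np.random.default_rng(seed)
    C = np.zeros((len(classes), len(features)))
    lo = np.zeros_like(C)
    hi = np.zeros_like(C)
    for ci, cname in enumerate(classes):
        sel = labels == ci
        if not sel.any():
            raise MissingClassError(f"class {cname!r} covers no defined window")
        for fi, fname in enumerate(features):
            vals = tex.features[fname][sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise MissingClassError(
                    f"class {cname!r} has no finite {fname!r} values"
                )
            C[ci, fi], lo[ci, fi], hi[ci, fi] = bootstrap_median(
                vals, B=B, level=level, seed=rng
            )
    return CalibrationMatrix(
        C=C,
        ci_low=lo,
        ci_high=hi,
        class_names=classes,
        feature_names=tuple(features),
        B=B,
        seed=seed,
    )
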