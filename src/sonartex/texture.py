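"""Windowed grey-level co-occurrence matrix (GLCM) texture features.

An echogram's texture encodes grain size: smooth, ordered backscatter
patterns come from sand (sub-pixel features), disordered high-contrast
patterns from boulders (supra-pixel features).  The GLCM tabulates how often
grey-level pairs ``(i, j)`` occur at a fixed pixel offset (search distance
``d``, reference angle ``theta``) inside a computational window; normalised
to probabilities ``P(i, j)`` it supports scalar texture descriptors:

* homogeneity  ``H  = sum P(i,j) / (1 + (i - j)^2)``  (contrast-inverse; high for sand)
* entropy      ``E  = -sum P(i,j) ln P(i,j)``         (disorder; high for boulders)
* GLCM mean    ``mu_G = sum i P(i,j)``
* GLCM variance ``var_G = sum (i - mu_G)^2 P(i,j)``
* GLCM correlation over the i/j marginals (standard co-occurrence
  correlation; undefined when a marginal variance is zero)
* ``H' = 1 - H`` so that all retained metrics increase with grain size.

Windows tile the raster without overlap; a window's features are defined only
when at least 75 % of its cells carry data (configurable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sonartex.raster_io import IntensityRaster

FEATURE_NAMES = ("E", "H", "H_prime", "mu_G", "var_G", "corr_G")

#: (d_row, d_col) pixel offset per reference angle, for row 0 = north.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GlcmParams:
    """GLCM tabulation parameters.

    d : search distance in pixels.
    theta : reference angle in degrees, one of 0, 45, 90, 135.
    L : window width in metres (converted to pixels via the raster cell size).
    N : number of grey levels after quantization of the 8-bit image.
    symmetric : also tabulate each pair in reverse order.
    coverage_min : minimum fraction of valid cells for a window to count.
    """

    d: int = 5
    theta: int = 0
    L: float = 3.0
    N: int = 64
    symmetric: bool = False
    coverage_min: float = 0.75

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("search distance d must be >= 1 pixel")
        if self.theta not in ANGLE_OFFSETS:
            raise ValueError("theta must be one of 0, 45, 90, 135 degrees")
        if self.L <= 0:
            raise ValueError("window width L must be positive")
        if self.N < 2:
            raise ValueError("need at least 2 grey levels")
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must lie in (0, 1]")

    def window_pixels(self, cell_size: float) -> int:
        return int(round(self.L / cell_size))

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = ANGLE_OFFSETS[self.theta]
        return dr * self.d, dc * self.d


@dataclass(frozen=True)
class Glcm:
    """Normalised co-occurrence probabilities for one window."""

    P: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("GLCM must be square")
        if (P < 0).any():
            raise ValueError("GLCM probabilities must be non-negative")
        if self.n_pairs > 0 and not np.isclose(P.sum(), 1.0):
            raise ValueError("GLCM must be normalised to sum 1")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class FeatureVector:
    E: float
    H: float
    H_prime: float
    mu_G: float
    var_G: float
    corr_G: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def quantize(raster: IntensityRaster, N: int) -> np.ndarray:
    """Map 8-bit grey levels onto ``0..N-1`` by fixed global scaling.

    The scaling ``floor(g * N / 256)`` is independent of the image content so
    that calibration signatures transfer across scans.
    """
    if N < 2:
        raise ValueError("need at least 2 grey levels")
    g = raster.values.astype(np.int64)
    if g.min() < 0 or g.max() > 255:
        raise ValueError("grey levels must lie in 0-255")
    return (g * N) // 256


def compute_glcm(
    window: np.ndarray, mask: np.ndarray, params: GlcmParams
) -> Glcm:
    """Tabulate the GLCM of one quantized window.

    A pair is counted only when both the reference pixel and the pixel at the
    ``(d, theta)`` offset are valid.  Tabulation is directed (reference ->
    neighbour); with ``params.symmetric`` the reverse pairs are added too.
    Returns a GLCM with ``n_pairs == 0`` (all-zero ``P``) when no pair is
    countable, which marks the window as undefined downstream.
    """
    w = np.asarray(window)
    m = np.asarray(mask, bool)
    N = params.N
    dr, dc = params.offset
    rows, cols = w.shape

    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    V = np.zeros(N * N, dtype=np.int64)
    if r0 < r1 and c0 < c1:
        i = w[r0:r1, c0:c1]
        j = w[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if ok.any():
            V = np.bincount(i[ok] * N + j[ok], minlength=N * N)
    V = V.reshape(N, N)
    if params.symmetric:
        V = V + V.T
    n = int(V.sum())
    P = V / n if n > 0 else V.astype(float)
    return Glcm(P=P, n_pairs=n)


def glcm_features(glcm: Glcm) -> FeatureVector:
    """Scalar texture metrics of a normalised GLCM (see module docstring)."""
    if glcm.n_pairs <= 0:
        raise ValueError("features undefined for an empty GLCM")
    P = glcm.P
    N = P.shape[0]
    i = np.arange(N)[:, None]
    j = np.arange(N)[None, :]

    H = float((P / (1.0 + (i - j) ** 2)).sum())
    nz = P > 0
    E = float(-(P[nz] * np.log(P[nz])).sum())
    mu = float((i * P).sum())
    var = float(((i - mu) ** 2 * P).sum())

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.dot(np.arange(N), pi))
    mu_j = float(np.dot(np.arange(N), pj))
    sig_i = float(np.sqrt(np.dot((np.arange(N) - mu_i) ** 2, pi)))
    sig_j = float(np.sqrt(np.dot((np.arange(N) - mu_j) ** 2, pj)))
    if sig_i > 0 and sig_j > 0:
        corr = float(((i - mu_i) * (j - mu_j) * P).sum() / (sig_i * sig_j))
        corr = min(1.0, max(-1.0, corr))
    else:
        corr = float("nan")

    return FeatureVector(E=E, H=H, H_prime=1.0 - H, mu_G=mu, var_G=var, corr_G=corr)


@dataclass
class TextureGrid:
    """Per-window texture features on the non-overlapping window lattice.

    ``features[name]`` is an ``(n_win_rows, n_win_cols)`` array, NaN where the
    window is undefined (insufficient coverage or no countable pairs).
    """

    features: dict[str, np.ndarray]
    coverage: np.ndarray
    defined: np.ndarray
    params: GlcmParams
    cell_size: float
    origin: tuple[float, float]
    window_px: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.coverage.shape

    def window_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Easting/northing of window centroids, shaped like the lattice."""
        wr, wc = self.shape
        step = self.window_px * self.cell_size
        e0, n0 = self.origin
        east = e0 + (np.arange(wc) + 0.5) * step
        north = n0 - (np.arange(wr) + 0.5) * step
        return np.meshgrid(east, north)

    def feature_matrix(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Stack the requested features for defined windows.

        Returns ``(X, index)`` where ``X`` is ``(n_defined, len(names))`` and
        ``index`` holds the flat lattice index of each row.
        """
        for n in names:
            if n not in self.features:
                raise KeyError(f"unknown feature {n!r}")
        idx = np.flatnonzero(self.defined.ravel())
        X = np.column_stack([self.features[n].ravel()[idx] for n in names])
        keep = np.isfinite(X).all(axis=1)
        return X[keep], idx[keep]

    def to_dataframe(self) -> pd.DataFrame:
        wr, wc = self.shape
        rows, cols = np.meshgrid(np.arange(wr), np.arange(wc), indexing="ij")
        ee, nn = self.window_centers()
        data = {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "easting": ee.ravel(),
            "northing": nn.ravel(),
            "coverage": self.coverage.ravel(),
        }
        for name in FEATURE_NAMES:
            data[name] = self.features[name].ravel()
        return pd.DataFrame(data)


def sliding_texture_grid(raster: IntensityRaster, params: GlcmParams) -> TextureGrid:
    """Tile the raster into non-overlapping windows and compute features.

    Windows are ``L_px x L_px`` with ``L_px = round(L / cell_size)``, anchored
    at the raster origin; only complete windows are evaluated, so the lattice
    is ``(rows // L_px, cols // L_px)``.  Features are defined only where the
    window's valid-cell fraction reaches ``coverage_min``.
    """
    L_px = params.window_pixels(raster.cell_size)
    if L_px <= params.d:
        raise ValueError(
            f"window of {L_px} px cannot host pairs at distance d={params.d}"
        )
    q = quantize(raster, params.N)
    rows, cols = raster.shape
    wr, wc = rows // L_px, cols // L_px
    if wr < 1 or wc < 1:
        raise ValueError("raster smaller than one window")

    features = {n: np.full((wr, wc), np.nan) for n in FEATURE_NAMES}
    coverage = np.zeros((wr, wc))
    defined = np.zeros((wr, wc), bool)
    area = L_px * L_px
    for r in range(wr):
        for c in range(wc):
            sl = (slice(r * L_px, (r + 1) * L_px), slice(c * L_px, (c + 1) * L_px))
            m = raster.valid_mask[sl]
            cov = m.sum() / area
            coverage[r, c] = cov
            if cov < params.coverage_min:
                continue
            glcm = compute_glcm(q[sl], m, params)
            if glcm.n_pairs == 0:
                continue
            fv = glcm_features(glcm)
            for name, val in fv.as_dict().items():
                features[name][r, c] = val
            defined[r, c] = True

    return TextureGrid(
        features=features,
        coverage=coverage,
        defined=defined,
        params=params,
        cell_size=raster.cell_size,
        origin=raster.origin,
        window_px=L_px,
    )


@dataclass(frozen=True)
class SweepEntry:
    d: int
    theta: int
    L: float
    metric: str
    grid: TextureGrid


def parameter_sweep(
    raster: IntensityRaster,
    d_set: Iterable[int],
    theta_set: Iterable[int],
    L_set: Iterable[float],
    metric_set: Iterable[str] = ("E", "H", "mu_G", "var_G", "corr_G"),
    N: int = 64,
    symmetric: bool = False,
) -> list[SweepEntry]:
    """Evaluate every (d, theta, L, metric) combination on one raster.

    One :class:`TextureGrid` is computed per (d, theta, L) and shared across
    its metrics; the returned table has one entry per texture feature.
    """
    d_set, theta_set, L_set = list(d_set), list(theta_set), list(L_set)
    metric_set = list(metric_set)
    if not (d_set and theta_set and L_set and metric_set):
        raise ValueError("parameter sets must be non-empty")
    entries = []
    for d, theta, L in itertools.product(d_set, theta_set, L_set):
        grid = sliding_texture_grid(
            raster, GlcmParams(d=d, theta=theta, L=L, N=N, symmetric=symmetric)
        )
        for metric in metric_set:
            entries.append(SweepEntry(d=d, theta=theta, L=L, metric=metric, grid=grid))
    return entries
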