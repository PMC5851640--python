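"""Synthetic echogram textures, patch layouts, feature mixtures and point
clouds.

The generator emulates the statistical structure side-scan echogram textures
show over different substrates — not the acoustics:

* sand — smoothed correlated noise: low contrast, highly ordered (sub-pixel
  roughness), so windows have high homogeneity and low entropy;
* gravel — intermediate-scale speckle with occasional small clasts;
* boulders — sparse bright supra-pixel blobs with adjacent dark acoustic
  shadows over a rough background: high contrast, disordered.

All generators are bit-reproducible under a fixed seed.  A nadir stripe of
nodata cells mimics the over-saturated region beneath the boat track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from sonartex.raster_io import (
    IntensityRaster,
    SonarPointCloud,
    SubstratePolygon,
    SubstratePolygonSet,
)


@dataclass(frozen=True)
class TextureClassSpec:
    """Statistical recipe for one substrate's echogram texture.

    correlation_length : Gaussian smoothing radius (cells) of the background
        random field; larger = smoother, more ordered texture.
    contrast : grey-level standard deviation of the background field.
    blob_density : expected clasts per cell (Poisson placement).
    blob_radius : clast radius in cells (supra-pixel features).
    shadow_prob : probability a clast casts an adjacent dark shadow.
    base_level : mean grey level.
    """

    name: str
    correlation_length: float = 1.0
    contrast: float = 20.0
    blob_density: float = 0.0
    blob_radius: int = 0
    shadow_prob: float = 0.0
    base_level: float = 100.0

    def __post_init__(self) -> None:
        if min(self.correlation_length, self.contrast, self.blob_density,
               self.blob_radius, self.shadow_prob, self.base_level) < 0:
            raise ValueError("spec parameters must be non-negative")


DEFAULT_SPECS = {
    "sand": TextureClassSpec(
        "sand", correlation_length=6.0, contrast=8.0, base_level=80.0
    ),
    "gravel": TextureClassSpec(
        "gravel",
        correlation_length=1.5,
        contrast=25.0,
        blob_density=0.02,
        blob_radius=1,
        shadow_prob=0.3,
        base_level=100.0,
    ),
    "boulders": TextureClassSpec(
        "boulders",
        correlation_length=0.8,
        contrast=55.0,
        blob_density=0.012,
        blob_radius=3,
        shadow_prob=0.7,
        base_level=120.0,
    ),
}


@dataclass
class SceneLayout:
    """Raster geometry plus labeled patches and nodata masks.

    ``patches`` maps shapely polygons (in raster CRS) to class names; later
    patches take precedence where they overlap.  ``nodata_mask`` marks cells
    with no data (e.g. the over-saturated nadir stripe).
    """

    shape: tuple[int, int] = (400, 120)
    cell_size: float = 0.25
    origin: tuple[float, float] = (0.0, 100.0)
    patches: list[tuple[object, str]] = field(default_factory=list)
    nodata_mask: np.ndarray | None = None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        e0, n0 = self.origin
        east = e0 + (np.arange(cols) + 0.5) * self.cell_size
        north = n0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(east, north)


def default_layout(
    shape: tuple[int, int] = (400, 120),
    cell_size: float = 0.25,
    nadir_cols: tuple[int, int] = (57, 63),
    polygon_inset_m: float = 1.5,
) -> SceneLayout:
    """Three equal downstream bands (sand, gravel, boulders) plus a nadir
    nodata stripe; default 400x120 cells = 100 m x 30 m at 0.25 m.

    Patch polygons are inset from the band edges so labeled windows sit in
    texturally pure terrain, as in manual delineation.
    """
    rows, cols = shape
    n0 = rows * cell_size
    width = cols * cell_size
    layout = SceneLayout(shape=shape, cell_size=cell_size, origin=(0.0, n0))
    bands = ("sand", "gravel", "boulders")
    edges = np.linspace(0, rows, len(bands) + 1).astype(int)
    ins = polygon_inset_m
    for k, cname in enumerate(bands):
        top_n = n0 - edges[k] * cell_size
        bot_n = n0 - edges[k + 1] * cell_size
        layout.patches.append(
            (box(ins, bot_n + ins, width - ins, top_n - ins), cname)
        )
    mask = np.zeros(shape, bool)
    mask[:, nadir_cols[0] : nadir_cols[1]] = True
    layout.nodata_mask = mask
    return layout


def _correlated_field(
    shape: tuple[int, int], corr_length: float, contrast: float,
    base: float, rng: np.random.Generator,
) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        noise = gaussian_filter(noise, corr_length, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return base + contrast * noise


def _plant_blobs(
    img: np.ndarray, region: np.ndarray, spec: TextureClassSpec,
    rng: np.random.Generator,
) -> None:
    if spec.blob_density <= 0 or spec.blob_radius <= 0:
        return
    cells = np.flatnonzero(region)
    n_blobs = rng.poisson(spec.blob_density * cells.size)
    if n_blobs == 0:
        return
    rows, cols = img.shape
    centers = rng.choice(cells, size=n_blobs, replace=True)
    r = spec.blob_radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2) <= r**2
    for c in centers:
        cr, cc = divmod(c, cols)
        # each clast gets its own backscatter level; shadows are dark but
        # not uniformly black, so the pair distribution stays wide
        bright = rng.uniform(spec.base_level + spec.contrast, 255.0)
        dark = rng.uniform(2.0, max(10.0, spec.base_level - 1.5 * spec.contrast))
        shadow = rng.random() < spec.shadow_prob
        for val, (orow, ocol) in (
            ((bright, (0, 0)),) + (((dark, (0, 2 * r + 1)),) if shadow else ())
        ):
            rr = cr + yy + orow
            ccc = cc + xx + ocol
            ok = disk & (rr >= 0) & (rr < rows) & (ccc >= 0) & (ccc < cols)
            # clast facets scatter unevenly: internal texture, not a flat disk
            img[rr[ok], ccc[ok]] = val + rng.normal(
                0.0, 0.5 * spec.contrast, int(ok.sum())
            )


def simulate_echogram(
    layout: SceneLayout,
    specs: dict[str, TextureClassSpec] | None = None,
    seed: int | None = None,
) -> tuple[IntensityRaster, SubstratePolygonSet]:
    """Render a labeled synthetic echogram from a scene layout.

    Every patch class must have a spec; each class's texture is generated as
    a full-raster field and composited by patch membership (cell-centre test,
    last-listed patch wins).  The returned polygon set carries each patch
    with role ``calibration``.
    """
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    classes = [c for _, c in layout.patches]
    missing = set(classes) - set(specs)
    if missing:
        raise ValueError(f"no texture spec for classes {sorted(missing)}")

    rng = np.random.default_rng(seed)
    shape = layout.shape
    rows, cols = shape
    ee, nn = layout.cell_centers()

    vocab = tuple(dict.fromkeys(classes))
    polys = SubstratePolygonSet(
        [
            SubstratePolygon(geometry=g, class_label=c, role="calibration")
            for g, c in layout.patches
        ],
        vocabulary=vocab,
    )
    labels = polys.label_points(ee, nn)

    img = np.zeros(shape, float)
    for ci, cname in enumerate(vocab):
        spec = specs[cname]
        field_rng = np.random.default_rng(rng.integers(2**31))
        f = _correlated_field(
            shape, spec.correlation_length, spec.contrast, spec.base_level, field_rng
        )
        region = labels == ci
        _plant_blobs(f, region.ravel(), spec, field_rng)
        img[region] = f[region]

    valid = labels >= 0
    if layout.nodata_mask is not None:
        valid &= ~layout.nodata_mask
    img = np.clip(np.rint(img), 0, 255)
    raster = IntensityRaster(
        np.where(valid, img, 0), valid, layout.cell_size, layout.origin, ""
    )
    return raster, polys


def default_scene(
    seed: int | None = None,
) -> tuple[IntensityRaster, SubstratePolygonSet]:
    """The package's reference synthetic scene: 100 m x 30 m, three bands."""
    return simulate_echogram(default_layout(), DEFAULT_SPECS, seed=seed)


def simulate_feature_mixture(
    components: list[tuple[np.ndarray, np.ndarray, float]],
    n: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labeled samples from a Gaussian mixture.

    ``components`` is a list of ``(mean, covariance, weight)``; weights must
    sum to 1 and covariances be symmetric positive definite.  Returns
    ``(X, labels)`` with the true component label of every draw.
    """
    weights = np.array([w for _, _, w in components], float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("component weights must sum to 1")
    means = [np.atleast_1d(np.asarray(m, float)) for m, _, _ in components]
    covs = []
    for _, c, _ in components:
        c = np.atleast_2d(np.asarray(c, float))
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        covs.append(c)
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(components), size=n, p=weights)
    D = means[0].size
    X = np.empty((n, D))
    for k in range(len(components)):
        sel = labels == k
        if sel.any():
            X[sel] = rng.multivariate_normal(means[k], covs[k], size=int(sel.sum()))
    return X, labels


def simulate_point_cloud(
    raster: IntensityRaster,
    density: float = 1.0,
    jitter: float = 0.0,
    seed: int | None = None,
) -> SonarPointCloud:
    """Sample an intensity point cloud from a raster's valid cells.

    ``density`` points per cell (rounded to an integer count per cell) are
    jittered uniformly within ``+-jitter * cell_size`` of the cell centre and
    carry the cell's intensity.  ``density=1, jitter=0`` makes gridding an
    exact inverse.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    per_cell = max(1, int(round(density)))
    rng = np.random.default_rng(seed)
    ee, nn = raster.cell_centers()
    e = np.repeat(ee[raster.valid_mask], per_cell)
    n = np.repeat(nn[raster.valid_mask], per_cell)
    v = np.repeat(raster.values[raster.valid_mask].astype(float), per_cell)
    if jitter > 0:
        span = jitter * raster.cell_size
        e = e + rng.uniform(-span, span, e.size)
        n = n + rng.uniform(-span, span, n.size)
    return SonarPointCloud(e, n, v)


def load_scene_config(path) -> tuple[SceneLayout, dict[str, TextureClassSpec], int | None]:
    """Parse a declarative YAML scene description.

    Keys: ``shape`` [rows, cols]; ``cell_size``; ``nadir_cols`` [lo, hi];
    ``seed``; ``specs`` mapping class name to TextureClassSpec fields.
    Omitted keys fall back to the package defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    layout = default_layout(
        shape=tuple(cfg.get("shape", (400, 120))),
        cell_size=float(cfg.get("cell_size", 0.25)),
        nadir_cols=tuple(cfg.get("nadir_cols", (57, 63))),
    )
    specs = dict(DEFAULT_SPECS)
    for name, kv in (cfg.get("specs") or {}).items():
        base = specs.get(name, TextureClassSpec(name))
        specs[name] = TextureClassSpec(
            name,
            **{
                k: kv.get(k, getattr(base, k))
                for k in (
                    "correlation_length",
                    "contrast",
                    "blob_density",
                    "blob_radius",
                    "shadow_prob",
                    "base_level",
                )
            },
        )
    return layout, specs, cfg.get("seed")
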