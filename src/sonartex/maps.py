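"""Classification map container shared by both classifiers and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sonartex.texture import TextureGrid

#: label code for windows with no defined features
NODATA = -1
#: label code for indeterminate (LSQ) / below-acceptance "other" (GMM) windows
NULL = -2


@dataclass
class ClassificationMap:
    """Per-window substrate labels with confidence on the texture lattice.

    ``labels`` holds an index into ``class_names`` per window, or ``NODATA``
    (undefined window) / ``NULL`` (defined but indeterminate or rejected).
    ``confidence`` is the winning class's confidence (LSQ alpha or GMM
    posterior), NaN where no label was assigned.
    """

    labels: np.ndarray
    confidence: np.ndarray
    class_names: tuple[str, ...]
    grid: TextureGrid
    null_name: str = "null"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.confidence = np.asarray(self.confidence, float)
        if self.labels.shape != self.confidence.shape:
            raise ValueError("labels and confidence shapes differ")
        ok = (self.labels >= NULL) & (self.labels < len(self.class_names))
        if not ok.all():
            raise ValueError("label codes outside declared vocabulary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_name(self, code: int) -> str:
        if code == NODATA:
            return "nodata"
        if code == NULL:
            return self.null_name
        return self.class_names[code]

    def downstream_distance(
        self, track: np.ndarray | None = None
    ) -> np.ndarray:
        """Downstream distance (m) of each window centroid.

        With a ``track`` polyline (``(k, 2)`` easting/northing vertices) the
        distance is the arc-length position of the centroid's projection onto
        the track.  Without one, centroids are projected onto the first
        principal axis of the classified windows, oriented so distance
        increases along the axis, and shifted to start at zero.
        """
        ee, nn = self.grid.window_centers()
        pts = np.column_stack([ee.ravel(), nn.ravel()])
        if track is not None:
            track = np.asarray(track, float)
            seg = np.diff(track, axis=0)
            seg_len = np.hypot(seg[:, 0], seg[:, 1])
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            best_d = np.full(len(pts), np.inf)
            best_s = np.zeros(len(pts))
            for k in range(len(seg)):
                a, v, ln = track[k], seg[k], seg_len[k]
                if ln == 0:
                    continue
                t = np.clip(((pts - a) @ v) / ln**2, 0.0, 1.0)
                proj = a + t[:, None] * v
                dist = np.hypot(*(pts - proj).T)
                better = dist < best_d
                best_d[better] = dist[better]
                best_s[better] = cum[k] + t[better] * ln
            s = best_s
        else:
            classified = (self.labels >= 0).ravel()
            ref = pts[classified] if classified.any() else pts
            center = ref.mean(axis=0)
            _, _, vt = np.linalg.svd(ref - center, full_matrices=False)
            axis = vt[0]
            s = (pts - center) @ axis
            # SVD leaves the axis sign arbitrary; orient it so distance
            # increases away from the first classified window in lattice order
            which = np.flatnonzero(classified) if classified.any() else np.arange(len(pts))
            if s[which[0]] > s[which[-1]]:
                s = -s
        s = s - s.min()
        return s.reshape(self.shape)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.grid.to_dataframe()[["row", "col", "easting", "northing"]]
        df["label"] = [self.label_name(c) for c in self.labels.ravel()]
        df["confidence"] = self.confidence.ravel()
        return df
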