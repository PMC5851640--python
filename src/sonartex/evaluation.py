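"""Skill assessment and map summaries for substrate classifications.

Confusion matrices are tallied per window against the visually delineated
polygons (observed class = polygon containing the window centroid).  Null /
"other" predictions are kept as an explicit predicted column: they lower a
substrate's recall but are never counted as false positives of another
substrate.  Skill is summarized per class by precision, recall and

    F1 = 2 P R / (P + R)

with unweighted (macro) class averages.  Map summaries cover areal fractions
of the classified area, their cumulative-downstream convergence curves, and
reach-averaged comparison of two maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sonartex.maps import NODATA, NULL, ClassificationMap
from sonartex.raster_io import SubstratePolygonSet
from sonartex.signatures import windows_by_class


class EmptyEvaluationError(ValueError):
    """No overlap between the classification map and the reference polygons."""


@dataclass
class ConfusionMatrix:
    """Counts of observed (rows) vs predicted (columns) substrate windows.

    Predicted columns include the substrate classes plus a trailing null /
    other column; rows cover only observed substrate classes.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def null_column(self) -> str:
        return self.counts.columns[-1]

    def row_percent(self) -> pd.DataFrame:
        """Each row as percentages of that row's total (0 rows stay 0)."""
        totals = self.counts.sum(axis=1)
        pct = self.counts.div(totals.replace(0, np.nan), axis=0) * 100.0
        return pct.fillna(0.0)

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path)


@dataclass
class SkillScores:
    per_class: pd.DataFrame  # columns: precision, recall, f1
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_csv(self, path: str | Path) -> None:
        df = self.per_class.copy()
        df.loc["macro"] = [self.macro_precision, self.macro_recall, self.macro_f1]
        df.to_csv(path)


def confusion(
    cmap: ClassificationMap,
    polys: SubstratePolygonSet,
    roles: Sequence[str] = ("validation", "calibration"),
) -> ConfusionMatrix:
    """Tally the map's window labels against the labeled polygons."""
    truth = windows_by_class(cmap.grid, polys, roles=roles)
    pred = cmap.labels
    defined = (truth >= 0) & (pred != NODATA)
    if not defined.any():
        raise EmptyEvaluationError("no defined window falls inside a labeled polygon")
    obs_classes = list(polys.vocabulary)
    pred_cols = list(cmap.class_names) + [cmap.null_name]
    counts = pd.DataFrame(
        0, index=obs_classes, columns=pred_cols, dtype=int
    )
    for oi, oname in enumerate(obs_classes):
        sel = defined & (truth == oi)
        for pi, pname in enumerate(cmap.class_names):
            counts.loc[oname, pname] = int((pred[sel] == pi).sum())
        counts.loc[oname, cmap.null_name] = int((pred[sel] == NULL).sum())
    counts = counts.loc[counts.sum(axis=1) > 0]
    return ConfusionMatrix(counts)


def skill(cm: ConfusionMatrix) -> SkillScores:
    """Per-class precision, recall and F1 from a confusion matrix.

    Null/other predictions count against recall (they are missed windows)
    but never as false positives of a substrate.  Classes absent from both
    the truth rows and the prediction columns are skipped; a class present
    as a column but absent from truth gets NaN scores and is excluded from
    the macro averages.
    """
    counts = cm.counts
    substrate_cols = [c for c in counts.columns[:-1]]
    rows = []
    for cls in substrate_cols:
        tp = counts.loc[cls, cls] if cls in counts.index else 0
        fp = counts[cls].sum() - tp
        support = counts.loc[cls].sum() if cls in counts.index else 0
        fn = support - tp
        if support == 0:
            rows.append({"class": cls, "precision": np.nan, "recall": np.nan, "f1": np.nan})
            continue
        p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        rows.append({"class": cls, "precision": p, "recall": r, "f1": f1})
    df = pd.DataFrame(rows).set_index("class")
    valid = df.dropna()
    return SkillScores(
        per_class=df,
        macro_precision=float(valid["precision"].mean()),
        macro_recall=float(valid["recall"].mean()),
        macro_f1=float(valid["f1"].mean()),
    )


def f1_score(precision: float, recall: float) -> float:
    """The harmonic F1 of a precision/recall pair (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def areal_fractions(cmap: ClassificationMap) -> pd.Series:
    """Fraction of substrate-classified windows per class (null excluded)."""
    classified = cmap.labels >= 0
    total = int(classified.sum())
    if total == 0:
        raise EmptyEvaluationError("map has no substrate-classified window")
    fracs = {
        name: float((cmap.labels == i).sum()) / total
        for i, name in enumerate(cmap.class_names)
    }
    return pd.Series(fracs, name="fraction")


def cumulative_fractions(
    cmap: ClassificationMap, track: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-class areal fraction over every downstream prefix of the map.

    Windows are ordered by downstream distance of their centroid (projection
    onto ``track`` when given, else the map's principal axis).  Row ``k``
    gives the fractions among the first ``k+1`` classified windows; the last
    row equals :func:`areal_fractions`.
    """
    dist = cmap.downstream_distance(track)
    lab = cmap.labels.ravel()
    d = dist.ravel()
    sel = lab >= 0
    if not sel.any():
        raise EmptyEvaluationError("map has no substrate-classified window")
    lab, d = lab[sel], d[sel]
    order = np.argsort(d, kind="stable")
    lab, d = lab[order], d[order]
    n = np.arange(1, lab.size + 1, dtype=float)
    out = {"distance_m": d}
    for i, name in enumerate(cmap.class_names):
        out[name] = np.cumsum(lab == i) / n
    return pd.DataFrame(out)


def compare_maps(map_a: ClassificationMap, map_b: ClassificationMap) -> dict:
    """Reach-averaged fraction differences and per-window agreement.

    Maps must share the window lattice shape.  Agreement is computed over
    windows classified (as a substrate) in both maps; fraction differences
    are absolute differences of areal fractions, in percent.
    """
    if map_a.shape != map_b.shape:
        raise EmptyEvaluationError("maps are on different lattices")
    fa, fb = areal_fractions(map_a), areal_fractions(map_b)
    classes = sorted(set(fa.index) | set(fb.index))
    diffs = {
        c: abs(fa.get(c, 0.0) - fb.get(c, 0.0)) * 100.0 for c in classes
    }
    both = (map_a.labels >= 0) & (map_b.labels >= 0)
    if not both.any():
        raise EmptyEvaluationError("no co-classified windows")
    names_a = [map_a.label_name(c) for c in map_a.labels[both]]
    names_b = [map_b.label_name(c) for c in map_b.labels[both]]
    agree = float(np.mean([a == b for a, b in zip(names_a, names_b)]))
    return {
        "fraction_difference_percent": diffs,
        "agreement_rate": agree,
        "n_compared": int(both.sum()),
    }


def comparison_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
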