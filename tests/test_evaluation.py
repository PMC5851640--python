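"""Confusion matrices, skill scores, areal fractions and map comparison."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import sonartex as st
from sonartex.evaluation import (
    ConfusionMatrix,
    EmptyEvaluationError,
    areal_fractions,
    compare_maps,
    confusion,
    cumulative_fractions,
    f1_score,
    skill,
)
from sonartex.maps import NODATA, NULL, ClassificationMap
from sonartex.raster_io import SubstratePolygon, SubstratePolygonSet
from sonartex.texture import FEATURE_NAMES, GlcmParams, TextureGrid

CLASSES = ("sand", "gravel", "boulders")


def make_map(labels, class_names=CLASSES, window_px=4, cell=1.0):
    labels = np.asarray(labels, int)
    feats = {n: np.zeros(labels.shape) for n in FEATURE_NAMES}
    grid = TextureGrid(
        features=feats,
        coverage=np.ones(labels.shape),
        defined=labels != NODATA,
        params=GlcmParams(),
        cell_size=cell,
        origin=(0.0, labels.shape[0] * window_px * cell),
        window_px=window_px,
    )
    return ClassificationMap(
        labels=labels,
        confidence=np.where(labels >= 0, 1.0, np.nan),
        class_names=class_names,
        grid=grid,
    )


def full_cover_polys(cmap, truth):
    """One polygon per window, labeled with the truth grid."""
    polys = []
    step = cmap.grid.window_px * cmap.grid.cell_size
    rows, cols = truth.shape
    top = rows * step
    for r in range(rows):
        for c in range(cols):
            if truth[r, c] < 0:
                continue
            polys.append(
                SubstratePolygon(
                    box(c * step, top - (r + 1) * step, (c + 1) * step, top - r * step),
                    CLASSES[truth[r, c]],
                    "validation",
                )
            )
    return SubstratePolygonSet(polys)


def hand_skill(counts: pd.DataFrame, cls: str):
    """Independent per-class P/R/F1 from raw counts (loops, no reuse)."""
    tp = counts.loc[cls, cls]
    fp = sum(counts.loc[o, cls] for o in counts.index if o != cls)
    fn = sum(counts.loc[cls, p] for p in counts.columns if p != cls)
    P = tp / (tp + fp) if tp + fp else 0.0
    R = tp / (tp + fn) if tp + fn else 0.0
    return P, R, (2 * P * R / (P + R) if P + R else 0.0)


class TestConfusion:
    def test_perfect_map_is_diagonal(self):
        truth = np.array([[0, 1], [2, 0]])
        cmap = make_map(truth)
        cm = confusion(cmap, full_cover_polys(cmap, truth))
        pct = cm.row_percent()
        for c in CLASSES:
            assert pct.loc[c, c] == 100.0
        assert np.allclose(pct.sum(axis=1), 100.0)

    def test_all_null_map(self):
        truth = np.array([[0, 1], [2, 0]])
        cmap = make_map(np.full((2, 2), NULL))
        cm = confusion(cmap, full_cover_polys(cmap, truth))
        assert (cm.row_percent()["null"] == 100.0).all()

    def test_planted_noise_rate_recovered(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, size=(20, 20))
        pred = truth.copy()
        flip = rng.random(truth.shape) < 0.10
        pred[flip] = (truth[flip] + 1) % 3
        cmap = make_map(pred)
        cm = confusion(cmap, full_cover_polys(cmap, truth))
        off = 1 - np.trace(cm.counts.values[:, :3]) / cm.counts.values.sum()
        assert abs(off - 0.10) < 0.03

    def test_no_overlap_flagged(self):
        cmap = make_map(np.zeros((2, 2), int))
        empty = SubstratePolygonSet(
            [SubstratePolygon(box(1000, 1000, 1001, 1001), "sand", "validation")]
        )
        with pytest.raises(EmptyEvaluationError):
            confusion(cmap, empty)


class TestSkill:
    @pytest.mark.parametrize(
        "P,R,expected",
        [(0.86, 0.97, 0.91), (0.28, 0.31, 0.29), (0.75, 0.89, 0.81)],
    )
    def test_f1_from_precision_recall(self, P, R, expected):
        assert round(f1_score(P, R), 2) == expected

    def test_harmonic_mean_identity(self):
        for x in (0.0, 0.25, 0.5, 1.0):
            assert np.isclose(f1_score(x, x), x)

    @pytest.mark.parametrize(
        "counts",
        [
            # 2x2 and 3x3 integer fixtures, hand-checkable
            [[8, 2, 0], [3, 5, 2], [1, 1, 9]],
            [[10, 0, 1], [0, 10, 1], [0, 0, 0]],
            [[50, 10, 5], [20, 30, 10], [5, 5, 40]],
        ],
    )
    def test_matches_hand_computation(self, counts):
        counts = np.asarray(counts)
        df = pd.DataFrame(
            np.column_stack([counts, np.zeros(3, int)]),
            index=list(CLASSES),
            columns=list(CLASSES) + ["null"],
        )
        df = df.loc[df.sum(axis=1) > 0]
        scores = skill(ConfusionMatrix(df))
        for cls in df.index:
            P, R, F1 = hand_skill(df, cls)
            got = scores.per_class.loc[cls]
            assert np.isclose(got["precision"], P)
            assert np.isclose(got["recall"], R)
            assert np.isclose(got["f1"], F1)
            # harmonic mean never exceeds arithmetic mean
            assert got["f1"] <= (P + R) / 2 + 1e-12

    def test_null_predictions_hit_recall_not_precision(self):
        df = pd.DataFrame(
            [[6, 0, 0, 4], [0, 10, 0, 0], [0, 0, 10, 0]],
            index=list(CLASSES),
            columns=list(CLASSES) + ["null"],
        )
        scores = skill(ConfusionMatrix(df))
        sand = scores.per_class.loc["sand"]
        assert sand["precision"] == 1.0
        assert sand["recall"] == 0.6

    def test_absent_class_flagged_nan(self):
        df = pd.DataFrame(
            [[5, 0, 1, 0], [1, 0, 6, 0]],
            index=["sand", "boulders"],
            columns=list(CLASSES) + ["null"],
        )
        scores = skill(ConfusionMatrix(df))
        assert np.isnan(scores.per_class.loc["gravel", "f1"])
        assert not np.isnan(scores.macro_f1)


class TestFractions:
    def test_homogeneous_map(self):
        cmap = make_map(np.zeros((3, 3), int))
        fr = areal_fractions(cmap)
        assert fr["sand"] == 1.0 and fr["gravel"] == 0.0

    def test_half_and_half_excludes_null(self):
        labels = np.array([[0, 0, 2, 2], [0, 0, 2, 2], [NULL, NODATA, NULL, NODATA]])
        fr = areal_fractions(make_map(labels))
        assert fr["sand"] == 0.5 and fr["boulders"] == 0.5

    def test_planted_layout_recovered(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(3, size=(30, 10), p=[0.6, 0.25, 0.15])
        fr = areal_fractions(make_map(labels))
        expect = [np.mean(labels == i) for i in range(3)]
        np.testing.assert_allclose([fr[c] for c in CLASSES], expect)

    def test_cumulative_matches_closed_form_for_alternating_bands(self):
        # row bands alternate sand/boulders; prefix fractions oscillate
        # around 0.5 with amplitude decaying as 1/k
        labels = np.tile(np.repeat([0, 2], 1)[:, None], (5, 4))  # rows alternate
        cmap = make_map(labels)
        curves = cumulative_fractions(cmap)
        n = np.arange(1, labels.size + 1)
        # windows ordered along the principal (downstream) axis = row order
        flat = labels.ravel()
        expect_sand = np.cumsum(flat == 0) / n
        np.testing.assert_allclose(curves["sand"].to_numpy(), expect_sand)
        assert abs(curves["sand"].iloc[-1] - 0.5) < 1e-12

    def test_full_curve_end_equals_areal_fractions(self, scene_texture, calibration):
        _, _, tex = scene_texture
        cmap = st.classify_lsq(tex, st.LsqModel(calibration))
        fr = areal_fractions(cmap)
        curves = cumulative_fractions(cmap)
        for c in CLASSES:
            assert np.isclose(curves[c].iloc[-1], fr[c])

    def test_convergence_to_asymptote_for_stationary_reach(self):
        # stationary patch statistics: fractions settle near the reach
        # values well before the end of the scan
        rng = np.random.default_rng(4)
        labels = rng.choice(3, size=(120, 5), p=[0.5, 0.3, 0.2])
        cmap = make_map(labels)
        curves = cumulative_fractions(cmap)
        fr = areal_fractions(cmap)
        tail = curves.iloc[len(curves) // 2 :]
        for c in CLASSES:
            assert (tail[c] - fr[c]).abs().max() < 0.05


class TestCompareMaps:
    def test_self_comparison(self):
        labels = np.random.default_rng(2).integers(0, 3, size=(6, 6))
        cmap = make_map(labels)
        rep = compare_maps(cmap, cmap)
        assert rep["agreement_rate"] == 1.0
        assert all(v == 0.0 for v in rep["fraction_difference_percent"].values())

    def test_planted_relabeling_rate(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, size=(20, 20))
        b = a.copy()
        flip = rng.random(a.shape) < 0.05
        b[flip] = (a[flip] + 1) % 3
        rep = compare_maps(make_map(a), make_map(b))
        assert abs(rep["agreement_rate"] - 0.95) < 0.02

    def test_disjoint_lattices_rejected(self):
        a = make_map(np.zeros((2, 2), int))
        b = make_map(np.full((2, 2), NODATA))
        with pytest.raises(EmptyEvaluationError):
            compare_maps(a, b)
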