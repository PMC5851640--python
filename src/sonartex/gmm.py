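"""Gaussian mixture model classification of texture features.

A mixture of ``q`` Gaussian components models the distribution of texture
feature vectors; each component (or group of components) represents one
substrate.  Parameters (means, covariances, mixing weights) are fitted by
expectation-maximization; four covariance structures are supported — full,
diagonal, spherical and tied (one full matrix shared by all components).
Model order, covariance structure and feature subset are selected by the
Bayesian Information Criterion

    BIC = -2 ln L + k ln n

with ``k`` the number of free parameters.  Model-search fits are
"uninitialized" — started from seeded random observations rather than any
proposed solution, so the search is not biased toward an expected answer; a
selected model is then re-fit initialized at the calibration class means.  Per-window component posteriors (the E-step
responsibilities) provide classification confidence and posterior maps.

Fitting is done on raw (unstandardized) feature values so component means
remain directly comparable to the calibration medians.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from sonartex.maps import NODATA, NULL, ClassificationMap
from sonartex.signatures import CalibrationMatrix
from sonartex.texture import TextureGrid

Structure = Literal["full", "diag", "spherical", "tied"]
STRUCTURES = ("full", "diag", "spherical", "tied")

COV_FLOOR = 1e-6


class DegenerateComponentWarning(UserWarning):
    """A component's weight vanished or its covariance was floored."""


@dataclass
class GmmModel:
    """A fitted Gaussian mixture over texture features.

    ``means`` is (q, D); ``covariances`` is stored per structure: (q, D, D)
    for full, (q, D) for diag, (q,) for spherical, (D, D) for tied.
    ``component_labels`` maps each component to a substrate name (several
    components may share one substrate).
    """

    q: int
    structure: Structure
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    feature_names: tuple[str, ...]
    log_likelihood: float = np.nan
    bic: float = np.nan
    n_iter: int = 0
    converged: bool = False
    seed: int | None = None
    component_labels: tuple[str, ...] | None = None

    @property
    def D(self) -> int:
        return self.means.shape[1]

    def n_parameters(self) -> int:
        """Free-parameter count used by BIC."""
        q, D = self.q, self.D
        mean_p = q * D
        weight_p = q - 1
        cov_p = {
            "full": q * D * (D + 1) // 2,
            "diag": q * D,
            "spherical": q,
            "tied": D * (D + 1) // 2,
        }[self.structure]
        return mean_p + weight_p + cov_p

    def full_covariances(self) -> np.ndarray:
        """Covariances expanded to (q, D, D) regardless of structure."""
        q, D = self.q, self.D
        if self.structure == "full":
            return self.covariances
        if self.structure == "diag":
            return np.array([np.diag(c) for c in self.covariances])
        if self.structure == "spherical":
            return np.array([np.eye(D) * c for c in self.covariances])
        return np.broadcast_to(self.covariances, (q, D, D)).copy()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "q": self.q,
                    "structure": self.structure,
                    "means": self.means.tolist(),
                    "covariances": np.asarray(self.covariances).tolist(),
                    "weights": self.weights.tolist(),
                    "feature_names": list(self.feature_names),
                    "log_likelihood": self.log_likelihood,
                    "bic": self.bic,
                    "seed": self.seed,
                    "component_labels": list(self.component_labels)
                    if self.component_labels
                    else None,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GmmModel":
        d = json.loads(Path(path).read_text())
        labels = d.get("component_labels")
        return cls(
            q=d["q"],
            structure=d["structure"],
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            weights=np.array(d["weights"]),
            feature_names=tuple(d["feature_names"]),
            log_likelihood=d["log_likelihood"],
            bic=d["bic"],
            seed=d.get("seed"),
            component_labels=tuple(labels) if labels else None,
        )


@dataclass
class PosteriorMap:
    """Per-window, per-component posterior probabilities on the lattice."""

    posteriors: np.ndarray  # (wr, wc, q); NaN where undefined
    model: GmmModel
    acceptance_threshold: float

    def substrate_maps(self) -> dict[str, np.ndarray]:
        """Per-substrate posterior maps: sums of member-component posteriors."""
        if self.model.component_labels is None:
            raise ValueError("model components are unlabeled")
        out: dict[str, np.ndarray] = {}
        for k, name in enumerate(self.model.component_labels):
            out[name] = out.get(name, 0) + self.posteriors[..., k]
        return out


# ---------------------------------------------------------------------------
# E-M internals


def _log_gauss(V: np.ndarray, means: np.ndarray, covs_full: np.ndarray) -> np.ndarray:
    """(n, q) log N(v | mu_x, Sigma_x) via Cholesky factors."""
    n, D = V.shape
    q = means.shape[0]
    out = np.empty((n, q))
    for k in range(q):
        L = np.linalg.cholesky(covs_full[k])
        diff = V - means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (D * np.log(2 * np.pi) + logdet + maha)
    return out


def _m_step_cov(
    V: np.ndarray, resp: np.ndarray, means: np.ndarray, structure: Structure
) -> np.ndarray:
    n, D = V.shape
    q = means.shape[0]
    nk = resp.sum(axis=0)
    if structure == "tied":
        S = np.zeros((D, D))
        for k in range(q):
            diff = V - means[k]
            S += (resp[:, k, None] * diff).T @ diff
        S /= n
        S[np.diag_indices_from(S)] += COV_FLOOR
        return S
    if structure == "full":
        covs = np.empty((q, D, D))
        for k in range(q):
            diff = V - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
            covs[k][np.diag_indices(D)] += COV_FLOOR
        return covs
    if structure == "diag":
        covs = np.empty((q, D))
        for k in range(q):
            diff = V - means[k]
            covs[k] = (resp[:, k] @ diff**2) / nk[k] + COV_FLOOR
        return covs
    if structure == "spherical":
        covs = np.empty(q)
        for k in range(q):
            diff = V - means[k]
            covs[k] = (resp[:, k] @ (diff**2).sum(axis=1)) / (nk[k] * D) + COV_FLOOR
        return covs
    raise ValueError(f"unknown covariance structure {structure!r}")


def _expand(covs: np.ndarray, structure: Structure, q: int, D: int) -> np.ndarray:
    if structure == "full":
        return covs
    if structure == "diag":
        return np.array([np.diag(c) for c in covs])
    if structure == "spherical":
        return np.array([np.eye(D) * c for c in covs])
    return np.broadcast_to(covs, (q, D, D))


def fit_gmm(
    V: np.ndarray,
    q: int,
    structure: Structure = "full",
    init: Literal["uninitialized", "means"] = "uninitialized",
    init_means: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> GmmModel:
    """Fit a q-component mixture by expectation-maximization.

    ``init='uninitialized'`` starts from q randomly drawn observations used
    as hard-assignment cluster seeds (no proposed solution, so repeated
    search fits are unbiased; seeded); ``init='means'`` starts at the
    supplied component means with the pooled data covariance.  Convergence is declared when the relative change of the
    per-sample log-likelihood drops below ``tol``.  The log-likelihood is
    checked to be non-decreasing at every iteration.
    """
    V = np.asarray(V, float)
    if V.ndim == 1:
        V = V[:, None]
    n, D = V.shape
    if q < 1:
        raise ValueError("need at least one component")
    if n < q * (D + 1):
        raise ValueError(f"need at least q*(D+1)={q * (D + 1)} samples, got {n}")
    if structure not in STRUCTURES:
        raise ValueError(f"unknown covariance structure {structure!r}")

    rng = np.random.default_rng(seed)
    if init == "uninitialized":
        # seeded draw of q observations as cluster seeds, then one hard
        # nearest-seed assignment and an M-step.  (Soft random
        # responsibilities average every mean onto the grand mean — a
        # symmetric E-M stationary point the algorithm cannot leave.)
        seeds = V[rng.choice(n, size=q, replace=False)]
        assign = np.argmin(
            ((V[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        resp = np.zeros((n, q))
        resp[np.arange(n), assign] = 1.0
        weights, means, covs = _m_step(V, resp, structure)
    elif init == "means":
        if init_means is None:
            raise ValueError("init='means' requires init_means")
        means = np.atleast_2d(np.asarray(init_means, float))
        if means.shape != (q, D):
            raise ValueError(f"init_means must have shape ({q}, {D})")
        weights = np.full(q, 1.0 / q)
        base = np.cov(V.T, ddof=0) if D > 1 else np.array([[V.var()]])
        base = np.atleast_2d(base) + COV_FLOOR * np.eye(D)
        if structure == "full":
            covs = np.repeat(base[None], q, axis=0)
        elif structure == "diag":
            covs = np.repeat(np.diag(base)[None], q, axis=0)
        elif structure == "spherical":
            covs = np.full(q, np.diag(base).mean())
        else:
            covs = base
    else:
        raise ValueError(f"unknown init {init!r}")

    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_g = _log_gauss(V, means, _expand(covs, structure, q, D))
        log_w = np.log(np.maximum(weights, 1e-300))
        log_joint = log_g + log_w
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise AssertionError(
                f"E-M log-likelihood decreased at iteration {it}: "
                f"{ll_prev} -> {ll}"
            )
        resp = np.exp(log_joint - log_norm[:, None])
        if ll_prev > -np.inf and abs(ll - ll_prev) < tol * max(1.0, abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
        weights, means, covs = _m_step(V, resp, structure)

    model = GmmModel(
        q=q,
        structure=structure,
        means=means,
        covariances=covs,
        weights=weights,
        feature_names=tuple(feature_names) if feature_names else tuple(
            f"f{i}" for i in range(D)
        ),
        log_likelihood=ll,
        n_iter=it,
        converged=converged,
        seed=seed,
    )
    model.bic = bic(model, n)
    return model


def _m_step(
    V: np.ndarray, resp: np.ndarray, structure: Structure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, D = V.shape
    q = resp.shape[1]
    nk = resp.sum(axis=0)
    if (nk < 1e-10).any():
        warnings.warn(
            "a mixture component's weight collapsed; re-regularizing",
            DegenerateComponentWarning,
        )
        resp = resp + 1e-10
        nk = resp.sum(axis=0)
    weights = nk / n
    means = (resp.T @ V) / nk[:, None]
    covs = _m_step_cov(V, resp, means, structure)
    return weights, means, covs


def bic(model: GmmModel, n: int) -> float:
    """Bayesian Information Criterion: -2 ln L + k ln n (lower is better)."""
    return -2.0 * model.log_likelihood + model.n_parameters() * np.log(n)


def posterior(model: GmmModel, v: np.ndarray) -> np.ndarray:
    """Per-component posterior probabilities P(i | v), computed in log space.

    ``v`` may be a single vector or an (n, D) batch; returns (q,) or (n, q)
    arrays summing to 1 across components.
    """
    v = np.asarray(v, float)
    single = v.ndim == 1
    V = np.atleast_2d(v)
    log_g = _log_gauss(V, model.means, model.full_covariances())
    log_joint = log_g + np.log(np.maximum(model.weights, 1e-300))
    post = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
    return post[0] if single else post


@dataclass(frozen=True)
class SearchRecord:
    feature_subset: tuple[str, ...]
    q: int
    structure: Structure
    bic: float
    model: GmmModel | None
    error: str | None = None


def bic_model_search(
    V_by_subset: dict[tuple[str, ...], np.ndarray],
    q_range: Sequence[int] = (1, 2, 3, 4, 5),
    structures: Sequence[Structure] = STRUCTURES,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> list[SearchRecord]:
    """Rank (feature subset, component count, covariance structure) by BIC.

    Every fit is uninitialized (seeded random starting observations) so the
    search cannot converge onto a proposed solution.  Failed fits are recorded with
    infinite BIC and excluded from the head of the ranking.
    """
    ss = np.random.SeedSequence(seed)
    records: list[SearchRecord] = []
    combos = list(itertools.product(V_by_subset.items(), q_range, structures))
    child_seeds = ss.generate_state(len(combos))
    for ((names, V), q, structure), s in zip(combos, child_seeds):
        try:
            model = fit_gmm(
                V,
                q=q,
                structure=structure,
                init="uninitialized",
                seed=int(s % (2**31)),
                tol=tol,
                max_iter=max_iter,
                feature_names=names,
            )
            records.append(SearchRecord(tuple(names), q, structure, model.bic, model))
        except (ValueError, np.linalg.LinAlgError, AssertionError) as exc:
            records.append(
                SearchRecord(tuple(names), q, structure, np.inf, None, error=str(exc))
            )
    records.sort(key=lambda r: r.bic)
    return records


def interpolated_means(
    calibration: CalibrationMatrix, feature_names: Sequence[str], q: int
) -> np.ndarray:
    """Initial component means for a q-component fit from a 3-class calibration.

    q=3 uses the class medians directly; q=2 drops the middle (gravel) class;
    q=4 splits gravel into two components whose means are the midpoints
    between the gravel median and each neighbouring class median (classes are
    assumed ordered by grain size: sand, gravel, boulders).
    """
    fi = [calibration.feature_names.index(f) for f in feature_names]
    C = calibration.C[:, fi]
    if C.shape[0] != 3:
        raise ValueError("mean interpolation assumes a 3-class calibration")
    sand, gravel, boulders = C
    if q == 2:
        return np.vstack([sand, boulders])
    if q == 3:
        return C.copy()
    if q == 4:
        fine = (sand + gravel) / 2.0
        coarse = (gravel + boulders) / 2.0
        return np.vstack([sand, fine, coarse, boulders])
    raise ValueError("q must be 2, 3 or 4 for calibration-based initialization")


def label_components(
    model: GmmModel, calibration: CalibrationMatrix
) -> tuple[str, ...]:
    """Assign a substrate name to every mixture component.

    Components are ordered by their mean along the first model feature shared
    with the calibration (the grain-size-correlated axis, oriented so the
    calibration signatures increase from sand to boulders).  q=2 maps to
    (sand, boulders), q=4 to (sand, gravel, gravel, boulders); any other q
    assigns each component the nearest calibration signature (z-scored
    Euclidean distance).  Ties in the ordering are broken by component index.
    """
    shared = [f for f in model.feature_names if f in calibration.feature_names]
    if not shared:
        raise ValueError("model and calibration share no feature")
    dom = shared[0]
    col = calibration.feature_names.index(dom)
    # orient so larger along-axis mean = coarser substrate
    sign = 1.0 if calibration.C[-1, col] >= calibration.C[0, col] else -1.0
    axis = model.feature_names.index(dom)
    means = sign * model.means[:, axis]
    if np.unique(means).size < means.size:
        warnings.warn("equal component means; ordering by index", UserWarning)
    order = np.argsort(means, kind="stable")

    names = calibration.class_names
    labels = [""] * model.q
    if model.q == 2:
        labels[order[0]], labels[order[1]] = names[0], names[-1]
    elif model.q == 4 and len(names) == 3:
        labels[order[0]] = names[0]
        labels[order[1]] = names[1]
        labels[order[2]] = names[1]
        labels[order[3]] = names[-1]
    else:
        fi = [model.feature_names.index(f) for f in shared]
        ci = [calibration.feature_names.index(f) for f in shared]
        scale = calibration.feature_scale()[ci]
        for k in range(model.q):
            d = np.linalg.norm(
                (model.means[k, fi] - calibration.C[:, ci]) / scale, axis=1
            )
            labels[k] = names[int(np.argmin(d))]
    return tuple(labels)


def classify_gmm(
    tex: TextureGrid,
    model: GmmModel,
    acceptance_threshold: float = 0.6,
) -> tuple[ClassificationMap, PosteriorMap]:
    """Label every defined window by its maximum-posterior component.

    A window whose maximum component posterior falls below the acceptance
    threshold is labeled "other"; undefined windows are nodata.  The returned
    posterior map carries the full per-component probabilities.
    """
    if model.component_labels is None:
        raise ValueError("label the model's components before classifying")
    X, idx = tex.feature_matrix(model.feature_names)
    wr, wc = tex.shape
    post_grid = np.full((wr * wc, model.q), np.nan)
    labels = np.full(wr * wc, NODATA, int)
    conf = np.full(wr * wc, np.nan)
    if len(X):
        post = posterior(model, X)
        post_grid[idx] = post
        best = np.argmax(post, axis=1)
        pmax = post[np.arange(len(X)), best]
        class_names = tuple(dict.fromkeys(model.component_labels))
        comp_to_class = np.array(
            [class_names.index(l) for l in model.component_labels]
        )
        lab = comp_to_class[best]
        lab[pmax < acceptance_threshold] = NULL
        labels[idx] = lab
        conf[idx] = pmax
    else:
        class_names = tuple(dict.fromkeys(model.component_labels))
    cmap = ClassificationMap(
        labels=labels.reshape(wr, wc),
        confidence=conf.reshape(wr, wc),
        class_names=class_names,
        grid=tex,
        null_name="other",
    )
    pmap = PosteriorMap(
        posteriors=post_grid.reshape(wr, wc, model.q),
        model=model,
        acceptance_threshold=acceptance_threshold,
    )
    return cmap, pmap
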