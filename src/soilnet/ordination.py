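"""Bray–Curtis dissimilarity and nonmetric multidimensional scaling.

NMDS is fitted by iterative majorization (SMACOF): each iteration fits
monotone disparities to the configuration distances by isotonic regression
over the rank order of the input dissimilarities (primary tie handling:
tied dissimilarities may carry unordered fitted values), then moves the
configuration by a Guttman transform.  An accepted iteration never
increases Kruskal stress-1,

    stress = sqrt( Σ (D_ij − d̂_ij)² / Σ D_ij² ),

where D are configuration distances and d̂ the isotonic disparities; a
step-halving safeguard backtracks toward the previous configuration when
the raw Guttman step would overshoot.  The first restart starts from
classical (Torgerson) metric scaling of the dissimilarities, further
restarts from seeded random configurations; the restart with lowest final
stress wins, and its configuration is centred and rotated to principal
axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .io_model import SampleTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of pairwise dissimilarities."""

    sample_ids: tuple
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        d = np.asarray(self.d, dtype=float).copy()
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError(f"distance matrix must be square, got shape {d.shape}")
        if d.shape[0] != len(self.sample_ids):
            raise ValidationError("sample_ids length does not match matrix size")
        if not np.all(np.isfinite(d)):
            raise ValidationError("distance matrix holds non-finite values")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < -1e-12):
            raise ValidationError("distances must be non-negative")
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        d.setflags(write=False)
        object.__setattr__(self, "d", d)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(np.asarray(self.d), checks=False)


def bray_curtis(table: SampleTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarities d_ij = Σ|x_i − x_j| / Σ(x_i + x_j).

    Bounded in [0, 1] for non-negative profiles.  A pair of all-zero rows
    leaves the index undefined and raises.
    """
    values = np.asarray(table.values, dtype=float)
    zero_rows = np.where(values.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        a, b = table.sample_ids[zero_rows[0]], table.sample_ids[zero_rows[1]]
        raise ValidationError(
            f"Bray–Curtis undefined for all-zero sample pair ({a!r}, {b!r})"
        )
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


@dataclass(frozen=True)
class OrdinationResult:
    """A fitted NMDS configuration with Shepard-fit diagnostics.

    ``per_sample_fit`` is each sample's summed squared disparity residual
    (larger = worse fitted; used for bubble sizing in ordination plots).
    ``stress_path`` records stress-1 after every accepted iteration of the
    winning restart (non-increasing by construction).
    """

    sample_ids: tuple
    coordinates: np.ndarray
    stress: float
    r2_nonlinear: float
    r2_linear: float
    per_sample_fit: np.ndarray
    n_restarts_used: int
    converged: bool
    stress_path: tuple


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _disparities(delta: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Isotonic (PAVA) fit of configuration distances over dissimilarity
    ranks; ties in delta are ordered by current distance (primary tie
    handling: within-tie order is free, so ties are never penalised)."""
    order = np.lexsort((distances, delta))
    fitted = isotonic_regression(distances[order], increasing=True).x
    out = np.empty_like(distances)
    out[order] = fitted
    return out


def _stress1(delta: np.ndarray, distances: np.ndarray):
    dhat = _disparities(delta, distances)
    denom = float(np.sum(distances ** 2))
    if denom == 0.0:
        return float("inf"), dhat
    return float(np.sqrt(np.sum((distances - dhat) ** 2) / denom)), dhat


def _guttman_step(coords: np.ndarray, dhat_sq: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    dist = squareform(pdist(coords))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dhat_sq / dist, 0.0)
    b = -ratio
    np.fill_diagonal(b, ratio.sum(axis=1))
    return b @ coords / n


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    w_top = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w_top)


def _single_run(delta: np.ndarray, init: np.ndarray, max_iter: int, tol: float):
    coords = init - init.mean(axis=0)
    dist = pdist(coords)
    stress, dhat = _stress1(delta, dist)
    path = [stress]
    converged = False
    for _ in range(max_iter):
        proposal = _guttman_step(coords, squareform(dhat))
        new_dist = pdist(proposal)
        new_stress, new_dhat = _stress1(delta, new_dist)
        if new_stress > stress:
            accepted = False
            for t in (0.5, 0.25, 0.125, 0.0625, 0.03125):
                blend = (1.0 - t) * coords + t * proposal
                blend_dist = pdist(blend)
                s, dh = _stress1(delta, blend_dist)
                if s <= stress:
                    proposal, new_stress, new_dhat = blend, s, dh
                    accepted = True
                    break
            if not accepted:
                converged = True  # no descent direction left
                break
        drop = stress - new_stress
        coords, stress, dhat = proposal, new_stress, new_dhat
        path.append(stress)
        if stress <= tol ** 2 or drop < tol * max(stress, 1e-12):
            converged = True
            break
    return coords, stress, path, converged


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Best-of-restarts nonmetric MDS of a dissimilarity matrix.

    Restart 0 starts from classical scaling; restart i ≥ 1 from a random
    configuration drawn from the substream ``SeedSequence([seed, i])``, so
    raising ``n_restarts`` only ever appends candidate starts (the returned
    stress is non-increasing in ``n_restarts``).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if n_restarts < 1:
        raise ValidationError(f"n_restarts must be >= 1, got {n_restarts}")
    if dist.n_samples < 3:
        raise ValidationError("NMDS needs at least 3 samples")

    delta = dist.condensed()
    scale = max(float(delta.mean()), 1e-6)
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            init = _classical_scaling(np.asarray(dist.d), k)
            if init.shape[1] < k:
                init = np.hstack([init, np.zeros((dist.n_samples, k - init.shape[1]))])
        else:
            rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
            init = rng.normal(scale=scale, size=(dist.n_samples, k))
        coords, stress, path, converged = _single_run(delta, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (coords, stress, path, converged)
    coords, stress, path, converged = best
    if not converged:
        logger.warning("NMDS did not converge within %d iterations (stress %.6g)",
                       max_iter, stress)

    # centre and rotate to principal axes, with a deterministic sign convention
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col

    final_dist = pdist(coords)
    stress, _ = _stress1(delta, final_dist)
    result = OrdinationResult(
        sample_ids=dist.sample_ids,
        coordinates=coords,
        stress=stress,
        r2_nonlinear=float("nan"),
        r2_linear=float("nan"),
        per_sample_fit=np.zeros(dist.n_samples),
        n_restarts_used=n_restarts,
        converged=converged,
        stress_path=tuple(path),
    )
    r2_nonlinear, r2_linear, per_sample_fit = shepard_fit(dist, result)
    return OrdinationResult(
        sample_ids=dist.sample_ids,
        coordinates=coords,
        stress=stress,
        r2_nonlinear=r2_nonlinear,
        r2_linear=r2_linear,
        per_sample_fit=per_sample_fit,
        n_restarts_used=n_restarts,
        converged=converged,
        stress_path=tuple(path),
    )


def shepard_fit(dist: DistanceMatrix, result: OrdinationResult):
    """Shepard-diagram goodness of fit for a configuration.

    Returns ``(r2_nonlinear, r2_linear, per_sample_fit)`` where the
    non-linear R² uses the isotonic disparities, the linear R² is the
    squared Pearson correlation between configuration distances and the
    original dissimilarities, and ``per_sample_fit[i]`` sums the squared
    disparity residuals of pairs involving sample i.
    """
    if result.sample_ids != dist.sample_ids:
        raise ValidationError("ordination result and distance matrix sample sets differ")
    delta = dist.condensed()
    distances = pdist(np.asarray(result.coordinates))
    dhat = _disparities(delta, distances)
    resid_sq = (distances - dhat) ** 2
    centred = distances - distances.mean()
    sst = float(np.sum(centred ** 2))
    if sst == 0.0:
        r2_nonlinear = 1.0 if float(resid_sq.sum()) == 0.0 else 0.0
        r2_linear = 1.0 if np.allclose(delta, delta.mean()) else 0.0
    else:
        r2_nonlinear = 1.0 - float(resid_sq.sum()) / sst
        dc = delta - delta.mean()
        denom = float(np.sqrt(np.sum(dc ** 2) * sst))
        r2_linear = float((dc @ centred) ** 2 / denom ** 2) if denom > 0 else 0.0

    residual_matrix = squareform(resid_sq)
    per_sample_fit = residual_matrix.sum(axis=1)
    return float(r2_nonlinear), float(r2_linear), per_sample_fit
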