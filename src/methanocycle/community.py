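"""Bray-Curtis dissimilarity and non-metric multidimensional scaling.

``bray_curtis`` builds the site-by-site dissimilarity matrix over the union
of taxa (absent taxon = 0 abundance). ``nmds`` minimizes Kruskal stress-1,

    stress = sqrt( sum_ij (d_ij - dhat_ij)^2 / sum_ij d_ij^2 ),

where d are the embedded configuration distances and dhat the disparities
fitted to them by monotone (pool-adjacent-violators) regression on the input
dissimilarities, with ties averaged within equal-dissimilarity blocks. The
optimizer is iterative majorization (a Guttman transform per iteration, so
raw stress is non-increasing within a restart); the best configuration over
``n_restarts`` seeded random initializations is returned. Coordinates are
centered, rotated to principal axes, and sign-fixed (largest-magnitude
coordinate positive per axis) for a reproducible orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .abundance import AbundanceProfile
from .tables_io import TableValidationError


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # n_sites x k
    stress: float
    stress_trace: list[float]  # per-iteration stress-1 of the winning restart
    restart_stresses: list[float]
    seed: int


def profile_matrix(profiles: Sequence[AbundanceProfile]) -> tuple[list[str], list[str], np.ndarray]:
    """Sites x taxa abundance matrix over the union of taxa."""
    ranks = {p.rank for p in profiles}
    if len(ranks) > 1:
        raise TableValidationError(f"profiles mix ranks: {sorted(ranks)}")
    taxa = sorted(set().union(*(p.entries.keys() for p in profiles)))
    sites = [p.site_id for p in profiles]
    x = np.zeros((len(profiles), len(taxa)))
    for i, p in enumerate(profiles):
        for j, taxon in enumerate(taxa):
            x[i, j] = p.entries.get(taxon, 0.0)
    return sites, taxa, x


def bray_curtis(profiles: Sequence[AbundanceProfile]) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity between site profiles."""
    sites, _, x = profile_matrix(profiles)
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise TableValidationError(
            f"Bray-Curtis undefined between all-zero profiles: "
            f"{[sites[i] for i in zero_rows]}"
        )
    values = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(ids=list(sites), values=values)


def _stress1(dist: np.ndarray, disparities: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disparities) ** 2).sum() / denom))


def _single_run(
    d: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    n = squareform(d, checks=False).shape[0]
    order = np.argsort(d, kind="mergesort")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = rng.normal(size=(n, k))
    trace: list[float] = []
    prev_raw = np.inf
    for _ in range(max_iter):
        dist = pdist(x)
        # monotone regression of configuration distances on dissimilarity rank;
        # IsotonicRegression averages within tied-x blocks (weak/secondary ties)
        disparities = iso.fit_transform(d[order], dist[order])
        dhat = np.empty_like(dist)
        dhat[order] = disparities
        # scale so the Guttman step targets distances of comparable magnitude
        scale = np.sqrt((dist**2).sum() / max((dhat**2).sum(), 1e-300))
        dhat = dhat * scale
        trace.append(_stress1(dist, dhat))
        raw = ((dist - dhat) ** 2).sum()
        if np.isfinite(prev_raw) and prev_raw - raw <= tol * max(prev_raw, 1e-300):
            break
        prev_raw = raw
        # Guttman transform toward the disparities
        ratio = np.where(dist > 1e-12, dhat / np.maximum(dist, 1e-12), 0.0)
        b = -squareform(ratio, checks=False)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    dist = pdist(x)
    disparities = iso.fit_transform(d[order], dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = disparities
    return x, _stress1(dist, dhat), trace


def _orient(x: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix signs for reproducibility."""
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        col = x[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            x[:, j] = -col
    return x


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Best-of-restarts non-metric MDS on a dissimilarity matrix."""
    values = np.asarray(d.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise TableValidationError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise TableValidationError("dissimilarity matrix must be symmetric")
    if k < 1 or n_restarts < 1:
        raise TableValidationError("k and n_restarts must be >= 1")
    condensed = squareform(values, checks=False)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    restart_stresses = []
    for _ in range(n_restarts):
        x, stress, trace = _single_run(condensed, k, rng, max_iter, tol)
        restart_stresses.append(stress)
        if best is None or stress < best[1]:
            best = (x, stress, trace)
    assert best is not None
    return OrdinationResult(
        ids=list(d.ids),
        coordinates=_orient(best[0]),
        stress=best[1],
        stress_trace=best[2],
        restart_stresses=restart_stresses,
        seed=seed,
    )
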