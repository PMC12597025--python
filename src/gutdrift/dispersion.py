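"""Beta-diversity as multivariate dispersion in principal-coordinate space.

Mirrors the betadisper-style analysis: square-root transform of the
dissimilarities, principal coordinates analysis retaining negative-eigenvalue
("imaginary") axes, distance of each sample to its group's spatial median
under the subtractive real/imaginary metric, and an n/(n-1) small-sample
bias correction.  Group beta is the mean corrected distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

#: eigenvalues with |lambda| <= EIG_TOL_FACTOR * max|lambda| are treated as zero
EIG_TOL_FACTOR = 1e-8


@dataclass
class OrdinationResult:
    """PCoA embedding that keeps both real and imaginary axes.

    ``real`` holds coordinates on positive-eigenvalue axes (scaled by
    sqrt(lambda)); ``imag`` holds coordinates on negative-eigenvalue axes
    (scaled by sqrt(|lambda|)).  Squared input dissimilarities are recovered
    as (real-block squared distance) - (imag-block squared distance).
    """

    sample_ids: list
    real: np.ndarray  # (n, r)
    imag: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # descending, length n

    def reconstructed_sq_dissimilarity(self) -> np.ndarray:
        """(n, n) matrix of real^2 - imag^2 squared distances (may be <0)."""
        d2r = _sq_dists(self.real)
        d2i = _sq_dists(self.imag)
        return d2r - d2i


def _sq_dists(x: np.ndarray) -> np.ndarray:
    if x.shape[1] == 0:
        return np.zeros((x.shape[0], x.shape[0]))
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, d2.T)  # enforce exact symmetry


def sqrt_transform(dm: DistanceMatrix) -> DistanceMatrix:
    """Element-wise square root of a dissimilarity matrix.

    A monotone transform that makes semimetric dissimilarities such as
    Bray-Curtis closer to Euclidean-embeddable, reducing the weight of
    negative eigenvalues in the ordination.
    """
    data = dm.data
    if (data < 0).any():
        raise ValueError("dissimilarities must be nonnegative")
    return DistanceMatrix(np.sqrt(data), ids=dm.ids)


def pcoa(dm: DistanceMatrix, tol_factor: float = EIG_TOL_FACTOR) -> OrdinationResult:
    """Principal coordinates analysis retaining imaginary axes.

    Gower-centers -0.5 * D^2 and eigendecomposes; axes with eigenvalue
    above ``tol`` become real axes, axes below ``-tol`` imaginary axes, and
    near-zero axes are dropped.  Unlike ordinations that discard negative
    eigenvalues, the imaginary block is needed for the subtractive distance
    used by the dispersion analysis.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    # Gower double-centering: G = (I - 11'/n) A (I - 11'/n)
    row_means = a.mean(axis=1, keepdims=True)
    col_means = a.mean(axis=0, keepdims=True)
    g = a - row_means - col_means + a.mean()
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = tol_factor * max(np.abs(eigvals).max(), 1e-300)
    pos = eigvals > tol
    neg = eigvals < -tol
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return OrdinationResult(
        sample_ids=list(dm.ids),
        real=real,
        imag=imag,
        eigenvalues=eigvals,
    )


def _weiszfeld(points: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Geometric median of rows of ``points`` by damped Weiszfeld iteration.

    n=1 returns the point; n=2 returns the midpoint (the symmetric
    representative of the non-unique minimizer on the segment).
    """
    n, d = points.shape
    if d == 0:
        return np.zeros(0)
    if n == 1:
        return points[0].copy()
    if n == 2:
        return points.mean(axis=0)
    y = points.mean(axis=0)
    eps = 1e-12
    for _ in range(max_iter):
        dists = np.linalg.norm(points - y, axis=1)
        w = 1.0 / np.maximum(dists, eps)
        y_new = (w[:, None] * points).sum(axis=0) / w.sum()
        # damping toward the previous iterate keeps the step stable when the
        # iterate lands on (or very near) a data point
        y_new = 0.9 * y_new + 0.1 * y
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def spatial_median(
    ordination: OrdinationResult, indices: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial (geometric) median of a set of ordination rows.

    Computed per block: the real-block median minimizes summed Euclidean
    distances among real coordinates, and the imaginary block is treated the
    same way in its own subspace; the subtractive metric is applied only
    when distances to the median are evaluated.
    """
    if indices is None:
        indices = range(len(ordination.sample_ids))
    idx = np.asarray(list(indices), dtype=int)
    if idx.size < 1:
        raise ValueError("spatial_median needs at least one point")
    return _weiszfeld(ordination.real[idx]), _weiszfeld(ordination.imag[idx])


def centroid(
    ordination: OrdinationResult, indices: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block arithmetic mean, the alternative group center."""
    if indices is None:
        indices = range(len(ordination.sample_ids))
    idx = np.asarray(list(indices), dtype=int)
    if idx.size < 1:
        raise ValueError("centroid needs at least one point")
    return ordination.real[idx].mean(axis=0), ordination.imag[idx].mean(axis=0)


def distance_to_median(
    point: tuple[np.ndarray, np.ndarray], median: tuple[np.ndarray, np.ndarray]
) -> float:
    """Distance from a sample to a group center under the subtractive metric.

    z = sqrt(max(0, d_real^2 - d_imag^2)); the imaginary block contributes
    negatively, and negative squared distances clamp to zero.
    """
    pr, pi = point
    mr, mi = median
    if pr.shape != mr.shape or pi.shape != mi.shape:
        raise ValueError(
            f"axis structure mismatch: point ({pr.shape}, {pi.shape}) vs "
            f"median ({mr.shape}, {mi.shape})"
        )
    d2 = np.sum((pr - mr) ** 2) - np.sum((pi - mi) ** 2)
    return float(np.sqrt(max(0.0, d2)))


def bias_adjust(distances: np.ndarray, n: int) -> np.ndarray:
    """Small-sample bias correction: multiply distances by sqrt(n/(n-1))."""
    if n < 2:
        raise ValueError("bias adjustment requires n >= 2")
    return np.asarray(distances, dtype=float) * np.sqrt(n / (n - 1))


@dataclass
class DispersionResult:
    """Dispersion of one group: per-sample distances and their mean (beta)."""

    group: Hashable
    n: int
    sample_ids: list
    distances: np.ndarray
    beta: float
    sqrt_dist: bool
    bias_adjusted: bool


@dataclass
class GroupDispersion:
    """Container for per-group dispersion results and skipped groups."""

    results: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": str(r.group),
                "n": r.n,
                "beta": r.beta,
                "sqrt_dist": r.sqrt_dist,
                "bias_adjust": r.bias_adjusted,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows)

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results.values():
            for sid, dist in zip(r.sample_ids, r.distances):
                rows.append({"sample_id": sid, "group": str(r.group), "distance": dist})
        return pd.DataFrame(rows)


def group_dispersion(
    dm: DistanceMatrix,
    groups: Mapping[str, Hashable] | pd.Series,
    sqrt_dist: bool = True,
    bias: bool = True,
    center: str = "spatial_median",
) -> GroupDispersion:
    """Multivariate dispersion of each group of samples.

    Pipeline: optional square-root transform of the dissimilarities, PCoA
    keeping imaginary axes, per-group center (spatial median by default,
    ``center='centroid'`` for the mean), per-sample distance to the center
    under the subtractive metric, optional n/(n-1) bias adjustment, and the
    group mean as beta.  Groups with fewer than 2 samples are skipped with
    a warning.
    """
    if center not in ("spatial_median", "centroid"):
        raise ValueError(f"unknown center {center!r}")
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    missing = [s for s in dm.ids if s not in groups]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    work = sqrt_transform(dm) if sqrt_dist else dm
    ordination = pcoa(work)
    id_pos = {sid: i for i, sid in enumerate(ordination.sample_ids)}
    by_group: dict = {}
    for sid in dm.ids:
        by_group.setdefault(groups[sid], []).append(sid)
    out = GroupDispersion()
    center_fn = spatial_median if center == "spatial_median" else centroid
    for label in by_group:
        members = by_group[label]
        n = len(members)
        if n < 2:
            logger.warning("group %r has n=%d < 2; skipped", label, n)
            out.skipped.append(label)
            continue
        idx = [id_pos[s] for s in members]
        med = center_fn(ordination, idx)
        dists = np.array(
            [
                distance_to_median(
                    (ordination.real[i], ordination.imag[i]), med
                )
                for i in idx
            ]
        )
        if bias:
            dists = bias_adjust(dists, n)
        out.results[label] = DispersionResult(
            group=label,
            n=n,
            sample_ids=members,
            distances=dists,
            beta=float(dists.mean()),
            sqrt_dist=sqrt_dist,
            bias_adjusted=bias,
        )
    return out
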