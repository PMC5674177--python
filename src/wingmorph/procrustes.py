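"""Generalized Procrustes superimposition and Kendall tangent-space tools.

The superimposition removes translation (centring), size (unit centroid
size) and orientation (least-squares rotation) from every configuration,
leaving pure shape.  Rotation is restricted to proper rotations
(determinant +1): left/right wings are reflections of one another and a
silent reflection match would hide digitisation errors, so mirroring must
be requested explicitly upstream (:func:`wingmorph.tps.mirror`).

"Procrustes distance" throughout means the *partial* Procrustes distance —
the Euclidean norm of the difference between two unit-size configurations
after optimal rotation — which is exactly the geometry the aligned
coordinates and tangent projection inherit, so the tangent-space adequacy
check below is self-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateShapeError, ValidationError
from .tps import LandmarkConfiguration, ShapeDataset

#: Relative singular-value ratio below which the pairwise rotation problem
#: is considered rank-deficient (nearly collinear shapes).
_DEGENERATE_SV_RATIO = 1e-12


@dataclass
class AlignedShapes:
    """Result of generalized Procrustes superimposition.

    Attributes
    ----------
    specimen_ids:
        Order matches ``aligned`` rows.
    aligned:
        ``(n, k, 2)`` superimposed coordinates: centred, unit centroid size,
        optimally rotated to the consensus.
    consensus:
        ``(k, 2)`` mean shape, unit centroid size.
    centroid_sizes:
        ``(n,)`` original (pre-scaling) centroid sizes.
    tangent:
        ``(n, 2k)`` tangent-space coordinates at the consensus.
    iterations, converged:
        Iteration count of the alignment and whether the consensus moved by
        less than the tolerance before the iteration cap.
    """

    specimen_ids: list[str]
    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    tangent: np.ndarray
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


@dataclass
class TangentCheckResult:
    """Tangent-space adequacy statistics.

    ``slope`` is the through-origin least-squares slope of tangent Euclidean
    distances on Procrustes distances over all specimen pairs; values of
    both statistics near 1 justify doing linear multivariate statistics in
    the tangent plane.
    """

    slope: float
    correlation: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "correlation": self.correlation,
            "n_pairs": self.n_pairs,
        }


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances to the centroid."""
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(coords - coords.mean(axis=0)))


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def preshape(config) -> tuple[np.ndarray, float]:
    """Centre a configuration and scale it to unit centroid size.

    Returns the pre-shape (centroid exactly at the origin, centroid size
    exactly 1) together with the original centroid size.
    """
    coords = _as_coords(config)
    centred = coords - coords.mean(axis=0)
    size = float(np.linalg.norm(centred))
    if size < 1e-12:
        name = getattr(config, "specimen_id", "configuration")
        raise DegenerateShapeError(f"{name}: zero centroid size (all landmarks coincide)")
    return centred / size, size


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` (2x2, det +1) minimising ``||a @ R - b||``.

    Solved from the SVD of the cross-covariance ``a.T @ b`` with the usual
    determinant correction that forbids reflection.  When the
    cross-covariance is rank deficient the optimum is not unique; the SVD's
    deterministic sign convention (non-negative singular values, fixed
    column ordering) picks one rotation reproducibly and a warning is
    emitted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if s[0] <= 0 or s[1] / s[0] < _DEGENERATE_SV_RATIO:
        warnings.warn(
            "rank-deficient cross-covariance: optimal rotation is not unique; "
            "using the SVD tie-break",
            RuntimeWarning,
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    Both inputs are preshaped, ``a`` is optimally rotated onto ``b``, and
    the Euclidean norm of the residual is returned.  Symmetric; zero iff
    the shapes are identical up to translation, scale and proper rotation
    (reflection is NOT removed).
    """
    pa, _ = preshape(a)
    pb, _ = preshape(b)
    if pa.shape != pb.shape:
        raise ValidationError(f"landmark count mismatch: {pa.shape[0]} vs {pb.shape[0]}")
    r = optimal_rotation(pa, pb)
    return float(np.linalg.norm(pa @ r - pb))


def _orient_consensus(aligned: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic orientation: rotate the whole aligned set so the
    # consensus's first landmark-pair axis points along +x.  Makes outputs
    # identical across runs, input orderings and platforms.
    v = consensus[1] - consensus[0]
    theta = np.arctan2(v[1], v[0])
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, s], [-s, c]])  # applied as coords @ rot
    return aligned @ rot, consensus @ rot


def tangent_coordinates(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Project aligned configurations into the tangent space at the consensus.

    Each configuration is flattened to a 2k-vector, its component along the
    (unit) consensus direction is removed, and the consensus is subtracted;
    the consensus itself therefore maps to the zero vector and every tangent
    vector is orthogonal to the flattened consensus.
    """
    c = consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    x = aligned.reshape(aligned.shape[0], -1) if aligned.ndim == 3 else np.atleast_2d(aligned)
    # removing the component along c also removes the consensus itself
    # (c is unit, so its projection is exactly c): the consensus maps to 0
    return x - np.outer(x @ c, c)


def gpa(dataset, tol: float = 1e-10, max_iter: int = 100) -> AlignedShapes:
    """Generalized (least-squares) Procrustes superimposition.

    Iterates: preshape every configuration, rotate each onto the current
    consensus, recompute the consensus as the arithmetic mean rescaled to
    unit centroid size, until the consensus moves by less than ``tol`` or
    ``max_iter`` is reached.  The result is invariant (up to a common
    rotation, fixed by a deterministic orientation rule) to the input
    ordering and to arbitrary similarity transforms of the inputs.
    """
    if isinstance(dataset, ShapeDataset):
        dataset.validate()
        configs = dataset.configurations
    else:
        configs = list(dataset)
    if len(configs) < 2:
        raise ValidationError("gpa needs at least 2 configurations")
    ids = [getattr(c, "specimen_id", f"specimen_{i}") for i, c in enumerate(configs)]

    preshapes = []
    sizes = []
    bad = []
    for c, sid in zip(configs, ids):
        try:
            p, s = preshape(c)
        except DegenerateShapeError:
            bad.append(sid)
            continue
        preshapes.append(p)
        sizes.append(s)
    if bad:
        raise DegenerateShapeError(f"degenerate configurations: {bad}")
    preshapes = np.stack(preshapes)
    sizes = np.asarray(sizes)

    consensus = preshapes[0]
    aligned = preshapes
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = np.stack([p @ optimal_rotation(p, consensus) for p in preshapes])
        new_consensus = aligned.mean(axis=0)
        norm = np.linalg.norm(new_consensus)
        if norm < 1e-12:
            raise DegenerateShapeError("consensus collapsed to zero (antipodal shapes)")
        new_consensus = new_consensus / norm
        movement = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if movement < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iter} iterations", RuntimeWarning, stacklevel=2
        )

    aligned, consensus = _orient_consensus(aligned, consensus)
    tangent = tangent_coordinates(aligned, consensus)
    return AlignedShapes(
        specimen_ids=ids,
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        tangent=tangent,
        iterations=iterations,
        converged=converged,
    )


def align_to_consensus(config, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Superimpose one configuration on a fixed consensus (a posteriori).

    The consensus is NOT recomputed; this is how an unknown specimen is
    placed into an already-aligned reference sample.  Returns the aligned
    ``(k, 2)`` coordinates and the ``(2k,)`` tangent vector.
    """
    p, _ = preshape(config)
    if p.shape != consensus.shape:
        raise ValidationError(
            f"landmark count mismatch: {p.shape[0]} vs consensus {consensus.shape[0]}"
        )
    aligned = p @ optimal_rotation(p, consensus)
    tangent = tangent_coordinates(aligned[None], consensus)[0]
    return aligned, tangent


def tangent_adequacy(dataset, tol: float = 1e-10, max_iter: int = 100) -> TangentCheckResult:
    """Check how well the tangent plane approximates shape space.

    Computes every pairwise partial Procrustes distance and the matching
    Euclidean distance between tangent vectors, then the through-origin
    regression slope (tangent on Procrustes) and the product-moment
    correlation over pairs.  Both near 1 mean shape variation is small
    enough for linear multivariate methods.
    """
    if isinstance(dataset, ShapeDataset):
        configs = dataset.configurations
    else:
        configs = list(dataset)
    if len(configs) < 3:
        raise ValidationError("tangent adequacy needs at least 3 specimens")
    result = gpa(configs, tol=tol, max_iter=max_iter)
    tangent_d = pdist(result.tangent)

    preshapes = [preshape(c)[0] for c in configs]
    n = len(preshapes)
    proc_d = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            r = optimal_rotation(preshapes[i], preshapes[j])
            proc_d[idx] = np.linalg.norm(preshapes[i] @ r - preshapes[j])
            idx += 1

    denom = float(np.dot(proc_d, proc_d))
    if proc_d.max() < 1e-12:
        raise DegenerateShapeError(
            "all shapes identical: distance statistics are undefined"
        )
    slope = float(np.dot(tangent_d, proc_d) / denom)
    if np.std(proc_d) == 0.0 or np.std(tangent_d) == 0.0:
        # all pair distances equal: the two distance sets are trivially
        # collinear through the origin
        correlation = 1.0
    else:
        correlation = float(np.corrcoef(tangent_d, proc_d)[0, 1])
    return TangentCheckResult(slope=slope, correlation=correlation, n_pairs=len(proc_d))
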