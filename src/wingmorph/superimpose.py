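"""Generalized Procrustes superimposition and tangent-space geometry.

Shape is what remains of a landmark configuration after position, scale and
orientation are removed.  Each configuration is centred and scaled to unit
centroid size (a *preshape*); generalized Procrustes analysis (GPA) then
iteratively rotates all preshapes onto a consensus until the consensus
stabilizes.  Statistics are done in the Euclidean space tangent to Kendall's
shape space at the consensus, and the adequacy of that linearization is
checked by regressing tangent distances on shape-space (rho) distances —
a slope and uncentred correlation near 1 licenses linear multivariate
methods downstream.

Conventions: unit centroid size is enforced for every specimen throughout
(partial Procrustes; no residual per-specimen scale fitting), and reflections
are never fitted — handedness is handled explicitly at ingest by
:func:`wingmorph.tps.reflect_configuration`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .tps import LandmarkConfiguration, LandmarkDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Preshape",
    "GPAResult",
    "TangentScores",
    "AdequacyReport",
    "DegenerateConfigurationError",
    "centroid_size",
    "to_preshape",
    "optimal_rotation",
    "procrustes_distance",
    "gpa",
    "project_to_tangent",
    "tangent_adequacy",
]


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide: the configuration has no shape."""


@dataclass(frozen=True)
class Preshape:
    """A centred, unit-centroid-size configuration (a point on the preshape sphere)."""

    coordinates: np.ndarray  # (k, 2)
    source_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        scale = float(np.abs(coords).max())
        if np.abs(coords.mean(axis=0)).max() > 1e-9 * max(scale, 1.0):
            raise ValueError(f"{self.source_id}: preshape centroid is not at the origin")
        if abs(np.linalg.norm(coords) - 1.0) > 1e-9:
            raise ValueError(f"{self.source_id}: preshape centroid size is not 1")
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class GPAResult:
    """Outcome of a generalized Procrustes superimposition."""

    consensus: Preshape
    aligned: tuple[Preshape, ...]          # input order
    centroid_sizes: np.ndarray             # original units, per specimen
    iterations: int
    converged: bool
    total_sum_of_squares_trace: np.ndarray  # objective after each iteration

    @property
    def n(self) -> int:
        return len(self.aligned)

    @property
    def k(self) -> int:
        return self.consensus.k

    def aligned_array(self) -> np.ndarray:
        """Aligned coordinates stacked as (n, k, 2)."""
        return np.stack([p.coordinates for p in self.aligned])


@dataclass(frozen=True)
class TangentScores:
    """Vectorized tangent-space deviations from the consensus (one row per specimen)."""

    matrix: np.ndarray  # (n, 2k)
    basis_note: str
    rank_bound: int     # 2k - 4 for planar landmarks


@dataclass(frozen=True)
class AdequacyReport:
    """Through-origin regression of tangent distances on shape-space distances.

    ``slope`` near 1 (and uncentred ``correlation`` near 1) means the tangent
    plane is an adequate flat approximation of shape space for this sample.
    """

    slope: float
    correlation: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Elementary operations


def _coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.landmarks
    if isinstance(config, Preshape):
        return config.coordinates
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    coords = _coords(config)
    centered = coords - coords.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return size


def to_preshape(config) -> Preshape:
    """Centre and scale a configuration to unit centroid size."""
    coords = _coords(config)
    centered = coords - coords.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    source_id = config.specimen_id if isinstance(config, LandmarkConfiguration) else ""
    return Preshape(coordinates=centered / size, source_id=source_id)


def optimal_rotation(source: Preshape | np.ndarray, target: Preshape | np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ``||source @ R - target||`` (no reflections).

    Solved from the SVD of the 2x2 cross-product matrix with the determinant
    constrained to +1, so a mirror image is never silently un-mirrored.
    """
    a, b = _coords(source), _coords(target)
    if a.shape != b.shape:
        raise ValueError(f"configurations differ in shape: {a.shape} vs {b.shape}")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def procrustes_distance(a, b, metric: str = "partial") -> float:
    """Shape distance after optimal (proper) rotation.

    ``partial``: chordal distance ``||a R - b||`` on the preshape sphere;
    ``rho``: the arc (geodesic) distance ``arccos <a R, b>``.  Both vanish
    iff the shapes coincide up to translation, scale and rotation.
    """
    pa = a if isinstance(a, Preshape) else to_preshape(a)
    pb = b if isinstance(b, Preshape) else to_preshape(b)
    if pa.k != pb.k:
        raise ValueError(f"landmark counts differ: {pa.k} vs {pb.k}")
    # complex representation: rotating a by theta multiplies it by e^{i theta},
    # and the optimal angle aligns the phase of the Hermitian inner product
    za = pa.coordinates[:, 0] + 1j * pa.coordinates[:, 1]
    zb = pb.coordinates[:, 0] + 1j * pb.coordinates[:, 1]
    partial = _partial_complex(za, zb)
    if metric == "partial":
        return partial
    if metric == "rho":
        return float(2.0 * np.arcsin(min(partial / 2.0, 1.0)))
    raise ValueError(f"unknown metric {metric!r}")


def _partial_complex(za: np.ndarray, zb: np.ndarray) -> float:
    """Partial Procrustes distance between two complex preshape vectors.

    Computed by rotating and subtracting rather than via ``2 - 2 cos``, which
    loses half the significant digits for nearly identical shapes.
    """
    ip = np.vdot(za, zb)
    mod = abs(ip)
    phase = ip / mod if mod > 0 else 1.0
    return float(np.linalg.norm(za * phase - zb))


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis


def _rotate_all_to(z: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Optimally rotate each complex row configuration onto complex consensus c."""
    ip = z @ c.conj()                    # (n,) complex inner products
    mod = np.abs(ip)
    # unit phase; a zero inner product (antipodal/degenerate) keeps phase 1
    phase = np.where(mod > 0, ip / np.where(mod > 0, mod, 1.0), 1.0)
    return z * phase.conj()[:, None]


def gpa(
    dataset: LandmarkDataset | list,
    tol: float = 1e-8,
    max_iter: int = 100,
    orient_principal_axis: bool = True,
) -> GPAResult:
    """Generalized least-squares Procrustes superimposition.

    All configurations are centred and scaled to unit centroid size, then
    iteratively rotated onto a consensus; the consensus is recomputed as the
    mean of the aligned set rescaled to unit centroid size, until it moves
    less than ``tol`` (partial Procrustes distance) or ``max_iter`` is hit.

    When ``orient_principal_axis`` is set (default) the whole aligned set is
    finally rotated so the consensus's major principal axis is horizontal,
    with a deterministic sign convention, removing the arbitrary global
    rotation so repeated runs produce identical files.
    """
    configs = list(dataset)
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in configs])
    pres = [to_preshape(c) for c in configs]
    ids = [p.source_id for p in pres]
    k = pres[0].k
    for p in pres:
        if p.k != k:
            raise ValueError("all configurations must share one landmark count")

    z = np.stack([p.coordinates[:, 0] + 1j * p.coordinates[:, 1] for p in pres])  # (n, k)
    c = z[0].copy()  # consensus initialized from the first specimen

    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        z = _rotate_all_to(z, c)
        m = z.mean(axis=0)
        norm_m = np.linalg.norm(m)
        if norm_m == 0.0:
            raise ValueError("degenerate consensus (aligned shapes cancel out)")
        c_new = m / norm_m
        trace.append(float(np.sum(np.abs(z - c_new[None, :]) ** 2)))
        # movement of the consensus in partial Procrustes distance
        move = _partial_complex(c, c_new)
        c = c_new
        if move < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations (last move above tol)", max_iter)

    z = _rotate_all_to(z, c)

    if orient_principal_axis:
        rot = _principal_axis_phase(c)
        z = z * rot
        c = c * rot

    aligned = tuple(
        Preshape(np.column_stack([zi.real, zi.imag]), source_id=i) for zi, i in zip(z, ids)
    )
    consensus = Preshape(np.column_stack([c.real, c.imag]), source_id="consensus")
    return GPAResult(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        total_sum_of_squares_trace=np.asarray(trace),
    )


def _principal_axis_phase(c: np.ndarray) -> complex:
    """Unit phase rotating consensus c so its major principal axis lies on x.

    The remaining 180-degree ambiguity is resolved by making the x-coordinate
    skewness non-negative (falling back to y-skewness when x is symmetric);
    handedness is never flipped because only proper rotations are applied.
    """
    xy = np.column_stack([c.real, c.imag])
    cov = xy.T @ xy
    _, vecs = np.linalg.eigh(cov)
    major = vecs[:, -1]  # eigenvector of the largest eigenvalue
    phase = complex(major[0], -major[1])
    phase /= abs(phase)
    rotated = c * phase
    sx = float(np.sum(rotated.real**3))
    if abs(sx) < 1e-12:
        sy = float(np.sum(rotated.imag**3))
        if sy < 0:
            phase = -phase
    elif sx < 0:
        phase = -phase
    return phase


# ---------------------------------------------------------------------------
# Tangent space


def project_to_tangent(result: GPAResult) -> TangentScores:
    """Orthogonally project aligned preshapes onto the tangent plane at the consensus.

    Each vectorized aligned configuration ``x`` (unit norm) maps to
    ``x' = x - (x.c - 1) c`` with ``c`` the vectorized consensus, and the
    returned rows are the deviations ``x' - c``.  The row space has rank at
    most ``2k - 4``: 2 translation, 1 scale and 1 rotation degree of freedom
    are already removed.
    """
    if not result.converged:
        logger.warning("projecting a non-converged GPA result to tangent space")
    x = result.aligned_array().reshape(result.n, -1)            # (n, 2k)
    c = result.consensus.coordinates.reshape(-1)                # (2k,)
    proj = x - np.outer(x @ c - 1.0, c)
    return TangentScores(
        matrix=proj - c[None, :],
        basis_note="orthogonal projection onto the hyperplane tangent at the consensus, "
        "expressed as deviations from the consensus",
        rank_bound=2 * result.k - 4,
    )


def _pairwise_rho(aligned: np.ndarray) -> np.ndarray:
    """Condensed pairwise rho distances among (n, k, 2) aligned coordinates.

    Row-wise rotate-and-subtract keeps full precision for nearly identical
    shapes (an arccos of the Gram matrix bottoms out around 1e-8).
    """
    z = aligned[..., 0] + 1j * aligned[..., 1]
    n = len(z)
    ip = z.conj() @ z.T  # ip[i, j] = <z_i, z_j>
    mod = np.abs(ip)
    phase = np.where(mod > 0, ip / np.where(mod > 0, mod, 1.0), 1.0)
    out = []
    for i in range(n - 1):
        diff = z[i][None, :] * phase[i, i + 1 :, None] - z[i + 1 :]
        partial = np.linalg.norm(diff, axis=1)
        out.append(2.0 * np.arcsin(np.minimum(partial / 2.0, 1.0)))
    return np.concatenate(out)


def tangent_adequacy(result: GPAResult) -> AdequacyReport:
    """Check how well the tangent plane approximates shape space for this sample.

    All pairwise rho distances are compared with the corresponding Euclidean
    distances between tangent projections via a through-origin least-squares
    regression (slope) and the uncentred correlation.  Values close to 1 —
    expected whenever shape variation is small — justify treating the tangent
    scores with ordinary linear multivariate statistics.
    """
    if result.n < 3:
        raise ValueError("adequacy check needs at least 3 specimens")
    rho = _pairwise_rho(result.aligned_array())
    if rho.max() < 1e-12:
        raise ValueError("no shape variation: all specimens have identical shape")
    eu = pdist(project_to_tangent(result).matrix)
    slope = float(np.dot(eu, rho) / np.dot(rho, rho))
    corr = float(np.dot(eu, rho) / (np.linalg.norm(eu) * np.linalg.norm(rho)))
    return AdequacyReport(slope=slope, correlation=corr, n_pairs=len(rho))
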