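"""Interface geometry of protein dimers.

This module holds the geometric core of the growth-mode analysis: the
polymerization angle and dihedral that summarize a dimer interface, the
gyration-tensor shape descriptors used to judge how sphere-like a monomer
is, and rigid-body superposition.

The two angles are computed from four points measured on a dimer:

* ``GC_A``, ``GC_B`` -- geometric centers of monomers A and B;
* ``GC_IA``, ``GC_IB`` -- geometric centers of the interfacial residues of
  A (those in contact with B) and of B (those in contact with A).

The polymerization angle ``theta_pol`` is the angle at ``GC_IA`` between
the directions from each monomer center toward it; it encodes how much a
chain of replicated dimers bends per step.  The polymerization dihedral
``phi_pol`` is the angle between the planes spanned by the inter-center
axis and each interface centroid; it encodes the relative twist of the two
monomers.  Both are reported unsigned in [0, 180] degrees.

"Mapping onto the surface" of the partner monomer (projecting an interface
centroid radially onto the partner sphere) changes only vector lengths,
never directions, so all angles here are computed from direction vectors;
:func:`project_to_surface` is provided to make that invariance testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "PolymerizationAngles",
    "ShapeDescriptor",
    "RigidTransform",
    "polymerization_angle",
    "polymerization_dihedral",
    "project_to_surface",
    "shape_descriptor",
    "superpose",
    "angles_from_dimer",
]

_EPS = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when points are coincident/colinear and an angle is undefined."""


@dataclass(frozen=True)
class PolymerizationAngles:
    """The (theta_pol, phi_pol) pair summarizing a dimer interface, degrees."""

    theta: float
    phi: float

    def __post_init__(self) -> None:
        for name, value in (("theta", self.theta), ("phi", self.phi)):
            if not np.isfinite(value):
                raise DegenerateGeometryError(f"{name}_pol is not finite: {value}")
            if not 0.0 <= value <= 180.0:
                raise ValueError(f"{name}_pol must lie in [0, 180] deg, got {value}")


@dataclass(frozen=True)
class ShapeDescriptor:
    """Gyration-tensor shape summary of a point cloud.

    Attributes
    ----------
    rg : float
        Radius of gyration (same length unit as the input coordinates).
    lambdas : ndarray, shape (3,)
        Eigenvalues of the gyration tensor, sorted descending: the squared
        principal radii of gyration R_x^2 >= R_y^2 >= R_z^2.
    asphericity : float
        Relative shape anisotropy A_s in [0, 1]; 0 for three equal principal
        radii (ideal sphere), 1 in the collinear (rod) limit.
    sphericity : float
        psi = (1 - A_s) * 100, in percent.
    """

    rg: float
    lambdas: np.ndarray
    asphericity: float
    sphericity: float


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t.

    ``rotation`` must be orthonormal with determinant +1; ``translation`` is
    in the same length unit as the coordinates it acts on.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is improper (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or an array of points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))

    def power(self, k: int) -> "RigidTransform":
        """The k-fold iterate (k >= 0)."""
        if k < 0:
            raise ValueError("power requires k >= 0")
        out = RigidTransform.identity()
        for _ in range(k):
            out = self.compose(out)
        return out


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateGeometryError(f"{what} has (near-)zero length")
    return v / n


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def polymerization_angle(gc_a, gc_b, gc_ia) -> float:
    """Polymerization angle theta_pol in degrees.

    The angle between the direction from the center of monomer A toward the
    interface centroid GC_IA and the direction from the center of monomer B
    toward the same centroid (equivalently, toward GC_IA mapped onto B's
    surface -- the mapping preserves direction).

    Raises
    ------
    DegenerateGeometryError
        If GC_IA coincides with either monomer center.
    """
    gc_a = np.asarray(gc_a, dtype=float)
    gc_b = np.asarray(gc_b, dtype=float)
    gc_ia = np.asarray(gc_ia, dtype=float)
    v1 = _unit(gc_ia - gc_a, "vector GC_A -> GC_IA")
    v2 = _unit(gc_ia - gc_b, "vector GC_B -> GC_IA")
    return _angle_between(v1, v2)


def polymerization_dihedral(gc_a, gc_b, gc_ia, gc_ib) -> float:
    """Polymerization dihedral phi_pol in degrees, unsigned in [0, 180].

    ``P_A = (GC_B - GC_A) x (GC_IB - GC_A)`` is the normal of the plane
    spanned by the inter-center axis and B's interface centroid (seen from
    A); ``P_B = (GC_A - GC_B) x (GC_IA - GC_B)`` is the analogous normal on
    the B side.  phi_pol is the angle between the two normals.

    Raises
    ------
    DegenerateGeometryError
        If either defining triple is colinear (its plane collapses).
    """
    gc_a = np.asarray(gc_a, dtype=float)
    gc_b = np.asarray(gc_b, dtype=float)
    gc_ia = np.asarray(gc_ia, dtype=float)
    gc_ib = np.asarray(gc_ib, dtype=float)
    p_a = np.cross(gc_b - gc_a, gc_ib - gc_a)
    if np.linalg.norm(p_a) < _EPS:
        raise DegenerateGeometryError(
            "plane (GC_A, GC_B, GC_IB) is degenerate: the three points are colinear"
        )
    p_b = np.cross(gc_a - gc_b, gc_ia - gc_b)
    if np.linalg.norm(p_b) < _EPS:
        raise DegenerateGeometryError(
            "plane (GC_B, GC_A, GC_IA) is degenerate: the three points are colinear"
        )
    return _angle_between(p_a / np.linalg.norm(p_a), p_b / np.linalg.norm(p_b))


def project_to_surface(center, point, radius: float = 1.0) -> np.ndarray:
    """Map ``point`` radially onto the sphere of ``radius`` around ``center``.

    Direction-preserving normalization: angle computations are invariant
    under this mapping, which is why the angle functions accept raw centroids.
    """
    center = np.asarray(center, dtype=float)
    d = _unit(np.asarray(point, dtype=float) - center, "center -> point direction")
    return center + radius * d


def shape_descriptor(coordinates, weights=None) -> ShapeDescriptor:
    """Gyration-tensor shape descriptor of a point cloud.

    Parameters
    ----------
    coordinates : array-like, shape (n, 3)
    weights : None or array-like, shape (n,)
        ``None`` for uniform (geometric) weighting; pass atomic masses for a
        mass-weighted tensor.

    Notes
    -----
    With lambda_i the eigenvalues of the (weighted) gyration tensor and
    lambda_bar their mean, the asphericity is

        A_s = (3/2) * sum_i (lambda_i - lambda_bar)^2 / (sum_i lambda_i)^2

    which is 0 when the three principal radii are equal, 1 for collinear
    points, and bounded by [0, 1] for every configuration.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must have shape (n, 3)")
    if len(coords) == 0:
        raise ValueError("no coordinates given")
    if weights is None:
        w = np.ones(len(coords))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(coords),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    centered = coords - w @ coords
    tensor = (centered * w[:, None]).T @ centered
    lambdas = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    lambdas = np.clip(lambdas, 0.0, None)
    trace = float(lambdas.sum())
    if trace < _EPS:
        raise DegenerateGeometryError(
            "all points coincide: radius of gyration is zero, shape undefined"
        )
    lam_bar = trace / 3.0
    asph = 1.5 * float(np.sum((lambdas - lam_bar) ** 2)) / trace**2
    asph = float(np.clip(asph, 0.0, 1.0))
    return ShapeDescriptor(
        rg=float(np.sqrt(trace)),
        lambdas=lambdas,
        asphericity=asph,
        sphericity=(1.0 - asph) * 100.0,
    )


def superpose(mobile, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rigid transform minimizing the RMSD between the
    transformed mobile points and the target points, together with the
    post-fit RMSD.

    Raises
    ------
    ValueError
        For fewer than 3 points, mismatched shapes, or a rank-deficient
        (all points colinear/coincident) configuration.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("mobile and target must both have shape (n, 3)")
    if len(X) < 3:
        raise ValueError("superposition requires at least 3 points")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < _EPS * max(1.0, S[0]):
        raise ValueError(
            "rank-deficient configuration: points are colinear or coincident"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    delta = transform.apply(X) - Y
    rmsd = float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))
    return transform, rmsd


def angles_from_dimer(descriptor) -> PolymerizationAngles:
    """Polymerization angles of a dimer from its interface descriptor.

    ``descriptor`` is an :class:`~dimergrow.interface.InterfaceDescriptor`
    (anything exposing ``gc_a``, ``gc_b``, ``gc_ia``, ``gc_ib`` and
    ``no_interface``).  Raises ``ValueError`` for a descriptor flagged
    "no interface": angles of a non-contacting pair are meaningless.
    """
    if getattr(descriptor, "no_interface", False):
        raise ValueError(
            "dimer has no interface (no residue buried above threshold); "
            "polymerization angles are undefined"
        )
    theta = polymerization_angle(descriptor.gc_a, descriptor.gc_b, descriptor.gc_ia)
    phi = polymerization_dihedral(
        descriptor.gc_a, descriptor.gc_b, descriptor.gc_ia, descriptor.gc_ib
    )
    return PolymerizationAngles(theta=theta, phi=phi)
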