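"""Idealized two-sphere dimer model and growth-mode classification.

A dimer is reduced to two tangent unit spheres: monomer A centered at the
origin, monomer B at (-2, 0, 0).  Its interface is summarized by the
polymerization angle theta_pol and dihedral phi_pol, and the dimer is
propagated into a chain by iterating the rigid transform that maps monomer
A onto monomer B.  A chain whose non-adjacent spheres overlap within the
propagation horizon is classified *limited* (it collides with itself or
closes into a ring); otherwise growth is *unlimited*.

Construction
------------
The remaining rigid degrees of freedom of the (theta, phi) -> dimer map
are fixed by a backbone convention: the chain of sphere centers is the
screw-generated chain with

* bond length 2 (tangency),
* bond angle theta at every center, and
* backbone torsion phi between consecutive center quadruples.

This makes theta = 180 deg a straight chain and yields the limited regime
below 60 deg analytically: the gap-2 center distance is 4*sin(theta/2),
which drops below the sphere diameter exactly at theta = 60 deg.

Interface markers are placed exactly: the marker of A sits at polar angle
``alpha_A = 180 - theta - arcsin(sin(theta)/2)`` from the bond direction
(the unique surface point measuring theta), and the marker of B at the
mirrored polar position rotated by ``180 - phi`` degrees about the
inter-center axis, which measures phi exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, superpose

__all__ = [
    "SphereDimer",
    "SphereChain",
    "OverlapResult",
    "ScrewParameters",
    "GrowthClassification",
    "build_sphere_dimer",
    "propagate_chain",
    "detect_overlap",
    "screw_parameters",
    "helix_radius",
    "classify_sphere_growth",
]

CENTER_A = np.zeros(3)
CENTER_B = np.array([-2.0, 0.0, 0.0])


@dataclass(frozen=True)
class SphereDimer:
    """Two decorated unit spheres plus the A -> B propagation transform."""

    theta: float
    phi: float
    center_a: np.ndarray
    center_b: np.ndarray
    iface_a: np.ndarray  # marker point on sphere A (GC_IA analogue)
    iface_b: np.ndarray  # marker point on sphere B (GC_IB analogue)
    transform: RigidTransform


@dataclass(frozen=True)
class SphereChain:
    """Ordered monomer centers of a propagated sphere chain (radius 1)."""

    centers: np.ndarray
    transform: RigidTransform
    radius: float = 1.0

    @property
    def n_monomers(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class OverlapResult:
    """Non-adjacent sphere overlaps within a chain."""

    pairs: tuple[tuple[int, int], ...]
    min_distance: float
    min_pair: tuple[int, int]

    @property
    def overlapping(self) -> bool:
        return bool(self.pairs)

    @property
    def first_pair(self) -> tuple[int, int] | None:
        return self.pairs[0] if self.pairs else None


@dataclass(frozen=True)
class ScrewParameters:
    """Chasles decomposition of a rigid transform."""

    axis: np.ndarray
    angle: float  # degrees, in [0, 180]
    pitch: float  # translation component along the axis, per step


@dataclass(frozen=True)
class GrowthClassification:
    """Growth mode verdict with its geometric evidence."""

    mode: str  # "limited" | "unlimited"
    subtype: str  # "h2h" | "doughnut" | "helical" | "linear" | "generic"
    min_nonadjacent_distance: float
    first_overlap: tuple[int, int] | None
    screw_angle: float  # degrees
    screw_pitch: float  # sphere-radius units per step
    helix_radius: float  # distance of centers from the screw axis
    theta: float
    phi: float


def _marker_polar(theta_deg: float) -> float:
    """Polar angle (deg, from the bond direction) of the surface marker.

    For a unit sphere at distance 1 from its center and the partner center
    at distance 2, the marker measuring a polymerization angle theta sits at
    ``180 - theta - arcsin(sin(theta)/2)`` degrees from the bond direction
    (sine rule in the triangle center_A -- marker -- center_B).
    """
    th = np.radians(theta_deg)
    return 180.0 - theta_deg - np.degrees(np.arcsin(np.sin(th) / 2.0))


def _rot_x(deg: float) -> np.ndarray:
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


def _backbone(theta: float, phi: float) -> np.ndarray:
    """Virtual center quadruple (c_-1, c_0, c_1, c_2) defining the screw.

    c_0 = origin, c_1 = (-2, 0, 0); c_-1 lies in the +y half of the xy
    plane at bond angle theta; c_2 continues the chain at bond angle theta
    with torsion phi.
    """
    th = np.radians(theta)
    c_m1 = np.array([-2.0 * np.cos(th), 2.0 * np.sin(th), 0.0])
    c0 = CENTER_A
    c1 = CENTER_B
    # internal-coordinate placement of c_2
    tor = np.radians(phi)
    bc = c1 - c0
    bc = bc / np.linalg.norm(bc)
    ab = c0 - c_m1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    local = np.array(
        [
            -2.0 * np.cos(th),
            2.0 * np.sin(th) * np.cos(tor),
            2.0 * np.sin(th) * np.sin(tor),
        ]
    )
    c2 = c1 + np.column_stack([bc, m, n]) @ local
    return np.array([c_m1, c0, c1, c2])


def build_sphere_dimer(theta: float, phi: float) -> SphereDimer:
    """Construct the decorated sphere dimer realizing (theta, phi).

    ``theta`` in (0, 180) and ``phi`` in [0, 180] degrees.  The boundary
    values theta = 0 and theta = 180 fall back to analytic colinear
    constructions: a pure translation along the inter-center axis for 180
    (straight chain) and a half-turn fold-back for 0.
    """
    if not 0.0 <= theta <= 180.0 or not 0.0 <= phi <= 180.0:
        raise ValueError("theta and phi must lie in [0, 180] degrees")

    polar = _marker_polar(theta)
    alpha = np.radians(180.0 - polar)  # marker angle from +x (away from B)
    iface_a = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    psi = 180.0 - phi  # azimuth of the mirrored B marker about the x-axis
    iface_b = CENTER_B + _rot_x(psi) @ np.array(
        [-np.cos(alpha), np.sin(alpha), 0.0]
    )

    if theta >= 180.0:
        transform = RigidTransform(np.eye(3), CENTER_B.copy())
    elif theta <= 0.0:
        # fold-back: half turn about the z-axis through the contact point
        half_turn = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()
        transform = RigidTransform(half_turn, CENTER_B.copy())
    else:
        quad = _backbone(theta, phi)
        transform, rmsd = superpose(quad[:3], quad[1:])
        if rmsd > 1e-8:
            raise RuntimeError(
                f"internal error: backbone triples are not congruent (rmsd {rmsd})"
            )
    return SphereDimer(
        theta=float(theta),
        phi=float(phi),
        center_a=CENTER_A.copy(),
        center_b=CENTER_B.copy(),
        iface_a=iface_a,
        iface_b=iface_b,
        transform=transform,
    )


def propagate_chain(dimer: SphereDimer, n: int) -> SphereChain:
    """Chain of ``n`` monomer centers: T^k applied to the origin, k < n."""
    if n < 2:
        raise ValueError("a chain needs at least 2 monomers")
    T = dimer.transform
    centers = np.empty((n, 3))
    centers[0] = dimer.center_a
    for k in range(1, n):
        centers[k] = T.apply(centers[k - 1])
    return SphereChain(centers=centers, transform=T)


def detect_overlap(
    chain: SphereChain, delta: float = 0.05, min_gap: int = 2
) -> OverlapResult:
    """Find non-adjacent sphere pairs closer than ``2 * radius * (1 - delta)``.

    Pairs with index gap below ``min_gap`` are never counted: consecutive
    monomers are tangent by construction.  Returns all overlapping pairs in
    lexicographic order plus the global minimal non-adjacent distance.
    """
    centers = chain.centers
    n = len(centers)
    if n < min_gap + 1:
        return OverlapResult(pairs=(), min_distance=np.inf, min_pair=(0, 0))
    d = pdist(centers)
    ii, jj = np.triu_indices(n, k=1)
    keep = (jj - ii) >= min_gap
    d, ii, jj = d[keep], ii[keep], jj[keep]
    cutoff = 2.0 * chain.radius * (1.0 - delta)
    hit = d < cutoff
    pairs = tuple(
        (int(i), int(j)) for i, j in sorted(zip(ii[hit], jj[hit]))
    )
    k = int(np.argmin(d))
    return OverlapResult(
        pairs=pairs,
        min_distance=float(d[k]),
        min_pair=(int(ii[k]), int(jj[k])),
    )


def screw_parameters(transform: RigidTransform) -> ScrewParameters:
    """Chasles decomposition: rotation angle, axis and pitch of a screw.

    For a (near-)pure translation the axis defaults to the translation
    direction and the pitch to the full translation length.
    """
    rot = Rotation.from_matrix(transform.rotation)
    rotvec = rot.as_rotvec()
    angle = np.linalg.norm(rotvec)
    t = transform.translation
    if angle < 1e-9:
        norm = np.linalg.norm(t)
        axis = t / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        return ScrewParameters(axis=axis, angle=0.0, pitch=float(norm))
    axis = rotvec / angle
    return ScrewParameters(
        axis=axis, angle=float(np.degrees(angle)), pitch=float(t @ axis)
    )


def helix_radius(
    transform: RigidTransform, point=None, screw: ScrewParameters | None = None
) -> float:
    """Distance of a chain point (default: the origin) from the screw axis.

    Iterating a screw moves a point on a cylinder around the screw axis;
    this cylinder radius separates chains that look like lines (radius well
    below the monomer radius) from visibly helical ones.  Zero for a pure
    translation.
    """
    screw = screw or screw_parameters(transform)
    if screw.angle < 1e-6:
        return 0.0
    p = np.zeros(3) if point is None else np.asarray(point, dtype=float)
    a = screw.axis
    R = transform.rotation
    t_perp = transform.translation - screw.pitch * a
    # a point q on the axis satisfies (I - R) q = t_perp (in the plane |_ a)
    q, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    q = q - (q @ a) * a + (p @ a) * a
    rvec = p - q
    return float(np.linalg.norm(rvec - (rvec @ a) * a))


def classify_sphere_growth(
    theta: float,
    phi: float,
    n: int = 32,
    delta: float = 0.05,
    linear_max_radius: float = 1.0,
    linear_max_angle: float = 15.0,
    doughnut_max_pitch: float = 0.5,
) -> GrowthClassification:
    """Classify the growth mode of the (theta, phi) sphere dimer.

    The mode is *limited* iff non-adjacent spheres overlap within the
    ``n``-monomer horizon.  Subtypes:

    * ``h2h`` -- limited with the first overlap at pair (0, 2): the chain
      folds straight back onto itself (head-to-head interface);
    * ``doughnut`` -- limited with |screw pitch| below ``doughnut_max_pitch``
      (the chain closes into a ring);
    * ``linear`` -- unlimited with screw angle below ``linear_max_angle``
      degrees or helix radius below ``linear_max_radius`` sphere radii (the
      chain extends along its axis within its own width; this covers both
      slowly twisting chains and tight planar zigzags);
    * ``helical`` -- any other unlimited chain;
    * ``generic`` -- limited chains matching neither special pattern.

    The subtype thresholds are visual-taxonomy conventions and deliberately
    configurable; only the limited/unlimited mode is a sharp prediction.
    """
    dimer = build_sphere_dimer(theta, phi)
    chain = propagate_chain(dimer, n)
    overlap = detect_overlap(chain, delta=delta)
    screw = screw_parameters(dimer.transform)
    radius = helix_radius(dimer.transform, screw=screw)

    if overlap.overlapping:
        mode = "limited"
        if overlap.first_pair == (0, 2):
            subtype = "h2h"
        elif abs(screw.pitch) < doughnut_max_pitch:
            subtype = "doughnut"
        else:
            subtype = "generic"
    else:
        mode = "unlimited"
        if screw.angle < linear_max_angle or radius < linear_max_radius:
            subtype = "linear"
        else:
            subtype = "helical"
    return GrowthClassification(
        mode=mode,
        subtype=subtype,
        min_nonadjacent_distance=overlap.min_distance,
        first_overlap=overlap.first_pair,
        screw_angle=screw.angle,
        screw_pitch=screw.pitch,
        helix_radius=radius,
        theta=float(theta),
        phi=float(phi),
    )
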