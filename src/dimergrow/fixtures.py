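"""Synthetic pseudo-protein monomers and dimers with controlled geometry.

Every pipeline stage can be exercised without external structure files:
:func:`make_monomer` builds quasi-spherical pseudo-monomers (one carbon-like
pseudo-atom per residue, named CA so core selections work), optionally with
protruding terminal strings that lower the sphericity -- emulating a
compact protein core with detached, unstructured termini; and
:func:`make_dimer` poses two copies so that the SASA-measured interface
realizes prescribed polymerization angles.

A pair of (quasi-)spherical bodies in point contact is axially symmetric,
so its interface centroids lie on the inter-center axis and theta_pol is
pinned near 180 degrees.  Mid-range target angles therefore *require*
monomers whose geometric center is displaced from their contact-sphere
center -- which is precisely what the terminal strings provide (and what
detached termini do in real aggregation-prone conformers).  Hence
``make_dimer`` refuses mid-range angles for monomers whose center offset
is too small, with an error reporting what was achievable.
"""

from __future__ import annotations

import numpy as np

from .geometry import angles_from_dimer
from .interface import interface_descriptor
from .structio import MolecularStructure
from .geometry import RigidTransform

__all__ = ["FixturePoseError", "make_monomer", "place_dimer", "make_dimer"]

_SPACING = 3.2  # minimal pseudo-atom separation, Angstrom (CA-like packing)


class FixturePoseError(RuntimeError):
    """Raised when a dimer pose cannot realize the requested angles."""


def _sample_ball(rng, n: int, spacing: float) -> np.ndarray:
    """Quasi-uniform points in a ball with a minimal-separation constraint."""
    radius = 0.7 * spacing * n ** (1 / 3) + spacing
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > 20000:
            radius *= 1.1
            attempts = 0
        p = rng.uniform(-radius, radius, 3)
        if p @ p > radius * radius:
            continue
        if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < spacing:
            continue
        points.append(p)
    pts = np.array(points)
    return pts - pts.mean(axis=0)


def make_monomer(
    n_residues: int = 50,
    atoms_per_residue: int = 1,
    shape: str = "spherical",
    termini_length: int = 15,
    seed: int = 0,
    spacing: float = _SPACING,
    chain_id: str = "A",
) -> MolecularStructure:
    """Generate a pseudo-monomer of carbon-like spheres.

    ``shape="spherical"`` places ``n_residues`` quasi-uniformly in a ball
    (sphericity psi > 90 is guaranteed by construction -- configurations
    falling short are resampled deterministically).  ``shape="with-termini"``
    appends two protruding linear residue strings of ``termini_length``
    residues emerging from neighboring surface points, lowering psi and
    displacing the geometric center off the core -- the aggregation-prone
    conformer morphology.

    Residues are numbered from 1 (core first, then termini); each residue
    holds ``atoms_per_residue`` pseudo-atoms (the first is named CA), all
    carbon.  Deterministic for a given seed.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if atoms_per_residue < 1:
        raise ValueError("atoms_per_residue must be >= 1")
    if shape not in ("spherical", "with-termini"):
        raise ValueError(f"unknown shape {shape!r}")
    if shape == "with-termini" and termini_length < 1:
        raise ValueError("termini_length must be >= 1 for with-termini shape")
    rng = np.random.default_rng(seed)

    from .geometry import shape_descriptor

    core = None
    for _ in range(20):
        candidate = _sample_ball(rng, n_residues, spacing)
        if shape_descriptor(candidate).sphericity > 90.0:
            core = candidate
            break
    if core is None:
        raise RuntimeError(
            "could not sample a core with sphericity > 90; increase n_residues"
        )

    residues = [core]
    if shape == "with-termini":
        core_radius = np.linalg.norm(core, axis=1).max()
        d1 = np.array([1.0, 0.0, 0.0])
        d2 = np.array([np.cos(np.radians(50.0)), np.sin(np.radians(50.0)), 0.0])
        for direction in (d1, d2):
            start = direction * (core_radius + 0.6 * spacing)
            steps = np.arange(termini_length)[:, None] * spacing * direction
            jitter = rng.normal(0.0, 0.25, (termini_length, 3))
            residues.append(start + steps + jitter)
    centers = np.concatenate(residues)

    coords = []
    for c in centers:
        coords.append(c)
        for k in range(1, atoms_per_residue):
            offset = rng.normal(0.0, 1.0, 3)
            offset *= 1.3 / max(np.linalg.norm(offset), 1e-9)
            coords.append(c + offset)
    coords = np.array(coords)
    n_atoms = len(coords)
    names = ["CA"] + [f"C{k}" for k in range(1, atoms_per_residue)]
    return MolecularStructure(
        atom_name=np.array(names * len(centers), dtype=object),
        element=np.full(n_atoms, "C", dtype=object),
        res_id=np.repeat(np.arange(1, len(centers) + 1), atoms_per_residue),
        res_name=np.full(n_atoms, "UNK", dtype=object),
        chain_id=np.full(n_atoms, chain_id, dtype=object),
        coords=coords[None],
    )


def place_dimer(
    monomer: MolecularStructure, transform: RigidTransform
) -> MolecularStructure:
    """Dimer built from a monomer and an explicit A -> B rigid transform.

    Chain A is the monomer as given; chain B is its image under
    ``transform``.  Useful for posing dimers with exactly known propagation
    geometry (e.g. a scaled sphere-model transform).
    """
    mono_a = monomer.relabel_chain("A")
    coords_b = transform.apply(monomer.coords)
    mono_b = monomer.with_coords(coords_b).relabel_chain("B")
    return MolecularStructure(
        atom_name=np.concatenate([mono_a.atom_name, mono_b.atom_name]),
        element=np.concatenate([mono_a.element, mono_b.element]),
        res_id=np.concatenate([mono_a.res_id, mono_b.res_id]),
        res_name=np.concatenate([mono_a.res_name, mono_b.res_name]),
        chain_id=np.concatenate([mono_a.chain_id, mono_b.chain_id]),
        coords=np.concatenate([mono_a.coords, mono_b.coords], axis=1),
    )


def _robust_core_center(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and membership mask of the compact core, ignoring termini."""
    center = coords.mean(axis=0)
    keep = np.ones(len(coords), dtype=bool)
    for _ in range(8):
        d = np.linalg.norm(coords - center, axis=1)
        keep = d <= 1.3 * np.median(d)
        center = coords[keep].mean(axis=0)
    return center, keep


def _min_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix taking direction ``src`` to ``dst``."""
    a = src / np.linalg.norm(src)
    b = dst / np.linalg.norm(dst)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate half turn about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        from scipy.spatial.transform import Rotation

        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)




def _arm_direction(body: np.ndarray, core_mask: np.ndarray) -> np.ndarray | None:
    """Mean direction of the atoms outside the core (the termini), if any."""
    outside = body[~core_mask]
    if len(outside) < 3:
        return None
    d = outside.mean(axis=0)
    n = np.linalg.norm(d)
    return None if n < 1e-6 else d / n


def make_dimer(
    monomer: MolecularStructure,
    theta: float,
    phi: float,
    contact_gap: float = 0.5,
    tolerance: float = 5.0,
    max_rounds: int = 40,
    sasa_points: int = 120,
    verify_points: int = 960,
    threshold: float = 10.0,
    probe_radius: float = 1.4,
) -> MolecularStructure:
    """Pose two copies of a monomer realizing target polymerization angles.

    The two copies face each other core-to-core at a fixed separation
    (``contact_gap`` Angstrom between the effective core surfaces) with
    their terminal arms draped toward the partner: the arm tilt controls
    where the buried-residue centroids sit relative to the monomer centers
    (hence theta) and the arm azimuths around the inter-core axis control
    the relative twist of the two interface patches (hence phi).

    The pose is found in closed loop through the actual SASA -> interface
    -> angle pipeline: a deterministic coarse scan over (tilt, azimuth A,
    azimuth B) followed by a Nelder-Mead polish of the angle error, with a
    final verification at ``verify_points`` sphere points per atom (the
    default measurement resolution).  Everything is deterministic.

    Near-colinear targets (theta >= 168) are judged on theta alone: the
    dihedral of a colinear arrangement is undefined.

    Raises
    ------
    FixturePoseError
        When no pose reaches the tolerance (e.g. a monomer without termini
        for a mid-range theta, or an unreachable angle combination),
        reporting the best achieved angles.
    """
    if not (0.0 < theta <= 180.0 and 0.0 <= phi <= 180.0):
        raise ValueError("theta must lie in (0, 180], phi in [0, 180] degrees")
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    coords = monomer.coords[0]
    c_core, core_mask = _robust_core_center(coords)
    body = coords - c_core
    r_eff = float(np.quantile(np.linalg.norm(body[core_mask], axis=1), 0.9))
    d = 2.0 * r_eff + 1.5 + contact_gap
    arm = _arm_direction(body, core_mask)
    check_phi = theta < 168.0

    def rot_x(deg):
        return Rotation.from_euler("x", deg, degrees=True).as_matrix()

    def assemble(params):
        gamma, beta_a, beta_b = params
        g = np.radians(gamma)
        t_a = np.array([-np.cos(g), np.sin(g), 0.0])
        t_b = np.array([np.cos(g), np.sin(g), 0.0])
        if arm is None:
            rot_a = np.eye(3)
            rot_b = np.eye(3)
        else:
            rot_a = rot_x(beta_a) @ _min_rotation(arm, t_a)
            rot_b = rot_x(beta_b) @ _min_rotation(arm, t_b)
        a_coords = body @ rot_a.T
        b_coords = body @ rot_b.T + np.array([-d, 0.0, 0.0])
        return place_dimer(monomer, RigidTransform.identity()).with_coords(
            np.concatenate([a_coords, b_coords])[None]
        )

    last_no_interface = [None]

    def measure(params, n_points):
        dimer = assemble(params)
        try:
            desc = interface_descriptor(
                dimer,
                chains=("A", "B"),
                threshold=threshold,
                n_points=n_points,
                probe_radius=probe_radius,
            )
            angles = angles_from_dimer(desc)
        except ValueError as exc:
            last_no_interface[0] = exc
            return None, dimer
        return (angles.theta, angles.phi), dimer

    def error(meas):
        if meas is None:
            return 1e3
        err = abs(meas[0] - theta)
        if check_phi:
            dp = abs(meas[1] - phi)
            err = max(err, min(dp, 360.0 - dp))
        return err

    if arm is None:
        # a bare quasi-spherical monomer admits only near-colinear contact
        grid = [(90.0, 0.0, 0.0)]
    else:
        grid = [
            (g, ba, bb)
            for g in (10.0, 25.0, 40.0, 55.0, 75.0, 100.0, 130.0, 165.0)
            for ba in (0.0, 90.0, 180.0, 270.0)
            for bb in (0.0, 90.0, 180.0, 270.0)
        ]
    scored = []
    for params in grid:
        meas, _ = measure(params, sasa_points)
        scored.append((error(meas), params, meas))
    scored.sort(key=lambda x: x[0])

    def objective(p):
        meas, _ = measure(tuple(p), sasa_points)
        return error(meas)

    mid_points = max(sasa_points, verify_points // 2)

    def objective_mid(p):
        meas, _ = measure(tuple(p), mid_points)
        return error(meas)

    best_err, best_params, best_meas = scored[0]
    if arm is not None:
        for _err, start, _meas in scored[:2]:
            simplex = np.array(start, float) + np.array(
                [[0, 0, 0], [8, 0, 0], [0, 25, 0], [0, 0, 25]], float
            )
            res = minimize(
                objective,
                np.array(start, float),
                method="Nelder-Mead",
                options=dict(
                    maxfev=max_rounds, xatol=0.5, fatol=0.25,
                    initial_simplex=simplex,
                ),
            )
            # re-polish the candidate at an intermediate resolution so the
            # final verification does not drift out of tolerance
            simplex = np.array(res.x, float) + np.array(
                [[0, 0, 0], [3, 0, 0], [0, 8, 0], [0, 0, 8]], float
            )
            res = minimize(
                objective_mid,
                np.array(res.x, float),
                method="Nelder-Mead",
                options=dict(maxfev=max_rounds // 2, xatol=0.3, fatol=0.2,
                             initial_simplex=simplex),
            )
            if res.fun < best_err:
                best_err, best_params = float(res.fun), tuple(res.x)
            if best_err <= 0.5 * tolerance:
                break

    # verify (and if needed polish) at the full measurement resolution
    meas, dimer = measure(best_params, verify_points)
    if error(meas) <= tolerance:
        return dimer
    if arm is not None and meas is not None:

        def objective_hi(p):
            m, _ = measure(tuple(p), verify_points)
            return error(m)

        simplex = np.array(best_params, float) + np.array(
            [[0, 0, 0], [4, 0, 0], [0, 10, 0], [0, 0, 10]], float
        )
        res = minimize(
            objective_hi,
            np.array(best_params, float),
            method="Nelder-Mead",
            options=dict(maxfev=20, xatol=0.5, fatol=0.25,
                         initial_simplex=simplex),
        )
        meas, dimer = measure(tuple(res.x), verify_points)
        if error(meas) <= tolerance:
            return dimer
    if meas is None:
        raise FixturePoseError(
            "posed monomers form no measurable interface: "
            f"{last_no_interface[0]}"
        )
    raise FixturePoseError(
        f"pose refinement did not reach tolerance {tolerance} deg: target "
        f"({theta:.1f}, {phi:.1f}), best achieved ({meas[0]:.1f}, {meas[1]:.1f})"
    )
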