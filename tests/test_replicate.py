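"""Atomic dimer replication, clash counting and structural classification."""

import numpy as np
import pytest

from dimergrow.fixtures import place_dimer
from dimergrow.geometry import RigidTransform
from dimergrow.replicate import (
    clash_count,
    classify_structure_growth,
    dimer_transform,
    polymerize_structure,
)
from dimergrow.spheremodel import build_sphere_dimer
from dimergrow.structio import B2M_CORE, CoreSelection, MolecularStructure

CORE_1_50 = CoreSelection(((1, 50),))


def _scaled_sphere_transform(theta, phi, scale):
    """Atomic-scale propagation screw of the (theta, phi) sphere dimer."""
    T = build_sphere_dimer(theta, phi).transform
    return RigidTransform(T.rotation, T.translation * scale)


def _monomer_radius(monomer):
    c = monomer.coords[0]
    return float(np.linalg.norm(c - c.mean(axis=0), axis=1).max())


def _contact_scale(monomer, theta, phi, closest=3.5):
    """Scale of the (theta, phi) screw placing the copies in atomic contact."""
    from scipy.spatial import cKDTree

    body = monomer.coords[0]
    T0 = build_sphere_dimer(theta, phi).transform
    tree = cKDTree(body)

    def min_dist(scale):
        T = RigidTransform(T0.rotation, T0.translation * scale)
        return tree.query(T.apply(body), k=1)[0].min()

    lo, hi = 1.0, _monomer_radius(monomer) + 10.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < closest:
            lo = mid
        else:
            hi = mid
    return hi


def test_translation_dimer_recovers_pure_translation(spherical_monomer):
    T = RigidTransform(np.eye(3), np.array([40.0, 0.0, 0.0]))
    dimer = place_dimer(spherical_monomer, T)
    got, rmsd = dimer_transform(dimer, core=CORE_1_50)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(got.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(got.translation, T.translation, atol=1e-9)


def test_rotated_dimer_recovers_exact_transform(spherical_monomer):
    from scipy.spatial.transform import Rotation

    T = RigidTransform(
        Rotation.from_euler("z", 90, degrees=True).as_matrix(),
        np.array([25.0, 5.0, -3.0]),
    )
    dimer = place_dimer(spherical_monomer, T)
    got, rmsd = dimer_transform(dimer, core=CORE_1_50)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(got.rotation, T.rotation, atol=1e-9)
    assert np.allclose(got.translation, T.translation, atol=1e-9)


def test_perturbed_dimer_rmsd_matches_quaternion_oracle(spherical_monomer):
    from test_geometry import _quaternion_rmsd

    rng = np.random.default_rng(17)
    T = RigidTransform(np.eye(3), np.array([40.0, 0.0, 0.0]))
    dimer = place_dimer(spherical_monomer, T)
    coords = dimer.coords.copy()
    mask_b = dimer.chain_id == "B"
    coords[0, mask_b] += rng.normal(scale=0.2, size=(mask_b.sum(), 3))
    dimer = dimer.with_coords(coords)
    _, rmsd = dimer_transform(dimer, core=CORE_1_50)
    from dimergrow.structio import select_core

    mobile = select_core(dimer, "A", CORE_1_50)
    target = select_core(dimer, "B", CORE_1_50)
    assert rmsd == pytest.approx(_quaternion_rmsd(mobile, target), abs=1e-9)


def test_missing_core_residues_error(spherical_monomer):
    dimer = place_dimer(
        spherical_monomer, RigidTransform(np.eye(3), np.array([40.0, 0, 0]))
    )
    with pytest.raises(ValueError, match="missing"):
        dimer_transform(dimer, core=B2M_CORE)  # residues 51..82 do not exist


def test_polymerize_translation_chain(spherical_monomer):
    T = RigidTransform(np.eye(3), np.array([40.0, 0.0, 0.0]))
    dimer = place_dimer(spherical_monomer, T)
    polymer = polymerize_structure(dimer, n=5, core=CORE_1_50)
    assert polymer.n_models == 5
    assert polymer.n_atoms == spherical_monomer.n_atoms
    for k in range(5):
        assert np.allclose(
            polymer.coords[k],
            spherical_monomer.coords[0] + [40.0 * k, 0, 0],
            atol=1e-9,
        )


def test_polymerize_monomer1_matches_monomer_b(spherical_monomer):
    scale = _monomer_radius(spherical_monomer) + 2.0
    T = _scaled_sphere_transform(100.0, 70.0, scale)
    dimer = place_dimer(spherical_monomer, T)
    polymer = polymerize_structure(dimer, n=32, core=CORE_1_50)
    assert polymer.n_models == 32
    mask_b = dimer.chain_id == "B"
    assert np.allclose(polymer.coords[1], dimer.coords[0, mask_b], atol=1e-8)
    # iteration associativity: monomer k equals T^k applied to monomer 0
    assert np.allclose(
        polymer.coords[7], T.power(7).apply(polymer.coords[0]), atol=1e-6
    )


def test_clash_count_straight_chain_is_zero(spherical_monomer):
    T = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
    dimer = place_dimer(spherical_monomer, T)
    polymer = polymerize_structure(dimer, n=6, core=CORE_1_50)
    assert clash_count(polymer) == 0


def test_clash_count_limited_regime_collides(spherical_monomer):
    """A chain built from a theta=30 screw folds back onto itself."""
    scale = _monomer_radius(spherical_monomer) + 1.0
    T = _scaled_sphere_transform(30.0, 0.0, scale)
    dimer = place_dimer(spherical_monomer, T)
    polymer = polymerize_structure(dimer, n=16, core=CORE_1_50)
    assert clash_count(polymer, cutoff=2.0) > 0


def test_clash_count_matches_brute_force(spherical_monomer):
    scale = _monomer_radius(spherical_monomer) + 1.0
    T = _scaled_sphere_transform(45.0, 20.0, scale)
    dimer = place_dimer(spherical_monomer, T)
    polymer = polymerize_structure(dimer, n=8, core=CORE_1_50)
    for cutoff in (2.0, 3.5, 5.0):
        fast = clash_count(polymer, cutoff=cutoff)
        coords = polymer.coords.reshape(-1, 3)
        mono = np.repeat(np.arange(polymer.n_models), polymer.n_atoms)
        brute = 0
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if abs(mono[i] - mono[j]) >= 2:
                    if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                        brute += 1
        assert fast == brute


def test_clash_count_monotone_in_cutoff(spherical_monomer):
    scale = _monomer_radius(spherical_monomer) + 1.0
    T = _scaled_sphere_transform(60.0, 10.0, scale)
    polymer = polymerize_structure(
        place_dimer(spherical_monomer, T), n=12, core=CORE_1_50
    )
    counts = [clash_count(polymer, cutoff=c) for c in (1.0, 2.0, 4.0, 8.0)]
    assert counts == sorted(counts)


def test_classify_translation_homodimer_linear(spherical_monomer, default_landscape):
    d = 2.0 * _monomer_radius(spherical_monomer)  # touching-ball spacing
    T = RigidTransform(np.eye(3), np.array([d, 0.0, 0.0]))
    dimer = place_dimer(spherical_monomer, T)
    cls, details = classify_structure_growth(
        dimer, n=16, core=CORE_1_50, landscape=default_landscape, force_atomic=True
    )
    assert cls.mode == "unlimited"
    assert cls.subtype == "linear"
    assert details["clashes"] == 0


def test_classify_helical_anchor(spherical_monomer, default_landscape):
    """The (123, 16) interface propagates into a clash-free helix."""
    scale = _contact_scale(spherical_monomer, 123.0, 16.0)
    T = _scaled_sphere_transform(123.0, 16.0, scale)
    dimer = place_dimer(spherical_monomer, T)
    cls, details = classify_structure_growth(
        dimer, n=32, core=CORE_1_50, landscape=default_landscape, force_atomic=True
    )
    assert cls.mode == "unlimited"
    assert cls.subtype == "helical"


def test_classify_low_theta_anchor_limited(spherical_monomer, default_landscape):
    """The (30, 25) interface self-collides: limited growth."""
    scale = _contact_scale(spherical_monomer, 30.0, 25.0)
    T = _scaled_sphere_transform(30.0, 25.0, scale)
    dimer = place_dimer(spherical_monomer, T)
    cls, details = classify_structure_growth(
        dimer, n=32, core=CORE_1_50, landscape=default_landscape, force_atomic=True
    )
    assert cls.mode == "limited"
    assert details["clashes"] > 0


def test_classify_uses_landscape_region_when_confident(
    closed_loop_dimer, default_landscape
):
    """A (90, 90) dimer sits well inside the unlimited region: no atomic step."""
    cls, details = classify_structure_growth(
        closed_loop_dimer, n=16, core=CORE_1_50, landscape=default_landscape
    )
    assert details["region"] in {"unlimited", "uncertain"}
    if details["region"] == "unlimited":
        assert not details["atomic_override"]
        assert cls.mode == "unlimited"
    else:
        assert details["atomic_override"]


def test_sphere_model_agreement_for_spherical_monomers(
    spherical_monomer, default_landscape
):
    """Near-spherical monomers in near-colinear contact: atomic and sphere
    classifications agree (both unlimited/linear)."""
    from dimergrow.geometry import shape_descriptor
    from dimergrow.spheremodel import classify_sphere_growth

    psi = shape_descriptor(spherical_monomer.coords[0]).sphericity
    assert psi > 90.0
    d = 2.0 * _monomer_radius(spherical_monomer)
    T = RigidTransform(np.eye(3), np.array([d, 0.0, 0.0]))
    dimer = place_dimer(spherical_monomer, T)
    cls, details = classify_structure_growth(
        dimer, n=16, core=CORE_1_50, landscape=default_landscape, force_atomic=True
    )
    sphere_cls = classify_sphere_growth(details["theta"], details["phi"])
    assert cls.mode == sphere_cls.mode == "unlimited"
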