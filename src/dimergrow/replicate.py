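"""Replication of atomic dimers into polymer chains.

The replication protocol turns a dimer (monomers A and B, one chain each)
into an n-monomer chain: the rigid transform superposing monomer A's core
Calpha atoms onto monomer B's is applied iteratively to monomer A's full
atom set, exactly as one would repeatedly align a duplicate dimer onto the
previous one.  No conformational relaxation is applied -- every monomer
carries A's conformation -- so the chain shows what the interface geometry
alone implies.

Steric self-collision of the resulting chain (heavy-atom clashes between
non-adjacent monomers) is the atomic analogue of overlapping spheres and
resolves dimers that fall in the uncertain band of the sphere-model
landscape.  A small clash budget is tolerated: near-boundary chains often
show a few contacts that modest side-chain rearrangement would relieve.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, angles_from_dimer, superpose
from .interface import InterfaceDescriptor, interface_descriptor
from .landscape import GrowthLandscape, cached_landscape, classify_region
from .spheremodel import (
    GrowthClassification,
    SphereChain,
    detect_overlap,
    helix_radius,
    screw_parameters,
)
from .structio import B2M_CORE, CoreSelection, MolecularStructure, select_core

__all__ = [
    "dimer_transform",
    "polymerize_structure",
    "clash_count",
    "contact_pair_count",
    "classify_structure_growth",
]


def _dimer_chains(dimer: MolecularStructure, chains) -> tuple[str, str]:
    if chains is not None:
        return tuple(chains)
    cs = dimer.chains
    if len(cs) != 2:
        raise ValueError(
            f"dimer must have exactly two chains (found {cs}); pass chains=(a, b)"
        )
    return (cs[0], cs[1])


def dimer_transform(
    dimer: MolecularStructure,
    core: CoreSelection = B2M_CORE,
    chains: tuple[str, str] | None = None,
    model: int = 0,
) -> tuple[RigidTransform, float]:
    """Rigid transform mapping monomer A's core onto monomer B's core.

    Returns the least-squares transform plus its fit RMSD, which doubles as
    a homodimer-similarity diagnostic (zero iff B is a rigid copy of A over
    the core).  Both chains must contain the same core residues; the dimers
    handled here are homodimers -- heterodimers (differing core residue
    sets) are rejected.
    """
    ca, cb = _dimer_chains(dimer, chains)
    present: dict[str, set[int]] = {}
    for chain in (ca, cb):
        mask = (dimer.chain_id == chain) & (dimer.atom_name.astype(str) == "CA")
        present[chain] = set(int(r) for r in dimer.res_id[mask])
    wanted = set(core.residue_ids())
    missing = {
        chain: sorted(wanted - present[chain] & wanted) for chain in (ca, cb)
    }
    missing = {c: m for c, m in missing.items() if m}
    if missing:
        raise ValueError(f"core residues missing from the dimer: {missing}")
    if (present[ca] & wanted) != (present[cb] & wanted):
        raise ValueError(
            "monomers expose different core residue sets; replication assumes "
            "a homodimer"
        )
    mobile = select_core(dimer, ca, core, model=model)
    target = select_core(dimer, cb, core, model=model)
    return superpose(mobile, target)


def polymerize_structure(
    dimer: MolecularStructure,
    n: int,
    core: CoreSelection = B2M_CORE,
    chains: tuple[str, str] | None = None,
    model: int = 0,
) -> MolecularStructure:
    """Propagate a dimer into an ``n``-monomer atomic chain.

    Monomer k is the A -> B transform applied k times to monomer A's full
    atom set; the result is a multi-model structure with one monomer per
    model (sharing monomer A's topology).  Monomer 1 coincides with monomer
    B's core within the dimer's own fit RMSD.
    """
    if n < 2:
        raise ValueError("a polymer needs at least 2 monomers")
    ca, _ = _dimer_chains(dimer, chains)
    transform, _rmsd = dimer_transform(dimer, core=core, chains=chains, model=model)
    monomer = dimer.select_chain(ca)
    coords = np.empty((n, monomer.n_atoms, 3))
    coords[0] = monomer.coords[model]
    for k in range(1, n):
        coords[k] = transform.apply(coords[k - 1])
    return monomer.with_coords(coords)


def clash_count(
    polymer: MolecularStructure,
    cutoff: float = 2.0,
    min_gap: int = 2,
) -> int:
    """Heavy-atom clashes between non-adjacent monomers of a polymer.

    ``polymer`` is a multi-model structure with one monomer per model (the
    output of :func:`polymerize_structure`).  A clash is a pair of heavy
    atoms from monomers with index gap >= ``min_gap`` closer than
    ``cutoff`` Angstrom.  Neighbor search uses a k-d tree, so the cost is
    near-linear in the number of atoms for extended chains.
    """
    if polymer.n_models < 3:
        raise ValueError("clash counting needs a polymer of at least 3 monomers")
    heavy = polymer.heavy_mask()
    n_mono = polymer.n_models
    pts = polymer.coords[:, heavy].reshape(-1, 3)
    mono_of = np.repeat(np.arange(n_mono), int(heavy.sum()))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    gap = np.abs(mono_of[pairs[:, 0]] - mono_of[pairs[:, 1]])
    return int(np.count_nonzero(gap >= min_gap))


def contact_pair_count(
    polymer: MolecularStructure,
    shell: float = 6.0,
    min_gap: int = 2,
) -> int:
    """Heavy-atom pairs of non-adjacent monomers within the contact shell."""
    return clash_count(polymer, cutoff=shell, min_gap=min_gap)


def classify_structure_growth(
    dimer: MolecularStructure,
    n: int = 32,
    clash_budget: float = 0.005,
    core: CoreSelection = B2M_CORE,
    chains: tuple[str, str] | None = None,
    landscape: GrowthLandscape | None = None,
    descriptor: InterfaceDescriptor | None = None,
    force_atomic: bool = False,
    clash_cutoff: float = 2.0,
    contact_shell: float = 6.0,
    model: int = 0,
    **subtype_kwargs,
) -> tuple[GrowthClassification, dict]:
    """Growth-mode verdict for an atomic dimer.

    The dimer's polymerization angles place it on the sphere-model growth
    landscape.  If it falls in the uncertain band (or ``force_atomic`` is
    set), the verdict is decided atomically: the dimer is replicated into an
    ``n``-monomer chain and classified *limited* iff the number of
    non-adjacent heavy-atom clashes exceeds ``clash_budget`` times the
    number of non-adjacent atom pairs within the ``contact_shell`` --
    a small tolerance, since a few clashes are compatible with growth after
    minor rearrangement.

    The subtype uses the sphere-model taxonomy applied to the atomic
    propagation screw, with lengths expressed in units of half the
    inter-monomer spacing (the atomic analogue of the sphere radius).

    Returns ``(classification, details)`` where ``details`` reports the
    angles, landscape region, fit RMSD and clash statistics.
    """
    if descriptor is None:
        descriptor = interface_descriptor(dimer, chains=chains, model=model)
    angles = angles_from_dimer(descriptor)
    if landscape is None:
        landscape = cached_landscape()
    region = classify_region(landscape, angles.theta, angles.phi)

    transform, fit_rmsd = dimer_transform(dimer, core=core, chains=chains, model=model)
    gc_a = descriptor.gc_a
    spacing = float(np.linalg.norm(transform.apply(gc_a) - gc_a))
    unit = spacing / 2.0 if spacing > 0 else 1.0

    # sphere-equivalent chain of monomer centers, in sphere-radius units
    centers = np.empty((n, 3))
    centers[0] = gc_a
    for k in range(1, n):
        centers[k] = transform.apply(centers[k - 1])
    pseudo = SphereChain(centers=centers / unit, transform=transform)
    overlap = detect_overlap(pseudo, delta=subtype_kwargs.pop("delta", 0.05))

    unit_transform = RigidTransform(transform.rotation, transform.translation / unit)
    screw = screw_parameters(unit_transform)
    radius = helix_radius(unit_transform, point=gc_a / unit, screw=screw)

    details: dict = {
        "theta": angles.theta,
        "phi": angles.phi,
        "region": region,
        "fit_rmsd": fit_rmsd,
        "clashes": None,
        "contact_pairs": None,
        "atomic_override": False,
    }

    if region == "uncertain" or force_atomic:
        polymer = polymerize_structure(dimer, n=n, core=core, chains=chains, model=model)
        clashes = clash_count(polymer, cutoff=clash_cutoff)
        contacts = contact_pair_count(polymer, shell=contact_shell)
        budget = clash_budget * contacts
        mode = "limited" if clashes > budget else "unlimited"
        details.update(
            clashes=clashes, contact_pairs=contacts, atomic_override=True
        )
    elif region == "limited":
        mode = "limited"
    else:
        mode = "unlimited"

    linear_max_radius = subtype_kwargs.pop("linear_max_radius", 1.0)
    linear_max_angle = subtype_kwargs.pop("linear_max_angle", 15.0)
    doughnut_max_pitch = subtype_kwargs.pop("doughnut_max_pitch", 0.5)
    if subtype_kwargs:
        raise TypeError(f"unknown options: {sorted(subtype_kwargs)}")
    if mode == "limited":
        if overlap.first_pair == (0, 2):
            subtype = "h2h"
        elif abs(screw.pitch) < doughnut_max_pitch:
            subtype = "doughnut"
        else:
            subtype = "generic"
    else:
        if screw.angle < linear_max_angle or radius < linear_max_radius:
            subtype = "linear"
        else:
            subtype = "helical"

    classification = GrowthClassification(
        mode=mode,
        subtype=subtype,
        min_nonadjacent_distance=overlap.min_distance,
        first_overlap=overlap.first_pair,
        screw_angle=screw.angle,
        screw_pitch=screw.pitch,
        helix_radius=radius,
        theta=angles.theta,
        phi=angles.phi,
    )
    return classification, details
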