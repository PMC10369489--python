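"""Dimer interface detection from solvent-accessible surface area (SASA).

The interfacial area of a residue is the SASA it loses upon complexation:
SASA computed for each monomer in isolation minus its SASA within the
dimer.  Residues burying more than a threshold fraction (default 10%) of
a per-residue-type maximum SAS area are the *interface residues*; their
unweighted geometric centers (``GC_IA``, ``GC_IB``) and those of the whole
monomers (``GC_A``, ``GC_B``) feed the polymerization-angle geometry.

SASA uses Shrake-Rupley sphere-point sampling: each atom is represented by
a deterministic golden-spiral point set on its solvent-expanded sphere
(van der Waals radius + probe radius, probe 1.4 A by default) and the
accessible fraction is the fraction of points not buried inside any
neighbor's expanded sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import MolecularStructure

__all__ = [
    "VDW_RADII",
    "MAX_RESIDUE_SASA",
    "UnknownElementError",
    "InterfaceDescriptor",
    "sphere_points",
    "atom_sasa",
    "residue_sasa",
    "interfacial_areas",
    "interface_descriptor",
    "conserved_interface_fraction",
]

#: van der Waals radii in Angstrom (Bondi-style values).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Maximum solvent-accessible surface area per residue type, A^2
#: (theoretical Gly-X-Gly maxima; the normalization reference for turning
#: per-residue interfacial areas into percentages).
MAX_RESIDUE_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class UnknownElementError(ValueError):
    """Raised when an element has no van der Waals radius and no fallback."""


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _radii_for(
    elements: np.ndarray,
    overrides: dict[str, float] | None,
    fallback: float | None,
) -> np.ndarray:
    table = dict(VDW_RADII)
    if overrides:
        table.update({k.upper(): float(v) for k, v in overrides.items()})
    radii = np.empty(len(elements))
    unknown = []
    for i, el in enumerate(np.char.upper(elements.astype(str))):
        r = table.get(el)
        if r is None:
            if fallback is not None:
                r = fallback
            else:
                unknown.append(el)
                r = np.nan
        radii[i] = r
    if unknown:
        raise UnknownElementError(
            "no van der Waals radius for element(s) "
            f"{sorted(set(unknown))}; pass radii overrides or a fallback radius"
        )
    return radii


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    point_set: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA in A^2.

    ``point_set`` may supply an alternative unit-sphere sampling (used by the
    brute-force oracle in the tests); by default the deterministic golden
    spiral with ``n_points`` points per atom is used.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(coords) == 0:
        raise ValueError("structure has no atoms")
    pts = sphere_points(n_points) if point_set is None else np.asarray(point_set)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    reach = expanded.max()
    areas = np.empty(len(coords))
    for i, (c, r) in enumerate(zip(coords, expanded)):
        surface = c + r * pts
        neighbors = [j for j in tree.query_ball_point(c, r + reach) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = np.sum(
                (surface[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2
            )
            buried = (d2 < expanded[nb][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r * r * frac
    return areas


def residue_sasa(
    structure: MolecularStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    model: int = 0,
    radii: dict[str, float] | None = None,
    fallback_radius: float | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue SASA, keyed by (chain id, residue index), in A^2.

    The per-residue areas sum to the total molecular SASA by construction.
    Hydrogens are included if present (they carry their own radius).
    """
    r = _radii_for(structure.element, radii, fallback_radius)
    areas = atom_sasa(structure.coords[model], r, probe_radius, n_points)
    out: dict[tuple[str, int], float] = {}
    for chain, rid, a in zip(structure.chain_id, structure.res_id, areas):
        key = (str(chain), int(rid))
        out[key] = out.get(key, 0.0) + float(a)
    return out


def _residue_table(structure: MolecularStructure) -> dict[tuple[str, int], str]:
    names: dict[tuple[str, int], str] = {}
    for chain, rid, rname in zip(
        structure.chain_id, structure.res_id, structure.res_name
    ):
        names.setdefault((str(chain), int(rid)), str(rname))
    return names


def interfacial_areas(
    dimer: MolecularStructure,
    chains: tuple[str, str] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    model: int = 0,
    normalization: str = "reference-table",
    radii: dict[str, float] | None = None,
    fallback_radius: float | None = None,
    max_sasa: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue interfacial areas of a two-chain dimer.

    For every residue, ``dsasa`` is the SASA of the residue in its isolated
    monomer minus its SASA in the complex (clamped at zero -- sampling noise
    can make it marginally negative) and ``relative`` is that loss as a
    percentage of the maximum SAS area of the residue type.

    Normalization
    -------------
    ``"reference-table"`` (default) divides by a fixed per-residue-type
    maximum (``max_sasa`` overrides the built-in table); residue types
    missing from the table fall back to the residue's own isolated-monomer
    SASA.  ``"ensemble-max"`` divides by the maximum isolated-monomer SASA
    of that residue observed across all models of the input, and requires a
    multi-model structure.

    Returns a DataFrame with columns ``chain, res_id, res_name, dsasa,
    relative, interface`` (the flag uses a 10% threshold for convenience;
    :func:`interface_descriptor` applies its own).  The total interfacial
    area of the dimer, in nm^2, is stored in ``df.attrs["total_area_nm2"]``.
    """
    if chains is None:
        cs = dimer.chains
        if len(cs) != 2:
            raise ValueError(
                f"dimer must have exactly two chains (found {cs}); "
                "pass chains=(a, b) to disambiguate"
            )
        chains = (cs[0], cs[1])
    mono_a = dimer.select_chain(chains[0])
    mono_b = dimer.select_chain(chains[1])
    if mono_a.n_atoms == 0 or mono_b.n_atoms == 0:
        raise ValueError("each monomer must contain at least one atom")
    kwargs = dict(
        probe_radius=probe_radius,
        n_points=n_points,
        radii=radii,
        fallback_radius=fallback_radius,
    )
    complex_sasa = residue_sasa(dimer, model=model, **kwargs)
    iso_a = residue_sasa(mono_a, model=model, **kwargs)
    iso_b = residue_sasa(mono_b, model=model, **kwargs)
    isolated = {**iso_a, **iso_b}

    if normalization == "reference-table":
        table = MAX_RESIDUE_SASA if max_sasa is None else max_sasa
        def norm_for(key, rname):
            return table.get(rname, isolated[key])
    elif normalization == "ensemble-max":
        if dimer.n_models < 2:
            raise ValueError(
                "ensemble-max normalization needs a multi-model ensemble"
            )
        ens: dict[tuple[str, int], float] = {}
        for m in range(dimer.n_models):
            for part in (dimer.select_chain(chains[0]), dimer.select_chain(chains[1])):
                for key, a in residue_sasa(part, model=m, **kwargs).items():
                    ens[key] = max(ens.get(key, 0.0), a)
        def norm_for(key, rname):
            return ens[key]
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    names = _residue_table(dimer)
    rows = []
    for key in isolated:
        chain, rid = key
        dsasa = max(isolated[key] - complex_sasa.get(key, 0.0), 0.0)
        ref = norm_for(key, names[key])
        rel = 0.0 if ref <= 0 else min(100.0 * dsasa / ref, 100.0)
        rows.append((chain, rid, names[key], dsasa, rel))
    df = pd.DataFrame(
        rows, columns=["chain", "res_id", "res_name", "dsasa", "relative"]
    ).sort_values(["chain", "res_id"], ignore_index=True)
    df["interface"] = df["relative"] > 10.0
    df.attrs["total_area_nm2"] = float(df["dsasa"].sum()) / 100.0
    df.attrs["chains"] = chains
    return df


@dataclass(frozen=True)
class InterfaceDescriptor:
    """Interface summary of a dimer.

    ``relative_area`` maps (chain, residue index) to the percent interfacial
    area; ``interface_a``/``interface_b`` are the residue indices whose
    relative area exceeds ``threshold``; the geometric centers are unweighted
    means over heavy atoms (or Calpha atoms in ``ca`` mode).  ``gc_ia`` /
    ``gc_ib`` are ``None`` when the corresponding interface set is empty, in
    which case the descriptor is flagged ``no_interface``.
    """

    chains: tuple[str, str]
    relative_area: dict[tuple[str, int], float]
    interface_a: frozenset[int]
    interface_b: frozenset[int]
    gc_a: np.ndarray
    gc_b: np.ndarray
    gc_ia: np.ndarray | None
    gc_ib: np.ndarray | None
    threshold: float = 10.0
    total_area_nm2: float = 0.0

    @property
    def no_interface(self) -> bool:
        return not self.interface_a or not self.interface_b


def _center(structure: MolecularStructure, mask: np.ndarray, model: int) -> np.ndarray:
    return structure.coords[model][mask].mean(axis=0)


def interface_descriptor(
    dimer: MolecularStructure,
    chains: tuple[str, str] | None = None,
    threshold: float = 10.0,
    center_atoms: str = "all-atom",
    model: int = 0,
    areas: pd.DataFrame | None = None,
    **sasa_kwargs,
) -> InterfaceDescriptor:
    """Detect the interface of a dimer and compute its geometric centers.

    ``center_atoms`` selects the atoms whose unweighted means define the
    four centers: ``"all-atom"`` (heavy atoms, the default) or ``"ca"``
    (Calpha only).  A precomputed :func:`interfacial_areas` table can be
    passed via ``areas`` to avoid recomputing SASA.
    """
    if areas is None:
        areas = interfacial_areas(dimer, chains=chains, model=model, **sasa_kwargs)
    chains = areas.attrs["chains"]
    rel = {
        (row.chain, int(row.res_id)): float(row.relative)
        for row in areas.itertuples()
    }
    iface = {c: frozenset(
        int(row.res_id)
        for row in areas.itertuples()
        if row.chain == c and row.relative > threshold
    ) for c in chains}

    if center_atoms == "all-atom":
        atom_mask = dimer.heavy_mask()
    elif center_atoms == "ca":
        atom_mask = dimer.atom_name.astype(str) == "CA"
        if not atom_mask.any():
            raise ValueError("no Calpha atoms present for ca center mode")
    else:
        raise ValueError(f"unknown center_atoms mode {center_atoms!r}")

    masks = {c: atom_mask & (dimer.chain_id == c) for c in chains}
    gc_a = _center(dimer, masks[chains[0]], model)
    gc_b = _center(dimer, masks[chains[1]], model)

    centers_i = {}
    for c in chains:
        m = masks[c] & np.isin(dimer.res_id, sorted(iface[c]))
        centers_i[c] = _center(dimer, m, model) if m.any() else None

    return InterfaceDescriptor(
        chains=chains,
        relative_area=rel,
        interface_a=iface[chains[0]],
        interface_b=iface[chains[1]],
        gc_a=gc_a,
        gc_b=gc_b,
        gc_ia=centers_i[chains[0]],
        gc_ib=centers_i[chains[1]],
        threshold=threshold,
        total_area_nm2=areas.attrs["total_area_nm2"],
    )


def _tagged_interface(d: InterfaceDescriptor) -> frozenset[tuple[str, int]]:
    return frozenset(
        {(d.chains[0], r) for r in d.interface_a}
        | {(d.chains[1], r) for r in d.interface_b}
    )


def conserved_interface_fraction(
    reference: InterfaceDescriptor, current: InterfaceDescriptor
) -> float:
    """Percentage of reference interface residues still present in ``current``.

    Interface membership is binary on residue identities (chain, index): the
    magnitude of the buried area is not compared.  The fraction is computed
    over the union of the A-side and B-side residue sets.
    """
    ref = _tagged_interface(reference)
    if not ref:
        raise ValueError("reference interface is empty; fraction undefined")
    cur = _tagged_interface(current)
    return 100.0 * len(ref & cur) / len(ref)
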