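"""Reading, writing and atom selection for molecular structures.

Structures are carried as :class:`MolecularStructure`, a plain container of
parallel numpy arrays (one entry per atom) plus a coordinate block of shape
``(n_models, n_atoms, 3)``.  PDB parsing and writing is delegated to biotite;
residue numbering is taken verbatim from the file (author numbering), since
the core-residue ranges used for superposition are author-numbered.

The default superposition core is the beta-2-microglobulin core (the Calpha
atoms of residues 23-27, 36-39, 51-55, 62-66 and 78-82, the B-F strands),
chosen so loops and the mobile N-/C-termini do not pollute alignments; it is
fully configurable because the method itself is protein-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "StructureFormatError",
    "EmptySelectionError",
    "MolecularStructure",
    "CoreSelection",
    "B2M_CORE",
    "read_structure",
    "write_structure",
    "write_polymer",
    "select_core",
]

_CHAIN_NAMESPACE = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be interpreted."""


class EmptySelectionError(ValueError):
    """Raised when an atom selection matches nothing (never silently empty)."""


@dataclass
class MolecularStructure:
    """Atoms with coordinates and residue/chain bookkeeping.

    ``coords`` has shape ``(n_models, n_atoms, 3)`` in Angstrom; all models
    share one topology (the per-atom annotation arrays).  ``masses`` is
    optional (Dalton).
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        n = self.coords.shape[1]
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom ({n})")
            setattr(self, name, arr)
        self.res_id = self.res_id.astype(int)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must all be finite")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses must have one entry per atom")

    # -- bookkeeping -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        """Unique chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def model(self, index: int = 0) -> np.ndarray:
        """Coordinates of one model, shape (n_atoms, 3)."""
        return self.coords[index]

    def subset(self, mask: np.ndarray) -> "MolecularStructure":
        """New structure restricted to the atoms where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise EmptySelectionError("subset mask selects no atoms")
        return MolecularStructure(
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            chain_id=self.chain_id[mask],
            coords=self.coords[:, mask],
            masses=None if self.masses is None else self.masses[mask],
        )

    def select_chain(self, chain: str) -> "MolecularStructure":
        if chain not in self.chains:
            raise KeyError(f"chain {chain!r} not present (have {self.chains})")
        return self.subset(self.chain_id == chain)

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Same topology with a new coordinate block."""
        return MolecularStructure(
            atom_name=self.atom_name,
            element=self.element,
            res_id=self.res_id,
            res_name=self.res_name,
            chain_id=self.chain_id,
            coords=coords,
            masses=self.masses,
        )

    def relabel_chain(self, chain: str) -> "MolecularStructure":
        out = self.with_coords(self.coords.copy())
        out.chain_id = np.full(self.n_atoms, chain, dtype=object)
        return out

    def heavy_mask(self) -> np.ndarray:
        """Mask of non-hydrogen atoms."""
        elements = np.char.upper(self.element.astype(str))
        return ~np.isin(elements, ("H", "D"))


@dataclass(frozen=True)
class CoreSelection:
    """Inclusive 1-based residue ranges defining a superposition core."""

    ranges: tuple[tuple[int, int], ...]
    ca_only: bool = True

    def __post_init__(self) -> None:
        ranges = tuple((int(a), int(b)) for a, b in self.ranges)
        for a, b in ranges:
            if a > b:
                raise ValueError(f"range start {a} exceeds end {b}")
        ordered = sorted(ranges)
        for (_, b1), (a2, _) in zip(ordered, ordered[1:]):
            if a2 <= b1:
                raise ValueError("core residue ranges overlap")
        object.__setattr__(self, "ranges", ranges)

    def residue_ids(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out


#: beta-2-microglobulin structural core (strands B-F), author numbering.
B2M_CORE = CoreSelection(((23, 27), (36, 39), (51, 55), (62, 66), (78, 82)))


# -- biotite bridge ------------------------------------------------------


def _to_atom_array(structure: MolecularStructure, model: int) -> bts.AtomArray:
    n = structure.n_atoms
    array = bts.AtomArray(n)
    array.coord = np.asarray(structure.coords[model], dtype=np.float32)
    array.chain_id = structure.chain_id.astype("U4")
    array.res_id = structure.res_id.astype(int)
    array.res_name = structure.res_name.astype("U5")
    array.atom_name = structure.atom_name.astype("U6")
    array.element = np.char.upper(structure.element.astype("U2"))
    return array


def _from_stack(stack) -> MolecularStructure:
    if isinstance(stack, bts.AtomArray):
        coords = np.asarray(stack.coord, dtype=float)[None]
        template = stack
    else:
        coords = np.asarray(stack.coord, dtype=float)
        template = stack[0]
    return MolecularStructure(
        atom_name=np.asarray(template.atom_name, dtype=object),
        element=np.asarray(template.element, dtype=object),
        res_id=np.asarray(template.res_id, dtype=int),
        res_name=np.asarray(template.res_name, dtype=object),
        chain_id=np.asarray(template.chain_id, dtype=object),
        coords=coords,
    )


def read_structure(path, format: str = "PDB") -> MolecularStructure:
    """Read an atomic structure (all models) from a PDB file.

    Chain order is preserved from the file; for atoms with alternate
    locations only the highest-occupancy variant is kept.
    """
    if format.upper() != "PDB":
        raise ValueError(f"unsupported format {format!r}; only PDB is handled")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such structure file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        raise StructureFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureFormatError(f"{path} contains no atoms")
    return _from_stack(stack)


def write_structure(structure: MolecularStructure, path) -> None:
    """Write all models of a structure to a PDB file (MODEL records)."""
    write_polymer(
        [structure.with_coords(structure.coords[m]) for m in range(structure.n_models)],
        path,
    )


def write_polymer(monomers, path, mode: str = "models") -> None:
    """Write a list of topology-sharing structures to one PDB file.

    ``mode="models"`` (default) writes each monomer as a MODEL record --
    chains would exhaust the one-character chain namespace quickly.
    ``mode="chains"`` writes a single model with one chain per monomer
    (at most 62 monomers).  Coordinates round-trip to PDB precision (1e-3 A).
    """
    monomers = list(monomers)
    if not monomers:
        raise ValueError("cannot write a polymer of zero monomers")
    first = monomers[0]
    for m in monomers[1:]:
        if m.n_atoms != first.n_atoms or not np.array_equal(
            m.atom_name, first.atom_name
        ):
            raise ValueError("all monomers must share one topology")
    if first.n_atoms > 99999:
        raise ValueError(
            "more than 99999 atoms per model cannot be represented in PDB; "
            "split the polymer into several files"
        )
    path = Path(path)
    pdb = PDBFile()
    if mode == "models":
        arrays = [
            _to_atom_array(m.with_coords(m.coords[0]), 0) for m in monomers
        ]
        stack = bts.stack(arrays) if len(arrays) > 1 else arrays[0]
        pdb.set_structure(stack)
    elif mode == "chains":
        if len(monomers) > len(_CHAIN_NAMESPACE):
            raise ValueError(
                f"chain mode supports at most {len(_CHAIN_NAMESPACE)} monomers; "
                "use mode='models'"
            )
        if len(monomers) * first.n_atoms > 99999:
            raise ValueError(
                "combined chain-mode model exceeds 99999 atoms; use mode='models'"
            )
        parts = []
        for k, m in enumerate(monomers):
            arr = _to_atom_array(m.with_coords(m.coords[0]), 0)
            arr.chain_id = np.full(m.n_atoms, _CHAIN_NAMESPACE[k], dtype="U4")
            parts.append(arr)
        pdb.set_structure(bts.concatenate(parts))
    else:
        raise ValueError(f"unknown polymer mode {mode!r}")
    pdb.write(str(path))


def select_core(
    structure: MolecularStructure,
    chain: str,
    selection: CoreSelection = B2M_CORE,
    model: int = 0,
) -> np.ndarray:
    """Coordinates of the core atoms of one chain, in residue order.

    Only Calpha atoms are used when ``selection.ca_only`` (the default);
    the same residue set is selected in every model, only ``model`` decides
    which coordinates are returned.

    Raises
    ------
    KeyError
        If the chain does not exist.
    EmptySelectionError
        If no atom falls in the requested ranges.
    """
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not present (have {structure.chains})")
    mask = structure.chain_id == chain
    if selection.ca_only:
        mask &= structure.atom_name.astype(str) == "CA"
    wanted = np.isin(structure.res_id, selection.residue_ids())
    mask &= wanted
    if not mask.any():
        raise EmptySelectionError(
            f"core selection {selection.ranges} matches no atoms in chain {chain!r}"
        )
    idx = np.flatnonzero(mask)
    order = np.argsort(structure.res_id[idx], kind="stable")
    return structure.coords[model][idx[order]]
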