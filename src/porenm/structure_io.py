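"""Read/write multi-chain PDB structures and reduce them to Cα pseudo-atoms.

Two structure representations are used throughout the package:

* :class:`FullAtomStructure` keeps every ATOM record of one model and is used
  only for side-chain distance measurements.
* :class:`CGStructure` keeps one node per residue (the Cα atom) and is the
  input to the elastic-network stages.

Parsing is delegated to :mod:`biotite`; writing is plain fixed-column
formatting so that coarse-grained structures round-trip at PDB precision
(3 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyStructureError, FormatError

__all__ = [
    "CGStructure",
    "FullAtomStructure",
    "read_pdb",
    "to_calpha",
    "write_pdb",
]

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class CGStructure:
    """Ordered Cα pseudo-atoms with chain/residue identity.

    Atoms are kept sorted by (chain_id, residue_number); the constructor
    enforces the ordering and the uniqueness of (chain_id, residue_number).
    Coordinates are in Å.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray
    source_label: str = ""
    model_index: int = 1
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.chain_ids)
        if n < 2:
            raise EmptyStructureError(
                f"a coarse-grained structure needs at least 2 atoms, got {n}"
            )
        if self.coords.shape != (n, 3):
            raise FormatError(
                f"coordinate array shape {self.coords.shape} does not match {n} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise FormatError("non-finite coordinates in structure")
        order = np.lexsort((self.res_ids, self.chain_ids))
        if not np.array_equal(order, np.arange(n)):
            self.chain_ids = self.chain_ids[order]
            self.res_ids = self.res_ids[order]
            self.res_names = self.res_names[order]
            self.coords = self.coords[order]
        keys = list(zip(self.chain_ids.tolist(), self.res_ids.tolist()))
        if len(set(keys)) != n:
            raise FormatError("duplicate (chain_id, residue_number) in structure")
        self._index = {key: i for i, key in enumerate(keys)}

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in atom order (each once)."""
        seen: dict[str, None] = {}
        for c in self.chain_ids.tolist():
            seen.setdefault(c, None)
        return list(seen)

    def node_index(self, chain_id: str, res_id: int) -> int:
        """Index of the node for (chain, residue); KeyError if absent."""
        return self._index[(chain_id, int(res_id))]

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def with_coords(self, coords: np.ndarray) -> "CGStructure":
        """Copy of this structure with replaced coordinates (same identities)."""
        return CGStructure(
            chain_ids=self.chain_ids.copy(),
            res_ids=self.res_ids.copy(),
            res_names=self.res_names.copy(),
            coords=np.asarray(coords, dtype=np.float64).copy(),
            source_label=self.source_label,
            model_index=self.model_index,
            meta=dict(self.meta),
        )


@dataclass
class FullAtomStructure:
    """All ATOM records of one PDB model, in file order."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    ins_codes: np.ndarray
    coords: np.ndarray
    source_label: str = ""
    model_index: int = 1

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        self.ins_codes = np.asarray(self.ins_codes, dtype="U1")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.n_atoms == 0:
            raise EmptyStructureError("structure selection contains no atoms")
        if not np.isfinite(self.coords).all():
            raise FormatError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids.tolist():
            seen.setdefault(c, None)
        return list(seen)

    def residue_atoms(self, chain_id: str, res_id: int) -> np.ndarray:
        """Boolean mask of atoms belonging to the given residue."""
        return (self.chain_ids == chain_id) & (self.res_ids == int(res_id))


def read_pdb(path, model: int = 1, chain_filter=None) -> FullAtomStructure:
    """Read one model of a PDB file into a :class:`FullAtomStructure`.

    HETATM records are excluded; for altloc duplicates the first-listed
    conformer is kept; residues are retained in file order.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such PDB file: {path}")
    try:
        pdb_file = PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        if not 1 <= model <= n_models:
            raise FormatError(
                f"model {model} not present in {path.name} ({n_models} model(s))"
            )
        atoms = pdb_file.get_structure(model=model, altloc="first")
    except FormatError:
        raise
    except Exception as exc:  # biotite raises a mixture of error types
        raise FormatError(f"could not parse {path.name} as PDB: {exc}") from exc

    keep = ~atoms.hetero
    if chain_filter is not None:
        chain_filter = set(chain_filter)
        keep &= np.isin(atoms.chain_id, sorted(chain_filter))
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"no protein ATOM records selected from {path.name}")

    # drop duplicate (chain, residue, icode, atom name) keeping first occurrence
    seen: set[tuple] = set()
    keep_idx = []
    keys = zip(
        atoms.chain_id.tolist(),
        atoms.res_id.tolist(),
        atoms.ins_code.tolist(),
        atoms.atom_name.tolist(),
    )
    for i, key in enumerate(keys):
        if key not in seen:
            seen.add(key)
            keep_idx.append(i)
    atoms = atoms[np.asarray(keep_idx, dtype=np.int64)]

    return FullAtomStructure(
        chain_ids=atoms.chain_id,
        res_ids=atoms.res_id,
        res_names=atoms.res_name,
        atom_names=atoms.atom_name,
        ins_codes=atoms.ins_code,
        coords=atoms.coord,
        source_label=path.stem,
        model_index=model,
    )


def to_calpha(full: FullAtomStructure) -> CGStructure:
    """One node per residue possessing a CA atom.

    Residues without a CA atom are skipped; their identities are listed in
    ``result.meta["skipped_residues"]``. Duplicate residue numbers within a
    chain (insertion codes) keep the first-listed CA.
    """
    chain_ids, res_ids, res_names, coords = [], [], [], []
    seen_res: set[tuple] = set()
    residues_seen: dict[tuple, str] = {}
    has_ca: set[tuple] = set()
    for i in range(full.n_atoms):
        res_key = (full.chain_ids[i], int(full.res_ids[i]), full.ins_codes[i])
        residues_seen.setdefault(res_key, full.res_names[i])
        if full.atom_names[i] != "CA":
            continue
        node_key = (full.chain_ids[i], int(full.res_ids[i]))
        if node_key in seen_res:
            continue
        seen_res.add(node_key)
        has_ca.add(res_key)
        chain_ids.append(full.chain_ids[i])
        res_ids.append(int(full.res_ids[i]))
        res_names.append(full.res_names[i])
        coords.append(full.coords[i])
    if not chain_ids:
        raise EmptyStructureError("structure contains no CA atoms")
    skipped = sorted(
        (c, r, ic) for (c, r, ic) in residues_seen if (c, r, ic) not in has_ca
        and (c, r) not in seen_res
    )
    cg = CGStructure(
        chain_ids=np.array(chain_ids),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names),
        coords=np.array(coords),
        source_label=full.source_label,
        model_index=full.model_index,
    )
    cg.meta["skipped_residues"] = skipped
    return cg


def _format_atom_line(serial, name, res_name, chain_id, res_id, xyz, element) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{res_name:>3s} {chain_id[:1]:1s}"
        f"{res_id:>4d}{'':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(structure, path) -> None:
    """Write a structure as standards-compliant ATOM records (3-decimal coords)."""
    if structure is None or getattr(structure, "n_atoms", 0) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    is_full = isinstance(structure, FullAtomStructure)
    lines = []
    serial = 0
    prev_chain = None
    for i in range(structure.n_atoms):
        chain = structure.chain_ids[i]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        name = structure.atom_names[i] if is_full else "CA"
        element = name.strip()[:1] if is_full else "C"
        lines.append(
            _format_atom_line(
                serial,
                name,
                structure.res_names[i],
                chain,
                int(structure.res_ids[i]),
                structure.coords[i],
                element,
            )
        )
    lines.append("TER")
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise FormatError(f"cannot write PDB to {path}: {exc}") from exc
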