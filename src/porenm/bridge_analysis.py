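"""Inter-subunit residue-pair distance screen for carbamate-bridge candidates.

A bridge candidate is a lysine on one chain whose side-chain amine sits
within a stated distance of the guanidinium/amine group of an
arginine/lysine on another chain. Distances use full-atom coordinates;
the coarse-grained network never enters here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ResidueLookupError, SpecificationError
from .structure_io import FullAtomStructure

__all__ = [
    "BridgeCandidate",
    "SIDE_CHAIN_TIP_ATOMS",
    "measure_pair_distance",
    "scan_candidate_bridges",
]

# Atoms defining the chemically bridging end of each side chain. For other
# residue types the full set of non-backbone heavy atoms is used.
SIDE_CHAIN_TIP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
}
_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class BridgeCandidate:
    donor: tuple[str, int, str]  # (chain, residue_number, residue_name)
    acceptor: tuple[str, int, str]
    distance: float
    atom_pair_used: tuple[str, str]
    interface: tuple[str, str]


def _residue_atoms(structure: FullAtomStructure, chain: str, res_id: int):
    mask = structure.residue_atoms(chain, res_id)
    if not mask.any():
        raise ResidueLookupError(f"residue {res_id} absent from chain {chain}")
    idx = np.flatnonzero(mask)
    res_name = structure.res_names[idx[0]]
    return res_name, {structure.atom_names[i]: structure.coords[i] for i in idx}


def _tip_atoms(res_name: str, atoms: dict) -> dict:
    wanted = SIDE_CHAIN_TIP_ATOMS.get(res_name)
    if wanted is None:
        tips = {n: p for n, p in atoms.items() if n not in _BACKBONE}
    else:
        tips = {n: atoms[n] for n in wanted if n in atoms}
    return tips


def measure_pair_distance(
    structure: FullAtomStructure,
    resA: tuple[str, int],
    resB: tuple[str, int],
    metric: str = "side_chain_min",
    detail: bool = False,
):
    """Distance between two residues.

    ``side_chain_min``: minimum over the side-chain tip atoms of both
    residues (LYS: NZ; ARG: NE/CZ/NH1/NH2; otherwise all side-chain atoms).
    ``calpha``: Cα–Cα distance. With ``detail=True`` returns
    (distance, atom_name_A, atom_name_B) plus, for side_chain_min, the full
    per-atom-pair distance table.
    """
    nameA, atomsA = _residue_atoms(structure, *resA)
    nameB, atomsB = _residue_atoms(structure, *resB)
    if metric == "calpha":
        for name, atoms, res in ((nameA, atomsA, resA), (nameB, atomsB, resB)):
            if "CA" not in atoms:
                raise ResidueLookupError(f"residue {res} ({name}) has no CA atom")
        d = float(np.linalg.norm(atomsA["CA"] - atomsB["CA"]))
        return (d, "CA", "CA", {("CA", "CA"): d}) if detail else d
    if metric != "side_chain_min":
        raise SpecificationError(f"unknown metric {metric!r}")
    tipsA = _tip_atoms(nameA, atomsA)
    tipsB = _tip_atoms(nameB, atomsB)
    if not tipsA:
        raise ResidueLookupError(f"no side-chain tip atoms for {resA} ({nameA})")
    if not tipsB:
        raise ResidueLookupError(f"no side-chain tip atoms for {resB} ({nameB})")
    table = {
        (na, nb): float(np.linalg.norm(pa - pb))
        for na, pa in sorted(tipsA.items())
        for nb, pb in sorted(tipsB.items())
    }
    (na, nb), d = min(table.items(), key=lambda kv: (kv[1], kv[0]))
    return (d, na, nb, table) if detail else d


def scan_candidate_bridges(
    structure: FullAtomStructure,
    donor_type: str = "LYS",
    acceptor_types: tuple[str, ...] = ("ARG", "LYS"),
    max_distance: float = 8.0,
) -> list[BridgeCandidate]:
    """All inter-chain donor→acceptor pairs within ``max_distance``.

    Results are sorted by distance, then donor (chain, residue), then
    acceptor, for determinism. Residues whose tip atoms are unresolved are
    skipped with a warning rather than silently substituted.
    """
    chains = structure.chains
    if len(chains) < 2:
        raise SpecificationError("bridge scan needs a multi-chain structure")
    acceptor_types = tuple(acceptor_types)

    def _collect(res_type_filter):
        found = []
        seen = set()
        for i in range(structure.n_atoms):
            key = (structure.chain_ids[i], int(structure.res_ids[i]))
            if key in seen:
                continue
            seen.add(key)
            name = structure.res_names[i]
            if name not in res_type_filter:
                continue
            _, atoms = _residue_atoms(structure, *key)
            tips = _tip_atoms(name, atoms)
            if not tips:
                warnings.warn(
                    f"{name} {key[1]} chain {key[0]}: side-chain atoms unresolved; "
                    "residue skipped from the bridge scan"
                )
                continue
            found.append((key[0], key[1], name, tips))
        return found

    donors = _collect({donor_type})
    acceptors = _collect(set(acceptor_types))
    candidates = []
    for dchain, dres, dname, dtips in donors:
        for achain, ares, aname, atips in acceptors:
            if achain == dchain:
                continue
            table = {
                (na, nb): float(np.linalg.norm(pa - pb))
                for na, pa in sorted(dtips.items())
                for nb, pb in sorted(atips.items())
            }
            (na, nb), d = min(table.items(), key=lambda kv: (kv[1], kv[0]))
            if d <= max_distance:
                candidates.append(
                    BridgeCandidate(
                        donor=(dchain, dres, dname),
                        acceptor=(achain, ares, aname),
                        distance=d,
                        atom_pair_used=(na, nb),
                        interface=(dchain, achain),
                    )
                )
    candidates.sort(key=lambda c: (c.distance, c.donor, c.acceptor))
    return candidates
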