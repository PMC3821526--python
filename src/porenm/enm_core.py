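"""Anisotropic elastic-network model: springs, Hessian, normal modes.

Every pair of Cα nodes closer than the cutoff radius (default 8 Å) is joined
by a Hookean spring of uniform stiffness (default 1 kcal mol⁻¹ Å⁻²). Ligand
binding at an inter-subunit site is represented by one extra "bridge" spring
per adjacent-chain interface. Normal modes are the eigenpairs of the 3N×3N
anisotropic-network Hessian; the near-zero rigid-body modes are flagged and
excluded from mode numbering, so mode 1 is the lowest internal mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import cKDTree

from .errors import (
    DisconnectedNetworkError,
    ParameterError,
    SpecificationError,
)
from .structure_io import CGStructure

__all__ = [
    "Spring",
    "SpringNetwork",
    "BridgeSpec",
    "ModeSet",
    "build_spring_network",
    "add_bridge_springs",
    "build_hessian",
    "compute_modes",
    "mode_fraction",
    "mode_fractions",
]

WEIGHTINGS = ("inv", "inv_sqrt", "uniform")


@dataclass(frozen=True)
class Spring:
    i: int
    j: int
    rest_length: float
    k: float
    tag: str = "contact"  # "contact" or "bridge"


@dataclass
class SpringNetwork:
    """Node-indexed Hookean springs over the coordinates of a CGStructure."""

    n_nodes: int
    springs: list[Spring]
    node_coords: np.ndarray
    cutoff: float | None = None

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=np.float64)
        if self.node_coords.shape != (self.n_nodes, 3):
            raise ParameterError("node_coords shape does not match n_nodes")
        seen = set()
        for s in self.springs:
            if not 0 <= s.i < s.j < self.n_nodes:
                raise ParameterError(f"invalid spring indices ({s.i}, {s.j})")
            if (s.i, s.j) in seen:
                raise ParameterError(f"duplicate spring ({s.i}, {s.j})")
            seen.add((s.i, s.j))
            if s.rest_length <= 0 or s.k <= 0:
                raise ParameterError("springs need positive rest_length and k")

    @property
    def n_springs(self) -> int:
        return len(self.springs)

    def count(self, tag: str) -> int:
        return sum(1 for s in self.springs if s.tag == tag)

    def to_table(self):
        """Springs as a pandas DataFrame (i, j, rest_length, k, tag)."""
        import pandas as pd

        return pd.DataFrame(
            [(s.i, s.j, s.rest_length, s.k, s.tag) for s in self.springs],
            columns=["i", "j", "rest_length", "k", "tag"],
        )


@dataclass(frozen=True)
class BridgeSpec:
    """One donor→acceptor bridge spring per adjacent-chain interface.

    ``donor``/``acceptor`` are (residue_number, expected residue name) pairs;
    an expected name of None disables the identity guard. ``interface_rule``
    is "cyclic" (chain i bridges to chain i+1 in label order) or "nearest"
    (each donor pairs with the nearest acceptor on another chain; the mapping
    must visit every chain exactly once).
    """

    donor: tuple[int, str | None] = (125, "LYS")
    acceptor: tuple[int, str | None] = (104, "ARG")
    bridge_k: float = 1.0
    interface_rule: str = "cyclic"

    def __post_init__(self):
        if self.bridge_k <= 0:
            raise ParameterError("bridge_k must be positive")
        if self.interface_rule not in ("cyclic", "nearest"):
            raise ParameterError(f"unknown interface_rule {self.interface_rule!r}")


def build_spring_network(
    structure: CGStructure, cutoff: float = 8.0, k: float = 1.0
) -> SpringNetwork:
    """Contact springs for every node pair with separation ≤ cutoff (inclusive)."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if k <= 0:
        raise ParameterError("spring constant must be positive")
    if structure.n_atoms < 2:
        raise ParameterError("need at least 2 nodes to build a network")
    coords = structure.coords
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(r=cutoff))  # inclusive: d <= cutoff
    springs = [
        Spring(i, j, float(np.linalg.norm(coords[i] - coords[j])), float(k), "contact")
        for i, j in pairs
    ]
    return SpringNetwork(
        n_nodes=structure.n_atoms,
        springs=springs,
        node_coords=coords.copy(),
        cutoff=float(cutoff),
    )


def _resolve_bridge_nodes(structure: CGStructure, res_id: int, expected: str | None):
    """Per-chain node index of the residue; SpecificationError names misses."""
    nodes = {}
    for chain in structure.chains:
        try:
            idx = structure.node_index(chain, res_id)
        except KeyError:
            raise SpecificationError(
                f"residue {res_id} absent from chain {chain}"
            ) from None
        name = structure.res_names[idx]
        if expected is not None and name != expected:
            raise SpecificationError(
                f"residue {res_id} in chain {chain} is {name}, expected {expected}"
            )
        nodes[chain] = idx
    return nodes


def _interface_pairs(structure, donor_nodes, acceptor_nodes, rule):
    chains = structure.chains
    if rule == "cyclic":
        return [
            (chains[i], chains[(i + 1) % len(chains)]) for i in range(len(chains))
        ]
    # nearest: donor of each chain pairs with the closest acceptor elsewhere
    pairs = []
    for ci in chains:
        d = structure.coords[donor_nodes[ci]]
        best, best_dist = None, np.inf
        for cj in chains:
            if cj == ci:
                continue
            dist = float(np.linalg.norm(d - structure.coords[acceptor_nodes[cj]]))
            if dist < best_dist:
                best, best_dist = cj, dist
        pairs.append((ci, best))
    targets = [b for _, b in pairs]
    if sorted(targets) != sorted(chains):
        raise SpecificationError(
            "nearest-acceptor mapping does not visit every chain exactly once; "
            "specify interface_rule='cyclic' or check the bridge residues"
        )
    return pairs


def add_bridge_springs(
    network: SpringNetwork, structure: CGStructure, bridge: BridgeSpec
) -> SpringNetwork:
    """Return a copy of the network with one bridge spring per interface.

    If a contact spring already joins a donor/acceptor pair, the bridge
    stiffness is added to that spring's constant (and the spring is retagged
    "bridge") instead of creating a duplicate pair.
    """
    if network.n_nodes != structure.n_atoms:
        raise ParameterError("network and structure sizes differ")
    donor_nodes = _resolve_bridge_nodes(structure, bridge.donor[0], bridge.donor[1])
    acceptor_nodes = _resolve_bridge_nodes(
        structure, bridge.acceptor[0], bridge.acceptor[1]
    )
    springs = list(network.springs)
    index_of_pair = {(s.i, s.j): idx for idx, s in enumerate(springs)}
    for ci, cj in _interface_pairs(
        structure, donor_nodes, acceptor_nodes, bridge.interface_rule
    ):
        a, b = donor_nodes[ci], acceptor_nodes[cj]
        i, j = (a, b) if a < b else (b, a)
        rest = float(np.linalg.norm(structure.coords[a] - structure.coords[b]))
        if (i, j) in index_of_pair:
            old = springs[index_of_pair[(i, j)]]
            springs[index_of_pair[(i, j)]] = replace(
                old, k=old.k + bridge.bridge_k, tag="bridge"
            )
        else:
            springs.append(Spring(i, j, rest, bridge.bridge_k, "bridge"))
            index_of_pair[(i, j)] = len(springs) - 1
    return SpringNetwork(
        n_nodes=network.n_nodes,
        springs=springs,
        node_coords=network.node_coords.copy(),
        cutoff=network.cutoff,
    )


def build_hessian(network: SpringNetwork) -> np.ndarray:
    """Dense 3N×3N anisotropic-network Hessian.

    For a spring (i, j) with unit bond vector r̂ the off-diagonal 3×3 block is
    −k·r̂r̂ᵀ; diagonal blocks accumulate +k·r̂r̂ᵀ. The assembly is exactly
    symmetric and the three uniform translations span (part of) the null
    space.
    """
    n = network.n_nodes
    hessian = np.zeros((3 * n, 3 * n))
    coords = network.node_coords
    for s in network.springs:
        d = coords[s.i] - coords[s.j]
        block = (s.k / float(d @ d)) * np.outer(d, d)
        si, sj = 3 * s.i, 3 * s.j
        hessian[si : si + 3, si : si + 3] += block
        hessian[sj : sj + 3, sj : sj + 3] += block
        hessian[si : si + 3, sj : sj + 3] -= block
        hessian[sj : sj + 3, si : si + 3] -= block
    return hessian


@dataclass
class ModeSet:
    """Eigen-decomposition of an ENM Hessian with rigid modes flagged.

    ``eigenvalues`` ascending (kcal mol⁻¹ Å⁻², unit masses); ``eigenvectors``
    orthonormal columns; the first ``rigid_count`` eigenpairs are rigid-body
    motions. Non-rigid modes are numbered from 1 (mode 1 = first internal
    mode).
    """

    n_nodes: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    rigid_count: int
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def n_modes(self) -> int:
        """Number of non-rigid modes."""
        return len(self.eigenvalues) - self.rigid_count

    @property
    def nonrigid_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.rigid_count :]

    def eigenvalue(self, m: int) -> float:
        self._check_mode(m)
        return float(self.eigenvalues[self.rigid_count + m - 1])

    def mode_vector(self, m: int) -> np.ndarray:
        """Orthonormal 3N eigenvector of non-rigid mode ``m`` (1-based)."""
        self._check_mode(m)
        return self.eigenvectors[:, self.rigid_count + m - 1]

    def nonrigid_vectors(self, n_modes: int | None = None) -> np.ndarray:
        n_modes = self.n_modes if n_modes is None else min(n_modes, self.n_modes)
        return self.eigenvectors[:, self.rigid_count : self.rigid_count + n_modes]

    def _check_mode(self, m: int) -> None:
        if not 1 <= m <= self.n_modes:
            raise ParameterError(
                f"mode index {m} outside the non-rigid range 1..{self.n_modes}"
            )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def compute_modes(hessian: np.ndarray, rigid_tolerance: float | None = None) -> ModeSet:
    """Diagonalize the Hessian and flag rigid-body modes.

    ``rigid_tolerance`` defaults to 1e-8 × the largest eigenvalue. More than
    six eigenvalues below the tolerance means the network is disconnected.
    """
    hessian = np.asarray(hessian, dtype=np.float64)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ParameterError("hessian must be square")
    if hessian.shape[0] % 3 != 0:
        raise ParameterError("hessian dimension must be a multiple of 3")
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ParameterError("hessian must be symmetric")
    eigenvalues, eigenvectors = eigh(hessian)
    eigenvectors = _fix_signs(eigenvectors)
    scale = float(eigenvalues[-1]) if eigenvalues[-1] > 0 else 1.0
    tol = 1e-8 * scale if rigid_tolerance is None else float(rigid_tolerance)
    rigid = int(np.sum(eigenvalues < tol))
    if rigid > 6:
        raise DisconnectedNetworkError(
            f"{rigid} near-zero modes (tolerance {tol:g}): network is disconnected"
        )
    return ModeSet(
        n_nodes=hessian.shape[0] // 3,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        rigid_count=rigid,
        meta={"rigid_tolerance": tol},
    )


def _weights(eigenvalues: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "inv":
        return 1.0 / eigenvalues
    if weighting == "inv_sqrt":
        return 1.0 / np.sqrt(eigenvalues)
    if weighting == "uniform":
        return np.ones_like(eigenvalues)
    raise ParameterError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def mode_fractions(modes: ModeSet, weighting: str = "inv") -> np.ndarray:
    """Fractional contribution of every non-rigid mode to the total motion.

    The default weighting is the thermal mean-square amplitude 1/λ; fractions
    sum to 1 over all non-rigid modes.
    """
    w = _weights(modes.nonrigid_eigenvalues, weighting)
    return w / w.sum()


def mode_fraction(modes: ModeSet, m: int, weighting: str = "inv") -> float:
    """Fraction of the total motion carried by non-rigid mode ``m`` (1-based)."""
    modes._check_mode(m)
    return float(mode_fractions(modes, weighting)[m - 1])
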