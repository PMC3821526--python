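"""Parametric C_n-symmetric toy oligomers and analytic micro-systems.

The generated channel is a ring of ``n_subunits`` identical subunits around
the z axis. Each subunit is a compact serpentine grid of Cα pseudo-atoms
(three tangential tracks × ``residues_per_subunit // 3`` height levels)
whose radial position follows a Gaussian waist: ``ring_radius`` at the ends,
``pore_radius`` at mid-height. Neighbouring subunits touch only near the
waist, so the assembly's low-frequency modes include a radial
opening/closing swing of the subunits about that hinge — a toy gating
motion. The donor/acceptor pair sits above the waist where the interface
gap exceeds the usual 8 Å contact cutoff, so a bridge spring there adds a
genuinely new constraint that stiffens exactly the closing swing.

One residue per subunit is the bridge donor (residue name LYS) and one the
acceptor (ARG); the donor is repositioned along the donor→acceptor(next
chain) line so that the donor(i)–acceptor(i+1) distance equals
``target_bridge_distance`` exactly, on every interface, while preserving the
C_n symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .structure_io import CGStructure

__all__ = [
    "OligomerSpec",
    "make_cn_oligomer",
    "make_dimer",
    "perturb",
    "bridge_residues",
]

_TRACKS = 3  # tangential tracks per subunit
_TRACK_SPACING = 3.9  # Å between tracks, roughly Calpha spacing
_WAIST_WIDTH = 0.22  # Gaussian width of the radial bulge (fraction of height)


@dataclass(frozen=True)
class OligomerSpec:
    """Parameters of a C_n-symmetric toy channel."""

    n_subunits: int = 6
    residues_per_subunit: int = 30
    ring_radius: float = 16.0
    pore_radius: float = 11.5
    axial_rise: float = 3.6
    donor_index: int | None = None
    acceptor_index: int | None = None
    target_bridge_distance: float = 9.5  # Cα–Cα scale; beyond the 8 Å cutoff
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subunits < 2:
            raise ParameterError("n_subunits must be >= 2")
        if self.residues_per_subunit < 3:
            raise ParameterError("residues_per_subunit must be >= 3")
        if not (0 < self.pore_radius <= self.ring_radius):
            raise ParameterError("need 0 < pore_radius <= ring_radius")
        if self.axial_rise <= 0:
            raise ParameterError("axial_rise must be positive")
        if self.target_bridge_distance <= 0:
            raise ParameterError("target_bridge_distance must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _template(spec: OligomerSpec) -> tuple[np.ndarray, int, int]:
    """Coordinates of subunit A plus default donor/acceptor residue indices.

    The subunit is built in a local frame (u radial, v tangential, w axial)
    so its physical width does not scale with radius; residues run serpentine
    over (level, track) so consecutive residues are spatial neighbours.
    Returns 0-based donor/acceptor indices.
    """
    m = spec.residues_per_subunit
    n_levels = int(np.ceil(m / _TRACKS))
    coords = np.empty((m, 3))
    for j in range(m):
        level, pos = divmod(j, _TRACKS)
        track = pos if level % 2 == 0 else _TRACKS - 1 - pos
        t = level / max(n_levels - 1, 1)
        u = -(spec.ring_radius - spec.pore_radius) * np.exp(
            -(((t - 0.5) / _WAIST_WIDTH) ** 2)
        )
        v = (track - (_TRACKS - 1) / 2.0) * _TRACK_SPACING
        w = (level - (n_levels - 1) / 2.0) * spec.axial_rise
        coords[j] = (spec.ring_radius + u, v, w)

    # donor/acceptor face each other across the interface gap above the
    # waist, where neighbouring subunits are out of contact range.
    bridge_level = min(int(round(0.75 * (n_levels - 1))), n_levels - 1)

    def _residue_at(level: int, track: int) -> int:
        pos = track if level % 2 == 0 else _TRACKS - 1 - track
        return min(level * _TRACKS + pos, m - 1)

    donor = _residue_at(bridge_level, _TRACKS - 1)
    acceptor = _residue_at(bridge_level, 0)
    return coords, donor, acceptor


def bridge_residues(spec: OligomerSpec) -> tuple[int, int]:
    """(donor, acceptor) residue numbers the generator will use for ``spec``."""
    spec.validate()
    _, donor_default, acceptor_default = _template(spec)
    donor = spec.donor_index if spec.donor_index is not None else donor_default + 1
    acceptor = (
        spec.acceptor_index if spec.acceptor_index is not None else acceptor_default + 1
    )
    return donor, acceptor


def make_cn_oligomer(spec: OligomerSpec) -> CGStructure:
    """Generate the toy channel described by ``spec``.

    Deterministic for a fixed seed; exactly C_n symmetric when
    ``noise_sigma == 0``.
    """
    spec.validate()
    m = spec.residues_per_subunit
    template, donor_default, acceptor_default = _template(spec)
    donor = spec.donor_index - 1 if spec.donor_index is not None else donor_default
    acceptor = (
        spec.acceptor_index - 1 if spec.acceptor_index is not None else acceptor_default
    )
    if not (0 <= donor < m and 0 <= acceptor < m) or donor == acceptor:
        raise ParameterError("donor/acceptor indices out of range or identical")

    rot = _rotation_z(2.0 * np.pi / spec.n_subunits)
    # pin the donor at target distance from the next chain's acceptor; the
    # adjustment is applied to the template so every interface is identical.
    acceptor_next = template[acceptor] @ rot.T
    gap = template[donor] - acceptor_next
    gap_norm = float(np.linalg.norm(gap))
    if gap_norm < 1e-9:
        raise ParameterError("degenerate donor/acceptor geometry")
    if abs(spec.target_bridge_distance - gap_norm) > 5.0:
        raise ParameterError(
            f"target_bridge_distance {spec.target_bridge_distance} Å is too far "
            f"from the natural interface gap ({gap_norm:.2f} Å) for this geometry"
        )
    template = template.copy()
    template[donor] = acceptor_next + spec.target_bridge_distance * gap / gap_norm

    if spec.n_subunits > 26:
        raise ParameterError("at most 26 subunits (single-letter chain ids)")
    chain_letters = [chr(ord("A") + i) for i in range(spec.n_subunits)]
    chain_ids, res_ids, res_names, coords = [], [], [], []
    for i, letter in enumerate(chain_letters):
        rot_i = _rotation_z(2.0 * np.pi * i / spec.n_subunits)
        chain_coords = template @ rot_i.T
        for j in range(m):
            chain_ids.append(letter)
            res_ids.append(j + 1)
            if j == donor:
                res_names.append("LYS")
            elif j == acceptor:
                res_names.append("ARG")
            else:
                res_names.append("GLY")
        coords.append(chain_coords)
    coords = np.vstack(coords)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)

    structure = CGStructure(
        chain_ids=np.array(chain_ids),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names),
        coords=coords,
        source_label=f"cn_oligomer_n{spec.n_subunits}_seed{spec.seed}",
    )
    structure.meta["oligomer_spec"] = replace(spec)
    structure.meta["donor_res_id"] = donor + 1
    structure.meta["acceptor_res_id"] = acceptor + 1
    return structure


def make_dimer(separation: float) -> CGStructure:
    """Two Cα atoms on the x axis at the stated separation (single chain)."""
    if not separation > 1e-6:
        raise ParameterError(f"separation must be positive, got {separation!r}")
    return CGStructure(
        chain_ids=np.array(["A", "A"]),
        res_ids=np.array([1, 2]),
        res_names=np.array(["GLY", "GLY"]),
        coords=np.array([[0.0, 0.0, 0.0], [float(separation), 0.0, 0.0]]),
        source_label=f"dimer_{separation:g}",
    )


def perturb(structure: CGStructure, sigma: float, seed: int = 0) -> CGStructure:
    """Isotropic Gaussian displacement of every atom; sigma 0 is the identity."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return structure.with_coords(structure.coords)
    rng = np.random.default_rng(seed)
    return structure.with_coords(
        structure.coords + rng.normal(0.0, sigma, structure.coords.shape)
    )
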