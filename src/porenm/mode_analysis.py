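"""Compare unbound and bridge-bound mode sets and quantify pore occlusion.

The central objects are the overlap map — entry (a, b) is the absolute dot
product between unbound mode a and bound mode b, so 1 means the motion is
preserved — and the pore profile, the minimum radial clearance of the Cα
cloud around the channel axis, evaluated along a displaced structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComparisonError, FormatError, ParameterError
from .enm_core import ModeSet, mode_fractions
from .structure_io import CGStructure

__all__ = [
    "OverlapMap",
    "PoreProfile",
    "overlap_matrix",
    "reordering_report",
    "pore_profile",
    "channel_axis",
    "mode_displacement_vectors",
    "radial_character",
    "write_nmd",
    "read_nmd",
    "save_overlap_heatmap",
]


@dataclass
class OverlapMap:
    """|dot-product| similarity between two mode sets.

    ``values[a-1, b-1] = |v_a(unbound) · v_b(bound)|`` for non-rigid modes.
    ``best_match[a-1]`` is the 1-based bound mode of maximal overlap with
    unbound mode a (ties resolved toward the lower bound index).
    """

    values: np.ndarray
    n_modes_compared: int
    best_match: np.ndarray
    fraction_unbound: np.ndarray
    fraction_bound: np.ndarray
    eigenvalues_unbound: np.ndarray
    eigenvalues_bound: np.ndarray
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def one_to_one_match(self) -> np.ndarray:
        """Optimal one-to-one assignment (maximises total overlap), 1-based."""
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-self.values)
        out = np.empty(self.values.shape[0], dtype=int)
        out[rows] = cols + 1
        return out


def overlap_matrix(unbound: ModeSet, bound: ModeSet, n_modes: int = 20) -> OverlapMap:
    """Overlap of the ``n_modes`` lowest non-rigid modes of the two states."""
    if unbound.n_nodes != bound.n_nodes:
        raise ComparisonError(
            f"mode sets have different node counts "
            f"({unbound.n_nodes} vs {bound.n_nodes})"
        )
    if n_modes < 1:
        raise ParameterError("n_modes must be >= 1")
    n = min(n_modes, unbound.n_modes, bound.n_modes)
    u = unbound.nonrigid_vectors(n)
    v = bound.nonrigid_vectors(n)
    values = np.abs(u.T @ v)
    best = values.argmax(axis=1) + 1  # argmax takes the first (lowest) maximum
    return OverlapMap(
        values=values,
        n_modes_compared=n,
        best_match=best,
        fraction_unbound=mode_fractions(unbound)[:n],
        fraction_bound=mode_fractions(bound)[:n],
        eigenvalues_unbound=unbound.nonrigid_eigenvalues[:n],
        eigenvalues_bound=bound.nonrigid_eigenvalues[:n],
    )


def reordering_report(overlap: OverlapMap) -> pd.DataFrame:
    """Per-mode reordering table (one row per unbound mode).

    Columns include the scatter data of frequency-vs-frequency plots: the
    unbound mode's frequency (√λ) against its best-match bound frequency;
    rows on x = y are unchanged by binding.
    """
    n = overlap.n_modes_compared
    best = overlap.best_match
    rows = {
        "unbound_mode": np.arange(1, n + 1),
        "bound_best_match": best,
        "overlap": overlap.values[np.arange(n), best - 1],
        "unbound_fraction": overlap.fraction_unbound,
        "bound_fraction": overlap.fraction_bound[best - 1],
        "unbound_frequency": np.sqrt(overlap.eigenvalues_unbound),
        "bound_frequency": np.sqrt(overlap.eigenvalues_bound[best - 1]),
    }
    return pd.DataFrame(rows)


def channel_axis(structure: CGStructure) -> tuple[np.ndarray, np.ndarray]:
    """(origin, unit direction) of the pore axis.

    For an oligomer of ≥3 chains the chain centroids of a ring lie in a
    plane, so the axis is the smallest-variance principal direction of the
    centroid cloud; otherwise the global z axis is used. The direction is
    oriented with a non-negative z component.
    """
    origin = structure.coords.mean(axis=0)
    chains = structure.chains
    if len(chains) >= 3:
        centroids = np.array(
            [structure.coords[structure.chain_mask(c)].mean(axis=0) for c in chains]
        )
        centered = centroids - centroids.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=True)
        direction = vt[-1]
    else:
        direction = np.array([0.0, 0.0, 1.0])
    if direction[2] < 0:
        direction = -direction
    return origin, direction / np.linalg.norm(direction)


@dataclass
class PoreProfile:
    """Minimum radial clearance per axial slice."""

    origin: np.ndarray
    direction: np.ndarray
    slices: pd.DataFrame  # columns: z_lo, z_hi, min_radius, n_atoms
    min_radius: float


def pore_profile(
    structure: CGStructure,
    mode: np.ndarray | None = None,
    amplitude: float = 0.0,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    slice_thickness: float = 2.0,
) -> PoreProfile:
    """Radial clearance profile of the (optionally mode-displaced) structure.

    The structure is displaced by ``amplitude × v̂`` where v̂ is the mode
    eigenvector normalised to unit 3N norm; amplitude 0 gives the static
    profile.
    """
    if not np.isfinite(amplitude):
        raise ParameterError("amplitude must be finite")
    if slice_thickness <= 0:
        raise ParameterError("slice_thickness must be positive")
    coords = structure.coords
    if mode is not None:
        mode = np.asarray(mode, dtype=np.float64).ravel()
        if mode.size != 3 * structure.n_atoms:
            raise ParameterError(
                f"mode length {mode.size} does not match 3N = {3 * structure.n_atoms}"
            )
        norm = np.linalg.norm(mode)
        if norm == 0:
            raise ParameterError("mode vector is zero")
        coords = coords + amplitude * (mode / norm).reshape(-1, 3)
    origin, direction = channel_axis(structure) if axis is None else axis
    direction = np.asarray(direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    rel = coords - origin
    axial = rel @ direction
    radial = np.linalg.norm(rel - np.outer(axial, direction), axis=1)
    lo, hi = float(axial.min()), float(axial.max())
    n_slices = max(1, int(np.ceil((hi - lo) / slice_thickness)))
    rows = []
    for s in range(n_slices):
        z_lo = lo + s * slice_thickness
        z_hi = z_lo + slice_thickness
        mask = (axial >= z_lo) & (axial < z_hi if s < n_slices - 1 else axial <= z_hi)
        if not mask.any():
            continue
        rows.append((z_lo, z_hi, float(radial[mask].min()), int(mask.sum())))
    slices = pd.DataFrame(rows, columns=["z_lo", "z_hi", "min_radius", "n_atoms"])
    return PoreProfile(
        origin=origin,
        direction=direction,
        slices=slices,
        min_radius=float(slices["min_radius"].min()),
    )


def mode_displacement_vectors(
    structure: CGStructure, mode: np.ndarray, scale: float = 1.0
) -> np.ndarray:
    """Per-node 3-vectors of a mode, with total 3N norm equal to ``scale``."""
    mode = np.asarray(mode, dtype=np.float64).ravel()
    if mode.size != 3 * structure.n_atoms:
        raise ParameterError("mode length does not match structure")
    if scale == 0:
        return np.zeros((structure.n_atoms, 3))
    norm = np.linalg.norm(mode)
    if norm == 0:
        raise ParameterError("mode vector is zero")
    return (scale / norm) * mode.reshape(-1, 3)


def radial_character(structure: CGStructure, mode: np.ndarray) -> float:
    """Fraction of a mode's squared norm that is radial w.r.t. the pore axis.

    1 means a purely radial (opening/closing-type) motion, 0 a purely
    tangential/axial one.
    """
    origin, direction = channel_axis(structure)
    rel = structure.coords - origin
    axial = rel @ direction
    radial_vec = rel - np.outer(axial, direction)
    norms = np.linalg.norm(radial_vec, axis=1)
    norms[norms == 0] = 1.0
    radial_unit = radial_vec / norms[:, None]
    disp = np.asarray(mode, dtype=np.float64).reshape(-1, 3)
    radial_comp = np.einsum("ij,ij->i", disp, radial_unit)
    total = float(np.sum(disp**2))
    if total == 0:
        raise ParameterError("mode vector is zero")
    return float(np.sum(radial_comp**2) / total)


# ---------------------------------------------------------------------------
# NMD (NMWiz-compatible) export/import


def write_nmd(
    path,
    structure: CGStructure,
    modes: ModeSet,
    n_modes: int = 20,
    name: str | None = None,
) -> None:
    """Write the lowest non-rigid modes in NMD format.

    Each mode line is scaled by 1/√λ so that rendered arrow lengths follow
    thermal amplitudes.
    """
    n = min(n_modes, modes.n_modes)
    if modes.n_nodes != structure.n_atoms:
        raise ComparisonError("mode set and structure sizes differ")
    lines = [
        "nmwiz_load porenm.nmd",
        f"name {name or structure.source_label or 'porenm'}",
        "resnames " + " ".join(structure.res_names.tolist()),
        "chainids " + " ".join(structure.chain_ids.tolist()),
        "resids " + " ".join(str(r) for r in structure.res_ids.tolist()),
        "coordinates " + " ".join(f"{x:.8f}" for x in structure.coords.ravel()),
    ]
    for m in range(1, n + 1):
        scale = 1.0 / np.sqrt(modes.eigenvalue(m))
        comps = " ".join(f"{x:.8f}" for x in modes.mode_vector(m))
        lines.append(f"mode {m} {scale:.8f} {comps}")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise FormatError(f"cannot write NMD to {path}: {exc}") from exc


def read_nmd(path) -> dict:
    """Parse an NMD file back into coordinates and (index, scale, vector) modes."""
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such NMD file: {path}")
    out: dict = {"modes": []}
    for line in path.read_text().splitlines():
        fields = line.split()
        if not fields:
            continue
        key = fields[0]
        if key == "coordinates":
            out["coordinates"] = np.array(fields[1:], dtype=float).reshape(-1, 3)
        elif key == "mode":
            index = int(fields[1])
            scale = float(fields[2])
            vector = np.array(fields[3:], dtype=float)
            out["modes"].append((index, scale, vector))
        elif key in ("resnames", "chainids"):
            out[key] = fields[1:]
        elif key == "resids":
            out[key] = [int(x) for x in fields[1:]]
        elif key == "name":
            out["name"] = " ".join(fields[1:])
    if "coordinates" not in out:
        raise FormatError(f"{path.name} has no coordinates line")
    return out


def save_overlap_heatmap(overlap: OverlapMap, path) -> None:
    """Grayscale heat map of the overlap matrix (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = overlap.n_modes_compared
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        overlap.values,
        cmap="gray_r",
        vmin=0.0,
        vmax=1.0,
        origin="lower",
        extent=(0.5, n + 0.5, 0.5, n + 0.5),
    )
    ax.plot([0.5, n + 0.5], [0.5, n + 0.5], ls=":", c="tab:red", lw=0.8)
    ax.set_xlabel("bound mode")
    ax.set_ylabel("unbound mode")
    fig.colorbar(im, ax=ax, label="|overlap|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
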