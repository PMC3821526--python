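"""End-to-end comparison pipeline: structure → two ENMs → modes → report.

A run is fully determined by its :class:`RunConfig` (including seeds), so
re-running an identical config yields byte-identical outputs. All artifacts
are plain text (CSV/TSV/NMD/JSON) and can be re-loaded to resume analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .structure_io import read_pdb, to_calpha, write_pdb
from .synthetic_structures import OligomerSpec, make_cn_oligomer
from .enm_core import (
    BridgeSpec,
    add_bridge_springs,
    build_hessian,
    build_spring_network,
    compute_modes,
    mode_fractions,
)
from .mode_analysis import (
    overlap_matrix,
    pore_profile,
    reordering_report,
    write_nmd,
)
from .bridge_analysis import scan_candidate_bridges

__all__ = ["RunConfig", "run_comparison", "run_bridge_scan"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a comparison run."""

    pdb_path: str | None = None
    synthetic: OligomerSpec | None = None
    cutoff: float = 8.0
    k: float = 1.0
    bridge: BridgeSpec = field(default_factory=BridgeSpec)
    n_modes_report: int = 20
    rigid_tolerance: float | None = None
    weighting: str = "inv"
    outdir: str = "porenm_out"
    label: str = "run"

    def __post_init__(self):
        if (self.pdb_path is None) == (self.synthetic is None):
            raise ParameterError("exactly one of pdb_path / synthetic must be set")

    # -- flat key=value (de)serialization --------------------------------

    def to_flat(self) -> str:
        lines = [
            f"label={self.label}",
            f"cutoff={self.cutoff!r}",
            f"k={self.k!r}",
            f"n_modes_report={self.n_modes_report}",
            f"rigid_tolerance={'' if self.rigid_tolerance is None else repr(self.rigid_tolerance)}",
            f"weighting={self.weighting}",
            f"outdir={self.outdir}",
            f"bridge.donor={self.bridge.donor[0]}:{self.bridge.donor[1] or ''}",
            f"bridge.acceptor={self.bridge.acceptor[0]}:{self.bridge.acceptor[1] or ''}",
            f"bridge.bridge_k={self.bridge.bridge_k!r}",
            f"bridge.interface_rule={self.bridge.interface_rule}",
        ]
        if self.pdb_path is not None:
            lines.append(f"pdb_path={self.pdb_path}")
        if self.synthetic is not None:
            for f_ in dataclasses.fields(self.synthetic):
                value = getattr(self.synthetic, f_.name)
                lines.append(f"synthetic.{f_.name}={'' if value is None else value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "RunConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"bad config line: {line!r}")
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

        def _res(text_: str) -> tuple[int, str | None]:
            num, _, name = text_.partition(":")
            return int(num), (name or None)

        bridge = BridgeSpec(
            donor=_res(kv.get("bridge.donor", "125:LYS")),
            acceptor=_res(kv.get("bridge.acceptor", "104:ARG")),
            bridge_k=float(kv.get("bridge.bridge_k", "1.0")),
            interface_rule=kv.get("bridge.interface_rule", "cyclic"),
        )
        synthetic = None
        syn_keys = {k_ for k_ in kv if k_.startswith("synthetic.")}
        if syn_keys:
            kwargs = {}
            for f_ in dataclasses.fields(OligomerSpec):
                raw = kv.get(f"synthetic.{f_.name}")
                if raw is None or raw == "" or raw == "None":
                    continue
                caster = int if f_.type in ("int", "int | None") else float
                kwargs[f_.name] = caster(raw)
            synthetic = OligomerSpec(**kwargs)
        rigid_tol = kv.get("rigid_tolerance", "")
        return cls(
            pdb_path=kv.get("pdb_path"),
            synthetic=synthetic,
            cutoff=float(kv.get("cutoff", "8.0")),
            k=float(kv.get("k", "1.0")),
            bridge=bridge,
            n_modes_report=int(kv.get("n_modes_report", "20")),
            rigid_tolerance=None if rigid_tol in ("", "None") else float(rigid_tol),
            weighting=kv.get("weighting", "inv"),
            outdir=kv.get("outdir", "porenm_out"),
            label=kv.get("label", "run"),
        )


def _load_structure(config: RunConfig):
    if config.pdb_path is not None:
        full = read_pdb(config.pdb_path)
        return to_calpha(full)
    return make_cn_oligomer(config.synthetic)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_comparison(config: RunConfig) -> dict:
    """Run the unbound-vs-bridged comparison and write the report bundle.

    Returns the machine-readable summary (also written as summary.json).
    """
    structure = _load_structure(config)
    outdir = Path(config.outdir)

    network = build_spring_network(structure, cutoff=config.cutoff, k=config.k)
    bound_network = add_bridge_springs(network, structure, config.bridge)
    unbound = compute_modes(build_hessian(network), config.rigid_tolerance)
    bound = compute_modes(build_hessian(bound_network), config.rigid_tolerance)

    n_report = min(config.n_modes_report, unbound.n_modes, bound.n_modes)
    overlap = overlap_matrix(unbound, bound, n_modes=n_report)
    report = reordering_report(overlap)

    frac_unbound = mode_fractions(unbound, config.weighting)
    frac_bound = mode_fractions(bound, config.weighting)
    best = int(overlap.best_match[0])

    outdir.mkdir(parents=True, exist_ok=True)
    write_pdb(structure, outdir / "structure.pdb")
    network.to_table().to_csv(outdir / "springs_unbound.tsv", sep="\t", index=False)
    bound_network.to_table().to_csv(outdir / "springs_bound.tsv", sep="\t", index=False)
    pd.DataFrame({"eigenvalue": unbound.nonrigid_eigenvalues}).to_csv(
        outdir / "eigenvalues_unbound.csv", index_label="mode"
    )
    pd.DataFrame({"eigenvalue": bound.nonrigid_eigenvalues}).to_csv(
        outdir / "eigenvalues_bound.csv", index_label="mode"
    )
    pd.DataFrame(
        {
            "mode": np.arange(1, n_report + 1),
            "fraction_unbound": frac_unbound[:n_report],
            "fraction_bound": frac_bound[:n_report],
        }
    ).to_csv(outdir / "mode_fractions.tsv", sep="\t", index=False)
    pd.DataFrame(
        overlap.values,
        index=[f"u{m}" for m in range(1, n_report + 1)],
        columns=[f"b{m}" for m in range(1, n_report + 1)],
    ).to_csv(outdir / "overlap.csv")
    report.to_csv(outdir / "reordering.tsv", sep="\t", index=False)
    write_nmd(outdir / "unbound.nmd", structure, unbound, n_modes=n_report)
    write_nmd(outdir / "bound.nmd", structure, bound, n_modes=n_report)
    for state, modes in (("unbound", unbound), ("bound", bound)):
        profile = pore_profile(structure, mode=modes.mode_vector(1), amplitude=0.0)
        profile.slices.to_csv(outdir / f"pore_{state}.tsv", sep="\t", index=False)

    summary = {
        "label": config.label,
        "n_nodes": structure.n_atoms,
        "n_chains": len(structure.chains),
        "n_contact_springs": network.count("contact"),
        "bridge_spring_count": bound_network.count("bridge"),
        "rigid_count_unbound": unbound.rigid_count,
        "rigid_count_bound": bound.rigid_count,
        "weighting": config.weighting,
        "unbound_mode1_fraction": float(frac_unbound[0]),
        "unbound_mode1_best_match_bound_index": best,
        "bound_best_match_fraction": float(frac_bound[best - 1]),
        "bound_best_match_overlap": float(overlap.values[0, best - 1]),
    }
    _json_dump(summary, outdir / "summary.json")
    (outdir / "config.cfg").write_text(config.to_flat())
    return summary


def run_bridge_scan(
    pdb_path,
    max_distance: float = 8.0,
    donor_type: str = "LYS",
    acceptor_types: tuple[str, ...] = ("ARG", "LYS"),
    out_path=None,
) -> pd.DataFrame:
    """Bridge-candidate scan on a full-atom structure, optionally written as TSV."""
    full = read_pdb(pdb_path)
    candidates = scan_candidate_bridges(
        full,
        donor_type=donor_type,
        acceptor_types=acceptor_types,
        max_distance=max_distance,
    )
    table = pd.DataFrame(
        [
            {
                "donor_chain": c.donor[0],
                "donor_res": c.donor[1],
                "donor_name": c.donor[2],
                "acceptor_chain": c.acceptor[0],
                "acceptor_res": c.acceptor[1],
                "acceptor_name": c.acceptor[2],
                "distance": c.distance,
                "donor_atom": c.atom_pair_used[0],
                "acceptor_atom": c.atom_pair_used[1],
            }
            for c in candidates
        ],
        columns=[
            "donor_chain",
            "donor_res",
            "donor_name",
            "acceptor_chain",
            "acceptor_res",
            "acceptor_name",
            "distance",
            "donor_atom",
            "acceptor_atom",
        ],
    )
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
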