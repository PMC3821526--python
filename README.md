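# porenm

Coarse-grained elastic-network analysis of oligomeric channel gating.

`porenm` builds anisotropic elastic-network models (ANM/ENM) from the Cα
atoms of multi-chain channel structures, represents inter-subunit ligand
bridges (e.g. a CO₂-derived lysine-carbamate → arginine salt bridge) as one
extra Hookean spring per interface, and quantifies how those springs reorder
the normal modes — in particular, how a pore-closing mode is demoted so that
it no longer dominates the total motion. Supporting tools screen structures
for bridge-competent residue pairs, detect the KVREI carbamylation sequence
motif, and build engineered variants from mutation labels.

## Layout

| module | purpose |
| --- | --- |
| `porenm.structure_io` | PDB reading/writing, Cα reduction (`CGStructure`, `FullAtomStructure`) |
| `porenm.synthetic_structures` | parametric C_n-symmetric toy channels and micro-systems for testing |
| `porenm.enm_core` | spring networks (8 Å cutoff, k = 1 kcal mol⁻¹ Å⁻² defaults), bridge springs, Hessian, normal modes, mode fractions |
| `porenm.mode_analysis` | overlap matrices, mode-reordering reports, pore radial-clearance profiles, NMD export |
| `porenm.bridge_analysis` | inter-subunit side-chain distance screens (LYS NZ ↔ ARG NE/CZ/NH1/NH2) |
| `porenm.motif_toolkit` | motif search, mutation-label parsing, range-replacement edits, FASTA I/O |
| `porenm.pipeline` / `porenm.cli` | end-to-end comparison runs and the `porenm` command line |

## CLI

```sh
porenm synth --out toy.pdb                       # C6 toy channel
porenm build --pdb toy.pdb --cutoff 8 --k 1 --out springs.tsv
porenm modes --pdb toy.pdb --out-prefix toy
porenm bridge --pdb toy.pdb --donor 22:LYS --acceptor 24:ARG --out bound.tsv
porenm compare --synthetic --outdir run/         # unbound vs bridged report
porenm compare --pdb 2ZW3.pdb --donor 125:LYS --acceptor 104:ARG --outdir cx26/
porenm pore --pdb toy.pdb --nmd toy.nmd --mode 1 --amplitude 40 --out pore.tsv
porenm bridge-scan --pdb 2ZW3.pdb --max-distance 8 --out candidates.tsv
porenm motif --fasta seqs.fasta --pattern KVREI
porenm mutate --fasta seqs.fasta --edit "replace:123-124:TQKVREI" --edit K125R --out mutants.fasta
```

`compare` writes a report bundle (eigenvalue CSVs, mode-fraction table,
overlap matrix, reordering report, NMD files for both states, pore profiles,
`summary.json`); identical configurations yield byte-identical output.

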