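# oligoscan

Assessment toolkit for predicted homo-oligomer protein assemblies.  Given a
multi-chain structure prediction (PDB/mmCIF, pLDDT in the B-factor column),
its predicted-aligned-error (PAE) matrix, and a per-protein domain table
(BTB / hinge / CTD residue ranges), oligoscan produces:

- **Reliability grading** — per-block percentages of residue pairs with PAE
  strictly below 10 Å (intra-BTB / intra-CTD / inter-BTB / inter-CTD),
  graded reliable (R, all blocks > 65%), partially reliable (PR) or
  unreliable (U), plus a stable/unstable (S/U) oligomer call.
- **Sub-stoichiometry inference** — low-error chain-pair quadrants of the
  PAE linked into candidate sub-oligomers (e.g. dimer propensity).
- **Superposition** — Kabsch fits, iterative outlier-rejecting refinement,
  and symmetry-aware whole-assembly alignment with a chain-mapping search.
- **Assembly geometry** — Cn symmetry order/axis/angle, open/closed ring
  detection from buried interface areas (Shrake–Rupley SASA), an axial pore
  radius profile, and Cα-geometry secondary-structure assignment.
- **Trajectory analysis** — RMSD series against the starting model (global
  and per-domain, with optional fit-on-one-domain / measure-another mode),
  secondary-structure content evolution, closest-to-average frame, and
  low / limited / high stability labels (3 / 6 Å bands).
- **Synthetic data** — seeded generators for Cn-symmetric multi-domain toy
  assemblies (with optional open subunit), block-structured PAE matrices,
  and trajectories with an explicit BTB-vs-CTD rotation mode, so every
  stage is verifiable offline with known ground truth.

## CLI

```sh
# write a complete synthetic fixture set with known ground truth
oligoscan generate --out fixtures/ --protein-id demo --regime reliable --seed 7

# assess one assembly (JSON assessment + block-statistics TSV)
oligoscan assess --structure fixtures/demo_structure.pdb \
    --pae fixtures/demo_pae.json --domains fixtures/demo_domains.tsv \
    --trajectory fixtures/demo_trajectory.pdb --out out/

# one table row per fixture set in a directory
oligoscan batch --dir fixtures/ --out report.tsv --json report.json
```

Thresholds (PAE cutoff, R/PR percentages, chain adjacency mode, PAE
symmetrization) are exposed as flags on `assess`/`batch` and echoed into
logs and reports.

Domain tables are 4-column TSV (`protein`, `domain`, `start`, `end`;
1-based inclusive author numbering, one map applied to every chain of a
homo-oligomer).  PAE input accepts the nested-list JSON dialect
(`pae` / `predicted_aligned_error`) and the flat
`residue1`/`residue2`/`distance` triplet dialect.  Trajectories are
multi-model PDB.

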