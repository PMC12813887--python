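# cardyn

Domain-resolved trajectory analysis for membrane-spanning chimeric antigen
receptors (CARs), built around one question: **how does antigen binding
redistribute conformational sampling between the extracellular and the
intracellular side of the receptor?**

A second-generation CAR is a single chain of five structural domains — the
antigen-binding scFv head (AB), the hinge (HI), the transmembrane anchor
(TM), the costimulatory linker (CS), and the CD3ζ signaling tail (SI) —
plus, in the bound (holo) state, the antigen (AG). Mechanically it behaves
like a coupled pendulum hinged at the membrane: in the free (apo) state
the head sweeps a wide arch while the tail stays confined; binding tethers
the head to the target cell and the sampling width migrates to the
intracellular tail. `cardyn` implements the full analysis protocol that
establishes this switch, and a coarse-grained stochastic generator that
produces trajectories with exactly that statistical structure, so every
stage is testable at desk scale against a known ground truth.

## What it computes

Given multi-model PDB trajectories and a YAML domain map:

- **Cα-RMSD series** per domain, fit-to-TM (keeps inter-domain rigid-body
  motion) and fit-to-self (internal deformation only), and the apo/holo
  decomposition `inter = Δoverall − Δintra` attributing conformational
  contrast to inter-domain rearrangement;
- **RMSF profiles**, radii of gyration by terminus, domain-center
  distances (AB–TM, SI–TM), end-to-end distance;
- **sampling clouds**: per-frame domain centroids in the membrane frame,
  summarised by covariance trace, principal extents, planar/normal spread
  and hull volume, and the **switch score**

  S = ln(tr Σ_AB^apo / tr Σ_AB^holo) + ln(tr Σ_SI^holo / tr Σ_SI^apo),

  positive exactly when binding narrows head sampling and/or widens tail
  sampling;
- **membrane contacts** (heavy-atom pairs within 2.5 Å between the CD3ζ
  polybasic/ITAM groups and the lipid pseudo-atoms) and **burial depth**
  of the ITAM tyrosines in the slab;
- **secondary-structure fractions** per domain (dihedral-window rule),
  **leader clustering** at a 2.5 Å RMSD cutoff, and **correlation-network
  communities** (Girvan–Newman on a contact-filtered −log|C_ij| graph);
- **ITAM motif scanning** (Yxx(L/I) x{6–12} Yxx(L/I)) on sequences.

The synthetic generator (`cardyn simulate`) is a bead-spring receptor
spanning a membrane slab, sampled with overdamped Langevin dynamics; its
apo/holo presets program a ≥4-fold covariance-trace contrast in the
expected directions. See `docs/methods.md` for the model, parameters and
what the generator does and does not emulate.

## Worked example

Simulate both states, analyse each, and compare:

```
$ cardyn simulate --state apo  --seed 0 --out apo_sim
apo trajectory (601 frames, 91 atoms) written to apo_sim
$ cardyn simulate --state holo --seed 0 --out holo_sim
holo trajectory (601 frames, 92 atoms) written to holo_sim
$ cardyn analyze --trajectory apo_sim/trajectory.pdb \
    --domain-map apo_sim/domain_map.yaml --equil-cut 100 --out apo_bundle
bundle written to apo_bundle
$ cardyn analyze --trajectory holo_sim/trajectory.pdb \
    --domain-map holo_sim/domain_map.yaml --equil-cut 100 --out holo_bundle
bundle written to holo_bundle
$ cardyn compare apo_bundle holo_bundle --out report.json
switch score: 4.313
report written to report.json
```

Inside `report.json` (seed 0):

```
"switch": {"score": 4.313,
           "ab_trace_apo": 31.18, "ab_trace_holo": 5.70,
           "si_trace_apo": 3.56,  "si_trace_holo": 48.52}
```

Reading these numbers: the head's sampling covariance trace shrinks
~5.5-fold on binding (31.2 → 5.7 Å²) while the tail's grows ~13.6-fold
(3.6 → 48.5 Å²); the switch score ln 5.5 + ln 13.6 ≈ 4.3 > 0 is the
binding-induced sampling switch. The report also shows the head moving
toward the membrane on binding (mean AB–TM centroid distance 29.5 Å apo
vs 26.7 Å holo) and carries the per-domain RMSD decomposition, contact
and secondary-structure summaries, and cluster/community counts per state.

Each analysis bundle is a directory of TSV series (one row per frame) plus
one `summary.json`; everything is deterministic given the inputs, and a
rerun is byte-identical.

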