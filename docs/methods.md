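# Methods

## The analysis protocol

`cardyn` analyses trajectories of a membrane-spanning chimeric antigen
receptor (CAR) — antigen-binding head (AB), hinge (HI), transmembrane
anchor (TM), costimulatory linker (CS), signaling tail (SI), optionally a
bound antigen (AG) — and quantifies how antigen binding redistributes
conformational sampling between the extracellular and intracellular sides.
The receptor is treated as a coupled pendulum hinged at the membrane: in
the apo state the extracellular head sweeps a wide arch while the
intracellular tail is confined; binding tethers the head and the sampling
width migrates to the tail. All stages consume multi-model PDB trajectories
plus a YAML domain map, so synthetic and real inputs flow through an
identical pipeline.

### Superposition and frames of reference

Every per-frame metric is computed after a least-squares rigid
superposition (Kabsch, proper rotation only) of the frame onto a reference
over a *fit* selection. The reference is frame 0 of the same trajectory
unless an explicit reference structure is supplied. Fitting on the TM Cα
atoms places every frame in the membrane frame (z = membrane normal, x–y =
membrane plane, slab centred at z = 0); fitting a domain onto itself
removes its rigid-body motion and isolates internal deformation. Fewer
than 3 points, or a collinear point set, is a degeneracy error: the
rotation would be underdetermined, and the synthetic topology is built
with a small lateral helical offset (0.8 Å radius) precisely so that no
domain's reference configuration is collinear.

### The inter/intra decomposition

For each domain the pipeline computes two Cα-RMSD series per state:
*overall* (fit to TM) and *intra* (fit to self). With Δ denoting the
holo − apo difference of post-equilibration time averages,

    inter = Δ(overall) − Δ(intra)

attributes the conformational contrast to inter-domain rearrangement. The
identity `inter = overall − intra` holds exactly by construction; negative
values are legitimate (intra-domain deformation exceeding the overall
change). A domain with fewer than three Cα particles (the single-bead
blobs of the synthetic receptor) has intra ≡ 0: a point has no internal
deformation. Whether the published contrast is a difference of
time-averaged RMSDs or an RMSD between time-averaged structures is
ambiguous in the field's reporting style; the difference of time averages
is implemented, which reproduces the AB worked example exactly.

### Sampling clouds and the switch score

The per-frame Cα centroid of a domain, in the TM-aligned frame, forms a
point cloud whose 3×3 population covariance Σ summarises sampling:
covariance trace (Å², rotation invariant), principal extents (sorted
square-rooted eigenvalues), planar spread √(var x + var y), normal spread
sd(z), and convex-hull volume (0 for < 4 non-coplanar points). The switch
statistic is

    S = ln(tr Σ_AB^apo / tr Σ_AB^holo) + ln(tr Σ_SI^holo / tr Σ_SI^apo)

S > 0 iff binding, net, narrows extracellular sampling and/or widens
intracellular sampling; it is exactly antisymmetric under swapping the
state labels. The trace, not the hull volume, is scored because the trace
is stable at small frame counts; the hull volume is reported alongside.

### Contacts and burial

A contact is a heavy-atom *pair* (one group atom, one membrane atom)
within the cutoff (default 2.5 Å), counted per frame with a k-d tree;
hydrogens are excluded by the default selections. Burial depth of a
selection is `halfwidth − |z|` maximised over its atoms per frame in the
TM-aligned frame: positive inside the slab, so a series with positive mean
flags membrane insertion of, e.g., the ITAM tyrosines.

### Secondary structure

Assignment is dihedral-window based, not hydrogen-bond based: H iff
φ ∈ (−120°, −30°) and ψ ∈ (−80°, −5°); E iff φ ∈ (−180°, −70°) and
(ψ ∈ (90°, 180°] or ψ < −150°); else C; then H/E runs shorter than 3
residues are reassigned to C. The rule is simple, deterministic, and
exactly testable on ideal (φ, ψ) fixtures; it is *not* DSSP and will
differ from energy-based assignments near basin edges. Residues missing
backbone atoms (or chain termini) are labelled C.

### Clustering

A deterministic single-pass leader scan: frames in order join the first
existing representative within the RMSD cutoff (default 2.5 Å, RMSD after
pairwise superposition on the clustering selection) or found a new
cluster. Every frame is therefore within the cutoff of its representative,
the result is reproducible bit-for-bit, and the cluster count is
monotone non-increasing in the cutoff. Leader clustering is order
dependent by design — determinism was preferred over optimality.

### Correlation network and communities

Node displacements Δr_i are taken from the time-mean position after
per-frame fit; C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩). An edge joins
residues whose heavy atoms come within 4.5 Å in ≥ 75 % of frames, with
weight −log|C_ij| capped at −log(1e−6) to avoid infinities on uncorrelated
contacts. Communities come from Girvan–Newman edge-betweenness removal
(weighted betweenness; ties broken toward the lowest-index edge for
determinism), keeping the partition of maximal weighted modularity along
the dendrogram; the initial connected components are included among the
candidate partitions, so disconnected inputs seed separate communities.
The dendrogram is not guaranteed to contain the globally optimal
partition of an arbitrary graph; on small structured graphs (barbells,
cycles) it matches an exhaustive search, which the tests assert.

## The synthetic generator

### Model

One bead per blob (AB, SI, and AG in the holo state), short chains for HI
(4 beads), TM (9 beads spanning z ∈ [−15, +15] Å) and CS (4 beads), bonds
between consecutive beads (k = 2, rest lengths from the built geometry),
harmonic angles at every interior triple (k = 1, rest angle taken from the
built geometry so the initial configuration is a true energy minimum), TM
beads anchored to their rest sites (k = 5), and half-harmonic walls
(k = 5) keeping extracellular beads above and intracellular beads below
the slab. The AB and SI blobs are each anchored toward their rest position
with an effective *pendulum stiffness* — `k_HI` for AB, `k_CS` for SI —
the small-angle projection of the adjacent linker's torsional hinge
stiffness onto the bob. This form was chosen over bending-stiffness
control because with realistic lever arms the tip sampling width responds
to bending stiffness only at values that force a much smaller stable time
step and a wide stiff/soft timescale separation; the tip-anchor form
yields the same physics at desk scale.

Presets (the study conditions):

| parameter | apo | holo | meaning |
|---|---|---|---|
| k_HI (energy/Å²) | 0.05 | 1.0 | restoring stiffness on the AB head |
| k_CS (energy/Å²) | 1.0 | 0.05 | restoring stiffness on the SI tail |
| AG bead | absent | bonded to AB, anchored (k = 2) | target-cell tether |
| head bend (Å) | — | 8 lateral, 10 down | bound head rests nearer the membrane |

In the holo state the AB/AG rest position is displaced 8 Å laterally and
10 Å toward the membrane (`bend_lateral`, `bend_drop`), modelling the
target-cell tether bending the head down; this programs the second
direction the analysis must recover — the mean AB–TM centroid distance is
larger in apo than in holo (≈ 29.5 vs 26.7 Å at the defaults). The 20-fold
stiffness contrast programs a ≥ 4-fold covariance-trace contrast for both
the AB and the SI cloud; measured ratios across seeds are ~5.5–7× (AB)
and ~7–14× (SI), so the recovery tests pass with wide margin rather than
at the edge.

### Dynamics and units

Overdamped Langevin, Euler–Maruyama:
x ← x + (dt/γ)F(x) + √(2 kT dt/γ) η. Reduced units: kT = 1, γ = 1,
lengths Å-like, dt = 0.01, 60 000 steps, frames every 100 steps
(601 frames), one mandatory integer seed (NumPy PCG64); identical
seed + config reproduces trajectories bit-for-bit on the same build. The
stability bound dt·k_max/γ < 0.1 is validated at configuration time; a
deterministic displacement exceeding 10 Å in one step aborts with the step
index. Euler–Maruyama overestimates the stationary variance of a harmonic
coordinate by a factor ≈ 1/(1 − k·dt/2γ) (≤ 0.5 % at the default dt·k), far
inside the 5 % tolerance of the equipartition checks. Run length was
chosen so the softest mode (τ ≈ γ/k ≈ 20 reduced time units at k = 0.05)
relaxes ~30× within one trajectory; analyses discard the first 100 frames
as equilibration.

### What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes: a
five-domain membrane-spanning chain, wide extracellular head sampling in
apo, wide intracellular tail sampling in holo, a static membrane lattice
(6×6 pseudo-lipid atoms per leaflet) for contact/burial stages, and
residue groups (PBR/ITAM/tyrosine, mapped onto the single SI bead) so all
pipeline stages run unmodified. It does **not** emulate: atomistic detail
or secondary structure (beads are Cα pseudo-atoms, so SSE fractions on
synthetic input are all-coil), lipid chemistry or electrostatics, the sign
and magnitude of all-atom RMSD contrasts (the holo head here samples
*less*, so domain RMSD contrasts have the opposite sign to a system whose
receptor tilts wholesale), the direction of the SI–TM distance change (the
soft holo tail contracts entropically toward the membrane at the bead
scale, whereas an all-atom tail that unfolds extends away from it),
membrane insertion events, or µs kinetics.
Passing recovery tests therefore demonstrates that the pipeline measures
what it claims on data with a known ground truth — not that the biological
effect sizes are reproduced.

## Numerical choices and degenerate inputs

- Population (1/n) covariance throughout the sampling summaries, so the
  Gaussian-cloud trace converges to 3σ² without a correction factor.
- Coplanar or near-degenerate clouds: hull volume 0 (Qhull failure is
  treated as degeneracy, not error); eigenvalues clipped at 0 before the
  square root.
- Correlation nodes with variance ≤ 1e−12 Å² are errors naming the
  residue — below that the normalisation is float noise, not motion.
- PDB coordinates are fixed-column %8.3f: magnitudes ≥ 10 000 Å are an
  overflow error; round trips are lossless to 3 decimals.
- Equilibration cut defaults to 0 and is an explicit parameter everywhere;
  reports round Å quantities to 1 decimal and scores to 3, with raw
  full-precision values kept alongside in the same JSON.
- Analysis bundles are byte-deterministic given trajectory + parameters;
  the provenance block records a hash of the analysis parameters (output
  location excluded).

## Known limitations

- The dihedral-window SSE rule and the leader clustering algorithm are
  deliberate simplifications chosen for determinism and testability; both
  will differ from DSSP and from average-linkage-style clustering on real
  protein trajectories.
- ITAM residue ranges are not derivable from construct numbering and must
  come from user configuration; only the polybasic regions have canonical
  defaults (395–399, 406–410, 435–442). The motif scanner's default spacer
  range 6–12 spans both published conventions.
- Community counts and cluster counts on synthetic beads are on a
  19-node scale and are not comparable to all-atom counts.
- Cross-platform bit identity of simulations is not promised beyond the
  same NumPy build; run-to-run identity on one build is tested.
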