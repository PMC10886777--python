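# Methods

`pocketfp` reimplements, as a tested library, the in-silico analysis
layer that sits between an MD engine and a publication figure for
protein–ligand complexes: per-frame geometric interaction
fingerprints with per-residue contact-frequency histograms,
superposition-based RMSD/RMSF statistics, ligand-pose clustering with
representative-complex selection, and global conceptual-DFT
reactivity descriptors of the ligands. It does not run quantum
chemistry, docking or MD; it consumes their outputs (multi-model PDB
trajectories and species-energy tables).

## Reactivity descriptors

From total electronic energies (or enthalpies — the calculator is
agnostic about which energy column it is fed) of the neutral species A,
the cation radical A⁺ and the anion radical A⁻:

    IP = E(A⁺) − E(A)
    EA = E(A)  − E(A⁻)

The electron affinity uses the standard adiabatic convention: EA is
positive when the anion lies below the neutral. From IP and EA:

    gap = EA − IP          (signed; |gap| also reported)
    η   = (IP − EA)/2      chemical hardness (rigidity), eV
    S   = 1/(2η)           softness, 1/eV
    χ   = (IP + EA)/2      electronegativity, eV
    ω   = χ²/(2η)          electrophilicity index, eV

The gap is reported signed as EA − IP (so gap = −2η); most of the
literature quotes the positive magnitude, which is why `abs_gap` is
exposed alongside. When η = 0 the softness and electrophilicity are
undefined; the other fields are still returned and the two undefined
ones are `None` (a `DegenerateHardnessError` is raised only on
explicit access). The Koopmans route sets IP = −ε_HOMO and
EA = −ε_LUMO and then reuses the identical formulas, so the two routes
agree exactly by construction. Energies are accepted in eV or Hartree
(1 Hartree = 27.211386 eV) with an explicit unit tag; eV is canonical
internally.

## Interaction fingerprints

Five interaction classes are registered per frame between ligand and
protein, all by geometry only (no force-field scoring):

| kind          | criterion (defaults)                                       |
|---------------|------------------------------------------------------------|
| hydrogen bond | H···A < 2.5 Å, ∠(D–H–A) ≥ 120°, min over X of ∠(H–A–X) ≥ 90° |
| water bridge  | both legs as above with relaxed thresholds: < 2.8 Å, ≥ 110°, ≥ 90° |
| ionic         | min inter-atom distance between opposite formal charges ≤ 3.4 Å |
| hydrophobic   | any apolar-atom pair < 3.6 Å, ≤ 1 event per residue per frame |
| π–π / π–cation| centroid–centroid / centroid–charge-centre distance ≤ 4.5 Å |

Design choices worth stating:

* The two hydrogen-bond angle clauses are **conjunctive** by default:
  when the acceptor has bonded neighbours X, both the donor angle and
  the worst acceptor angle must clear their minima. This matches
  standard simulation-interaction-diagram practice. The disjunctive
  reading (distance plus either angle) is available as
  `angle_mode="or"`.
* The hydrogen-bond distance is measured **H···A**, not donor–acceptor:
  a 2.5 Å heavy-atom separation would be sterically impossible, so the
  threshold can only refer to the hydrogen–acceptor gap.
* π criteria are centroid-distance only; no ring-plane angle filter is
  applied by default, and a single `pi_max` governs both π–π and
  π–cation.
* Hydrophobic contacts are capped at one event per residue per frame;
  every other class counts each distinct site pair. This lets a residue
  accepting two simultaneous hydrogen bonds show a frequency of 2.0
  without letting a leucine with five close carbons inflate to 5.
* Detector output is deterministically ordered (kind, residue, site
  indices ascending), so event logs are reproducible byte for byte.

A contact frequency for a (residue, interaction-kind) key is the total
event count divided by the frame count — the mean number of qualifying
contacts per frame. 1.0 therefore means "present in 100% of frames",
0.25 "present a quarter of the time", and values above 1 mean multiple
simultaneous distinct contacts.

Pharmacophore typing of the protein comes from a shipped template
table (donors, acceptors with bonded neighbours, aromatic rings,
charged groups with fixed formal charges — LYS/ARG +1, ASP/GLU −1 —
and apolar side-chain atoms). No pKa or tautomer inference is done;
HIS is typed as a neutral π ring whose ND1/NE2 can both donate (when
protonated in the input) and accept. Donor hydrogens are resolved
geometrically (H within 1.3 Å of a donor-capable heavy atom in frame
0), so heavy-atom-only structures simply yield no donors — and the
hydrogen-bond detectors raise a capability error if the topology
contains no hydrogens at all, rather than silently reporting nothing.
Ligand sites are declared by the user in a small JSON annotation,
validated against the topology. Coordinates are Å throughout and
inputs are assumed imaged/whole; there is no periodic-boundary
handling.

## RMSD, RMSF, clustering

Superposition is the Kabsch algorithm (SVD of the weighted
cross-covariance with determinant correction; reflections are never
returned; < 3 points or a collinear set is an error). RMSD series
align every frame to the reference frame (frame 0 by default) on an
alignment selection — protein Cα by default — and then measure RMSD
over the analysis selection *without a second fit*. Ligand-mode RMSD
(selection = ligand heavy atoms, alignment = protein Cα) therefore
measures drift of the ligand within the pocket rather than internal
ligand motion. RMSF is the per-atom root-mean-square fluctuation about
the mean position after the same alignment, reported per residue at
Cα; mass weighting is off and a mean-structure reference is available
as an option.

Pose clustering subsamples every 10th frame (a 5000-frame, 100 ns
trajectory yields 500 analysed frames at 0.02 ns spacing), computes
the pairwise ligand-heavy-atom RMSD matrix after per-frame protein-Cα
alignment to the reference frame (again no per-pair refit — fast and
consistent with the RMSD definition above), and cuts an
average-linkage dendrogram at 2.0 Å. The representative complex is
the medoid of the largest cluster (minimum summed RMSD to members);
all ties — largest cluster and medoid alike — break toward the lowest
frame index. Stride, cutoff and linkage method are configuration, not
claims about any particular MD vendor's defaults.

## Synthetic data

The pocket generator builds each planted interaction as an isolated
geometric unit (ligand site + partner residue, or a bridging water) at
its own bearing on a 12 Å circle, with ≥ 30° spacing so no cross-unit
atom pair can satisfy any default criterion. Per frame each unit is
independently "on" with probability p (or follows an explicit boolean
schedule), the off state displacing the mobile part several Å past the
relevant cutoff. Gaussian jitter (σ = 0.03 Å by default) is truncated
at 3σ per coordinate; the worst-case truncated pair displacement
(≈ 0.31 Å) is smaller than every on/off geometric margin (≥ 0.34 Å on
the tightest, the salt bridge), so jitter can never flip a
classification and the planted Bernoulli state is the exact ground
truth for what the detectors should see. Both nominal geometries are
additionally validated at build time by running the real detectors on
the isolated unit. One seeded NumPy generator drives states first,
then jitter, so identical specs are bit-identical.

The two-state generator (clustering test bed) alternates a rigid
8-atom ligand between two poses 5 Å apart over a static 16-Cα
scaffold, with unconditional Gaussian jitter (0.3 Å default) and iid
state draws at the given weights.

What the generators deliberately do **not** emulate: force-field
energetics, correlated dynamics (state draws are iid, real contacts
persist in runs), solvent density (only planted bridging waters
exist), conformational coupling between sites, and periodic images.
Passing tests therefore demonstrate that the *measurement* layer —
detection, counting, superposition, clustering — is exact and
well-calibrated on data whose truth is known by construction; they do
not validate any claim about real kinase–inhibitor dynamics.

## Numerical choices and problem sizes

* Distance thresholds are applied exactly as stated (strict `<` for
  hydrogen-bond/hydrophobic/water distances, `≤` for ionic and π),
  with no fuzz; criteria monotonicity (growing a cutoff never removes
  an event) holds by construction.
* Kabsch degeneracy is declared when the second singular value of the
  centred reference falls below 1e−8 of the first.
* The RMSD at the reference frame is set to exactly 0 when the
  measured selection is contained in the alignment selection.
* Frequency tables are exact rationals realized in floating point
  (count/n_frames); aggregation conserves the total event count as an
  integer identity.
* Validation and test workloads use 200 random ≤ 300-atom frames for
  detector–oracle equivalence, 1000-frame pockets for frequency
  recovery, 2000 × 100-atom frames for the RMSF closed form (the
  finite-size alignment bias of removing six rigid degrees of freedom
  from 300 coordinates is ≈ 1%, well inside the 5% check band), and
  ten 5000-frame two-state runs for clustering recovery.

## Known limitations

* No protonation, tautomer or pKa inference; formal charges come from
  templates (protein) and the user annotation (ligand).
* π detection ignores ring orientation; T-shaped and parallel
  arrangements at equal centroid distance are treated identically.
* Water bridges consider single-water relays only.
* PDB is the only trajectory format (by design: the analysis layer is
  engine-agnostic and multi-model PDB is the lingua franca); binary
  formats (DCD/XTC) are out of scope.
* Clustering recomputes the full pairwise matrix; for very long
  trajectories raise the stride accordingly.
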