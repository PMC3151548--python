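# Methods

This note records the models implemented, the conventions and defaults
chosen where the methods literature leaves latitude, what the synthetic
test conditions do and do not demonstrate, and known limitations.

## Elastic network model

The energy is the pairwise harmonic E = ½ Σ k_ij (d_ij − d⁰_ij)² with the
equilibrium distances d⁰ taken from the input structure (the model is
built at its own minimum).  The Hessian super-element for a spring with
unit direction u is k·uuᵀ on the diagonal blocks and −k·uuᵀ off-diagonal;
block rows therefore sum to zero (translational invariance), which the
tests assert to 1e-8.

* **Linear-cutoff model**: k = 1 inside the cutoff, k = 10 for
  sequence-adjacent beads.  "Adjacent" means consecutive `resid` within
  one `segid`, so chain breaks never receive the stiff constant.  The
  default cutoff is 12 Å and is user-settable; note that sparse toy
  chains need a cutoff generous enough to engage i,i+3 contacts or the
  network has internal floppy modes (more than six near-zero
  eigenvalues, which triggers a warning rather than an error).
* **Kovacs model**: k(d) = C·(3.8 Å/d)⁶ for every pair, with
  C = 40 kcal mol⁻¹ Å⁻² by default and 3.8 Å the canonical Cα–Cα
  virtual-bond length; the inverse-sixth-power decay makes a cutoff
  unnecessary.
* Near-zero modes are identified by |λ| < 1e-8·λ_max, the practical floor
  of a double-precision symmetric eigensolver.  Mass weighting
  (H → M^(−1/2) H M^(−1/2)) is off by default, the classic
  anisotropic-network convention.
* SPM: each residue's incident springs are stiffened by δk = 0.1 and the
  response is δω_im = ν_mᵀ δH ν_m, computed per spring in closed form as
  δk·((ν_i − ν_j)·û)² and accumulated on both endpoints.  Mode indices
  count internal modes from 0 = lowest nonzero frequency.
* β-factors carry the full 8π²/3·kT prefactor with k_B in
  kcal mol⁻¹ K⁻¹, so the output is in Å² and directly comparable with a
  PDB B-factor column; the β correlation is the Pearson coefficient and
  is scale- and offset-invariant by construction.
* Involvement coefficients are computed against raw displacements; a
  displacement with rigid-body content has CSO < 1 over the internal
  modes, which is informative rather than wrong.  Callers who want pure
  internal overlap should superpose conformers first.
* Mode correlations use the traced 3×3 blocks of the mode-restricted
  pseudo-inverse covariance, normalized to unit diagonal.

## Motion correlation

The covariance estimator uses population (1/F) normalization; the factor
cancels in DCC and keeps the LMI determinant ratios consistent.  No
superposition is applied before the covariance; an optional least-squares
fit of every frame to frame 1 exists but is off by default so raw and
fitted analyses stay explicit and distinct.

The LMI-to-[0,1] map is r = √(1 − exp(−2I/3)), the Gaussian-channel
relation for three-dimensional variables.  It reproduces 0 at independence
and 1 for a deterministic dependence (singular pair covariance), and is
isolated in one function (`lmi_from_information`) should a different
normalization ever be preferred.  A singular *marginal* covariance is an
error with a regularization hint, since it indicates motion confined to a
subspace rather than a correlation.

## Protein structure network

"Side chain" is defined by exclusion: every atom except backbone N, CA, C,
O (and OXT).  Glycine consequently has no side-chain atoms and can never
form edges — a known, documented property of the normalization-factor
construction, which treats ligand nodes (GTP, GDP, Mg²⁺, retinal) as whole
molecules with all their heavy atoms.  Hydrogens are excluded from pair
counts by default (switchable): contact statistics underlying the
normalization factors are heavy-atom based.

The amino-acid normalization factors are the published per-residue
contact-propensity values; the ligand factors (retinal 170.13, GDP 220.19,
GTP 274.78, Mg²⁺ 14.65 in GDP-state and 22.01 in GTP-state GTPases) are
stored verbatim and the Mg²⁺ choice is a parameter of
`default_nf_table(mg_state=...)`.

Neighbour exclusion i±n (n = 2 default) applies only within one chain;
inter-chain pairs are always eligible, since the exclusion models covalent
adjacency.  The hub threshold is *inclusive* (degree ≥ 4 by default) with
a strict (> 4) switch, reconciling the two conventions found in practice.
Hub correlation reports pairs that are **jointly** hubs in more than the
stability fraction of frames; a matching-state variant (indicators equal,
both-hub or both-not) is available behind a flag.

I_critic is obtained by linear interpolation of the largest-cluster curve
between the bracketing I_min grid points; when the curve never reaches
half its I_min = 0 value on the grid, the result is flagged as
"I_critic > max(grid)" instead of being extrapolated.

## Communication paths

Edges cost one hop, so Dijkstra reduces to BFS and "shortest" counts
nodes; all tied shortest paths are enumerated.  A strength-weighted mode
(cost = 1/I_ij) exists behind a flag and is marked as an extension.  A
path's frequency is the fraction of frames whose PSN contains every edge
of the path, with a path identified with its reversal; the candidate set
is the union over frames of per-frame shortest paths, so every reported
path is certified shortest in at least one frame.  Correlation is a
whole-trajectory statistic (DCC or LMI), not a per-frame one.  Two-node
paths have no interior residue and are dropped by the correlation filter
unless explicitly waived.

## Clustering

RMSD uses optimal (Kabsch) superposition by default; DRMS — the RMS
difference of intramolecular distance matrices — needs none and is exactly
rotation/translation invariant.  The QT-like threshold is a cluster
*radius* (all members within the threshold of the reference frame), ties
between equal-size candidate clusters break toward the lower reference
frame index for determinism.  Hierarchical clustering uses average
linkage (stated in every output header) since the linkage choice was
genuinely open; its result is frame-order independent, whereas the
leader algorithms are order-dependent by design and tested as such.  The
two-pass scheme treats frames beyond every first-pass center as new
centers that later frames can join.  The persisted distance matrix is a
plain-text header (metric, selection, superposition flag, frame count)
followed by the binary upper triangle; loading verifies the header against
the requested parameters and refuses silent misuse.

## Free-energy surface analysis

Transition counts are taken at a user lag on the raw label series; counts
are not symmetrized by default (a detailed-balance symmetrization flag
exists) because the cut-based profile is defined on sampled transitions.
The committor and MFPT are exact linear solves on the row-normalized
matrix; MFPT is reported in lag units and states that cannot reach the
target are flagged infinite.

The cFEP orders states by kinetic proximity to the reference (descending
committor or ascending MFPT), breaking ties by statistical weight then
state id, and places cuts only between distinct coordinate values.  The
progress coordinate is x = Z_A/Z from the state weights; the ordinate is
−ln(Z_AB/Z_T) in kT with Z_T the total sampled transition count — the
choice of Z_T fixes only the additive constant, so barrier heights and
locations are unaffected.

Commitment probabilities are measured from every occurrence of the start
state (sliding, overlapping windows), with the start frame included so
p(i→i) = 1; start frames closer than τ_commit to the trajectory end are
dropped so every window is complete.  KGA groups the heavy subset by the
transitive closure of max(p_ij, p_ji) ≥ 0.5 (a `mutual` flag requires both
directions), then assigns each remaining state to the basin it commits to
with probability ≥ 0.5, or leaves it unassigned.  The first-passage-time
histogram measures first-return times by default (starts at occurrences of
the target, or of an explicit start state); on two-well chains its log-log
form separates intra- from inter-basin timescales and brackets the valid
τ_commit range.

## Synthetic conditions and their scope

The generators define the test conditions:

* Toy polypeptides: 2–10 residues, compact helix (2.3 Å radius, 1.0 Å
  rise, 100°/residue) or 3.8 Å zig-zag, two side-chain pseudo-atoms per
  residue 1.4 Å apart with 0.05 Å seeded jitter.  The compact helix
  brings residues one turn apart into side-chain contact so
  interaction-strength thresholds near 3 % are exercised.
* Gaussian trajectories: frames drawn from a prescribed 3N×3N covariance
  about the structure; 4 000–20 000 frames where sampling tolerances of
  0.05 on correlations are asserted.
* Markov microstate series: block transition matrices with intra-well
  mixing 0.5 and inter-well escape 0.002–0.01 per step, 60 000–200 000
  steps; τ_commit = 100 sits inside the resulting timescale gap
  (intra-well relaxation of a few steps, inter-well escape of ~500).

These fixtures have known ground truth but are idealized: harmonic,
isotropic, memoryless, with no solvent, no anharmonic basins, and no
force-field detail.  Passing tests demonstrate algorithmic correctness
against closed forms, brute-force enumeration and Monte-Carlo simulation —
not that any particular biological system will show the same signal
strength.  Problem sizes (≤ 12 microstates for exhaustive cut
enumeration, ≤ 100 frames for clustering oracles, 10⁵ Monte-Carlo
walkers) were chosen so each oracle remains exact or statistically tight.

## Known limitations

* The selection grammar is a minimal reconstruction
  (`/SEGID/RESID/ATOM` with `*`, comma lists and `@(a–b)` ranges —
  both hyphen and en-dash accepted); boolean operators and distance-based
  selections are out of scope.
* DCD reading rejects fixed-atom files explicitly; XTC/TRR are not read.
* The PSN assumes the residue naming of standard amino acids for the
  backbone/side-chain split; exotic residues are treated as hetero nodes
  (all atoms) and need a user-supplied normalization factor.
* cFEP is the ranking approximation of the min-cut construction; the
  exhaustive-cut check is feasible (and performed) only on small state
  spaces.
* Hierarchical clustering materializes the full distance matrix; for very
  long trajectories use two-pass or leader clustering.
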