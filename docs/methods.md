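# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Pharmacophore model and matching

The model is a receptor-frame constellation of exactly four mandatory
features — three hydrophobic, one H-bond acceptor — each a sphere of
tolerance radius (default 1.5 Å, a common pharmacophore-tool default),
plus excluded-volume spheres marking receptor-occupied space. Feature
typing on the ligand side follows a fixed, documented rule set, since
commercial tools do not publish theirs:

* hydrophobic points: centroid of each aromatic ring; centroid of each
  maximal connected set of ≥ 3 sp³ carbons bonded only to C/H; halogen
  atoms on carbon;
* acceptor points: N or O with a lone pair and no positive formal charge,
  excluding amide and aniline nitrogens and pyrrole-type NH.

Aromaticity, hybridization and the acceptor SMARTS are evaluated by RDKit.

Matching is exhaustive over kind-compatible injective assignments of
ligand feature points to the four model features. Each assignment is
scored by a *single* least-squares rigid superposition (hand-written
Kabsch SVD, proper rotations only) of the four assigned points onto the
model centers; "matched" requires every assigned point within its
tolerance after that one fit — no per-feature refits — and no ligand heavy
atom strictly inside an excluded volume (hydrogens are ignored in the
clash test). Among valid assignments the smallest-residual one is
reported. Because the Kabsch optimum is invariant under proper rigid
transforms of the input, the match flag is frame-independent.

A subtlety worth recording: a single least-squares fit over four points
can partially absorb the displacement of one point by rotating the whole
constellation, so "one feature displaced by 2× tolerance" does **not** by
itself guarantee a non-match. The synthetic library generator therefore
*verifies* every decoy it builds (see below). The bundled fixture model
(`data/site_model.json`, also `synthdata.fixture_model()`) uses a
deliberately scalene feature constellation — permuting the hydrophobic
assignment forces a fitted deviation > 4 Å — so assignments are
unambiguous at the default tolerance. Its geometry is plausible for a
GPCR retinal pocket (feature separations 4.5–8 Å, acceptor 5.5 Å from the
nearest hydrophobic center, volumes ≥ 4.6 Å from every feature) but is
illustrative, not a reconstruction of any published hypothesis.

## Consensus docking

Poses arriving from different engines share the receptor frame, so pose
RMSD is computed **in place**, without re-superposition: superposing would
mask translational disagreement between engines, which is exactly the
signal consensus docking uses. RMSD is optionally (default on) minimized
over automorphisms of the element- and bond-order-colored bond graph,
enumerated with networkx's VF2 matcher and capped at 10 000 (beyond the
cap the identity mapping is used, with a warning). Symmetry correction can
only lower the RMSD, since the group contains the identity.

Complete-linkage agglomerative clustering is hand-implemented because the
cut semantics and tie-break are part of the method's contract: merging
continues while the smallest complete-linkage distance is strictly below
the threshold (default 2.0 Å), which guarantees every reported cluster's
diameter is below it; ties on the minimal linkage distance are broken by
the lexicographically smallest (min-member, min-member) index pair, making
the partition deterministic and independent of input order once poses are
canonically sorted by method id. The test suite cross-checks partitions
against `scipy.cluster.hierarchy` on random matrices (where continuous
entries make ties a measure-zero event).

The consensus pose is the medoid — minimum summed RMSD to co-members — of
the largest cluster; when several clusters tie for largest, the one
containing the smallest pose index supplies the medoid and the result is
flagged. In the hierarchical screen the stage-2 11×11 matrix reuses the
stage-1 6×6 block as a cache and computes only the new pairs; a ligand
passes stage 2 only at the maximum consensus level (all 11 poses in one
cluster), per the screen's design.

## MD stability filter

Two criteria, each contributing one point of the 0/1/2 score:

* **Geometry stability**: mean in-place heavy-atom RMSD of the ligand
  versus frame 0 (the post-minimization disposition) strictly below
  2.0 Å. No trajectory re-alignment is performed, because the target
  simulations restrain the protein α-carbons, fixing the receptor frame;
  an optional α-carbon superposition mode serves unrestrained inputs.
* **Interaction persistence**: the water bridge (ligand acceptor ↔ water
  oxygen and water oxygen ↔ Y191 hydroxyl oxygen, both legs simultaneously
  ≤ 3.5 Å; donor–H–acceptor angle ≥ 135° additionally enforced when water
  hydrogens are labeled) present in ≥ 0.5 of analyzed frames. The 3.5 Å /
  135° values are standard MD-analysis conventions; the 0.5 occupancy
  threshold quantifies "maintained" and is configurable, with the raw
  occupancy always reported alongside.

When frame times are provided, frames within the first 5 ns (heating +
equilibration) are excluded from analysis; otherwise all frames after
frame 0 are used. The bridging water is identified by label; an optional
per-frame reselection picks the candidate water minimizing the larger leg
distance, tolerating water exchange. Score boundaries are deliberate:
RMSD uses strict `<` (a mean of exactly 2.0 Å fails), occupancy uses `≥`.

## Spectral quantification

The difference spectrum (dark − light; offset grids are linearly
regridded onto the overlapping dark-grid support) is fitted with
A·exp(−(λ−μ)²/2σ²) by unweighted nonlinear least squares
(`scipy.optimize.least_squares`; a soft-L1 robust loss is exposed).
An optional constant baseline term exists but defaults to off — the
difference operation already removes shared baselines. Initialization:
μ₀ at the argmax, A₀ the maximum, σ₀ from the half-maximum width. Poor
data never raises: all-zero or all-NaN input, solver failure, or a
negative fitted amplitude (regeneration cannot be negative) yield a
non-converged result with zero amplitude; the AUC accessor refuses
non-converged fits.

AUC is the analytic area A·σ·√2π (baseline excluded), cross-checked in
tests against trapezoidal integration over ±6σ to < 0.1%. Replicate AUCs
are aggregated as arithmetic mean ± sample SD (n−1; zero for a single
replicate) after dividing by the control-condition mean, which pins the
control's normalized mean at exactly 1.

## Synthetic data: what is and is not emulated

All generators are deterministic per (spec, seed) and write the same
formats the pipeline reads (SDF, multi-frame XYZ + JSON role sidecar,
two-column CSV).

* **Pose sets** (`gen_pose_set`): a rigid fused-ring template ligand
  (benzotriazole-like bicyclic, 9 heavy atoms, one clear acceptor
  nitrogen, Kekulé bond orders so RDKit sanitizes it directly); k planted
  consensus poses are the template plus i.i.d. Gaussian coordinate jitter
  (default SD 0.3 Å, comfortably inside the 2.0 Å threshold), the rest
  are displaced along distinct axis-aligned multiples of the spacer
  (default 10 Å, mutually and jointly > spacer apart). Which methods form
  the cluster is randomized per seed. Not emulated: scoring-function
  correlations between engines, partial pose overlap, conformational
  flexibility.
* **Trajectories** (`gen_trajectory`): each frame translates the ligand
  rigidly so the per-frame RMSD equals the displacement length exactly;
  lengths are Gamma-distributed with mean equal to the target (relative
  SD 0.1). The displacement moves the acceptor on a fixed 4.5 Å shell
  around the static Y191 oxygen, decoupling RMSD magnitude from bridge
  feasibility; the water oxygen sits midway between acceptor and Y191-O
  on planted-occupied frames (Bernoulli per frame) and 10 Å away
  otherwise. Not emulated: internal ligand motion, water dynamics,
  protein fluctuations, autocorrelated frames — so occupancy recovery
  here says nothing about H-bond *kinetics* in real trajectories.
* **Assays** (`gen_assay`): dark spectrum = scattering-like exponential
  baseline + Gaussian band (default center 485 nm, isorhodopsin-like for
  a 9-cis-retinal pigment, since no λmax is prescribed; σ 30 nm; control
  amplitude 0.02 AU) scaled by the condition's suppression factor; light
  spectrum = the bleached baseline. The single noise knob `noise_sd`
  (default 0.07) is the replicate-level relative SD of the band
  amplitude — the quantity that reproduces a control table entry of
  1 ± 0.07 at small n — plus a small proportional per-point absorbance
  noise (noise_sd·A/3) on both spectra; `noise_sd = 0` yields exactly
  noiseless spectra. Not emulated: wavelength-dependent instrument noise,
  scattering drift between dark and light scans, multi-band overlap.
* **Libraries** (`gen_library`): matching ligands carry three benzene
  rings centered (jitter 0.1 Å) at the hydrophobic features and a
  carbonyl oxygen at the acceptor feature; decoys either displace the
  acceptor outward or plant a carbon inside an excluded volume, and the
  whole conformer is returned in a random rigid frame. Because a 4-point
  least-squares fit can absorb single-point displacements, every decoy's
  label is *certified* at generation: an exhaustive assignment check
  (scipy `Rotation.align_vectors`, a code path separate from the
  matcher) must show each assignment either overshooting a tolerance or
  burying an atom in a volume by ≥ 0.3 Å margin, resampling (and growing
  the displacement) until certified. Matching ligands are likewise
  verified to fit with ≥ 0.3 Å margin. Fragments are deliberately
  disconnected — the generator targets the matcher's geometry, not
  synthesizability.
* **Cohorts** (`gen_cohort`): per-ligand planted fates (fail
  pharmacophore 30%, fail stage 1 at level 3 25%, fail stage 2 20%, fail
  the MD filter 12%, pass 10%, pass-but-PAINS 3%) drive consistent inputs
  for every stage; PAINS-planted ligands carry a rhodanine-like fragment
  placed far from the pharmacophore so only the alert screen removes
  them.

Passing tests on these generators demonstrates that the decision logic
recovers planted truth under the stated statistical structure; it does
not validate docking accuracy, force-field quality or assay chemistry.

## Funnel orchestration

Stages run in order with per-ligand short-circuiting, so stage counts are
non-increasing and every excluded ligand's trail names exactly one
failing stage. Stage-1 pose sets are required for every pharmacophore
survivor and stage-2 extras for every stage-1 survivor (missing ones
raise, listing ligand ids); ligands lacking a trajectory are reported as
`md_filter:not_evaluated` rather than failed, mirroring campaigns where
MD is run only on consensus survivors. The report carries a SHA-256
config hash and a canonical JSON serialization of counts and trails
(sorted keys, sorted ligands, no timestamps) that is byte-identical
across repeated runs with the same config and inputs — the property the
determinism checks assert.

The bundled 10-pattern PAINS mini-catalog is a test/demo fixture of
representative interference motifs; production screens should point
`FunnelConfig.pains_catalog` at a complete published pattern file.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use problem sizes chosen to
make each statistical check decisive at desk scale: 1000 random matrices
for clustering-reference agreement, 500 seeded pose sets per planted
consensus size, 1000-frame trajectories for occupancy recovery (binomial
SE ≈ 0.015), 200 noisy spectra for fit-bias estimation, and a
200-ligand cohort for end-to-end determinism. The Table-structured assay
check uses 50 replicates per condition: at wet-lab n = 3 the
"mean within one pooled SD" event is dominated by the control-mean draw
(SD 4%) and is close to a coin flip by construction, whereas at n = 50 a
failure indicates estimator bias. All randomness in the acceptance script
derives from its `--seed` argument through `numpy.random.SeedSequence`.

## Known limitations

* Feature typing is rule-based and intentionally simple; tautomers,
  charged species and sulfur acceptors are out of scope.
* The matcher's exhaustive assignment search is exponential in feature
  points per kind; it is intended for drug-like molecules (a handful of
  features), not macromolecules.
* In-place RMSD assumes a shared receptor frame; poses from differently
  superposed receptors must be aligned upstream.
* The automorphism cap falls back to the identity for pathologically
  symmetric graphs, which can overestimate RMSD there.
* Gaussian fitting assumes a single band in the window; overlapping bands
  require deconvolution, which is out of scope.
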