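# Methods

This note documents the models and procedures implemented in `pentasite`,
the defaults and their rationale, the synthetic-data generators' contracts,
and known limitations.

## Hill concentration–response fitting

Peak currents are normalized per oocyte to that oocyte's maximal agonist
response, then fitted with

  I/Imax = A^nH / (A^nH + EC50^nH)

by nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective). Internally the model is parametrised in (log10 EC50, nH,
Imax) — the log-concentration parametrisation conditions the Jacobian far
better across the µM–mM range — but the curve evaluated is exactly the
equation above.

Defaults and rationale:

* **Start values:** EC50 = geometric mean of the tested concentrations,
  nH = 1, Imax = 1.
* **Bounds:** EC50 ∈ [min A/10, max A·10], nH ∈ [0.1, 10],
  Imax ∈ [0.8, 1.2]. Imax is left free rather than pinned at 1 because
  per-oocyte normalization divides by the *observed* maximum, which sits
  below the true asymptote whenever the top concentration is not fully
  saturating; a bounded free Imax absorbs that bias without letting the
  asymptote run away.
* **Convergence:** optimizer tolerances are set to machine level so that
  noiseless synthetic data are recovered to < 1e-6 relative error.
  Non-convergence is reported via a flag on the result, not an exception;
  flat (zero-spread) data raise, since no sigmoid is identified.
* **Pooled vs per-oocyte:** both modes exist. Pooled (default) fits all
  normalized points jointly; per-oocyte fits each oocyte and averages
  parameters (geometric mean for EC50). Published EC50 tables rarely state
  which was used; pooled is the better-conditioned default for 6–8 oocytes
  on a 10-point grid.

Ca²⁺ modulation profiles normalize each oocyte's amplitudes to its own
response at 1.8 mM Ca²⁺ (so the reference level is exactly 1 per oocyte)
and then average across oocytes (mean ± SEM). Specific radioligand binding
is total − nonspecific; negative differences are clipped to zero and
flagged rather than silently propagated.

## Double-mutant cycle energetics

EC50 ratios are used as free-energy proxies exactly as is conventional for
cycle analysis on channel concentration–response data; no attempt is made
to separate binding from gating contributions. With
R = 0.0019872 kcal/(mol·K):

* per-mutant ΔΔG = −RT ln(EC50_mut / EC50_wt)
* Ω = (EC50_WR · EC50_TM)/(EC50_WM · EC50_TR)
* coupling energy ΔΔG_int = −RT ln Ω

**Temperature default: T = 294 K** (~21 °C, a typical oocyte-rig room
temperature). At this temperature the conversion reproduces standard
published cycle energetics from µM-scale EC50 tables to two decimals; T is
a config field on `EnergyParams` for other conventions. The identity
ΔΔG_int ≡ ΔΔG_TM − (ΔΔG_TR + ΔΔG_WM) holds algebraically and is asserted
to 1e-9 in the result type. Error propagation from EC50 standard errors
into Ω confidence intervals is out of scope.

## Pose orientation classification

A docked pose is **favorable** when its cationic nitrogen makes at least
*k* cation-π contacts (default k = 1) with the conserved pocket aromatic
set, addressed by Torpedo α1 numbers {55, 93, 149, 190}. A cation-π
contact requires:

* N → ring-centroid distance ≤ 6.0 Å, and
* angle between the ring normal and the centroid→N vector ≤ 60°
  (folded to [0°, 90°], since the normal's sign is arbitrary).

These thresholds follow common practice in protein–ligand contact
analysis; they are not uniquely dictated by any one dataset and are fully
config-exposed (`GeomConfig`). The angle is computed with the atan2 form
(‖n×v‖, |n·v|), which is well-conditioned near 0° where the acos form
loses ~half the significant digits. Ring planes come from an SVD plane fit
to the ring heavy atoms: for Trp the benzene six-ring of the indole, for
Tyr/Phe the phenyl ring; His is off by default. Whether "correctly
oriented" should require more than one aromatic contact is genuinely open;
k is therefore a parameter, with k = 1 the permissive default.

Hydrogen bonds (ligand ester/carbonyl oxygens vs protein polar side-chain
heavy atoms, ≤ 3.5 Å; D–H⋯A ≥ 120° when explicit hydrogens exist) are
detected and reported as evidence but never enter the favorable verdict.

**Clustering** is greedy and energy-ordered at a 2.0 Å RMSD cutoff: the
lowest-energy unassigned pose seeds a cluster and absorbs every pose
within the cutoff; ties break on pose id for determinism. RMSD is computed
without superposition because docked poses already share the receptor
frame — the docking-tool convention. Symmetry-equivalent atom handling is
off by default.

**Interface summaries:** BBE = minimum binding energy over all parsed
poses; favorable frequency = 100 × favorable/total with all parsed poses
as the denominator (an ensemble could alternatively be summarized per
post-clustering representative; the all-poses denominator is the
documented default). Replicate summaries average with mean ± SEM.

Flexible-receptor docking output (per-pose side-chain coordinates for
residues set flexible during the search) is honoured when present in the
pose record; otherwise the static model's side chains are used.

## Charge profiling

* **Pocket membership** (default radius 5 Å): a residue belongs to the
  pocket when any of its heavy atoms is within the radius of any ligand
  heavy atom — minimum heavy-atom distance, no centroids. Face annotation
  (principal/complementary) follows the interface's chain roles, not
  geometry.
* **Radial charge profile** (default radius 10 Å): charged groups are
  represented by single points chosen for stability to hydrogen absence —
  Arg CZ, Lys NZ, Asp/Glu carboxylate-oxygen midpoint — and listed with
  sign, face and distance from the ligand's cationic nitrogen, ascending.
* **Sequence balance:** acidic = D+E, basic = R+K, balance = basic −
  acidic. Histidine is deliberately excluded: the whole-domain bookkeeping
  this mirrors counts only R/K vs D/E. Reproducing any particular
  published domain count requires that study's exact sequence window,
  which is an input, not a package constant.

## Interface enumeration and numbering

A pentamer arrangement is an ordered ring of five subunit labels; under
the default `forward` orientation the principal face of subunit *i* pairs
with the complementary face of subunit *i+1* (ring-wrapped), `reverse`
flips the ring sense. The circular order of subunits in an
(α9)₂(α10)₃ receptor is not experimentally fixed, so the arrangement is an
explicit input; the default α9,α9,α10,α10,α10 is the arrangement class
that realizes all four interface types (α9(+)α9(−), α9(+)α10(−),
α10(+)α10(−), α10(+)α9(−)) in one pentamer.

Analysis-level residue identities (W55, Y93, W149, Y190, R117, D119,
Y197 …) are always addressed through the mature Torpedo α1 numbering.
Maps from author numbering are built from a pairwise alignment of the
chain's sequence against the Torpedo reference (any FASTA/Clustal
alignment Biopython can read); aligned non-gap columns contribute entries,
gaps contribute none, and a sequence mismatch against the chain is an
error naming the first discrepancy. The CLI treats author numbers as
Torpedo numbers by default, since docking models in this field are
conventionally pre-renumbered.

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested.

* **Dose–response** (`gen_dose_response`): response(A) =
  Imax·A^nH/(A^nH+EC50^nH)·exp(ε), ε ~ N(0, σ²) i.i.d. Noise is
  multiplicative log-normal because currents are positive and their spread
  grows with amplitude. Defaults: EC50 18 µM, nH 1.2 (published tables of
  this receptor family print EC50s but not Hill coefficients; 1.2 is a
  typical heteromeric-receptor slope), σ = 0.1 — which makes fitted-EC50
  spread comparable to the SEM-to-mean ratios of published tables — six
  oocytes, and a 10-point log-equidistant grid from 1 µM to 3 mM spanning
  the implied recording range.
* **Toy pentamer** (`gen_toy_pentamer`): five pseudo-subunit chains on a
  30 Å ring plus a compact acetylcholine-like ligand at the A/B interface.
  Planted residues are realized with correct side-chain atom names at
  *exactly* the specified distances/angles (ring centroids on the stated
  axis, charged representative points at the stated radii, H-bond partner
  atoms at the stated separation from the ligand ester oxygen). Directions
  are assigned deterministically from a golden-section spiral, skipping
  directions that would clash with the ligand or earlier plants; an
  unplaceable plant raises. The default roster puts the four aromatics at
  4.2–4.8 Å, Y197 at 3.1 Å from the ester oxygen, and a charged set whose
  radial ordering within 10 Å is D119 < R57 < R79 < D169 < D199 with R117
  at 8.7 Å and E59 at 10.5 Å (i.e. just outside the default profile) —
  the qualitative template of a mammalian α10-like complementary face. No
  structural realism is attempted or needed: the toy's only contract is
  exact known geometry.
* **Pose ensembles** (`gen_pose_ensemble`): exactly
  ⌊n·fraction⌋ poses place the cationic N 4–5 Å along a pocket-aromatic
  ring axis (axial angle 0, unambiguously inside the cation-π criterion);
  the rest are placed ≥ 7 Å from every ring centroid (unambiguously
  outside). Energies are drawn N(−5.5, 0.4²) kcal/mol for favorable and
  N(−3.5, 0.4²) for unfavorable poses, so the ensemble minimum comes from
  the favorable subpopulation with overwhelming probability at n = 200 —
  the regime in which a poorly binding interface distinguishes itself by
  frequency and BBE.

All generators are pure functions of (config, seed); planted truth is
returned beside each dataset for test consumption only.

What passing these tests does **not** show: real docking ensembles contain
borderline orientations near the geometric cutoffs, correlated noise
across concentrations within an oocyte, receptor flexibility, and homology
-model coordinate error. Absolute published docking energies and
model-derived distances therefore have no desk oracle here; the package
verifies the *procedures* (classification, clustering, summarization,
profiling) against exact planted truth instead.

## Numerical choices and degenerate inputs

* Distances/angles in Å and degrees; concentrations in molar internally
  (the CLI accepts µM/mM suffixes); energies in kcal/mol.
* Deterministic tie-breaks everywhere: pose id lexical order in clustering,
  file order for poses, ascending distance in profiles.
* Degenerate inputs raise early with specific messages: empty PDB, a
  malformed ATOM record (named by line), fewer than four distinct
  concentrations, flat responses, empty ensembles, non-positive EC50s,
  arrangement length ≠ 5, pose atom-count mismatches.
* Geometric detectors are invariant under joint rigid motion of model and
  pose to ≤ 1e-6 (asserted over 100 random transforms in the suite).

## Problem sizes used in the shipped checks

The suite's stochastic checks use 200 simulated experiments for noisy
Hill-fit recovery (6 oocytes, σ = 0.1), 200-pose ensembles across planted
fractions {0, 0.02, 0.3, 1}, 50 random 10-pose ensembles against the
brute-force clustering oracle, 100 random rigid transforms for invariance,
and 1,000 random sequences for charge accounting — sizes at which the
checked statistics are stable while the whole suite stays fast.

## Known limitations

* No continuum electrostatics, pKa prediction, or protonation assignment;
  charge signs are residue-type lookups.
* No docking search, scoring, or energy minimization — docking outputs are
  parsed and post-analyzed, never produced.
* No error propagation from EC50 uncertainty into Ω.
* The PDB writer emits minimal records (no occupancy/B-factor semantics,
  no CONECT); coordinates round-trip to 3 decimals.
* Histidine cation-π donors and symmetry-equivalent RMSD atom mapping are
  off by default (config-exposed where supported).
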