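# Methods

This note records the models implemented in `ifd`, the defaults and their
rationale, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Interface contacts and survival statistics

A hydrogen bond between the two partners is declared in a frame when the
donor–acceptor heavy-atom distance is strictly below 3.5 Å and the bond
angle is strictly below 30°.  Two angle conventions exist in trajectory
tooling and the criterion alone does not disambiguate them, so both are
implemented: the default measures the donor-centered angle between the
D–H bond vector and the D→A vector (0° = perfectly aligned); the
alternative (`angle_convention="h_centered"`) measures the deviation from
linearity at the hydrogen, 180° − ∠(D–H–A).  For near-linear bonds the two
agree; the default matches the common convention of per-frame H-bond
counting tools.  Donors and acceptors come from a built-in N/O table
(backbone N except proline, backbone O/OXT, standard side-chain N/O
groups); sulfur is excluded because every reported interfacial pair in
this system is N/O-mediated.  Hydrogens are attached to the nearest heavy
atom of the same residue within 1.2 Å of the topology coordinates.  When a
structure carries no hydrogens at all, detection errors out with a pointer
to distance-only mode (`require_hydrogen=False`), which applies only the
distance gate — appropriate for crystal structures.

A salt bridge is declared per residue pair when the minimum distance over
acidic-oxygen × basic-nitrogen atom pairs (Asp OD1/OD2, Glu OE1/OE2 ×
Arg NE/NH1/NH2, Lys NZ) is strictly below 4 Å.  Histidine is excluded by
default — the reported bridges in this system are all D/E × R/K — but can
be included per criteria object.

Detections are aggregated at the residue-pair level by a union rule: any
qualifying atom-level contact marks the pair present in that frame.  The
survival rate of a pair over a run is the percentage of frames in which it
is present.  Across runs (three independent equilibrium simulations in the
reference design) the table reports the arithmetic mean and
SEM = s/√n with the n−1 sample standard deviation; a pair absent from a
run contributes an explicit 0.0%, matching how such tables are printed.
Filters use strict inequalities (mean > threshold); ties sort by first-run
survival, then residue number.

One published hydrogen-bond table contains two rows with the same
residue-pair labels (Q1367–V1546) and different run values — presumably
distinct atom-level contacts of the same pair.  Survival tables therefore
key rows by a unique row identity (a `#2` suffix on the duplicate), and
heat-map cells sum rows that share residue labels rather than silently
dropping one.

The per-frame H-bond count distribution is fitted with a Gaussian
A·exp(−(x−μ)²/2σ²) by nonlinear least squares on unit-width integer bins
(counts are integers, so unit bins are the natural choice).  An all-equal
count series is rejected with a sigma-floor error rather than fitted.

## Geometry

Superposition is Kabsch via SVD with the sign correction that forbids
reflections (det R = +1); collinear point sets are rejected as degenerate.
Per-frame Cα-RMSD superposes each frame's selected Cα set onto the
reference frame and is exactly zero there.

SASA uses the Shrake–Rupley construction with a deterministic
golden-section spiral of 960 test points per atom (reproducibility over
Monte-Carlo point sets) and probe radius 1.4 Å.  Van der Waals radii come
from a built-in element table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80 Å — Bondi-style values; configurable per call).  Hydrogens are
included when present; hydrogen-free PDB inputs work unchanged.  Buried
interface area is SASA(A) + SASA(B) − SASA(AB), exactly symmetric in the
two partners by construction.  The implementation is validated against
closed-form single-sphere and two-sphere spherical-cap areas (within 1% at
960 points) and cross-checked against an independent Shrake–Rupley
implementation on the same radii.

## Pose screening

The biological screen — "A2 must occlude the GPIbα-binding site on A1" —
is qualitative in its original form (visual inspection).  It is
operationalized here as a quantitative filter: the footprint is the set of
receptor residues with any heavy atom within 4.5 Å of a ligand heavy atom
in the reference complex; a candidate pose's receptor is superposed onto
the reference receptor over Cα atoms shared by author residue number, the
transform is applied to the blocker, and the covered fraction is the share
of footprint residues within 4.5 Å of the transformed blocker.  The
defaults (cutoff 4.5 Å, minimum covered fraction 0.5) are declared
choices, both configurable; the statistic itself is this package's
operationalization, not a published definition.  Survivors rank by
external docking score when supplied (lower is better), otherwise by
covered fraction, with pose-name tie-breaks for determinism.

## Pulling curves

The steered-pulling model is a virtual spring F = k(vt − x) with defaults
k = 69.48 pN/Å and v = 5 Å/ns over a 25 ns pull, the reference setup for
this system.  Dissociation time is the earliest instant from which the
interface H-bond count is zero *and* buried SASA is below 1 Å², sustained
to the end of the trace — the sustained-zero rule guards against transient
zero crossings, which a bare "decreased to zero" reading would not.
Rupture force is the maximum of the (optionally moving-average smoothed)
force at or before dissociation, first occurrence on ties.  Smoothing
defaults to off (window 1) since the reference analysis does not mention
filtering; both raw and smoothed modes are exposed.  The published
dissociation times carry a seconds label but belong to a 25 ns pull; the
package treats them as nanoseconds (unit typo) and fixes ns/pN/Å² in all
file headers to prevent unit drift.

## Binding kinetics

Sensorgrams follow the closed-form 1:1 Langmuir model: association
R(t) = Req(1 − e^(−kobs t)) with kobs = kon·C + koff and
Req = Rmax·C/(C + KD); dissociation decays mono-exponentially with koff.
The baseline is assumed pre-subtracted.  The global fit shares kon, koff
and Rmax across all concentration curves (single site, uniform loading); a
per-curve-Rmax option exists but is off by default.  Because Langmuir fits
are initialization-sensitive, a 3×3 multi-start grid (kon ∈ {10³, 10⁴,
10⁵} M⁻¹s⁻¹ × koff ∈ {10⁻³, 10⁻², 10⁻¹} s⁻¹, Rmax from the maximum
observed response) is run and the lowest-RSS converged solution kept.
KD = koff/kon holds exactly in the returned fit.

The printed wild-type KD (2.16 μM) differs slightly from koff/kon of the
printed rates (2.176 μM), and the A1-mutant value similarly (6.1 vs
6.23 μM) — display rounding.  The package reports full precision and does
not attempt to reproduce the rounded values.

## Synthetic generators and what passing tests mean

The generators emulate the *statistical* structure of each input class at
the study's stated design, not the underlying physics:

- Trajectories toggle planted contacts by displacing the acceptor-side
  group 6 Å along the pair axis (beyond every cutoff) according to
  Bernoulli or two-state Markov occupancy laws; no dynamics is integrated.
  Default site spacing (20 Å) keeps sites independent at all cutoffs.
- Pulling curves ramp linearly to the planted rupture force, then collapse
  exponentially (τ = 0.25 ns); contact annotations reach exactly zero at
  the planted dissociation time.  Real pulls show multiple load–release
  events before rupture; the generator plants a single peak because the
  estimators under test depend only on peak location and the joint-zero
  instant.
- Sensorgram sets use the published schedule (125–4000 nM, 60 s/120 s) at
  0.2 s sampling with additive Gaussian noise.
- AFM cycle sets use Bernoulli adhesion at the published design
  (3 substrates × 5 points × 100 cycles) with Gaussian rupture forces,
  defaults p = 0.191 and N(42.2, 8²) pN.  The 8 pN spread is a typical
  single-bond width at this force scale (the source reports only means,
  SEMs and fitted peak centers).  Real rupture-force histograms are often
  right-skewed, which is why the most probable force X_C can sit below the
  mean; a Gaussian generator cannot reproduce that skew, so recovery tests
  demonstrate estimator correctness, not distribution realism.

Every generator is seed-deterministic (byte-identical outputs) and ships a
truth manifest; recovery tests compare against manifests, never against
re-hardcoded numbers.  Trajectory-scale published quantities (e.g. a
358.7 ± 30.8 pN rupture force from all-atom pulls) are not recomputable
without the original trajectories; they enter only as generator presets,
and the acceptance checks are property-based (recovery within sampling
bounds) at desk-scale problem sizes: 100–3000 frames per trajectory, 2501
samples per pulling curve, ~900 points per sensorgram, 1500 cycles per AFM
data set — sizes chosen so the whole suite runs in seconds while keeping
binomial/CLT bounds tight enough to be meaningful.

## Known limitations

- PDB only (single- and multi-MODEL); no DCD/XTC trajectory formats.
- No insertion-code support (none occur in the VWF A domains); altloc
  handling keeps the highest-occupancy conformer.
- No π-stacking, cation–π or hydrophobic contact detection; no force-field
  energies; no docking or HADDOCK score recomputation; no worm-like-chain
  or loading-rate (Bell–Evans) analysis; no mass-transport or bivalent
  kinetic models; no significance testing between groups.
- The SASA tool and its probe/point parameters used for the original
  trajectory numbers are unstated upstream; the defaults here (1.4 Å, 960
  points) are declared, not inferred, so absolute buried-SASA values are
  comparable within this package but not necessarily across tools.
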