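# Methods

This note documents the models, rules and numerical choices behind
`dyesorb`: what each stage computes, the parameters that matter and their
defaults, what the synthetic generator does and does not emulate, and the
known limitations.

## Geometry primitives

All analyses reduce a trajectory (frames × particles, Å, ns) to a handful of
per-frame scalars.

* **Center of mass.** Mass-weighted mean of a named selection.
* **Surface distance.** The nanoparticle is modelled as a sphere:
  `d = |COM_dye − COM_np| − R`. `R` defaults to half the nominal diameter
  (20 or 10 Å); an *empirical* mode instead takes the 95th percentile of the
  member radial distances in the first frame, because the heavy-atom
  diameter of a small crystal particle can deviate slightly from its nominal
  value. The nominal mode is the default for reproducibility. `d` may be
  negative when the dye COM dips inside the nominal sphere; this is expected
  near a non-spherical surface and is handled by every consumer.
* **Core plane.** The xanthene core is planar; its orientation is the
  eigenvector of the smallest principal second moment of the centered,
  unweighted core coordinates. Collinear or <3-point selections are
  rejected. When a radial reference direction is supplied the sign is fixed
  to a non-negative dot product with it. The *parallelism angle* between the
  core normal and the radial direction is folded to [0°, 90°]: 0° means the
  core lies flat on the local surface.
* **Dipoles.** `Σ qᵢ(rᵢ − ref)` in e·Å (1 e·Å = 4.8032 D). For net-charged
  selections the dipole depends on the reference point through the exact
  identity `D(ref + t) = D(ref) − q_net·t`; the default reference is the
  selection's own COM, which keeps dipoles of different bodies comparable
  and deliberately excludes the mobile counterion layer from the
  measurement. The angle θ between dye and particle dipoles is reported per
  adsorption segment (mean) as a corroborating observable; it is *never* a
  classification criterion, because in a crowded ionic environment θ
  fluctuates far from the ideal antiparallel 180°.

## Adsorption-state classification

A dye is *near the surface* while `d ≤ adsorption_threshold` (default 5 Å).
Maximal near-surface runs are extracted per dye–particle pair; excursions
shorter than `gap_tolerance` (default 0.2 ns) are merged, since a single
frame above threshold does not end a physical adsorption episode at thermal
noise. Each episode is labelled from its duration and its *parallel
fraction* — the fraction of episode frames with parallelism angle ≤
`parallel_tolerance` (default 30°):

| label | rule | reading |
| --- | --- | --- |
| A | duration ≥ `min_A_duration` (5 ns) **and** parallel fraction ≥ 0.8 | stable adsorption, core flat on the surface |
| T | parallel fraction < 0.2 | electrostatic trapping without adsorption geometry; typically ≤ 2 ns, longer ones keep the label but carry a `long_T` flag |
| R/A | otherwise | repositioning/reorientation near the surface |

The 30° tolerance and the 5 ns divider are package choices: the source
analyses describe "parallel" and "short" qualitatively; 30° separates flat
from tilted poses while tolerating thermal wobble, and 5 ns cleanly divides
the long-lived stable episodes from the "multiple and relatively short"
reorientation contacts. Both are configurable.

Per-run summaries report the percentage of the trajectory during which at
least one dye is in a counted state. The counted set defaults to **{A, R/A}**
because published per-repetition values include systems in which only R/A
episodes occur, so A-only counting could not reproduce them. Overlapping
segments of different dyes are counted once (union measure). Repetition
averages are rounded **half-up** to integers — the convention required to
reproduce printed averages like 23 from a mean of 22.5 and 33 from 32.5.
Two published column averages (the 20 Å-cristobalite systems) are *not* the
arithmetic means of their printed repetitions; the package does not force
agreement there, and its own averaging is the documented half-up mean.

## Dimers and trimers

Two dyes are in *stacking contact* while their core COMs are within
`core_distance_cutoff` (6 Å) and their core-plane normals are parallel or
antiparallel within `stacking_tolerance` (30°) — the geometry of
face-to-face π-stacked cores with tails protruding. Plane normals, not
dipole angles, carry the stacking test: the dimer geometry is defined by the
cores facing each other, and the plane fit is the directly measurable proxy.

Per frame, a dye may belong to at most one dimer; conflicting candidate
contacts are resolved greedily by ascending core distance. Contact flickers
shorter than `gap_tolerance` (0.2 ns, same value as the state classifier's)
are merged, and runs shorter than `min_dimer_duration` (1 ns) are dropped.
A third dye in stacking contact with either member of a live dimer defines a
*transient trimer* interval; trimers are flagged, never promoted to stable
species.

Events are classified by **location** — `matrix` when the median pair-COM
surface distance during the event is within `matrix_threshold` (5 Å), else
`solute` — and by **end reason** with precedence:

1. `censored`: the event reaches the final frame;
2. `desorption`: the intact pair's surface distance rises from within the
   matrix threshold to beyond twice it before the contact breaks;
3. `dissociation`: the contact breaks. The canonical signature is a break
   within `matrix_threshold + 5 Å` of a surface followed by one partner
   entering A/R-A within 1 ns; a pair separating far from any surface is
   also recorded as a dissociation, since the contact did break.

The 1 ns window and the 2× factor are package-defined operationalizations
of behaviour the source material narrates visually. Per-system statistics:
⟨Dimer⟩ = mean events per run, ⟨T⟩ = mean summed event time per run,
⟨T_PerDimer⟩ = mean of the pooled individual lifetimes. Note the published
reference statistics of this form are mutually inconsistent
(⟨T⟩/⟨Dimer⟩ ≠ ⟨T_PerDimer⟩), so they serve as a format reference only.

## Pulling energetics

A constant-velocity spring (stiffness `k` in pN/Å; 1 kcal mol⁻¹ Å⁻¹ =
69.477 pN·Å, so the canonical 4 kcal mol⁻¹ Å⁻¹ ≈ 278 pN/Å) produces a
sawtooth force trace. Detection: a centred moving average (default window
50 ps) smooths the force; the noise scale is 1.4826 × the median absolute
deviation of the detrended trace (robust to the sawtooth outliers); local
maxima at least one window apart, paired with the following minimum, become
transitions when the drop exceeds `drop_threshold` (3) × noise **and** the
displacement grows by at least `dF/k` across the drop (with a 0.8 slack
factor absorbing smoothing blur). Amplitudes are read from a short-window
(w/10; raw samples for noise-free traces) smooth at the located extrema.

Each transition releases spring energy

    dE = ((F₀ + dF)² − F₀²) / (2k),   1 pN·Å = 6.2415·10⁻⁴ eV,

with F₀ the force at the end of the transition. The source text names F₀
"the force at the end of the transition" but does not print the formula's
algebraic form; this implementation uses the spring-energy difference across
the drop, which is consistent with those symbol roles, and exposes the
alternative "F₀ at the peak" reading behind the `f0_convention` switch
(`transition_energy(..., f0_convention="peak")`, algebraically
`(F₀² − (F₀−dF)²)/(2k)`). The binding-energy estimate is ΔE = Σ dE, invariant
under transition reordering.

The published desorption/dissociation energies (∼1.08, ∼0.36, ∼0.27 eV)
require the original pulling trajectories and are not reproducible here;
the estimator is instead validated against generator traces of known total
well depth (see below).

## The synthetic generator

The generator fabricates inputs with known ground truth; it emulates the
*statistical shape* of dye/nanoparticle trajectories, not their physics.

**Rigid bodies.** Each dye is a rigid 64-site body (30-site coplanar core,
tail along +x, total charge +1e) so the geometry operators run on realistic
group sizes; internal flexibility is omitted. Nanoparticles are fixed
spheres of surface sites with a slight charge gradient (a nonzero dipole for
θ measurements). Orientations are unit quaternions.

**Scripted mode** replays user-specified state and dimer intervals exactly
and noise-free: A places the dye at 2 Å with the core flat; T at 3 Å with
the core tilted 70°; R/A oscillates the distance within the threshold with
the core parallel in exactly half the frames; dimers place two cores
face-to-face at 4 Å, in solution or on the surface, with desorption and
member-exchange variants. Interval boundaries should lie on the frame grid.
Optional Gaussian measurement noise (σ per coordinate) is added to the
emitted sites. Members of a scripted *matrix* dimer are near the surface
with cores perpendicular to it, which the classifier correctly sees as T;
the ground-truth states account for this.

**Emergent mode** integrates overdamped Langevin dynamics: translational
noise √(2 D_t δt), rotational noise as small random rotations of √(2 D_r δt)
per axis, a screened radial attraction `(A/λ)·e^(−d/λ)` toward each
particle, a short-range adsorption well engaged only while the core normal
is inside the orientation gate (30°) of the radial direction, a pairwise
face-to-face stacking well, and excluded-volume walls. Defaults are
Stokes–Einstein estimates for a ~5 Å dye in water at 300 K: D_t = 40 Å²/ns,
D_r = 1 rad²/ns, with a 0.01 ns frame interval (10⁴ frames per 100 ns run)
and Debye length 10 Å.

Numerical choices: the dynamics integrate with `substeps` (default 5)
substeps per emitted frame, and the total deterministic force per dye is
capped at 4 kT/Å — a regularized force field whose capped wells still
integrate to multi-kT effective depths. A deterministic displacement
exceeding 0.5 Å per substep raises an "unstable timestep" error. The
capture *torques* use a wide 90° cosine ramp (a misoriented dye can be
steered into the gate), while the gates and all analysis thresholds keep
their 30° definitions; gate functions are smooth cosine ramps to avoid
force discontinuities. Ground truth in emergent mode is obtained by
applying the episode rules to the exact latent (noise-free) distance and
orientation series, i.e. before site emission and measurement noise.

**Pulling traces** are quasi-static (appropriate for the slow 0.01 Å/ps
regime): the pulled compound stays pinned at each well while the force
ramps at slope k·v; at the rupture force √(2k·E_i) it relaxes to the
cantilever position, so each sawtooth releases exactly the scripted well
depth E_i and the ground-truth total is Σ E_i by construction. Gaussian
noise is added to the force channel. Well spacings must exceed the rupture
stretch F_i/k (otherwise "overlapping wells").

**What passing tests show.** Exact scripted recovery and ≥95 % frame
agreement at σ = 0.5 Å show the classifier implements its rules correctly
and tolerates realistic positional noise; they do not show that the rules
reproduce hand-labelled states of real force-field trajectories. The
free-dye MSD check (6·D_t·τ within 10 %) validates the integrator's noise
calibration; the 20-seed pulling sweep (ΔE within 15 % of truth) validates
the estimator against the generator's idealized sawtooth, not against
thermally activated rupture. Absolute adsorption percentages and dimer
counts of the real systems depend on the force field and are out of reach
by construction.

## Composition bookkeeping

Ionization fractions are tabulated: 13.3 % at pH 7, 30 % at pH 12; other pH
values are rejected rather than interpolated. Surface densities divide
counts by the nominal sphere area π·d² (sizes normalized to 40/20 Å for
comparability). The particle charge is −round(n_silanol × ionization
fraction); neutralization requires one Cl⁻ per dye charge and |charge| Na⁺
per particle, and declared counts are validated, never silently corrected.
Silanol counts for the eight reference systems are not published and are
back-computed from the Na⁺ counts (`round(n_Na/f)`), which round-trips
exactly for all eight; they are labelled synthetic. Two published rows
carry water-atom counts that are not multiples of three relative to their
printed molecule counts; the atom count is authoritative for totals, so
`validate_spec` reports (rather than rejects) the inconsistency, and all
eight printed totals are reproduced exactly from their components.

## Known limitations

* Spherical-surface approximation everywhere; no periodic-image minimum
  distance handling (the source systems showed no image interactions).
* The classifier works on instantaneous frames; heavily undersampled or
  extremely noisy series may need a larger `gap_tolerance`.
* End-reason rules are threshold operationalizations of visually narrated
  behaviour; borderline events near the 2× / 1 ns boundaries are sensitive
  to those choices.
* The emergent simulator is a calibrated toy: no explicit ions or water, no
  dipole-exclusion effect limiting adsorption to one dye per particle, and
  its absolute rates carry no force-field meaning.
* Binary MD trajectory formats are not read natively; convert to the
  trajectory-table TSV first.
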