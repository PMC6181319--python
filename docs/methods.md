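# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices behind the fits, what the synthetic data do
and do not emulate, and the design decisions taken where the underlying
workflow left the choice open.

## Single-site ITC

The forward model is the standard one-site, identical-sites isotherm for
a perfusion cell. After injection *i* (cumulative volume *v*, cell volume
*V₀* = 1.4 mL), total concentrations are corrected for the liquid pushed
out of the active volume,

    M_t = M₀ (1 − v/2V₀)/(1 + v/2V₀),   X_t = X_s (v/V₀)/(1 + v/2V₀),

the fractional saturation Θ is the closed-form root of the binding
quadratic, the cumulative heat is Q = N·Θ·M_t·V₀·ΔH, and the observable
per-injection heat adds back half the heat of the displaced liquid,
q_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2. This is the convention
used by the classic instrument analysis software, so parameters fitted
here are directly comparable to published single-site tables.

Fitting minimises Σ(q_model − q_obs)² with `scipy.optimize.least_squares`
over (N, log₁₀K_D, ΔH), bounds N ∈ [0.05, 20], log₁₀K_D ∈ [−12, −1],
|ΔH| ≤ 100 kcal/mol. K_D is optimised in log space for conditioning and
the fit is multi-started from five log-spaced K_D guesses (10⁻⁸–10⁻⁴ M),
keeping the lowest-cost solution. ΔH is initialised from the first
injection's heat per mole injected. With `fix_n=True` the stoichiometry
is pinned to 1 — the convention for weak binders whose shallow isotherms
cannot determine N; the tool never fixes N silently, but emits a warning
whenever the fitted c-value N·M₀/K_D drops below 1. All-zero heats and
schedules under six injections are rejected as degenerate.

Derived quantities use ΔG = RT ln K_D with R = 1.9872×10⁻³ kcal/(mol·K)
and T = 298.15 K for "298 K" experiments; this pairing reproduces every
ΔG in the packaged reference table at one-decimal rounding. −TΔS is
defined as ΔG − ΔH, so the additivity identity holds at machine
precision by construction, and the enthalpic efficiency is 100·ΔH/ΔG
(undefined at K_D = 1 M, where ΔG = 0). Buffer-ionisation corrections
are not applied. Dilution heats are removed injection-by-injection when
a blank titration is supplied; without one, the mean of the final three
(post-saturation) injections serves as a constant-dilution estimate.

ΔC_p is the OLS slope of ΔH versus T (288–303 K in 5 K steps in the
emulated design), converted to cal/(mol·K). The regression also reports
its Pearson r and intercept.

## Displacement ITC

The two-ligand competitive equilibrium
M_f(1 + [A]_f/K_A + [B]_f/K_B) = M_t, with each free-ligand
concentration the exact consequence of its own mass balance, is solved
by bisection on M_f. The bracketing function is strictly increasing, so
the solver cannot fail for valid inputs; iteration continues to
floating-point convergence because a loose interval on M_f is amplified
into the bound concentrations when one K_D is orders of magnitude
tighter than the other.

Per-injection heats are ΔH_A·Δ(bound A) + ΔH_B·Δ(bound B) with the same
displaced-volume convention as the direct titration. The displaced
ligand's heat is physically present and is included by default
(`include_displaced_heat=True`). One consequence worth knowing: when
the pre-loaded competitor is more exothermic than the marker (e.g.
ΔH_B = −4.7 vs ΔH_A = −3.0 kcal/mol), the endothermic heat of its
release can push the complex-arm total past zero, making the raw
inhibition statistic exceed 100% and *decrease* with competitor
affinity. The monotone tighter-competitor ⇒ higher-inhibition property
therefore holds for the marker-attribution convention
(`include_displaced_heat=False`), which is what the monotonicity tests
and the acceptance script use; the default full-physics convention is
the right choice for simulating what a calorimeter would actually
record. Co-solvent effects (1% DMSO in the emulated assay) are not
modelled.

Synthetic marker parameters default to warfarin-like site-I values
(K_D = 3 μM, ΔH = −3 kcal/mol), chosen from typical literature ranges
because the emulated study does not print them.

## Two-state DSC

Excess heat capacity follows the van't Hoff two-state closed form
C_p(T) = (ΔH_vH²/RT²)·K/(1+K)², K = exp[−(ΔH_vH/R)(1/T − 1/T_m)],
evaluated through sech²(ln K / 2)/4 for overflow safety. The peak sits
at T_m with height ΔH_vH²/(4RT_m²) and the baseline-free curve
integrates to ΔH_vH (verified to 1% over T_m ± 25 K). Fits add a single
shared linear baseline — the scan's baseline-handling procedure was not
specified in the emulated workflow, and one line across the transition
is the simplest defensible choice; it recovers T_m unchanged to
≤ 0.05 K under any linear perturbation the model can also express.
Multi-starts seed T_m at the empirical (endpoint-detrended) peak and
±5 K around it. Scans whose apparent peak touches the grid edge, or
that carry no transition five times above the point-to-point noise, are
rejected as unstable rather than fitted. Irreversibility and scan-rate
effects are ignored: the model is equilibrium two-state, matching the
analysis convention it reimplements. Scans default to 303–363 K sampled
every 0.1 K.

## Structure metrics

**SASA** is Shrake–Rupley point sampling: 960 quasi-uniform points
(golden-spiral lattice) per probe-expanded sphere (probe 1.4 Å), a point
exposed iff outside every neighbour's expanded sphere. This differs
from slicing-based implementations; the accuracy contract is the test
battery — a lone atom is exact by construction, two-sphere systems match
the analytic cap formula within 2%, and doubling the point count moves a
50-atom cluster's total by < 1%. An independent implementation
(Biopython's) agrees within 1% on random clusters. Radii are a
Bondi-type van der Waals table keyed by element; unknown elements fall
back to 1.7 Å with a warning.

**BSA** = ASA(A) + ASA(B) − ASA(AB); non-negative because occlusion can
only remove area.

**Shape complementarity** follows the Lawrence–Colman construction on
dot surfaces with outward normals: for a dot x on A with nearest
partner dot x′, S(x) = (n_x · −n_{x′})·exp(−w|x−x′|²) with w = 0.5 Å⁻²;
interface dots are those whose nearest-partner distance lies within the
band (1.5 Å) of the median distance of the closest contact shell, and
S_c is the mean of the two one-way medians. The dot surfaces are
probe-expanded (solvent-accessible) spheres rather than the molecular
(Connolly) surface — a documented stand-in. A consequence of that choice
is that two convex spheres in van der Waals contact interpenetrate in
expanded-surface terms and score poorly however well they "pack"; S_c is
meaningful here for surfaces of matched curvature (the dense toy pocket
below, or constructed plates), which is the regime the tests probe.

**Hydrogen bonds** are geometric: intermolecular donor–acceptor pairs
within 3.5 Å, plus a D–H···A angle ≥ 120° whenever the donor carries an
explicit hydrogen (within 1.3 Å).

**Interface score** is a deliberately simple decomposed physics analog —
no equivalence to any production docking scorefunction is claimed. Over
intermolecular pairs within 8 Å: screened Coulomb 332·q_iq_j/(4r²)
(distance-dependent dielectric ε = 4r); a 12-6 Lennard-Jones term with
r_min = r_i + r_j and well depth 0.1 kcal/mol, split at r_min into an
attractive and a repulsive part, the latter capped at +10 per pair; and
−0.5 per hydrogen bond. The total is the sum of the terms; more negative
is better. BSA and S_c are attached to the metrics on request and
skipped during pose scoring for speed.

**Pose sampling** applies uniform random rotations (about the ligand
centroid) and uniform-in-ball translations (default 5 Å) around a site
center, discards hard clashes (any pair closer than 0.7× the vdW-radius
sum), scores survivors with the energy terms, and ranks ascending.
`top_k_mean` averages the k = 10 best scores — the same top-10 averaging
used to stabilise docking-score comparisons against experimental ΔG.
Ligands are rigid; conformational flexibility is out of scope.

## Synthetic data: what it emulates, and what it does not

Titrations emulate a perfusion calorimeter at the published study
conditions: 50 μM macromolecule, 500 μM titrant, 28 × 10 μL injections
into 1.4 mL at 298.15 K (the study states the concentrations but not the
injection program; 28 × 10 μL is typical instrument practice), with
additive i.i.d. Gaussian heat noise of 0.2 μcal — typical baseline noise,
large enough to make recovery tests meaningful. The default ground-truth
set is the packaged 13-compound table (K_D converted to molar), with the
two measured ΔC_p values (−148 and −195 cal/(mol·K)) and a generic
−150 elsewhere. DSC melting shifts are synthetic (no published per-
compound values are packaged): 1.5 K per decade of affinity gain above
100 μM, giving 2–4 K shifts of the right order for ligand stabilisation,
with apo T_m 340 K and ΔH_vH 150 kcal/mol as round protein-like values.
Not modelled: instrument response time, baseline drift, feedback-power
units, titrant impurities, or heat-rate saturation — so passing recovery
tests demonstrate estimator correctness under the stated noise model,
not robustness to real-instrument artefacts.

Toy complexes come in two styles. The **sparse** pocket (default)
places 2–5 beads on a shell around a large central ligand sphere so that
every bead's expanded sphere is pairwise disjoint from the others; then
no surface point can be buried twice, and the ground-truth BSA is the
exact sum of pairwise spherical-cap areas — an analytic oracle the
Shrake–Rupley code must hit within 5%. The default contact distance is
van der Waals contact, which is simultaneously the Lennard-Jones optimum
of every ligand-bead pair, so the generating pose is the score optimum
the pose sampler should re-find. Hydrogen-bond probe atoms (2.9 Å from
their donor bead) and the three rotation-marking satellites are tucked
inside the central sphere's expanded envelope, where they cannot perturb
any surface area, keeping both the planted bond count and the analytic
BSA exact. The **dense** pocket covers a hemisphere with ~100
overlapping beads whose inner envelope is a concave sphere matching the
ligand's curvature at a 0.25 Å gap — a genuinely complementary surface
(S_c ≈ 0.9) used to exercise the shape-complementarity machinery; no
analytic BSA is claimed there.

The study-level generator ties interface metrics to each compound's true
ΔG by exact linear maps (BSA = −55·ΔG Å², S_c = 0.3 − 0.05·ΔG,
score = 2·ΔG) with optional fractional noise. This injected linearity is
what makes the correlation layer testable with a known answer; it is a
stand-in for, not a reproduction of, docking-derived metrics on the real
receptor, and the headline correlation magnitudes of the original study
are expressly not reproduced here.

## Problem sizes and determinism

Recovery statistics use 50 seeded titrations (median errors ~3% in K_D,
< 0.5% in ΔH and N at c ≈ 23); the pose-recovery study uses 20 seeds ×
2000 poses; the equilibrium-solver cross-check uses 1000 random systems
against direct multivariate root-finding. Every stochastic element takes
an explicit integer seed (sub-seeds drawn from a single root generator),
and no global random state is touched. The bisection solvers iterate to
floating-point convergence; least-squares tolerances are set to 1e-14 so
noiseless round-trips recover parameters to ≤ 0.1%.

## Known limitations

- One-site model only: no sequential, multi-site, cooperative, or global
  multi-experiment fitting.
- The table audit flags inconsistencies but never corrects them; the
  packaged reference table ships verbatim, including its one known
  internal inconsistency (an entropy-sign transcription in the tightest
  methylated compound's row, which the audit flags).
- S_c on expanded-sphere dots under-scores convex–convex contacts (see
  above); interpret it comparatively, on matched-curvature surfaces.
- The interface score is a teaching-grade physics analog: no solvation,
  no polarisation, fixed per-pair well depth, geometric H-bonds only.
- PDB round-trips preserve coordinates to the format's 3-decimal
  precision; donor/acceptor flags and partial charges are not PDB fields
  and must be re-supplied (e.g. via a charge table) after reading.
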