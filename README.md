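# thermobind

Calorimetric and structural analysis of small-molecule recognition by
proteins, built around the workflow used to dissect how tea catechins —
in particular those carrying a galloyl ester — bind human serum albumin
(HSA): isothermal titration calorimetry (ITC) with full thermodynamic
bookkeeping, competitive-displacement assays, differential scanning
calorimetry (DSC), and structure-derived interface metrics tied back to
the thermodynamics through correlation analysis.

It is intended for biophysicists and structural bioinformaticians who
want a tested, scriptable version of this pipeline that runs end-to-end
on synthetic data with known ground truth, plus the packaged published
binding table for bookkeeping checks.

## What it computes

**ITC (one set of identical sites).** For injection *i* with cumulative
injected volume *v·i* into a cell of volume *V₀*, the displaced-volume
corrected totals are

    M_t = M₀ (1 − v/2V₀)/(1 + v/2V₀),   X_t = X_s (v/V₀)/(1 + v/2V₀)

and the cumulative heat is *Q·i = N·Θ·i·M_t·V₀·ΔH* with Θ the root of the
one-site binding quadratic (the Wiseman isotherm). Nonlinear least
squares over (N, K_D, ΔH) — K_D in log space, multi-started — recovers
the binding parameters; ΔG = RT ln K_D, −TΔS = ΔG − ΔH, and the
enthalpic efficiency 100·ΔH/ΔG complete the table. ΔC_p comes from the
ordinary least-squares slope of ΔH versus T.

**Displacement ITC.** A site marker (warfarin for albumin site I) is
titrated into receptor pre-loaded with a test ligand; the exact
two-ligand competitive equilibrium is solved by bisection at every
injection, and the assay statistic is
`inhibition (%) = 100 − 100·ΔQ(complex)/ΔQ(free)`.

**DSC.** Two-state unfolding: K(T) = exp[−(ΔH_vH/R)(1/T − 1/T_m)],
C_p,excess = (ΔH_vH²/RT²)·K/(1+K)², fitted with a shared linear baseline;
ligand-induced stabilisation is reported as ΔT_m versus an apo reference.

**Structure metrics.** Shrake–Rupley SASA and buried surface area
BSA = ASA(A) + ASA(B) − ASA(AB); Lawrence–Colman-style shape
complementarity S_c on probe-expanded dot surfaces; geometric hydrogen
bonds; a decomposed physics interface score (screened Coulomb,
12-6 Lennard-Jones split into attractive/capped-repulsive, H-bond bonus);
rigid-body pose sampling with top-10 score averaging.

**Reporting.** Publication-convention rounding, an internal-consistency
audit of binding tables, and Pearson correlations of ΔG against interface
score, BSA, and S_c.

## Worked example

```python
>>> import thermobind as tb
>>> schedule = tb.default_schedule()          # 28 x 10 uL, 50/500 uM, 298.15 K
>>> truth = tb.GroundTruth("EGCg", n_sites=1.1, kd=2.2e-6, dh=-4.7)
>>> series = tb.synth_titration(truth, schedule, tb.NoiseModel(0.2, seed=1))
>>> fit = tb.fit_single_site(series)
>>> print(f"N={fit.n_sites:.2f}  KD={fit.kd_uM:.2f} uM  dH={fit.dh:.2f}  "
...       f"dG={fit.dg:.2f}  -TdS={fit.tds_neg:.2f}  eff={fit.efficiency:.0f}%")
N=1.10  KD=2.24 uM  dH=-4.70  dG=-7.71  -TdS=-3.01  eff=61%
```

The fit recovers the generating parameters of the strongest natural
gallated catechin: stoichiometry ~1, micromolar dissociation constant,
and an enthalpy-driven signature (ΔH accounts for ~61% of ΔG at 298 K —
the hallmark the galloyl group confers). A `thermobind` console script
exposes the same operations from the shell (`simulate-itc`, `fit-itc`,
`deltacp`, `displace`, `fit-dsc`, `sasa`, `bsa`, `sc`, `hbonds`, `dock`,
`report`).

## Layout

- `src/thermobind/itc.py` — isotherm, fitting, ΔG/−TΔS/ΔC_p, titration CSV I/O
- `src/thermobind/displacement.py` — competitive equilibrium and inhibition rate
- `src/thermobind/dsc.py` — two-state thermogram model and fitting
- `src/thermobind/structure.py` — PDB I/O, SASA/BSA, S_c, H-bonds, scoring, poses
- `src/thermobind/synth.py` — synthetic titrations, scans, toy complexes, study bundles
- `src/thermobind/report.py` — tables, audit, correlations
- `src/thermobind/reference.py` — packaged published binding table
- `docs/methods.md` — model assumptions, parameter choices, limitations
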