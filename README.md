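# sclerafit

Analysis pipeline for an ocular-biomechanics study design: poroelastic
characterization of scleral unconfined-compression stress-relaxation
tests, longitudinal ocular biometry / refraction statistics, gamma
log-link group contrasts, and biochemical assay quantification — all
exercisable end-to-end on seeded synthetic data.

## What's inside

| module | purpose |
| --- | --- |
| `sclerafit.poroelastic` | Forward model of a biphasic (poroelastic) cylindrical tissue disc in unconfined compression with tension–compression (conewise) moduli: semi-analytic Bessel-series solution plus an independent finite-difference reference solver. |
| `sclerafit.relaxation` | Trace → estimates pipeline: tare/thickness detection, ramp-hold segmentation, equilibrium detection, and per-step nonlinear least-squares fits of (H₊A, k) with closed-form H₋A. |
| `sclerafit.biometry` | OCT interface → segment lengths (optical-to-geometric conversion, n = 1.39), shift and Δ-from-baseline statistics, eye exclusions, dose arithmetic. |
| `sclerafit.cohort_stats` | Gamma log-link / gaussian GLMs with treatment × covariate interactions, profile-likelihood LRTs, estimated marginal means at exact target strains, multivariate-t multiplicity adjustment, percent differences. |
| `sclerafit.assays` | DMMB / PicoGreen standard curves and mass-fraction quantification; masked-intensity normalized fluorescence with superior/inferior splits. |
| `sclerafit.synthetic` | Seeded generators for every input: relaxation traces (tare + 3 strain steps), two-arm longitudinal cohorts (14/16 animals), assay plates, two-channel image sets — each shipping its ground truth. |
| `sclerafit.cli` | `sclerafit` command: `simulate`, `fit-uct`, `biometry`, `stats`, `assays`, `run-all`. |

## CLI quick start

```bash
# generate synthetic compression tests and refit them
sclerafit simulate uct --seed 1 --out scratch/uct
sclerafit fit-uct --traces scratch/uct --out scratch/estimates.csv

# cohort table and shift statistics
sclerafit simulate cohort --seed 1 --out scratch/cohort
sclerafit biometry --in scratch/cohort/cohort.csv --out scratch/shifts.csv \
    --stat shift --outcome VCD --timepoint t2wk

# group contrasts on the fitted estimates
sclerafit stats --estimates scratch/estimates.csv --out scratch/results.json

# everything at once, with a reproducible report
sclerafit run-all --seed 1 --out scratch/full
```

## Model summary

The compression sample is a saturated cylinder with radial fluid
drainage through a free lateral edge, frictionless impermeable platens,
in-plane tensile modulus `H_plus_A` (C11), axial equilibrium modulus
`H_minus_A` (C33), and hydraulic conductivity `k` (m⁴ N⁻¹ s⁻¹).  With
zero off-diagonal coupling the equilibrium load is
`H_minus_A · strain · area` and the transient depends on (H₊A, k)
through the gel time `a²/(H₊A·k)`.  The series solution uses the roots
of `α·J0(α) = J1(α)` (load-relaxation coefficients `1/(αₙ²−1)`); ramps
are handled by Duhamel superposition.  The finite-difference solver
discretizes the same boundary-value problem (including nonzero coupling
moduli) and serves as the normative cross-check.
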