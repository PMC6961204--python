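# tprspring

Trajectory analysis for repeat-protein **nanosprings**: fluctuation-based
spring-constant estimation with Gaussian population decomposition and
bootstrap errors, repeat-geometry descriptors, elastic-energy and
reversibility analysis, and neutral-variant control selection for
X-linked missense variants.

## The scientific problem

α-solenoid domains — stacks of helical repeat units such as
tetratricopeptide repeats (TPRs) — behave as elastic nanosprings: their
end-to-end length fluctuates harmonically around an equilibrium value,
and the domain stores deformation energy reversibly when stretched.
For the TPR domain of O-GlcNAc transferase (OGT), single-point mutations
associated with Intellectual Disability sit in this spring, and the
question is whether they change its biomechanics.

The central relation is the equipartition result for a harmonic mode:

```
k = k_B · T / σ²
```

where σ is the standard deviation of the equilibrium end-to-end distance
distribution, giving k in pN/nm for σ in nm at temperature T.  The
energy to deform the spring by Δx is E = ½·k·Δx² (converted to kJ/mol).
Ensembles that partition into two conformational populations are
decomposed into Gaussian components (EM, component count chosen by BIC
with a conservative ΔBIC > 6 rule), and each component's fitted width σ
yields a per-population spring constant; uncertainties come from a
1000-cycle bootstrap over replicates (or over contiguous blocks sized by
the autocorrelation time when only one series is available).

Because multi-microsecond MD trajectories are not reproducible at desk
scale, the package ships first-class synthetic generators that produce
data with exactly the statistical and geometric structure the analysis
assumes: stationary Ornstein–Uhlenbeck (OU) end-to-end distance series
(exact discrete-time update, so the stationary variance is k_BT/k at any
time step), state-switching OU mixtures for bimodal ensembles, and
idealised α-solenoid coordinates with controllable repeat geometry and
injectable helix kinks — each generator recording the ground truth its
output was built with.

## Who this is for

Computational structural biologists analysing equilibrium or steered MD
output of repeat proteins (distance series, multi-model PDB
trajectories), and anyone validating fluctuation-based stiffness
estimators against data with known ground truth.

## Worked example

Recover a wild-type-like spring constant from four synthetic replicate
ensembles (2×10⁵ frames each at 10 ps spacing, 298 K):

```python
from tprspring.protocols import simulate_variant_ensemble, analyze_variant_ensemble
from tprspring import elastic_energy

series = simulate_variant_ensemble("wt", seeds=(1, 2, 3, 4))
model, estimates = analyze_variant_ensemble(series, seed=0)
est = estimates[0]
print(f"{model.n_components} population(s)")
print(f"k = {est.k:.2f} pN/nm  (95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")
print(f"E(1 nm) = {elastic_energy(est.k, 1.0):.2f} kJ/mol")
```

prints

```
1 population(s)
k = 20.91 pN/nm  (95% CI 20.73-21.02)
E(1 nm) = 6.30 kJ/mol
```

The fit keeps one Gaussian population (BIC rejects a second component),
the recovered stiffness is within ~0.5% of the 20.80 pN/nm the
generator was parameterised with, and stretching this spring by 1 nm
costs about 6 kJ/mol.  The same pipeline on a bimodal variant (e.g. `"L254F"`)
returns two populations with distinct means and per-population
constants.

The numbered scripts under `analysis/` run the full study-style
analyses and write their tables to `results/`:
`01_spring_constants.py` (per-variant constants with bootstrap errors),
`02_elasticity_reversibility.py` (deformation energies, relaxation
verdicts, maximum elastic extension), `03_local_geometry.py` (repeat
geometry descriptors on ground-truth fixtures) and
`04_neutral_controls.py` (male-observed filtering and ranking of
neutral-control variants).

A `tprspring` command-line interface exposes the same stages
(`simulate`, `geometry`, `analyze-spring`, `relax-check`,
`pick-controls`); every run writes a manifest with its config and seed.

## Layout

```
src/tprspring/     library: io, synthetic, geometry, spring, variants,
                   protocols, cli (+ shipped annotation & property tables)
analysis/          numbered narrative drivers writing results/ tables
scripts/           acceptance.py (headline quantities, from scratch)
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, estimators, numerical choices, limitations
```
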