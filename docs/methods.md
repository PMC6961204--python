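# Methods

## The harmonic nanospring model

The analysis treats the end-to-end distance *x* of an α-solenoid domain
(here: the distance between the mass-weighted centres of mass of the
first and last repeat units) as a harmonic degree of freedom in thermal
equilibrium.  Equipartition then ties the stiffness to the equilibrium
fluctuations:

    k = k_B · T / σ²,

with σ the standard deviation of the stationary distribution of *x*.
Internally all lengths are in Å and k is reported in pN/nm
(1 nm = 10 Å); k_B = 0.0138065 pN·nm/K and the default bath temperature
is 298 K, always an explicit parameter.  Deformation energy is
E(Δx) = ½·k·Δx² in pN·nm per molecule, converted to kJ/mol with the
Avogadro factor 0.60221.  The model is purely harmonic; no
force–extension (worm-like-chain) fitting is attempted, and stiffness is
never estimated from force traces — only from equilibrium fluctuations
or relaxation series.

## Synthetic ensembles

**Ornstein–Uhlenbeck series.**  Thermal fluctuations in a harmonic well
are an OU process, so the generator draws stationary OU paths with mean
equal to the equilibrium length, stationary variance k_B·T/k and
relaxation time τ.  Integration uses the exact discrete-time transition
(AR(1) with decay factor e^(−dt/τ) and matched innovation variance),
initialised from the stationary distribution, so stationarity is exact
at any frame spacing; a small-step Euler–Maruyama integrator exists only
as an independent test oracle.  Defaults mirror the study conditions the
package targets: 2×10⁵ frames at dt = 10 ps per replicate, four
replicates (2 µs aggregate), τ = 100 ps.  τ is a modelling choice — the
generators only need *some* realistic autocorrelation so that
uncertainty estimation is non-trivial; 100 ps is of the order seen for
collective domain modes in equilibrium MD.

**Bimodal ensembles.**  Mixtures of OU components carry a latent state
driven by a discrete-time Markov chain: at each step a switch event
fires with probability `switch_rate·dt` (default 10⁻⁴/ps), and on an
event the new state is drawn from the component weights, making the
weights the exact stationary occupancies; the coordinate re-equilibrates
from the new component's stationary distribution.  No claim is made
about real interconversion kinetics — the chain is the simplest
mechanism that produces well-separated Gaussian populations with
labelled ground truth.  Note that at the default switch rate a
2×10⁵-frame run contains only ~200 latent segments, so single-run
occupancies scatter around the weights with SD ≈ 0.05; occupancy checks
therefore either average over seeds or use faster switching.

**Idealised solenoids.**  Repeat units are pairs of antiparallel ideal
α-helices (rise 1.5 Å/residue, 100°/residue, Cα radius 2.3 Å — textbook
values; the geometry is a fixture, not a claim about any real protein).
The helix-pair separation is solved (Brent) so the Cα(Ψ1)–Cα(Ψ30)
distance hits the requested intra-repeat distance.  Units are placed at
a 15 Å superhelix radius with configurable rise and twist per unit,
helix axes oriented tangentially (as in real solenoids, where repeat
helices run roughly perpendicular to the superhelix axis); a steric
check rejects self-intersecting specifications.  Kinks are injected by
rotating the helix segment downstream of a chosen residue about a
perpendicular axis through its Cα, so the injected angle is exact by
construction.  The builder records every descriptor of its own output
(intra/inter-repeat distances, turn angles, end-to-end distance, kink
angle) as ground-truth metadata, which the geometry operators must
reproduce in round-trip tests.

## Geometry descriptors

All descriptors accept a trajectory or a single structure and are
invariant under global rotation and translation (property-tested).
Residue numbering is 1-based author numbering with inclusive ranges.

* **Centres of mass** are mass-weighted over *all* atoms of a unit's
  residue range; a Cα-only mode exists for sensitivity checks.
* **B-A'-B' angle** (the turn between consecutive repeats) is the angle
  at the Cα of the current unit's Ψ1 (configurable to position 2, since
  both conventions appear in practice) between the Cα of Ψ30 of the
  previous and of the current repeat.
* **Dihedrals** follow the IUPAC sign convention (cross-checked against
  an independent library implementation), wrapped to (−180°, 180°];
  means and SDs of angle series are circular (the mean of {179°, −179°}
  is ±180°, never 0°).  χ1 resolves its fourth atom by side-chain type;
  Gly/Ala raise.  Rotamer states default to the gauche−/gauche+/trans
  partition at (−120°, 0°, 120°); occupancies always sum to 1 and empty
  states report occupancy 0 with NaN statistics.
* **Helix kink angle** splits the helix at the kink residue and measures
  the angle between the two local axes.  Each axis is estimated from
  cross products of successive second differences of the Cα positions:
  for an ideal helix the second difference points exactly at the axis,
  so the cross product lies exactly along it, independent of the twist
  per residue.  This estimator was chosen over a sliding-average +
  principal-axis fit, which leaves a residual helical ripple that tilts
  the fitted axis by 1–2° on ideal fixtures — more than the 1° accuracy
  the constructed-rotation oracle demands.  A per-residue-step bend
  profile is exposed as a secondary output.  Minimum window: 4 Cα per
  side.
* **RMSD** optionally applies optimal least-squares superposition
  (Kabsch) before the deviation.

## Population decomposition and spring constants

`fit_population_model` fits 1..max_components Gaussian mixtures by EM
and picks the component count by BIC, accepting a richer model only when
it improves BIC by more than 6 — a conservative threshold that keeps
genuinely unimodal ensembles at one component while still detecting the
well-separated bimodal cases.  Components are ordered by weight (major
first).  Two numerical choices matter for strongly *overlapping*
components:

1. **Initialisation.**  Default k-means-style inits systematically land
   in a wrong local optimum for overlapping 1-D mixtures, so most
   restarts come from a deterministic quantile grid (candidate minor
   fractions 0.1/0.2/0.35 on either tail), topped up with seeded random
   draws; exploration runs on a strided subsample (≤ 2×10⁴ points) for
   speed.
2. **Convergence.**  EM crawls along the flat likelihood ridge of
   overlapping components and can stop ~1 Å from the optimum at any
   practical tolerance, so the winning basin is polished with an
   analytic-gradient L-BFGS step on (weight logits, means, log-widths).

Widths below 10⁻³ Å mark a degenerate (collapsed) restart; if all
restarts collapse the fit errors out.

The per-population spring constant maps the *fitted component width*
(not the raw sample SD, which would conflate populations) through
k = k_B·T/σ².  Frames enter the fit unsubsampled: σ is unbiased under
autocorrelation; only the uncertainty is not.

**Bootstrap uncertainty.**  Uncertainty comes from 1000 bootstrap cycles
over the natural resampling units: the supplied replicates when ≥ 2
series are given, otherwise contiguous blocks of ~10× the integrated
autocorrelation time (estimated with initial-positive-sequence
truncation; ≥ 10 blocks required, else uncertainty is refused as
undefined).  Per-unit component widths are computed once under the
pooled model's posterior responsibilities; each cycle resamples units,
averages the widths and maps the mean width through the spring relation.
Reported are the bootstrap SD and a 95% interval taken as the percentile
spread of the bootstrap distribution *recentred on the pooled point
estimate*: per-block widths are slightly biased low (finite block length
relative to the autocorrelation time), and recentring anchors the
interval at the unbiased pooled estimate so it always brackets it.
Calibration is property-tested: over 100 seeded simulate→fit→estimate
repeats the 95% intervals cover the true stiffness ≥ 90% of the time.

## Reversibility and maximum elastic extension

A relaxation trace is *reversible* when the mean over its final sliding
window lies within `equilibrium ± band`; the band defaults to one
population σ (no principled tolerance exists, and one σ makes the
equilibrated process itself reversible with high probability).  The
time-to-return is the start time of the first window whose mean enters
the band.  The maximum elastic extension over a set of (start extension,
verdict) trials is the largest reversible start, also reported as a
ratio to the equilibrium length.

## Neutral-variant controls

For an X-linked gene, population-database variants observed in at least
one hemizygous male are the strongest presumed-neutral candidates.
Records are filtered on male allele count ≥ 1, scored for substitution
conservativeness as the fraction of shared binary physicochemical
properties (a Taylor/Zvelebil-style 10-property table shipped as an
editable data file, since published scales are tabulated in several
variants), and ranked by (1) co-location with a repeat unit containing a
known pathogenic site, (2) conservation score, (3) total allele count,
with stable input order on ties.  The key ordering is this package's
choice; the selection criteria themselves are usually stated narratively
in the literature.  Conservation with respect to a repeat-family
*alignment* is out of scope (it needs external databases); it enters
only as a per-record consensus-position label supplied by the
annotation, where a position counts as conserved when it belongs to the
extended OGT-type consensus set {6, 7, 8, 15, 20, 24, 27, 30, 32}.

## Shipped OGT annotation

The default TPR2–TPR11 annotation uses 34-residue periodicity with TPR2
starting at residue 55, anchored by the variant at repeat position 26 of
TPR8 (residue 284); this places residue 319 at the consensus alanine
(position 27) and residue 254 at the conserved hydrophobic position 30,
and residues 279/310 at unconserved positions.  Exact published repeat
boundaries are not available, so the offset and all ranges are
configurable, and the helix spans (positions 1–12 and 17–29 of each
unit) are approximate.

## Problem sizes and determinism

The acceptance script and the end-to-end tests run the estimation
pipeline at the study-scale sampling the package targets — four
replicates of 2×10⁵ frames for spring-constant recovery, single
2×10⁵-frame runs for the bimodal decompositions — which completes in a
few minutes; the bootstrap-calibration property uses 100 repeats of
2×10⁴-frame runs with 300 bootstrap cycles, a size at which coverage is
already stable.  Every stochastic component (generators, EM restarts,
bootstrap) is driven by explicit seeds, and fixed seeds reproduce
bit-identical outputs; CLI JSON output is rounded to 6 significant
digits so reruns are byte-identical.

## Known limitations

* The synthetic ensembles are exactly Gaussian/OU by construction; real
  MD end-to-end distances have anharmonic tails, slow non-Markovian
  memory and state-dependent kinetics.  Passing tests show the
  *estimators* are correct and calibrated on the assumed model, not that
  the harmonic model is adequate for any particular protein.
* Mixture decomposition of strongly overlapping populations is
  intrinsically ill-conditioned: with ~10⁴ effective samples the minor
  mean of an L254F-like ensemble carries ~0.3–0.5 Å statistical spread
  even at the exact MLE.
* The solenoid builder produces idealised geometry for round-trip
  validation; it is not a homology model, and its superhelix radius
  (15 Å) is an internal fixture constant.
* Proline "side-chain N" atom-pair requests resolve to the backbone N
  (proline has no side-chain nitrogen); the operator simply measures
  whatever pair of atoms is named.
* No PBC unwrapping, no force-field or topology parsing, no
  secondary-structure assignment: helix spans come from the annotation.
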