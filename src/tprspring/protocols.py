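"""Study parameterisation and canned analysis protocols.

The OGT-TPR equilibrium ensembles are characterised by per-variant
spring constants (pN/nm) and population mean extensions (Å); ensembles
of the two bimodal disease variants partition into a major (~80%) and a
minor (~20%) population.  These numbers parameterise the synthetic
generators so the full estimation pipeline can be exercised and
validated against the values it was built from.

Protocol defaults mirror the study's sampling: four replicate series,
2×10⁵ frames each at 10 ps spacing (2 µs per replicate set), bath
temperature 298 K, and a 100 ps end-to-end distance relaxation time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import DistanceSeries
from .spring import (PopulationModel, SpringEstimate,
                     estimate_spring_constants, fit_population_model)
from .synthetic import MixtureSimSpec, OUParams, simulate_mixture_series, simulate_ou_series
from .units import DEFAULT_TEMPERATURE_K


@dataclass(frozen=True)
class VariantEnsemble:
    """Per-population stiffnesses and mean extensions of one domain variant."""

    name: str
    stiffnesses: tuple[float, ...]   # pN/nm, major population first
    means: tuple[float, ...]         # Å, aligned with stiffnesses
    weights: tuple[float, ...]       # population occupancies, sum to 1


#: Equilibrium-ensemble parameters of the studied OGT-TPR variants.
VARIANTS: dict[str, VariantEnsemble] = {
    "wt": VariantEnsemble("wt", (20.80,), (71.6,), (1.0,)),
    "L254F": VariantEnsemble("L254F", (21.99, 12.61), (72.7, 65.7), (0.8, 0.2)),
    "R284P": VariantEnsemble("R284P", (19.92, 17.02), (73.0, 82.9), (0.8, 0.2)),
    "A319T": VariantEnsemble("A319T", (24.90,), (72.8,), (1.0,)),
    "A310T": VariantEnsemble("A310T", (20.31,), (72.1,), (1.0,)),
    "I279V": VariantEnsemble("I279V", (21.40,), (72.9,), (1.0,)),
    "L254I": VariantEnsemble("L254I", (22.99,), (71.5,), (1.0,)),
}

#: Wild-type maximum fully elastic end-to-end extension (Å).
MAX_ELASTIC_EXTENSION_A = {"wt": 101.7, "L254F": 103.7, "A319T": 107.5,
                           "R284P": 107.2}

N_FRAMES = 200_000
TAU_PS = 100.0
DT_PS = 10.0
SWITCH_RATE = 1e-4


def simulate_variant_ensemble(variant: str | VariantEnsemble,
                              seeds: tuple[int, ...] = (1, 2, 3, 4),
                              n_frames: int = N_FRAMES,
                              temperature: float = DEFAULT_TEMPERATURE_K
                              ) -> list[DistanceSeries]:
    """Replicate end-to-end distance series for one variant's ensemble.

    Single-population variants yield stationary OU series; bimodal ones
    yield state-switching OU mixtures.  One series per seed.
    """
    v = VARIANTS[variant] if isinstance(variant, str) else variant
    series = []
    for seed in seeds:
        if len(v.stiffnesses) == 1:
            series.append(simulate_ou_series(OUParams(
                k=v.stiffnesses[0], mean=v.means[0], tau=TAU_PS, dt=DT_PS,
                n_frames=n_frames, temperature=temperature, seed=seed),
                replicate=seed))
        else:
            comps = tuple(
                (OUParams(k=k, mean=m, tau=TAU_PS, dt=DT_PS,
                          n_frames=n_frames, temperature=temperature,
                          seed=seed), w)
                for k, m, w in zip(v.stiffnesses, v.means, v.weights))
            series.append(simulate_mixture_series(
                MixtureSimSpec(components=comps, switch_rate=SWITCH_RATE,
                               seed=seed), replicate=seed))
    return series


def analyze_variant_ensemble(series: list[DistanceSeries],
                             temperature: float = DEFAULT_TEMPERATURE_K,
                             n_bootstrap: int = 1000, seed: int = 0
                             ) -> tuple[PopulationModel, list[SpringEstimate]]:
    """Full estimation pipeline: mixture fit, then per-population constants."""
    model = fit_population_model(series, max_components=2, seed=seed)
    estimates = estimate_spring_constants(
        series, model, temperature=temperature, n_bootstrap=n_bootstrap,
        seed=seed)
    return model, estimates
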