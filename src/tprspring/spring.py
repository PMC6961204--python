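"""Nanospring analysis: population decomposition, spring constants,
elastic energies and reversibility.

The central relation is the equipartition result for a harmonic mode:
``k = k_B·T / σ²``, where σ is the standard deviation of the equilibrium
end-to-end distance distribution.  Ensembles that partition into several
conformational populations are decomposed into Gaussian components by
EM (model count chosen by BIC), and each component's fitted width yields
a per-population spring constant.  Uncertainties come from a bootstrap
over replicates — or over contiguous blocks when only a single series is
available, because frames are autocorrelated and a naive frame bootstrap
would understate the error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .io import DistanceSeries
from .units import (ANGSTROM_PER_NM, DEFAULT_TEMPERATURE_K, KB_PN_NM_PER_K,
                    KJ_PER_MOL_PER_PN_NM)


class FitError(RuntimeError):
    """A population fit could not be obtained."""


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Gaussian mixture fitted to a distance ensemble.

    Components are ordered by weight descending, so index 0 is the major
    population.  ``selection`` records the per-candidate BIC scores and
    the ΔBIC that chose ``n_components``.
    """

    weights: np.ndarray     # (n_components,), sum to 1
    means: np.ndarray       # Å
    sigmas: np.ndarray      # Å
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.sigmas)):
            raise ValueError("weights, means, sigmas must align")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1) > 1e-6:
            raise ValueError("weights must be positive and sum to 1")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def responsibilities(self, values: np.ndarray) -> np.ndarray:
        """(n, n_components) posterior component probabilities."""
        from scipy.stats import norm
        values = np.asarray(values, dtype=float)
        dens = np.stack([w * norm.pdf(values, m, s) for w, m, s in
                         zip(self.weights, self.means, self.sigmas)], axis=1)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


_SIGMA_COLLAPSE_A = 1e-3
DELTA_BIC_THRESHOLD = 6.0


def _pool_values(series) -> np.ndarray:
    if isinstance(series, DistanceSeries):
        return np.asarray(series.values, dtype=float)
    if isinstance(series, np.ndarray):
        return series.astype(float)
    return np.concatenate([_pool_values(s) for s in series])


def _quantile_inits(values: np.ndarray, n_comp: int,
                    n_restarts: int, seed: int) -> list[dict]:
    """Initial parameter sets for 1-D EM restarts.

    Overlapping 1-D mixtures have local likelihood optima that trap the
    default k-means initialisation, so most restarts come from a
    deterministic quantile grid: split the sorted sample at candidate
    minor-population fractions on either tail and use each part's mean
    and SD as a component seed.  Remaining restarts are seeded random
    draws from the data.
    """
    rng = np.random.default_rng(seed)
    order = np.sort(values)
    n = len(order)
    sd = values.std()
    inits: list[dict] = []
    if n_comp == 1:
        return [{"weights_init": np.array([1.0]),
                 "means_init": np.array([[values.mean()]]),
                 "precisions_init": np.array([[[1.0 / sd**2]]])}]
    for frac in (0.1, 0.2, 0.35):
        for minor_left in (True, False):
            cut = int(round(frac * n))
            lo, hi = order[:cut], order[cut:]
            if minor_left:
                parts = [hi, lo] + [order] * (n_comp - 2)
            else:
                parts = [order[:n - cut], order[n - cut:]] + [order] * (n_comp - 2)
            w = np.array([len(p) for p in parts], dtype=float)
            w /= w.sum()
            mu = np.array([[p.mean()] for p in parts])
            prec = np.array([[[1.0 / max(p.std(), 1e-6)**2]] for p in parts])
            inits.append({"weights_init": w, "means_init": mu,
                          "precisions_init": prec})
    while len(inits) < n_restarts:
        mu = np.sort(rng.choice(values, size=n_comp, replace=False))
        inits.append({"weights_init": np.full(n_comp, 1.0 / n_comp),
                      "means_init": mu[:, None],
                      "precisions_init": np.full((n_comp, 1, 1), 1.0 / sd**2)})
    return inits[:n_restarts]


def _mixture_nll_grad(theta: np.ndarray, values: np.ndarray, n_comp: int):
    """Negative log-likelihood and gradient of a 1-D Gaussian mixture.

    Parameterisation: weight logits (softmax), means, log-sigmas — all
    unconstrained, so a quasi-Newton polish can walk the flat likelihood
    ridge that EM crawls along for strongly overlapping components.
    """
    logits = theta[:n_comp]
    means = theta[n_comp:2 * n_comp]
    log_sig = theta[2 * n_comp:]
    sig = np.exp(log_sig)
    w = np.exp(logits - logits.max())
    w /= w.sum()
    z = (values[:, None] - means) / sig                    # (n, c)
    log_comp = np.log(w) - 0.5 * z**2 - log_sig - 0.5 * np.log(2 * np.pi)
    m = log_comp.max(axis=1, keepdims=True)
    log_mix = m.ravel() + np.log(np.exp(log_comp - m).sum(axis=1))
    nll = -log_mix.sum()
    resp = np.exp(log_comp - log_mix[:, None])             # responsibilities
    g_logits = -(resp.sum(axis=0) - len(values) * w)
    g_means = -(resp * z / sig).sum(axis=0)
    g_logsig = -(resp * (z**2 - 1.0)).sum(axis=0)
    return nll, np.concatenate([g_logits, g_means, g_logsig])


def _refine_mle(values: np.ndarray, weights, means, sigmas):
    """Gradient polish of mixture parameters; returns (w, mu, sig, ll)."""
    from scipy.optimize import minimize
    n_comp = len(weights)
    theta0 = np.concatenate([np.log(np.asarray(weights, dtype=float)),
                             np.asarray(means, dtype=float),
                             np.log(np.asarray(sigmas, dtype=float))])
    res = minimize(_mixture_nll_grad, theta0, args=(values, n_comp),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8})
    theta = res.x
    w = np.exp(theta[:n_comp] - theta[:n_comp].max())
    w /= w.sum()
    mu = theta[n_comp:2 * n_comp]
    sig = np.exp(theta[2 * n_comp:])
    return w, mu, sig, -res.fun


def fit_population_model(series, max_components: int = 2,
                         seed: int = 0, n_restarts: int = 10,
                         delta_bic: float = DELTA_BIC_THRESHOLD) -> PopulationModel:
    """Fit Gaussian mixtures with 1..max_components and pick one by BIC.

    EM with ``n_restarts`` seeded restarts per candidate count (quantile
    grid plus random draws; see :func:`_quantile_inits`); the restart
    exploration runs on a strided subsample for speed, the winning basin
    is polished by EM on the full data and finished with an
    analytic-gradient quasi-Newton step (EM alone crawls on the flat
    likelihood ridge of strongly overlapping components).  A richer
    model is accepted only when it improves BIC by more than
    ``delta_bic`` (a conservative criterion that keeps unimodal data at
    1 component).  Degenerate fits (component width below 1e-3 Å) are
    discarded; if every restart collapses a :class:`FitError` is raised.
    """
    values = _pool_values(series)
    if len(values) < 100:
        raise FitError(f"need at least 100 values, got {len(values)}")
    if not np.all(np.isfinite(values)):
        raise FitError("non-finite values in series")
    X = values[:, None]
    stride = max(len(values) // 20_000, 1)
    X_explore = X[::stride]

    candidates: dict[int, tuple[float, tuple]] = {}
    for n_comp in range(1, max_components + 1):
        best: GaussianMixture | None = None
        best_ll = -np.inf
        for init in _quantile_inits(values, n_comp, n_restarts, seed):
            gm = GaussianMixture(
                n_components=n_comp, covariance_type="full",
                max_iter=200, tol=1e-6, reg_covar=1e-10, **init)
            with warnings.catch_warnings():
                # exploration restarts need not converge; the polish does
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X_explore)
            sig = np.sqrt(gm.covariances_.ravel())
            if np.any(sig < _SIGMA_COLLAPSE_A):
                continue  # degenerate restart
            ll = gm.score(X_explore)
            if ll > best_ll:
                best_ll, best = ll, gm
        if best is None:
            raise FitError(
                f"all {n_restarts} restarts degenerate for {n_comp} component(s)")
        polish = GaussianMixture(
            n_components=n_comp, covariance_type="full",
            max_iter=500, tol=1e-8, reg_covar=1e-10,
            weights_init=best.weights_, means_init=best.means_,
            precisions_init=best.precisions_)
        with warnings.catch_warnings():
            # the gradient refinement below finishes convergence
            warnings.simplefilter("ignore", ConvergenceWarning)
            polish.fit(X)
        w, mu, sig, ll = _refine_mle(
            values, polish.weights_, polish.means_.ravel(),
            np.sqrt(polish.covariances_.ravel()))
        if np.any(sig < _SIGMA_COLLAPSE_A):
            raise FitError(f"{n_comp}-component fit degenerate after polish")
        n_params = 3 * n_comp - 1
        bic = n_params * np.log(len(values)) - 2.0 * ll
        candidates[n_comp] = (bic, (w, mu, sig))

    chosen = 1
    for n_comp in range(2, max_components + 1):
        if candidates[chosen][0] - candidates[n_comp][0] > delta_bic:
            chosen = n_comp
    bic_chosen, (weights, means, sigmas) = candidates[chosen]
    order = np.argsort(weights)[::-1]  # major population first
    selection = {
        "bic": {n: float(b) for n, (b, _) in candidates.items()},
        "chosen": chosen,
        "delta_bic_threshold": delta_bic,
        "delta_bic": float(candidates[1][0] - bic_chosen) if chosen > 1 else 0.0,
        "n_values": int(len(values)),
        "seed": seed,
    }
    return PopulationModel(weights=weights[order], means=means[order],
                           sigmas=sigmas[order], selection=selection)


# ---------------------------------------------------------------------------
# spring constants
# ---------------------------------------------------------------------------

def spring_constant(sigma_A: float,
                    temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """k = k_B·T/σ² in pN/nm, for σ given in Å.

    The equipartition relation for a harmonic degree of freedom; pure
    function, strictly decreasing in σ.
    """
    if not np.isfinite(sigma_A) or sigma_A <= 0:
        raise ValueError(f"sigma must be positive and finite, got {sigma_A}")
    sigma_nm = sigma_A / ANGSTROM_PER_NM
    return KB_PN_NM_PER_K * temperature / sigma_nm**2


def elastic_energy(k_pn_per_nm: float, dx_nm: float) -> float:
    """Harmonic deformation energy E = ½·k·Δx² in kJ/mol.

    ``k`` in pN/nm and ``dx`` in nm give pN·nm per molecule, converted
    to kJ/mol.  Exactly quadratic: E(2Δx) = 4·E(Δx).
    """
    if not np.isfinite(k_pn_per_nm) or k_pn_per_nm <= 0:
        raise ValueError(f"k must be positive and finite, got {k_pn_per_nm}")
    return 0.5 * k_pn_per_nm * dx_nm**2 * KJ_PER_MOL_PER_PN_NM


@dataclass
class SpringEstimate:
    """Per-population spring constant with bootstrap uncertainty."""

    k: float                 # pN/nm, from the pooled fitted width
    ci_low: float
    ci_high: float
    bootstrap_sd: float      # SD of the bootstrap k distribution
    sigma_A: float           # pooled fitted component width
    temperature: float
    component: int           # index into the PopulationModel (0 = major)
    n_bootstrap: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.k <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def integrated_autocorr_time(values: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time in frames (≥ 0.5 means i.i.d.-like).

    Sums the empirical normalised autocorrelation up to its first
    non-positive lag (initial-positive-sequence truncation).
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    n = len(x)
    if max_lag is None:
        max_lag = min(n // 4, 2000)
    var = np.dot(x, x) / n
    if var == 0:
        return 0.5
    tau = 0.5
    for lag in range(1, max_lag):
        rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += rho
    return tau


def _block_widths(values: np.ndarray, model: PopulationModel,
                  block_frames: int) -> np.ndarray:
    """Per-block responsibility-weighted component widths.

    Splits the series into contiguous blocks and computes, for each block
    and component, the width of that component's share of the block under
    the pooled model's posterior responsibilities.  Shape
    (n_blocks, n_components); NaN where a block holds (almost) no mass of
    a component.
    """
    n_blocks = len(values) // block_frames
    resp = model.responsibilities(values[:n_blocks * block_frames])
    widths = np.full((n_blocks, model.n_components), np.nan)
    for b in range(n_blocks):
        sl = slice(b * block_frames, (b + 1) * block_frames)
        r = resp[sl]
        v = values[sl]
        for c in range(model.n_components):
            w = r[:, c]
            wsum = w.sum()
            if wsum < 10.0:  # too little mass for a width estimate
                continue
            mu = np.dot(w, v) / wsum
            widths[b, c] = np.sqrt(np.dot(w, (v - mu) ** 2) / wsum)
    return widths


def estimate_spring_constants(series, model: PopulationModel,
                              temperature: float = DEFAULT_TEMPERATURE_K,
                              n_bootstrap: int = 1000, seed: int = 0,
                              block_frames: int | None = None
                              ) -> list[SpringEstimate]:
    """One spring constant per population, with bootstrap uncertainty.

    The point estimate maps each component's pooled fitted width through
    ``k = k_B·T/σ²``.  Uncertainty comes from ``n_bootstrap`` cycles that
    resample the resampling units — the supplied replicates when two or
    more series are given, otherwise contiguous blocks of ~10× the
    estimated autocorrelation time — recompute the mean component width,
    and map it through the same relation.  The 95% interval is the
    percentile spread of that bootstrap distribution recentred on the
    pooled point estimate, so the interval always brackets it.
    """
    if isinstance(series, DistanceSeries):
        replicates = [np.asarray(series.values, dtype=float)]
    else:
        replicates = [np.asarray(s.values if isinstance(s, DistanceSeries) else s,
                                 dtype=float) for s in series]

    if len(replicates) >= 2:
        unit_widths = np.stack([
            _replicate_widths(rep, model) for rep in replicates])
    else:
        values = replicates[0]
        if block_frames is None:
            tau_frames = integrated_autocorr_time(values)
            block_frames = max(int(round(10 * tau_frames)), 2)
        n_blocks = len(values) // block_frames
        if n_blocks < 10:
            raise ValueError(
                f"uncertainty undefined: single series yields only {n_blocks} "
                f"blocks of {block_frames} frames (need ≥ 10); supply "
                "replicates or a longer series")
        unit_widths = _block_widths(values, model, block_frames)

    rng = np.random.default_rng(seed)
    n_units = len(unit_widths)
    boot_means = np.empty((n_bootstrap, model.n_components))
    for b in range(n_bootstrap):
        pick = rng.integers(0, n_units, size=n_units)
        boot_means[b] = np.nanmean(unit_widths[pick], axis=0)

    estimates = []
    for c in range(model.n_components):
        sigma = float(model.sigmas[c])
        k_hat = spring_constant(sigma, temperature)
        boot_k = KB_PN_NM_PER_K * temperature / (boot_means[:, c] / ANGSTROM_PER_NM) ** 2
        boot_k = boot_k[np.isfinite(boot_k)]
        if len(boot_k) < n_bootstrap // 2:
            raise FitError(
                f"component {c}: too few valid bootstrap cycles "
                f"({len(boot_k)}/{n_bootstrap})")
        lo_q, hi_q = np.percentile(boot_k, [2.5, 97.5])
        centre = float(np.mean(boot_k))
        ci_low = k_hat - (centre - lo_q)
        ci_high = k_hat + (hi_q - centre)
        estimates.append(SpringEstimate(
            k=k_hat, ci_low=min(ci_low, k_hat), ci_high=max(ci_high, k_hat),
            bootstrap_sd=float(np.std(boot_k, ddof=1)), sigma_A=sigma,
            temperature=temperature, component=c, n_bootstrap=n_bootstrap,
            seed=seed))
    return estimates


def _replicate_widths(values: np.ndarray, model: PopulationModel) -> np.ndarray:
    """Responsibility-weighted component widths of one replicate."""
    resp = model.responsibilities(values)
    widths = np.full(model.n_components, np.nan)
    for c in range(model.n_components):
        w = resp[:, c]
        wsum = w.sum()
        if wsum < 10.0:
            continue
        mu = np.dot(w, values) / wsum
        widths[c] = np.sqrt(np.dot(w, (values - mu) ** 2) / wsum)
    return widths


# ---------------------------------------------------------------------------
# relaxation and maximum elastic extension
# ---------------------------------------------------------------------------

@dataclass
class RelaxationVerdict:
    """Did a relaxation trace return to the equilibrium band?"""

    reversible: bool
    final_window_mean: float   # Å
    equilibrium: float         # Å
    band: float                # Å (± tolerance around equilibrium)
    time_to_return_ps: float | None

    def __post_init__(self) -> None:
        inside = abs(self.final_window_mean - self.equilibrium) <= self.band
        if inside != self.reversible:
            raise ValueError("reversible flag inconsistent with final window")


def classify_relaxation(series: DistanceSeries, equilibrium: float,
                        band: float, window_ps: float) -> RelaxationVerdict:
    """Classify a relaxation trace as reversible or not.

    Reversible iff the mean over the final ``window_ps`` lies within
    ``equilibrium ± band``; the time-to-return is the start time of the
    first sliding window whose mean enters the band (0 for a trace that
    starts equilibrated), or None when the trace never returns.
    The band conventionally defaults to one population σ upstream.
    """
    times = series.times
    values = series.values
    span = times[-1] - times[0]
    if window_ps <= 0 or span < 2 * window_ps:
        raise ValueError(
            f"series must cover at least two windows (span {span} ps, "
            f"window {window_ps} ps)")
    dt = float(np.median(np.diff(times)))
    w = max(int(round(window_ps / dt)), 1)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    win_means = (csum[w:] - csum[:-w]) / w  # window starting at index i
    final_mean = float(win_means[-1])
    reversible = abs(final_mean - equilibrium) <= band
    inside = np.abs(win_means - equilibrium) <= band
    first = np.flatnonzero(inside)
    time_to_return = float(times[first[0]] - times[0]) if len(first) else None
    return RelaxationVerdict(reversible=reversible, final_window_mean=final_mean,
                             equilibrium=equilibrium, band=band,
                             time_to_return_ps=time_to_return)


def max_elastic_extension(trials: list[tuple[float, RelaxationVerdict]],
                          equilibrium: float | None = None
                          ) -> tuple[float | None, float | None]:
    """Largest start extension whose relaxation verdict is reversible.

    Returns (extension in Å, ratio to equilibrium length); both are None
    when no trial is reversible.  ``equilibrium`` defaults to the
    equilibrium recorded in the first trial's verdict.
    """
    if not trials:
        raise ValueError("at least one trial required")
    reversible = [start for start, verdict in trials if verdict.reversible]
    if not reversible:
        return None, None
    best = max(reversible)
    if equilibrium is None:
        equilibrium = trials[0][1].equilibrium
    return best, best / equilibrium
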