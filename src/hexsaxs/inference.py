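"""Bayesian parameter estimation for the global H_II scattering model.

The posterior over the 12 model parameters x is

    p(x | I, sigma) ~ p(I | x, sigma) * p(x)

with a uniform (box) prior carrying the molecular constraints (the head
and backbone shells must be large enough to accommodate their molecular
groups, i.e. non-negative shell water counts), and a likelihood in which
the experimental error estimates sigma_i are trusted only up to a global
scale factor eta.  Marginalizing eta with the scale-invariant Jeffreys
prior p(eta) ~ 1/eta turns the Gaussian likelihood into

    ln p(I | x) = const - (N_q / 2) ln chi^2(x),
    chi^2(x) = sum_i (I_i^obs - I(q_i; x))^2 / sigma_i^2 .

Sampling uses a random-walk Metropolis-Hastings chain (Gaussian proposals
per parameter, +-1 integer walk for the ring count n, log-space walk for
the scale Gamma), with burn-in discard, thinning by the integrated
autocorrelation time of chi^2, and posterior summaries (means, standard
deviations, the minimum-chi^2 MAP sample, 2D marginal histograms).  An
explicit-eta mode that samples the error scale alongside x is provided as
a cross-check; both modes target the same marginal posterior for x.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .composition import ConstraintError, LipidSpec, load_lipid
from .scattering import (
    PARAM_NAMES,
    ForwardModel,
    ModelParams,
    QuadratureSettings,
)

__all__ = [
    "PriorBounds",
    "FitConfig",
    "PosteriorChain",
    "FitSummary",
    "log_prior",
    "chi_squared",
    "log_likelihood_marginal",
    "log_likelihood_scaled",
    "mh_step",
    "MetropolisHastings",
    "run_chain",
    "summarize",
    "integrated_autocorr_time",
]

log = logging.getLogger(__name__)

_CHI2_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

#: Default prior boxes.  They span the structural ranges reported for
#: PE H_II phases with wide margins; Gamma is log-uniform inside its box.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Delta": (0.0, 100.0),
    "n": (1, 30),
    "sigma_fluc": (0.0, 10.0),
    "C0": (-0.1, -0.001),
    "d_H": (0.1, 15.0),
    "d_BB": (0.1, 15.0),
    "V_lipid": (800.0, 1600.0),
    "c_lam": (0.0, 1.0),
    "A_L": (40.0, 120.0),
    "n_W_lam": (0.0, 30.0),
    "Gamma": (1e-8, 1e4),
    "I_inc": (0.0, 1e4),
}


@dataclass(frozen=True)
class PriorBounds:
    """Per-parameter uniform box constraints (min, max)."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")
        if self.bounds["Gamma"][0] <= 0:
            raise ValueError("Gamma bounds must be positive (log-uniform box)")

    def replace(self, **kw) -> "PriorBounds":
        b = dict(self.bounds)
        b.update(kw)
        return PriorBounds(b)

    def in_box(self, p: ModelParams) -> bool:
        return all(
            self.bounds[k][0] <= getattr(p, k) <= self.bounds[k][1]
            for k in PARAM_NAMES
        )

    def midpoint(self) -> ModelParams:
        kw = {k: 0.5 * (lo + hi) for k, (lo, hi) in self.bounds.items()}
        kw["Gamma"] = math.sqrt(
            self.bounds["Gamma"][0] * self.bounds["Gamma"][1]
        )  # geometric midpoint of the log-uniform box
        kw["n"] = int(round(kw["n"]))
        return ModelParams(**kw)


def log_prior(
    p: ModelParams,
    bounds: PriorBounds,
    lipid: LipidSpec,
    a: float,
) -> float:
    """Log prior density (up to a constant); -inf outside the support.

    The support requires every parameter inside its box AND a valid wedge
    geometry: ordered radii, positive water core, and head/backbone shells
    large enough for their molecular groups (non-negative shell water).
    Gamma carries a log-uniform density inside its box.
    """
    if not bounds.in_box(p):
        return -math.inf
    try:
        from .composition import build_wedge

        build_wedge(p.C0, p.d_H, p.d_BB, p.V_lipid, a, lipid)
    except ConstraintError:
        return -math.inf
    return -math.log(p.Gamma)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def chi_squared(intensity_model, intensity_obs, sigma) -> float:
    """chi^2 = sum_i (I_i^obs - I_i^mod)^2 / sigma_i^2."""
    r = (np.asarray(intensity_obs) - np.asarray(intensity_model)) / np.asarray(sigma)
    return float(np.dot(r, r))


def log_likelihood_marginal(chi2: float, n_q: int, sigma=None) -> float:
    """Error-scale-marginalized Gaussian log likelihood.

    Integrating the Gaussian likelihood with true errors eta*sigma_i over
    eta with the Jeffreys prior 1/eta gives

        ln p(I | x) = -(N_q/2) ln(pi chi^2) + ln Gamma(N_q/2)
                      - ln 2 - sum_i ln sigma_i ,

    a function of x only through chi^2.  ``sigma`` may be omitted, in
    which case the x-independent ``-sum ln sigma`` term is dropped.
    chi^2 = 0 (an exact fit) is guarded by a floor, with a warning.
    """
    if n_q <= 2:
        raise ValueError("need more than 2 data points")
    if chi2 < 0:
        raise ValueError("chi^2 must be non-negative")
    if chi2 < _CHI2_FLOOR:
        log.warning("chi^2 = 0 (exact fit); capping marginal log-likelihood")
        chi2 = _CHI2_FLOOR
    out = (
        -0.5 * n_q * math.log(math.pi * chi2)
        + gammaln(0.5 * n_q)
        - math.log(2.0)
    )
    if sigma is not None:
        out -= float(np.sum(np.log(np.asarray(sigma))))
    return out


def log_likelihood_scaled(chi2: float, n_q: int, eta: float, sigma=None) -> float:
    """Gaussian log likelihood with explicit error scale eta.

    ``ln p(I | x, eta) = -N ln eta - chi^2/(2 eta^2) + const``; used by the
    explicit-eta sampling mode (eta then carries the Jeffreys prior).
    """
    if eta <= 0:
        return -math.inf
    out = (
        -n_q * math.log(eta)
        - 0.5 * chi2 / eta**2
        - 0.5 * n_q * math.log(2.0 * math.pi)
    )
    if sigma is not None:
        out -= float(np.sum(np.log(np.asarray(sigma))))
    return out


# ---------------------------------------------------------------------------
# Metropolis-Hastings
# ---------------------------------------------------------------------------


def mh_step(
    state: np.ndarray,
    log_post: Callable[[np.ndarray], float],
    widths: np.ndarray,
    rng: np.random.Generator,
    *,
    current_lp: float | None = None,
    integer_dims: Sequence[int] = (),
    integer_prob: float = 0.3,
) -> tuple[np.ndarray, float, bool]:
    """One Metropolis-Hastings update with symmetric random-walk proposals.

    Continuous dimensions receive Gaussian perturbations of the given
    widths; ``integer_dims`` receive a +-1 step with probability
    ``integer_prob`` (otherwise unchanged).  Returns
    ``(state, log_posterior, accepted)``; a rejected proposal repeats the
    old state.
    """
    state = np.asarray(state, dtype=float)
    if current_lp is None:
        current_lp = log_post(state)
    prop = state + widths * rng.standard_normal(state.size)
    for d in integer_dims:
        move = rng.random() < integer_prob
        prop[d] = state[d] + (rng.integers(0, 2) * 2 - 1) * move
    lp = log_post(prop)
    if lp - current_lp >= 0 or rng.random() < math.exp(lp - current_lp):
        return prop, lp, True
    return state, current_lp, False


class MetropolisHastings:
    """Random-walk MH sampler over a vector state.

    Two update modes: ``"scan"`` (default, used for fitting) updates one
    randomly chosen parameter per step — robust when posterior widths
    differ by orders of magnitude between parameters and allows
    per-parameter width adaptation; ``"joint"`` perturbs all parameters at
    once.  The model-specific structure (parameter transforms, priors,
    constraints) lives entirely in the ``log_post`` callable; this class
    only walks, records and tunes.
    """

    def __init__(
        self,
        log_post: Callable[[np.ndarray], float],
        x0: np.ndarray,
        widths: np.ndarray,
        seed: int,
        integer_dims: Sequence[int] = (),
        mode: str = "scan",
    ):
        if mode not in ("scan", "joint"):
            raise ValueError(f"unknown sampler mode {mode!r}")
        self.log_post = log_post
        self.state = np.asarray(x0, dtype=float).copy()
        self.widths = np.asarray(widths, dtype=float).copy()
        self.rng = np.random.default_rng(seed)
        self.integer_dims = tuple(integer_dims)
        self.mode = mode
        # dimensions eligible for scan updates
        self.active = [
            d
            for d in range(self.state.size)
            if self.widths[d] > 0 or d in self.integer_dims
        ]
        if not self.active:
            raise ValueError("no free parameters to sample")
        self.lp = log_post(self.state)
        if not np.isfinite(self.lp):
            raise ValueError("initial state has zero posterior probability")
        self._prop = np.zeros(self.state.size, dtype=int)
        self._acc = np.zeros(self.state.size, dtype=int)
        self._chol: np.ndarray | None = None
        self._chol_dims: list[int] = []
        self.joint_prob = 0.5

    def set_joint_covariance(self, cov: np.ndarray, dims: Sequence[int]) -> None:
        """Enable correlated joint proposals over the given dimensions.

        ``cov`` is a pilot-run estimate of the posterior covariance of the
        continuous dimensions ``dims``; scan steps are then mixed with
        joint moves ``x += (2.38/sqrt(d)) L z`` (L the Cholesky factor),
        which follow the posterior's correlation ridges.  The kernel is
        fixed from this point on, so detailed balance is preserved.
        """
        dims = list(dims)
        cov = np.asarray(cov, dtype=float)
        jitter = 1e-12 * np.trace(cov) / len(dims) + 1e-300
        self._chol = np.linalg.cholesky(cov + jitter * np.eye(len(dims)))
        self._chol_dims = dims

    def _scan_step(self) -> bool:
        if self._chol is not None and self.rng.random() < self.joint_prob:
            prop = self.state.copy()
            z = self.rng.standard_normal(len(self._chol_dims))
            step = (2.38 / math.sqrt(len(self._chol_dims))) * (self._chol @ z)
            prop[self._chol_dims] += step
            d = -1  # bookkeeping slot for joint moves not tracked per-dim
        else:
            d = self.active[self.rng.integers(len(self.active))]
            prop = self.state.copy()
            if d in self.integer_dims:
                prop[d] = self.state[d] + (self.rng.integers(0, 2) * 2 - 1)
            else:
                prop[d] = self.state[d] + self.widths[d] * self.rng.standard_normal()
        lp = self.log_post(prop)
        if d >= 0:
            self._prop[d] += 1
        if lp - self.lp >= 0 or self.rng.random() < math.exp(lp - self.lp):
            self.state, self.lp = prop, lp
            if d >= 0:
                self._acc[d] += 1
            return True
        return False

    def run(self, n_steps: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Run ``n_steps`` updates; returns (states, log_posts, accept_rate)."""
        states = np.empty((n_steps, self.state.size))
        lps = np.empty(n_steps)
        accepted = 0
        for i in range(n_steps):
            if self.mode == "scan":
                acc = self._scan_step()
            else:
                self.state, self.lp, acc = mh_step(
                    self.state,
                    self.log_post,
                    self.widths,
                    self.rng,
                    current_lp=self.lp,
                    integer_dims=self.integer_dims,
                )
            accepted += acc
            states[i] = self.state
            lps[i] = self.lp
        return states, lps, accepted / max(n_steps, 1)

    def tune(
        self,
        n_steps: int,
        *,
        block: int = 400,
        target: tuple[float, float] = (0.2, 0.4),
    ) -> None:
        """Adapt proposal widths toward the target acceptance window.

        In scan mode each parameter's width adapts to its own acceptance
        fraction; in joint mode a global scale is adapted.  Tuning samples
        are discarded by the caller (they precede burn-in).
        """
        for _ in range(max(n_steps // block, 1)):
            self._prop[:] = 0
            self._acc[:] = 0
            _, _, rate = self.run(block)
            if self.mode == "joint":
                if rate < target[0]:
                    self.widths *= 0.7
                elif rate > target[1]:
                    self.widths *= 1.4
                continue
            for d in self.active:
                if d in self.integer_dims or self._prop[d] < 5:
                    continue
                r = self._acc[d] / self._prop[d]
                if r < target[0]:
                    self.widths[d] *= max(0.4, r / 0.3 + 0.1)
                elif r > target[1]:
                    self.widths[d] *= min(3.0, r / 0.3)


def integrated_autocorr_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time with a Sokal self-consistent window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return 1.0
    f = np.fft.rfft(x - x.mean(), n=2 * n)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    acf /= acf[0]
    tau = 2.0 * np.cumsum(acf) - 1.0
    window = np.arange(n) < c * tau
    idx = np.argmin(window) if not window.all() else n - 1
    return float(max(tau[idx], 1.0))


# ---------------------------------------------------------------------------
# chain container and fit driver
# ---------------------------------------------------------------------------


@dataclass
class PosteriorChain:
    """Thinned, equilibrated MCMC sample of the model posterior.

    ``samples`` has one column per model parameter (plus ``eta`` in the
    explicit-eta mode); ``chi2`` holds the cost function of every stored
    state.  Bookkeeping fields record what was discarded and how.
    """

    samples: pd.DataFrame
    chi2: np.ndarray
    acceptance_rate: float
    burn_in: int
    thinning: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.chi2):
            raise ValueError("samples and chi2 length mismatch")
        if np.any(self.chi2 < 0):
            raise ValueError("chi^2 must be non-negative")

    def __len__(self) -> int:
        return len(self.samples)

    def params(self, i: int) -> ModelParams:
        row = self.samples.iloc[i]
        return ModelParams(**{k: row[k] for k in PARAM_NAMES})

    def save(self, path: str | Path) -> None:
        """Write the chain as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        df = self.samples.copy()
        df["chi2"] = self.chi2
        df.to_csv(path, index=False)
        sidecar = {
            "acceptance_rate": self.acceptance_rate,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "seed": self.seed,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, default=float)
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorChain":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        chi2 = df.pop("chi2").to_numpy()
        return cls(samples=df, chi2=chi2, **sidecar)


@dataclass(frozen=True)
class FitConfig:
    """Sampler and model configuration of one fit.

    ``a`` may be omitted if the data carry the lattice parameter in their
    metadata.  ``proposal_frac`` sets the per-parameter random-walk width
    as a fraction of the prior-box width (Gamma: of the log-box width).
    ``fixed`` pins parameters at their ``x0`` value (no proposals).
    """

    lipid: str | LipidSpec = "DOPE"
    a: float | None = None
    L: float = 2500.0
    n_steps: int = 20_000
    burn_in_frac: float = 0.2
    seed: int = 0
    x0: ModelParams | None = None
    proposal_frac: float = 0.02
    tune_steps: int = 3_000
    pilot_steps: int = 4_000
    cov_rounds: int = 2
    auto_background_bound: bool = True
    thin: int | str = "auto"
    explicit_eta: bool = False
    fixed: tuple[str, ...] = ()
    settings: QuadratureSettings = field(default_factory=QuadratureSettings)
    bounds: PriorBounds = field(default_factory=PriorBounds)

    def __post_init__(self) -> None:
        if not 0.1 <= self.burn_in_frac <= 0.2:
            raise ValueError("burn-in fraction should lie in [0.1, 0.2]")
        for name in self.fixed:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown fixed parameter {name!r}")


_GAMMA_IDX = PARAM_NAMES.index("Gamma")
_N_IDX = PARAM_NAMES.index("n")


def _to_state(p: ModelParams) -> np.ndarray:
    x = p.as_array()
    x[_GAMMA_IDX] = math.log(x[_GAMMA_IDX])
    return x


def _from_state(x: np.ndarray) -> ModelParams:
    x = np.array(x, dtype=float)
    x[_GAMMA_IDX] = math.exp(x[_GAMMA_IDX])
    return ModelParams.from_array(x)


def run_chain(data, config: FitConfig) -> PosteriorChain:
    """Sample the posterior of the 12 model parameters for one pattern.

    ``data`` is a :class:`hexsaxs.io.ScatteringPattern` (or anything with
    ``q``, ``intensity``, ``sigma`` arrays and a ``meta`` mapping).  The
    state is the parameter vector with Gamma in log space (its log-uniform
    prior is then flat); ``n`` performs a +-1 integer walk.  The chain is
    tuned (discarded), burned in (discarded) and thinned by the integrated
    autocorrelation time of chi^2.  Non-finite model evaluations reject
    the proposed state and are logged, never fatal.
    """
    q = np.asarray(data.q, dtype=float)
    i_obs = np.asarray(data.intensity, dtype=float)
    sigma = np.asarray(data.sigma, dtype=float)
    if q.size <= 2:
        raise ValueError("need more than 2 data points")
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be positive")
    lipid = (
        config.lipid
        if isinstance(config.lipid, LipidSpec)
        else load_lipid(config.lipid)
    )
    a = config.a if config.a is not None else data.meta.get("a")
    if a is None:
        raise ValueError("lattice parameter 'a' not in config nor data metadata")
    model = ForwardModel(q, float(a), lipid, config.settings, L=config.L)
    bounds = config.bounds
    if config.auto_background_bound and "I_inc" not in config.fixed:
        # the incoherent background cannot exceed the measured signal;
        # a data-scaled box keeps proposals commensurate with the pattern
        bounds = bounds.replace(I_inc=(0.0, float(np.max(i_obs))))
    n_q = q.size

    # chi^2 per visited parameter vector; also serves to recover chi^2 of
    # every stored state after the run without re-evaluating the model
    chi2_cache: dict[bytes, float] = {}

    def chi2_of(p: ModelParams) -> float:
        try:
            i_mod = model.total_intensity(p)
        except ConstraintError:
            return math.inf
        if not np.all(np.isfinite(i_mod)):
            log.warning("non-finite model intensity; rejecting state")
            return math.inf
        return chi_squared(i_mod, i_obs, sigma)

    explicit = config.explicit_eta

    def chi2_of_state(x: np.ndarray) -> float:
        key = x[: len(PARAM_NAMES)].tobytes()
        if key not in chi2_cache:
            chi2_cache[key] = chi2_of(_from_state(x[: len(PARAM_NAMES)]))
        return chi2_cache[key]

    def log_post(x: np.ndarray) -> float:
        p = _from_state(x[:-1] if explicit else x)
        lp = log_prior(p, bounds, lipid, float(a))
        if not np.isfinite(lp):
            return -math.inf
        chi2 = chi2_of_state(x)
        if not np.isfinite(chi2):
            return -math.inf
        if explicit:
            # state carries ln(eta); Jeffreys prior is flat in ln(eta)
            return lp + log_likelihood_scaled(chi2, n_q, math.exp(x[-1]))
        return lp + log_likelihood_marginal(chi2, n_q)

    x0_params = config.x0 if config.x0 is not None else bounds.midpoint()
    x0 = _to_state(x0_params)
    widths = np.array(
        [
            (
                math.log(bounds.bounds[k][1] / bounds.bounds[k][0])
                if k == "Gamma"
                else bounds.bounds[k][1] - bounds.bounds[k][0]
            )
            * config.proposal_frac
            for k in PARAM_NAMES
        ]
    )
    widths[_N_IDX] = 0.0  # integer walk handled separately
    integer_dims = [] if "n" in config.fixed else [_N_IDX]
    for name in config.fixed:
        widths[PARAM_NAMES.index(name)] = 0.0
    if explicit:
        x0 = np.append(x0, 0.0)  # ln(eta) = 0
        widths = np.append(widths, 0.1)

    sampler = MetropolisHastings(
        log_post, x0, widths, config.seed, integer_dims=integer_dims
    )
    # adaptation phases (all discarded): per-parameter width tuning, then a
    # pilot run whose sample covariance drives correlated joint proposals
    if config.tune_steps > 0:
        sampler.tune(config.tune_steps)
    if config.pilot_steps >= 100:
        cont = [d for d in sampler.active if d not in sampler.integer_dims]
        history = np.empty((0, len(cont)))
        for _ in range(max(config.cov_rounds, 1)):
            pilot, _, _ = sampler.run(config.pilot_steps)
            history = np.vstack([history, pilot[:, cont]])
            if len(cont) < 2:
                continue
            cov = np.cov(history, rowvar=False)
            if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
                sampler.set_joint_covariance(cov, cont)
    states, _, accept = sampler.run(config.n_steps)

    burn = int(round(config.burn_in_frac * config.n_steps))
    kept = states[burn:]
    if kept.shape[0] == 0:
        raise ValueError("no samples left after burn-in")
    chi2_kept = np.array([chi2_of_state(s) for s in kept])
    if config.thin == "auto":
        # thin by the slowest of chi^2 and the parameter series
        taus = [integrated_autocorr_time(chi2_kept)]
        for d in sampler.active:
            if d not in sampler.integer_dims:
                taus.append(integrated_autocorr_time(kept[:, d]))
        thin = max(1, int(round(max(taus))))
    else:
        thin = max(1, int(config.thin))
    kept = kept[::thin]
    chi2_kept = chi2_kept[::thin]

    cols = {}
    for j, name in enumerate(PARAM_NAMES):
        vals = kept[:, j]
        cols[name] = np.exp(vals) if name == "Gamma" else vals
    if explicit:
        cols["eta"] = np.exp(kept[:, -1])
    df = pd.DataFrame(cols)
    return PosteriorChain(
        samples=df,
        chi2=chi2_kept,
        acceptance_rate=accept,
        burn_in=burn,
        thinning=thin,
        seed=config.seed,
        meta={
            "a": float(a),
            "lipid": lipid.name,
            "n_steps": config.n_steps,
            "explicit_eta": explicit,
            "n_q": int(n_q),
        },
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class FitSummary:
    """Posterior expectation values, spreads and the MAP sample."""

    expectation: pd.Series
    std: pd.Series
    map_params: ModelParams
    map_chi2: float
    n_samples: int
    _chain: PosteriorChain | None = None

    def marginal_2d(
        self, name_i: str, name_j: str, bins: int = 40
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """2D marginal posterior histogram (density) of a parameter pair."""
        if self._chain is None:
            raise ValueError("summary detached from its chain")
        xi = self._chain.samples[name_i].to_numpy()
        xj = self._chain.samples[name_j].to_numpy()
        return np.histogram2d(xi, xj, bins=bins, density=True)

    def correlation(self, name_i: str, name_j: str) -> float:
        """Posterior Pearson correlation of a parameter pair."""
        if self._chain is None:
            raise ValueError("summary detached from its chain")
        return float(
            np.corrcoef(
                self._chain.samples[name_i], self._chain.samples[name_j]
            )[0, 1]
        )

    def to_dict(self) -> dict:
        return {
            "expectation": self.expectation.to_dict(),
            "std": self.std.to_dict(),
            "map": {k: getattr(self.map_params, k) for k in PARAM_NAMES},
            "map_chi2": self.map_chi2,
            "n_samples": self.n_samples,
        }


def summarize(chain: PosteriorChain) -> FitSummary:
    """Posterior means, standard deviations and the minimum-chi^2 sample.

    The MAP solution is reported as the stored sample with the lowest
    chi^2 (no separate optimization).
    """
    if len(chain) < 2:
        raise ValueError("need at least 2 uncorrelated samples to summarize")
    i_map = int(np.argmin(chain.chi2))
    return FitSummary(
        expectation=chain.samples.mean(),
        std=chain.samples.std(ddof=1),
        map_params=chain.params(i_map),
        map_chi2=float(chain.chi2[i_map]),
        n_samples=len(chain),
        _chain=chain,
    )
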