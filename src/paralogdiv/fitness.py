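"""Parabolic fitness landscapes for expression optima, with and without
precision-economy constraints.

Model
-----
Each gene carries a parabolic fitness function of protein abundance,

    W(p) = mu + a (p - p_opt)**2,        a = -mu * Q / 2,

with vertex (p_opt, mu): fitness equals the maximal growth rate at the
abundance optimum and decays quadratically away from it.  Q (the noise
sensitivity) is the curvature of W relative to its height, per squared
absolute protein deviation; a large Q means a narrow parabola and sharp
fitness loss from abundance fluctuations.  In standard form W = a p**2 +
b p + c with b = -2 a p_opt and c = mu + a p_opt**2.

After duplication the pair is selected on cumulative abundance
p_tot = p1 + p2 with the optimum displaced to delta_opt * p_opt
(delta_opt = 1.87 by default; see ``minimal_delta_opt`` for its
derivation); Q and mu are unchanged.

The *minimal* model evaluates W at the mean cumulative abundance.  The
*precision-economy* model evaluates the populational mean of W over the
stochastic abundance distribution (mean P_tot, variance sigma_tot^2) and
subtracts a linear transcription cost:

    F = a (sigma_tot^2 + P_tot^2) + b P_tot + c  -  l_m c_m (bm1 + bm2).

Because W is quadratic this expectation is exact.  The pair noise variance
sums the intrinsic fluctuations of the two copies and adds a coherent
extrinsic noise floor (see ``pair_noise_variance``); for two identical
copies it reduces to the singleton formula at the summed transcription
rate, while for diverged copies it is smallest when each copy's
transcription tracks its expression share — the lever through which the
precision-economy trade-off biases divergence toward transcription.

Q links to the rates through the transcription cost scale:

    Q = c_m * alpha_m * l_m * (beta_m / beta_p),

which inverts to the precision-economy optimal ratio beta_p / beta_m =
c_m alpha_m l_m / Q: noise-sensitive genes are pushed toward
transcription-heavy expression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq, differential_evolution, minimize

from .rates import Constants, DEFAULT_CONSTANTS, protein_abundance

__all__ = [
    "FitnessFunction",
    "PairState",
    "build_fitness_function",
    "duplicate_fitness_function",
    "singleton_noise_variance",
    "pair_noise_variance",
    "transcription_cost",
    "expected_fitness",
    "infer_q",
    "optimal_ratio_from_q",
    "optimal_rates_minimal",
    "optimal_rates_precision_economy",
    "noise_load",
    "max_admissible_popt",
    "minimal_delta_opt",
    "curvature_filter",
]

Model = Literal["minimal", "precision_economy"]


@dataclass(frozen=True)
class FitnessFunction:
    """Parabola W(p) = mu + a (p - optimum)^2 with optimum p_opt (ancestral)
    or delta_opt * p_opt (post-duplication)."""

    p_opt: float
    mu: float = DEFAULT_CONSTANTS.mu
    q: float = DEFAULT_CONSTANTS.q_max / 10
    post_dup: bool = False
    delta_opt: float = DEFAULT_CONSTANTS.delta_opt

    @property
    def optimum(self) -> float:
        return self.p_opt * self.delta_opt if self.post_dup else self.p_opt

    @property
    def a(self) -> float:
        return -self.mu * self.q / 2.0

    @property
    def b(self) -> float:
        return -2.0 * self.a * self.optimum

    @property
    def c(self) -> float:
        return self.mu + self.a * self.optimum ** 2

    def __call__(self, p):
        p = np.asarray(p, dtype=float)
        out = self.mu + self.a * (p - self.optimum) ** 2
        return float(out) if out.ndim == 0 else out


def build_fitness_function(p_opt: float, q: float, mu: float = DEFAULT_CONSTANTS.mu,
                           constants: Constants = DEFAULT_CONSTANTS) -> FitnessFunction:
    if p_opt <= 0 or mu <= 0:
        raise ValueError("p_opt and mu must be strictly positive")
    if not 0 < q <= constants.q_max:
        raise ValueError(f"Q must lie in (0, {constants.q_max}]")
    return FitnessFunction(p_opt=p_opt, mu=mu, q=q, delta_opt=constants.delta_opt)


def duplicate_fitness_function(f: FitnessFunction,
                               delta_opt: float | None = None) -> FitnessFunction:
    """Shift the optimum to delta_opt * p_opt for a fresh duplicate pair;
    Q and mu are unchanged.  Applying this twice is an error."""
    if f.post_dup:
        raise ValueError("fitness function is already post-duplication")
    kwargs = {"post_dup": True}
    if delta_opt is not None:
        kwargs["delta_opt"] = delta_opt
    return replace(f, **kwargs)


@dataclass
class PairState:
    """Evolving rates of one duplicate pair plus its fitness function."""

    bm1: float
    bp1: float
    bm2: float
    bp2: float
    fitness_fn: FitnessFunction
    constants: Constants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if min(self.bm1, self.bp1, self.bm2, self.bp2) <= 0:
            raise ValueError("pair rates must be strictly positive")

    @property
    def p1(self) -> float:
        c = self.constants
        return protein_abundance(self.bm1, self.bp1, c.alpha_m, c.alpha_p)

    @property
    def p2(self) -> float:
        c = self.constants
        return protein_abundance(self.bm2, self.bp2, c.alpha_m, c.alpha_p)

    @property
    def p_tot(self) -> float:
        return self.p1 + self.p2

    @property
    def bm_tot(self) -> float:
        return self.bm1 + self.bm2

    @property
    def sigma_tot2(self) -> float:
        return pair_noise_variance(self.p1, self.p2, self.bm1, self.bm2,
                                   self.constants)

    @property
    def cost(self) -> float:
        return transcription_cost(self.bm1, self.bm2, self.constants)


# ---------------------------------------------------------------------------
# Noise, cost, expected fitness
# ---------------------------------------------------------------------------

def singleton_noise_variance(p, beta_m, cv0: float = DEFAULT_CONSTANTS.cv0,
                             alpha_p: float = DEFAULT_CONSTANTS.alpha_p):
    """Protein-abundance variance of a singleton across an isogenic
    population: sigma^2 = p^2 (1/p + alpha_p/beta_m + cv0^2).

    The three terms are protein-number (Poisson) noise, mRNA-fluctuation
    noise (smaller when expression is transcription-heavy), and the
    empirical noise floor cv0.
    """
    p = np.asarray(p, dtype=float)
    beta_m = np.asarray(beta_m, dtype=float)
    if np.any(p <= 0) or np.any(beta_m <= 0):
        raise ValueError("abundance and transcription rate must be strictly positive")
    out = p ** 2 * (1.0 / p + alpha_p / beta_m + cv0 ** 2)
    return float(out) if out.ndim == 0 else out


def pair_noise_variance(p1, p2, bm1, bm2,
                        constants: Constants = DEFAULT_CONSTANTS):
    """Variance of the cumulative abundance of a duplicate pair.

    Intrinsic fluctuations of the two copies (protein-number noise and
    mRNA-number noise) are independent and sum; the noise floor is
    extrinsic cell-state noise, coherent across co-expressed copies, so
    its standard deviations add:

        sigma_tot^2 = P_tot + alpha_p (p1^2/bm1 + p2^2/bm2)
                      + cv0^2 P_tot^2.

    For two identical copies this reduces to the singleton formula
    evaluated at (P_tot, bm1+bm2) — a pair of equal duplicates is
    indistinguishable from one gene transcribed at the summed rate.  For
    unequal copies the mRNA term depends on how transcription is
    allocated: noise is smallest when each copy's transcription tracks
    its share of expression, which couples expression divergence to
    transcriptional divergence.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    bm1 = np.asarray(bm1, dtype=float)
    bm2 = np.asarray(bm2, dtype=float)
    if np.any(p1 <= 0) or np.any(p2 <= 0) or np.any(bm1 <= 0) or np.any(bm2 <= 0):
        raise ValueError("pair abundances and transcription rates must be positive")
    p_tot = p1 + p2
    out = (p_tot + constants.alpha_p * (p1 ** 2 / bm1 + p2 ** 2 / bm2)
           + constants.cv0 ** 2 * p_tot ** 2)
    return float(out) if out.ndim == 0 else out


def transcription_cost(bm1, bm2, constants: Constants = DEFAULT_CONSTANTS):
    """Fitness penalty C = l_m * c_m * (bm1 + bm2), in 1/h; linear in the
    total nucleotide synthesis of the pair."""
    bm1 = np.asarray(bm1, dtype=float)
    bm2 = np.asarray(bm2, dtype=float)
    if np.any(bm1 < 0) or np.any(bm2 < 0):
        raise ValueError("transcription rates cannot be negative")
    out = constants.l_m * constants.c_m * (bm1 + bm2)
    return float(out) if out.ndim == 0 else out


def expected_fitness(state: PairState, model: Model = "precision_economy") -> float:
    """Populational fitness F of a pair (in 1/h, unscaled).

    minimal: F = W(P_tot) — deterministic, no noise, no cost.
    precision_economy: F = a (sigma_tot^2 + P_tot^2) + b P_tot + c - C,
    the exact mean of the quadratic W over the noisy abundance minus the
    transcription cost.
    """
    f = state.fitness_fn
    p_tot = state.p_tot
    if model == "minimal":
        return float(f(p_tot))
    if model == "precision_economy":
        s2 = state.sigma_tot2
        return float(f.a * (s2 + p_tot ** 2) + f.b * p_tot + f.c - state.cost)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Q and optimal rates
# ---------------------------------------------------------------------------

QConvention = Literal["balance", "optimality"]


def _opt_coef(constants: Constants) -> float:
    """2 l_m c_m / (mu alpha_p): prefactor of the optimality convention."""
    return 2.0 * constants.l_m * constants.c_m / (constants.mu * constants.alpha_p)


def infer_q(beta_m, beta_p, constants: Constants = DEFAULT_CONSTANTS,
            convention: QConvention = "balance"):
    """Noise sensitivity of a gene from its observed rates.

    Two interchangeable arrangements link Q to the rate balance; both
    invert to a rate construction (``optimal_rates_minimal``) and both
    make transcription-heavy genes the noise-sensitive ones:

    'balance' (default): Q = c_m alpha_m l_m * (bm / bp) — the empirical
    square-root rate law of the trade-off framework (at fixed Q the
    implied bm scales as sqrt(p)); used by the admissibility envelope and
    the post-duplication optimum derivation.

    'optimality': Q = 2 l_m c_m bm^2 / (mu alpha_p p^2), the curvature for
    which the observed rates exactly maximize the precision-economy
    fitness of this package (noise gain vs transcription cost); used to
    build the Q distribution driving the evolutionary simulations, where
    it keeps typical fitness functions soft enough for sequential
    fixation to explore the landscape.
    """
    beta_m = np.asarray(beta_m, dtype=float)
    beta_p = np.asarray(beta_p, dtype=float)
    if np.any(beta_m <= 0) or np.any(beta_p <= 0):
        raise ValueError("rates must be strictly positive")
    if convention == "balance":
        out = constants.q_scale * beta_m / beta_p
    elif convention == "optimality":
        p = beta_m * beta_p / (constants.alpha_m * constants.alpha_p)
        out = _opt_coef(constants) * beta_m ** 2 / p ** 2
    else:
        raise ValueError(f"unknown Q convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def optimal_ratio_from_q(q, constants: Constants = DEFAULT_CONSTANTS,
                         p_opt=None, convention: QConvention = "balance"):
    """Optimal beta_p / beta_m ratio for sensitivity q (the 'optimality'
    convention needs the abundance optimum as well)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Q must be strictly positive")
    if convention == "balance":
        out = constants.q_scale / q
    elif convention == "optimality":
        if p_opt is None:
            raise ValueError("optimality convention needs p_opt")
        bm, bp = optimal_rates_minimal(p_opt, q, constants, convention)
        out = np.asarray(bp / bm, dtype=float)
    else:
        raise ValueError(f"unknown Q convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def optimal_rates_minimal(p_opt, q, constants: Constants = DEFAULT_CONSTANTS,
                          convention: QConvention = "balance"):
    """The unique (beta_m, beta_p) with the Q-optimal balance and abundance
    p_opt (bm * bp = p_opt * alpha_m * alpha_p)."""
    p_opt = np.asarray(p_opt, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(p_opt <= 0) or np.any(q <= 0):
        raise ValueError("p_opt and Q must be strictly positive")
    prod = p_opt * constants.alpha_m * constants.alpha_p
    if convention == "balance":
        ratio = constants.q_scale / q            # bp / bm
        bm = np.sqrt(prod / ratio)
    elif convention == "optimality":
        bm = p_opt * np.sqrt(q / _opt_coef(constants))
    else:
        raise ValueError(f"unknown Q convention {convention!r}")
    bp = prod / bm
    if bm.ndim == 0:
        return float(bm), float(bp)
    return bm, bp


def _singleton_pe_fitness(log_rates: np.ndarray, f: FitnessFunction,
                          constants: Constants) -> np.ndarray:
    """Precision-economy fitness of a singleton, vectorized over columns of
    (2, n) log-rate arrays (log parameterization keeps rates positive)."""
    bm = np.exp(log_rates[0])
    bp = np.exp(log_rates[1])
    p = bm * bp / (constants.alpha_m * constants.alpha_p)
    s2 = p ** 2 * (1.0 / p + constants.alpha_p / bm + constants.cv0 ** 2)
    w = f.a * (s2 + p ** 2) + f.b * p + f.c
    return w - constants.l_m * constants.c_m * bm


def optimal_rates_precision_economy(f: FitnessFunction,
                                    bm_max: float = 1e5, bp_max: float = 1e6,
                                    seed: int | np.random.Generator | None = None,
                                    constants: Constants = DEFAULT_CONSTANTS,
                                    ) -> tuple[float, float, float]:
    """Globally maximize singleton precision-economy fitness over a bounded
    rate box with differential evolution, then polish.

    The search runs in log-rate space.  The polished optimum is compared
    with a local refinement started from the closed-form (Eq-13-ratio)
    rates, and the better of the two is returned, so the result can never
    fall below the minimal-model construction.

    Returns (beta_m, beta_p, fitness).
    """
    if f.post_dup:
        raise ValueError("ancestral (singleton) fitness function required")
    rng = np.random.default_rng(seed)
    bounds = [(np.log(1e-3), np.log(bm_max)), (np.log(1e-3), np.log(bp_max))]

    def neg_scalar(x):
        return float(-_singleton_pe_fitness(np.asarray(x)[:, None], f, constants)[0])

    res = differential_evolution(
        lambda x: -_singleton_pe_fitness(x if x.ndim == 2 else x[:, None], f, constants),
        bounds=bounds, seed=rng, vectorized=True, updating="deferred",
        maxiter=150, tol=1e-12, polish=False)
    best_x, best_val = res.x, float(res.fun)
    # polish from DE optimum and from the closed-form seed
    seeds = [best_x]
    bm0, bp0 = optimal_rates_minimal(f.p_opt, f.q, constants, "optimality")
    seeds.append(np.log(np.clip([bm0, bp0], 1e-3, [bm_max, bp_max])))
    for x0 in seeds:
        loc = minimize(neg_scalar, x0=x0, bounds=bounds, method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        if loc.fun < best_val:
            best_x, best_val = loc.x, float(loc.fun)
    bm, bp = np.exp(best_x)
    return float(bm), float(bp), -best_val


# ---------------------------------------------------------------------------
# Admissibility, post-duplication optimum, curvature filter
# ---------------------------------------------------------------------------

def noise_load(p_opt, q, constants: Constants = DEFAULT_CONSTANTS,
               convention: QConvention = "balance"):
    """Scaled fitness loss (Q/2) * sigma^2 from expression noise at the
    optimum, with the transcription rate at its Q-optimal value.

    A load of 1 means the one-SD abundance fluctuation reaches the zero of
    the fitness parabola; admissible (p_opt, Q) combinations keep the load
    at or below 1.
    """
    bm, _ = optimal_rates_minimal(p_opt, q, constants, convention)
    s2 = singleton_noise_variance(p_opt, bm, constants.cv0, constants.alpha_p)
    out = 0.5 * np.asarray(q, dtype=float) * s2
    return float(out) if np.ndim(out) == 0 else out


def max_admissible_popt(q, constants: Constants = DEFAULT_CONSTANTS,
                        convention: QConvention = "balance") -> float:
    """Largest abundance optimum with noise load <= 1 at sensitivity q."""
    if q <= 0:
        raise ValueError("Q must be strictly positive")
    return brentq(lambda p: noise_load(p, q, constants, convention) - 1.0,
                  1.0, 1e12, xtol=1e-8)


def minimal_delta_opt(q_max: float | None = None,
                      constants: Constants = DEFAULT_CONSTANTS,
                      step: float = 0.01, n_q: int = 200) -> float:
    """Smallest post-duplication optimum multiple keeping fitness positive.

    A duplication doubles abundance to 2 * p_opt while the pair optimum
    moves to delta * p_opt.  Scanning delta upward from 1.00 in steps of
    ``step``, this returns the smallest multiple for which
    W_dup(2 p_opt) > 0 across the whole admissible (p_opt, Q) envelope —
    in particular for the narrowest admissible fitness function, Q = q_max
    at the largest admissible optimum.  Positivity requires

        2 - delta  <  1 / (p_opt * sqrt(Q / 2))

    so only the envelope maximum of p_opt * sqrt(Q) matters; the Q grid
    guards against non-monotonicity of that product.
    """
    qm = constants.q_max if q_max is None else q_max
    qs = np.linspace(qm / n_q, qm, n_q)
    threshold = min(1.0 / (max_admissible_popt(q, constants) * np.sqrt(q / 2.0))
                    for q in qs)
    delta = 1.00
    while 2.0 - delta >= threshold - 1e-15:
        delta = round(delta + step, 10)
        if delta > 2.0:  # the vertex itself always satisfies positivity
            return 2.0
    return delta


def curvature_filter(p_opt, q, n_eff: float,
                     constants: Constants = DEFAULT_CONSTANTS) -> bool | np.ndarray:
    """True iff losing half the cumulative expression right after
    duplication is deleterious: halving abundance from 2 p_opt to p_opt
    under the post-duplication parabola drops scaled fitness by more than
    1/n_eff.  Flat fitness functions (tiny Q or p_opt) fail the filter."""
    p_opt = np.asarray(p_opt, dtype=float)
    q = np.asarray(q, dtype=float)
    d = constants.delta_opt
    w2 = 1.0 - 0.5 * q * (p_opt * (2.0 - d)) ** 2
    w1 = 1.0 - 0.5 * q * (p_opt * (1.0 - d)) ** 2
    out = (w2 - w1) > 1.0 / n_eff
    return bool(out) if out.ndim == 0 else out
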