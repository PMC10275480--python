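"""Sequential-fixation simulation of post-duplication expression divergence.

Each simulated pair starts as two identical copies of a randomly generated
ancestral singleton and accumulates mutations one at a time: a relative
effect is sampled, assigned to transcription or translation and to one of
the two copies, applied multiplicatively, and fixed or lost according to a
modified Metropolis criterion

    P_fix = 1                                   if F_j > F_i
          = exp(-2 N (log F_i - log F_j))       otherwise

on fitness scaled to (0, 1].  Rounds repeat until the simulated protein
abundance divergence is statistically indistinguishable (Mood's median
test, p > 0.1) from a reference distribution, or a safety cap is reached.

The minimal and precision-economy models are run on the *same* mutation
series: all random draws come from streams keyed only by the replicate
seed and the round, so the nth pair of both simulations receives identical
mutations and acceptance uniforms, and running one model alone reproduces
its half of a joint run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, brute

from .divergence import mood_median_pvalue
from .fitness import (FitnessFunction, PairState, curvature_filter, infer_q,
                      noise_load, optimal_rates_minimal,
                      optimal_rates_precision_economy)
from .rates import Constants, DEFAULT_CONSTANTS

__all__ = [
    "MutationModel",
    "MutationSpec",
    "SimulationConfig",
    "Population",
    "SimulationResult",
    "sample_mutation",
    "apply_mutation",
    "fixation_probability",
    "initialize_population",
    "check_stop",
    "run_simulation",
    "run_paired_simulations",
    "post_hoc_loss_filter",
    "calibrate_bivariate_sigmas",
]

Model = Literal["minimal", "precision_economy"]
_MODELS: tuple[Model, Model] = ("minimal", "precision_economy")


@dataclass(frozen=True)
class MutationModel:
    """Distribution of mutational effects on expression rates.

    family 'normal': effect ~ N(0, sigma_mut), assigned to beta_m with
    probability p_bm / (p_bm + p_bp) (relative mutational target sizes).
    family 'skew_normal': same assignment, effect from a skew-normal
    re-parameterized so the *distribution* has mean 0 and SD sigma_mut
    with shape alpha_skew.
    family 'bivariate': every mutation hits both rates, with effects from
    a mean-zero bivariate normal with SDs (sigma_bm, sigma_bp) and
    correlation r_mut; target-size asymmetry lives in the SD ratio.
    """

    family: Literal["normal", "skew_normal", "bivariate"] = "normal"
    sigma_mut: float = 0.025
    p_bm: float = 1.0
    p_bp: float = 1.0
    alpha_skew: float = 0.0
    sigma_bm: Optional[float] = None
    sigma_bp: Optional[float] = None
    r_mut: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "skew_normal", "bivariate"):
            raise ValueError(f"unknown mutation family {self.family!r}")
        if self.family == "bivariate":
            if self.sigma_bm is None or self.sigma_bp is None:
                raise ValueError("bivariate family needs sigma_bm and sigma_bp")
            if min(self.sigma_bm, self.sigma_bp) <= 0 or abs(self.r_mut) > 1:
                raise ValueError("invalid bivariate parameters")
        else:
            if self.sigma_mut <= 0:
                raise ValueError("sigma_mut must be strictly positive")
            if self.p_bm <= 0 or self.p_bp <= 0:
                raise ValueError("target sizes must be strictly positive")

    @property
    def prob_bm(self) -> float:
        return self.p_bm / (self.p_bm + self.p_bp)


@dataclass(frozen=True)
class MutationSpec:
    """One sampled mutation: relative effects and the targeted copy."""

    delta_m: float
    delta_p: float
    target_copy: Literal["P1", "P2"]


def _skew_loc_scale(alpha: float, sd: float) -> tuple[float, float, float]:
    """(delta, loc, scale) so the skew-normal has mean 0 and SD ``sd``."""
    d = alpha / np.sqrt(1.0 + alpha * alpha)
    var_std = 1.0 - 2.0 * d * d / np.pi
    scale = sd / np.sqrt(var_std)
    loc = -scale * d * np.sqrt(2.0 / np.pi)
    return d, loc, scale


def _sample_effects(model: MutationModel, rng: np.random.Generator, n: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draws: (delta_m, delta_p, target-is-P1) for n pairs."""
    if model.family == "bivariate":
        z = rng.standard_normal((n, 2))
        z2 = model.r_mut * z[:, 0] + np.sqrt(1.0 - model.r_mut ** 2) * z[:, 1]
        dm = model.sigma_bm * z[:, 0]
        dp = model.sigma_bp * z2
    else:
        if model.family == "normal":
            eff = model.sigma_mut * rng.standard_normal(n)
        else:
            d, loc, scale = _skew_loc_scale(model.alpha_skew, model.sigma_mut)
            z0 = rng.standard_normal(n)
            z1 = rng.standard_normal(n)
            eff = loc + scale * (d * np.abs(z0) + np.sqrt(1.0 - d * d) * z1)
        on_bm = rng.random(n) < model.prob_bm
        dm = np.where(on_bm, eff, 0.0)
        dp = np.where(on_bm, 0.0, eff)
    to_p1 = rng.random(n) < 0.5
    return dm, dp, to_p1


def sample_mutation(model: MutationModel, rng: np.random.Generator) -> MutationSpec:
    """Sample a single mutation (scalar convenience over the array path)."""
    dm, dp, to_p1 = _sample_effects(model, rng, 1)
    return MutationSpec(float(dm[0]), float(dp[0]), "P1" if to_p1[0] else "P2")


def apply_mutation(state: PairState, spec: MutationSpec,
                   bm_max: float = np.inf, bp_max: float = np.inf
                   ) -> Optional[PairState]:
    """Candidate state after a multiplicative mutation, or None when the
    mutation would take a rate to (or below) zero or above its maximum."""
    fm, fp = 1.0 + spec.delta_m, 1.0 + spec.delta_p
    if spec.target_copy == "P1":
        bm1, bp1, bm2, bp2 = state.bm1 * fm, state.bp1 * fp, state.bm2, state.bp2
    else:
        bm1, bp1, bm2, bp2 = state.bm1, state.bp1, state.bm2 * fm, state.bp2 * fp
    if min(bm1, bp1, bm2, bp2) <= 0 or max(bm1, bm2) > bm_max or max(bp1, bp2) > bp_max:
        return None
    return replace(state, bm1=bm1, bp1=bp1, bm2=bm2, bp2=bp2)


def fixation_probability(f_i, f_j, n_eff: float):
    """Modified Metropolis fixation probability for scaled fitness in (0, 1]."""
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if np.any(f_i <= 0):
        raise ValueError("pre-mutation fitness must be strictly positive")
    with np.errstate(divide="ignore", over="ignore"):
        p = np.where(f_j >= f_i, 1.0,
                     np.exp(-2.0 * n_eff * (np.log(f_i) - np.log(np.maximum(f_j, 1e-300)))))
    out = np.where(f_j <= 0, 0.0, p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Array-of-pairs state for one model."""

    model: Model
    bm1: np.ndarray
    bp1: np.ndarray
    bm2: np.ndarray
    bp2: np.ndarray
    p_opt: np.ndarray
    q: np.ndarray
    constants: Constants = DEFAULT_CONSTANTS

    @property
    def n(self) -> int:
        return self.bm1.size

    def protein_abundances(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.constants
        k = c.alpha_m * c.alpha_p
        return self.bm1 * self.bp1 / k, self.bm2 * self.bp2 / k

    def protein_fold_changes(self) -> np.ndarray:
        p1, p2 = self.protein_abundances()
        return np.abs(np.log2(p1 / p2))

    def scaled_fitness(self, bm1=None, bp1=None, bm2=None, bp2=None) -> np.ndarray:
        """Fitness of (candidate) rates scaled to (-inf, 1] by mu."""
        c = self.constants
        bm1 = self.bm1 if bm1 is None else bm1
        bp1 = self.bp1 if bp1 is None else bp1
        bm2 = self.bm2 if bm2 is None else bm2
        bp2 = self.bp2 if bp2 is None else bp2
        k = c.alpha_m * c.alpha_p
        p1 = bm1 * bp1 / k
        p2 = bm2 * bp2 / k
        p = p1 + p2
        w = 1.0 - 0.5 * self.q * (p - self.constants.delta_opt * self.p_opt) ** 2
        if self.model == "precision_economy":
            s2 = (p + c.alpha_p * (p1 * p1 / bm1 + p2 * p2 / bm2)
                  + c.cv0 ** 2 * p * p)
            w = w - 0.5 * self.q * s2 - c.l_m * c.c_m * (bm1 + bm2) / c.mu
        return w

    def pair_state(self, i: int) -> PairState:
        fn = FitnessFunction(p_opt=float(self.p_opt[i]), mu=self.constants.mu,
                             q=float(self.q[i]), post_dup=True,
                             delta_opt=self.constants.delta_opt)
        return PairState(float(self.bm1[i]), float(self.bp1[i]),
                         float(self.bm2[i]), float(self.bp2[i]), fn, self.constants)


def _pool_arrays(rate_pool: pd.DataFrame, constants: Constants
                 ) -> tuple[np.ndarray, np.ndarray]:
    bm = rate_pool["beta_m"].to_numpy(float)
    bp = rate_pool["beta_p"].to_numpy(float)
    p = bm * bp / (constants.alpha_m * constants.alpha_p)
    # curvature for which each gene's rate balance is precision-economy
    # optimal; keeps the simulated landscape family soft enough to explore
    q = infer_q(bm, bp, constants, convention="optimality")
    q = q[q <= constants.q_max]
    if q.size == 0:
        raise ValueError("rate pool has no genes with admissible Q")
    return p, q


def _sample_combos(n: int, pool_p: np.ndarray, pool_q: np.ndarray,
                   rng: np.random.Generator, n_eff: float, constants: Constants,
                   max_tries: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """(p_opt, Q) combinations passing the curvature filter and the noise-
    load admissibility bound, sampled independently with replacement."""
    p_out = np.empty(n)
    q_out = np.empty(n)
    filled = 0
    for _ in range(max_tries):
        need = n - filled
        if need == 0:
            break
        p_try = rng.choice(pool_p, size=need)
        q_try = rng.choice(pool_q, size=need)
        ok = curvature_filter(p_try, q_try, n_eff, constants)
        ok &= noise_load(p_try, q_try, constants, convention="optimality") <= 1.0
        k = int(ok.sum())
        p_out[filled:filled + k] = p_try[ok]
        q_out[filled:filled + k] = q_try[ok]
        filled += k
    else:
        raise RuntimeError("resampling cap exceeded while drawing admissible "
                           "(p_opt, Q) combinations")
    return p_out, q_out


def initialize_population(n: int, rate_pool: pd.DataFrame, model: Model,
                          rng: np.random.Generator,
                          n_eff: float = 1e6,
                          constants: Constants = DEFAULT_CONSTANTS,
                          bm_max: float | None = None,
                          bp_max: float | None = None,
                          resample_rng: np.random.Generator | None = None,
                          de_rng: np.random.Generator | None = None,
                          combos: tuple[np.ndarray, np.ndarray] | None = None,
                          ) -> Population:
    """Generate n duplicate pairs for one model.

    (p_opt, Q) pairs are drawn with replacement from the rate pool (Q above
    its theoretical maximum excluded; curvature and noise-load filters
    enforced by resampling).  Minimal model: rates from the closed-form
    Q-ratio construction, then Q resampled from the pool distribution
    (re-filtered).  Precision-economy: rates from the global singleton
    fitness optimization.  Both copies then inherit the ancestral rates and
    the pair optimum moves to delta_opt * p_opt.
    """
    if len(rate_pool) < 2:
        raise ValueError("rate pool needs at least 2 genes")
    if n < 1:
        raise ValueError("need at least one pair")
    pool_p, pool_q = _pool_arrays(rate_pool, constants)
    if combos is None:
        combos = _sample_combos(n, pool_p, pool_q, rng, n_eff, constants)
    p_opt, q = (c.copy() for c in combos)

    if model == "minimal":
        bm, bp = optimal_rates_minimal(p_opt, q, constants, convention="optimality")
        rrng = resample_rng if resample_rng is not None else rng
        # decouple curvature from precision-economy constraints
        for i in range(n):
            for _ in range(10_000):
                q_new = float(rrng.choice(pool_q))
                if curvature_filter(p_opt[i], q_new, n_eff, constants) and \
                        noise_load(p_opt[i], q_new, constants,
                                   convention="optimality") <= 1.0:
                    q[i] = q_new
                    break
            else:
                raise RuntimeError("resampling cap exceeded for minimal-model Q")
    elif model == "precision_economy":
        drng = de_rng if de_rng is not None else rng
        bm = np.empty(n)
        bp = np.empty(n)
        hi_bm = bm_max if bm_max is not None else float(rate_pool["beta_m"].max())
        hi_bp = bp_max if bp_max is not None else float(rate_pool["beta_p"].max())
        for i in range(n):
            fn = FitnessFunction(p_opt=float(p_opt[i]), mu=constants.mu,
                                 q=float(q[i]), delta_opt=constants.delta_opt)
            bm[i], bp[i], _ = optimal_rates_precision_economy(
                fn, bm_max=hi_bm, bp_max=hi_bp, seed=drng, constants=constants)
    else:
        raise ValueError(f"unknown model {model!r}")

    return Population(model=model, bm1=bm.copy(), bp1=bp.copy(),
                      bm2=bm.copy(), bp2=bp.copy(),
                      p_opt=p_opt, q=q, constants=constants)


# ---------------------------------------------------------------------------
# The mutation-selection loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Settings of one replicate run (one or both models)."""

    model: Model = "minimal"
    n_eff: float = 1e6
    n_pairs: int = 50
    mutation_model: MutationModel = field(default_factory=MutationModel)
    reference_fc: Optional[np.ndarray] = None   # |log2 fc| of protein abundance
    stop_p: float = 0.1
    bm_max: Optional[float] = None
    bp_max: Optional[float] = None
    seed: int = 0
    max_rounds: int = 200_000
    record_trace: bool = False
    trace_every: int = 10
    q_override: Optional[float] = None
    constants: Constants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.n_eff <= 0 or self.n_pairs < 1:
            raise ValueError("n_eff and n_pairs must be positive")
        if not 0.0 < self.stop_p < 1.0:
            raise ValueError("stop_p must lie in (0, 1)")


@dataclass
class SimulationResult:
    model: Model
    population: Population
    rounds_used: int
    stopped: bool
    final_stop_p: float
    n_accepted: int
    mean_fitness_trace: np.ndarray            # per round
    fitness_trace: Optional[np.ndarray]       # (n_records, n) when recorded
    median_fc_bm_trace: Optional[np.ndarray]
    median_fc_bp_trace: Optional[np.ndarray]
    trace_rounds: Optional[np.ndarray]

    def divergence_frame(self) -> pd.DataFrame:
        """Final per-pair fold changes in the divergence-table layout."""
        pop = self.population
        p1, p2 = pop.protein_abundances()
        sfc_bm = np.log2(pop.bm1 / pop.bm2)
        sfc_bp = np.log2(pop.bp1 / pop.bp2)
        return pd.DataFrame({
            "sfc_bm": sfc_bm, "sfc_bp": sfc_bp,
            "fc_bm": np.abs(sfc_bm), "fc_bp": np.abs(sfc_bp),
            "fc_p": np.abs(np.log2(p1 / p2)),
            "D": np.abs(sfc_bm) - np.abs(sfc_bp),
        })


def check_stop(fc_p: np.ndarray, reference_fc: np.ndarray,
               stop_p: float = 0.1) -> tuple[bool, float]:
    """Stop when Mood's median test cannot tell the simulated protein
    abundance divergence from the reference (p > stop_p)."""
    if reference_fc is None or len(reference_fc) == 0:
        raise ValueError("reference fold-change distribution is empty")
    p = mood_median_pvalue(fc_p, reference_fc)
    return p > stop_p, p


def _run(models: tuple[Model, ...], config: SimulationConfig,
         rate_pool: pd.DataFrame) -> dict[str, SimulationResult]:
    c = config.constants
    n = config.n_pairs
    # independent streams keyed by (seed, purpose); created unconditionally so
    # that single-model and joint runs consume identical randomness
    combo_rng = np.random.default_rng([config.seed, 11])
    minimal_rng = np.random.default_rng([config.seed, 13])
    de_rng = np.random.default_rng([config.seed, 17])
    mut_rng = np.random.default_rng([config.seed, 19])

    pool_p, pool_q = _pool_arrays(rate_pool, c)
    combos = _sample_combos(n, pool_p, pool_q, combo_rng, config.n_eff, c)
    bm_max = config.bm_max if config.bm_max is not None else float(rate_pool["beta_m"].max())
    bp_max = config.bp_max if config.bp_max is not None else float(rate_pool["beta_p"].max())

    pops: dict[str, Population] = {}
    for m in _MODELS:
        if m not in models:
            continue
        pops[m] = initialize_population(
            n, rate_pool, m, combo_rng, n_eff=config.n_eff, constants=c,
            bm_max=bm_max, bp_max=bp_max, resample_rng=minimal_rng,
            de_rng=de_rng, combos=combos)
        if config.q_override is not None:
            pops[m].q = np.full(n, float(config.q_override))

    state = {m: {"w": pops[m].scaled_fitness(), "stopped": False, "rounds": 0,
                 "p": 0.0, "acc": 0, "mean_w": [], "w_tr": [], "fbm": [], "fbp": [],
                 "tr_rounds": []} for m in pops}
    mm = config.mutation_model

    for rnd in range(1, config.max_rounds + 1):
        dm, dp, to_p1 = _sample_effects(mm, mut_rng, n)
        u_acc = mut_rng.random(n)
        fm, fp = 1.0 + dm, 1.0 + dp
        active = [m for m in pops if not state[m]["stopped"]]
        if not active:
            break
        for m in active:
            pop, st = pops[m], state[m]
            cb_m1 = np.where(to_p1, pop.bm1 * fm, pop.bm1)
            cb_p1 = np.where(to_p1, pop.bp1 * fp, pop.bp1)
            cb_m2 = np.where(to_p1, pop.bm2, pop.bm2 * fm)
            cb_p2 = np.where(to_p1, pop.bp2, pop.bp2 * fp)
            valid = (cb_m1 > 0) & (cb_p1 > 0) & (cb_m2 > 0) & (cb_p2 > 0) \
                & (cb_m1 <= bm_max) & (cb_m2 <= bm_max) \
                & (cb_p1 <= bp_max) & (cb_p2 <= bp_max)
            w_j = pop.scaled_fitness(cb_m1, cb_p1, cb_m2, cb_p2)
            w_i = st["w"]
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                pfix = np.where(w_j >= w_i, 1.0,
                                np.exp(-2.0 * config.n_eff
                                       * (np.log(w_i) - np.log(np.maximum(w_j, 1e-300)))))
            accept = valid & (w_j > 0.0) & (u_acc < pfix)
            if accept.any():
                pop.bm1 = np.where(accept, cb_m1, pop.bm1)
                pop.bp1 = np.where(accept, cb_p1, pop.bp1)
                pop.bm2 = np.where(accept, cb_m2, pop.bm2)
                pop.bp2 = np.where(accept, cb_p2, pop.bp2)
                st["w"] = np.where(accept, w_j, w_i)
                st["acc"] += int(accept.sum())
            st["rounds"] = rnd
            st["mean_w"].append(float(st["w"].mean()))
            if config.record_trace and (rnd % config.trace_every == 0 or rnd == 1):
                st["w_tr"].append(st["w"].copy())
                st["fbm"].append(float(np.median(np.abs(np.log2(pop.bm1 / pop.bm2)))))
                st["fbp"].append(float(np.median(np.abs(np.log2(pop.bp1 / pop.bp2)))))
                st["tr_rounds"].append(rnd)
            if config.reference_fc is not None:
                done, pval = check_stop(pop.protein_fold_changes(),
                                        config.reference_fc, config.stop_p)
                st["p"] = pval
                if done:
                    st["stopped"] = True

    out: dict[str, SimulationResult] = {}
    for m, pop in pops.items():
        st = state[m]
        out[m] = SimulationResult(
            model=m, population=pop, rounds_used=st["rounds"],
            stopped=st["stopped"] or config.reference_fc is None,
            final_stop_p=st["p"], n_accepted=st["acc"],
            mean_fitness_trace=np.asarray(st["mean_w"]),
            fitness_trace=np.asarray(st["w_tr"]) if st["w_tr"] else None,
            median_fc_bm_trace=np.asarray(st["fbm"]) if st["fbm"] else None,
            median_fc_bp_trace=np.asarray(st["fbp"]) if st["fbp"] else None,
            trace_rounds=np.asarray(st["tr_rounds"]) if st["tr_rounds"] else None)
    return out


def run_simulation(config: SimulationConfig, rate_pool: pd.DataFrame
                   ) -> SimulationResult:
    """Run one model to its stop condition (or the round cap)."""
    return _run((config.model,), config, rate_pool)[config.model]


def run_paired_simulations(config: SimulationConfig, rate_pool: pd.DataFrame
                           ) -> dict[str, SimulationResult]:
    """Run both models on the shared mutation series."""
    return _run(_MODELS, config, rate_pool)


def post_hoc_loss_filter(result: SimulationResult, n_eff: float | None = None
                         ) -> np.ndarray:
    """Mask of pairs for which losing *either* copy is deleterious
    (drops scaled fitness by more than 1/N).  Pairs where one copy could
    be lost with impunity would not have survived as duplicates."""
    pop = result.population
    n_eff = float(n_eff) if n_eff is not None else 1e6
    w_cur = pop.scaled_fitness()
    tiny = 1e-12  # a lost copy contributes nothing but keeps logs finite
    w_no1 = pop.scaled_fitness(bm1=np.full(pop.n, tiny), bp1=np.full(pop.n, tiny))
    w_no2 = pop.scaled_fitness(bm2=np.full(pop.n, tiny), bp2=np.full(pop.n, tiny))
    thr = 1.0 / n_eff
    return ((w_cur - w_no1) > thr) & ((w_cur - w_no2) > thr)


def calibrate_bivariate_sigmas(ratio: float, reference_sigma_mut: float,
                               rate_pool: pd.DataFrame | None = None,
                               rng: np.random.Generator | int | None = None,
                               r_mut: float = 0.0, n_mc: int = 200_000,
                               rel_tol: float = 0.01) -> tuple[float, float]:
    """Per-level effect SDs (sigma_bm, sigma_bp) with sigma_bm/sigma_bp =
    ratio whose mean absolute relative protein-abundance change per
    mutation matches the univariate reference sigma_mut.

    Mutational effects are multiplicative, so the ancestral rate pool
    cancels from the matching (the protein change factor is
    (1+delta_m)(1+delta_p) regardless of the rates); the pool argument is
    accepted for interface symmetry.  A brute grid localizes the scale,
    then a root solve on common random numbers refines it to ``rel_tol``.
    """
    if ratio <= 0 or reference_sigma_mut <= 0:
        raise ValueError("ratio and reference sigma must be positive")
    rng = np.random.default_rng(rng)
    target = reference_sigma_mut * np.sqrt(2.0 / np.pi)  # E|N(0, sigma)|
    z = rng.standard_normal((n_mc, 2))
    z2 = r_mut * z[:, 0] + np.sqrt(1.0 - r_mut ** 2) * z[:, 1]

    def mean_abs(sig_bp: float) -> float:
        dm = ratio * sig_bp * z[:, 0]
        dp = sig_bp * z2
        return float(np.mean(np.abs((1.0 + dm) * (1.0 + dp) - 1.0)))

    hi = reference_sigma_mut * 4.0
    res = brute(lambda s: abs(mean_abs(float(np.atleast_1d(s)[0])) - target),
                ranges=[(reference_sigma_mut / 100.0, hi)], Ns=40,
                finish=None, full_output=True)
    coarse = float(np.atleast_1d(res[0])[0])
    lo_b, hi_b = max(coarse * 0.5, 1e-9), min(coarse * 2.0, hi)
    try:
        sig_bp = brentq(lambda s: mean_abs(s) - target, lo_b, hi_b, xtol=1e-8)
    except ValueError:
        sig_bp = float(coarse)
    achieved = mean_abs(sig_bp)
    if abs(achieved - target) > rel_tol * target:
        raise RuntimeError("bivariate sigma calibration did not converge on the grid")
    return ratio * sig_bp, sig_bp
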