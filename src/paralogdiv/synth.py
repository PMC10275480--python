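"""Synthetic yeast-like expression datasets.

Generators here produce every input the analysis pipeline needs — a
genome-scale gene rate table, paralog-pair tables with known ground truth,
gene-specific decay rates, and noisy protein-abundance measurements — with
the statistical structure the downstream analyses assume: log-normal rate
marginals, a near-perfect correlation between mRNA and ribosome-footprint
abundances, and within-pair log2 fold-change spreads that are larger in
transcription than in translation.

What the generator emulates (and what it does not) is laid out in
docs/methods.md; briefly, it reproduces marginal spreads, the m-s
correlation, and pair fold-change structure, but not chromosomal context,
expression regulation, or any real gene identity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .rates import Constants, DEFAULT_CONSTANTS

__all__ = [
    "SyntheticSpec",
    "generate_gene_table",
    "generate_paralog_pairs",
    "generate_decay_dataset",
    "generate_protein_abundance_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic yeast-like dataset.

    Defaults emulate the published genome-scale rate compendium: 4440
    genes, corr(log m, log s) = 0.981, 245 WGD and 164 SSD pairs with
    log2 fold-change SDs 2.29 (transcription) and 1.11 (translation),
    mRNA decay median 5.10 1/h and protein decay median 1.34 1/h.
    ``rho_signed_target`` is a *rank* correlation target for the signed
    fold changes within pairs.
    """

    n_genes: int = 4440
    logbm_loc: float = 2.23     # natural-log location of beta_m (median ~1.8 mRNA/cell)
    logbm_scale: float = 2.0    # mRNA marginals span ~3 decades
    logbp_loc: float = 7.41     # natural-log location of beta_p
    logbp_scale: float = 0.45   # footprint-vs-mRNA residual spread at r = 0.981
    r_ms: float = 0.981
    n_wgd: int = 245
    n_ssd: int = 164
    sigma_dbm: float = 2.29     # log2 units
    sigma_dbp: float = 1.11     # log2 units
    rho_signed_target: float = 0.45
    decay_log_sd: float = 0.5   # natural-log spread of gene decay rates
    decay_fc_sd: float = 0.8    # log2 spread of within-pair decay fold changes
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_wgd, self.n_ssd) <= 0:
            raise ValueError("counts must be positive")
        if not (-1 <= self.r_ms <= 1 and -1 <= self.rho_signed_target <= 1):
            raise ValueError("correlations must lie in [-1, 1]")
        if min(self.sigma_dbm, self.sigma_dbp, self.decay_log_sd,
               self.logbm_scale, self.logbp_scale) < 0:
            raise ValueError("scales must be non-negative")
        if 2 * (self.n_wgd + self.n_ssd) > self.n_genes:
            raise ValueError("not enough genes to host the requested pairs")


def _rate_correlation_for_rms(sx: float, sy: float, r_ms: float) -> float:
    """Correlation between log beta_m and log beta_p needed so that
    corr(log m, log s) = r_ms, given log s = log m + log beta_p + const."""
    def f(rho):
        num = sx + rho * sy
        den = np.sqrt(sx ** 2 + sy ** 2 + 2 * rho * sx * sy)
        return num / den - r_ms

    # f is not monotone: it dips to a minimum at negative rho and rises to 1
    # at both ends when sy < sx; search the branch containing a sign change
    for lo, hi in ((0.0, 0.9999), (-0.9999, 0.0)):
        if f(lo) * f(hi) <= 0:
            return brentq(f, lo, hi, xtol=1e-12)
    raise ValueError(f"target corr(log m, log s)={r_ms} infeasible for "
                     f"scales ({sx}, {sy})")


def generate_gene_table(spec: SyntheticSpec,
                        constants: Constants = DEFAULT_CONSTANTS,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Genome-scale gene table with self-consistent rates and measurements.

    Rates are log-normal; the joint of (beta_m, beta_p) is tuned so the
    mRNA/footprint correlation hits ``spec.r_ms``.  The table is globally
    rescaled so that mRNA copies sum to n_m and the translational flux
    sums to n_p * alpha_p — hence recomputing beta_p from (s, m) via the
    footprint-share identity reproduces the stored values exactly.
    Gene-specific decay rates are log-normal with medians at the
    genome-wide constants.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    c = constants
    n = spec.n_genes
    rho = _rate_correlation_for_rms(spec.logbm_scale, spec.logbp_scale, spec.r_ms)
    cov = np.array([
        [spec.logbm_scale ** 2, rho * spec.logbm_scale * spec.logbp_scale],
        [rho * spec.logbm_scale * spec.logbp_scale, spec.logbp_scale ** 2]])
    draws = rng.multivariate_normal([spec.logbm_loc, spec.logbp_loc], cov, size=n,
                                    method="cholesky")
    beta_m = np.exp(draws[:, 0])
    beta_p = np.exp(draws[:, 1])

    m = beta_m / c.alpha_m
    u = c.n_m / m.sum()                      # transcript pool normalization
    m, beta_m = m * u, beta_m * u
    lam = c.n_p * c.alpha_p / (beta_p * m).sum()   # flux normalization
    beta_p = beta_p * lam

    r = 1e6 * m / m.sum()
    s_raw = beta_p * m
    s = 1e6 * s_raw / s_raw.sum()
    alpha_m_i = c.alpha_m * np.exp(rng.normal(0.0, spec.decay_log_sd, n))
    alpha_p_i = c.alpha_p * np.exp(rng.normal(0.0, spec.decay_log_sd, n))
    return pd.DataFrame({
        "id": [f"g{i:05d}" for i in range(n)],
        "beta_m": beta_m,
        "beta_p": beta_p,
        "m": m,
        "r": r,
        "s": s,
        "alpha_m": alpha_m_i,
        "alpha_p": alpha_p_i,
        "p": beta_m * beta_p / (c.alpha_m * c.alpha_p),
    })


def generate_paralog_pairs(spec: SyntheticSpec, genes: pd.DataFrame,
                           constants: Constants = DEFAULT_CONSTANTS,
                           rng: np.random.Generator | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assign paralog pairs within a gene table and imprint known divergence.

    2*(n_wgd+n_ssd) distinct genes are drawn; in each pair the second
    member's rates are overwritten as paralog-1 rates times 2**delta, with
    (delta_bm, delta_bp) from a mean-zero bivariate normal with SDs
    (sigma_dbm, sigma_dbp) and Pearson correlation 2*sin(pi*rho_s/6) so
    the rank correlation of signed fold changes targets
    ``rho_signed_target``.  The table is re-normalized afterwards (global
    rescalings, which leave all within-pair fold changes untouched).

    Returns (updated gene table, pair table, ground truth dict).
    """
    rng = np.random.default_rng(spec.seed + 1 if rng is None else rng)
    c = constants
    n_pairs = spec.n_wgd + spec.n_ssd
    idx = rng.choice(len(genes), size=2 * n_pairs, replace=False)
    i1, i2 = idx[:n_pairs], idx[n_pairs:]

    rho_p = 2.0 * np.sin(np.pi * spec.rho_signed_target / 6.0)
    cov = np.array([
        [spec.sigma_dbm ** 2, rho_p * spec.sigma_dbm * spec.sigma_dbp],
        [rho_p * spec.sigma_dbm * spec.sigma_dbp, spec.sigma_dbp ** 2]])
    deltas = rng.multivariate_normal([0.0, 0.0], cov, size=n_pairs, method="cholesky")
    dbm, dbp = deltas[:, 0], deltas[:, 1]

    g = genes.copy()
    bm = g["beta_m"].to_numpy(float).copy()
    bp = g["beta_p"].to_numpy(float).copy()
    bm[i2] = bm[i1] * 2.0 ** dbm
    bp[i2] = bp[i1] * 2.0 ** dbp

    m = bm / c.alpha_m
    u = c.n_m / m.sum()
    m, bm = m * u, bm * u
    lam = c.n_p * c.alpha_p / (bp * m).sum()
    bp = bp * lam
    s_raw = bp * m
    g["beta_m"], g["beta_p"], g["m"] = bm, bp, m
    g["r"] = 1e6 * m / m.sum()
    g["s"] = 1e6 * s_raw / s_raw.sum()
    g["p"] = bm * bp / (c.alpha_m * c.alpha_p)

    ids = g["id"].to_numpy()
    pairs = pd.DataFrame({
        "gene1": ids[i1],
        "gene2": ids[i2],
        "dup_type": ["WGD"] * spec.n_wgd + ["SSD"] * spec.n_ssd,
    })
    truth = {
        "sfc_bm": -dbm,          # orientation gene1 vs gene2
        "sfc_bp": -dbp,
        "sigma_dbm": spec.sigma_dbm,
        "sigma_dbp": spec.sigma_dbp,
        "rho_signed_target": spec.rho_signed_target,
        "fc_p": np.abs(dbm + dbp),
        "spec": asdict(spec),
    }
    return g, pairs, truth


def generate_decay_dataset(n: int, constants: Constants = DEFAULT_CONSTANTS,
                           log_sd: float = 0.5, fc_sd: float = 0.8,
                           rng: np.random.Generator | int | None = None
                           ) -> pd.DataFrame:
    """Table of n mRNA decay rates (log-normal, median alpha_m) and
    within-pair decay log2 fold changes, for the decay-variation studies."""
    rng = np.random.default_rng(rng)
    return pd.DataFrame({
        "alpha_m": constants.alpha_m * np.exp(rng.normal(0.0, log_sd, n)),
        "dfc": rng.normal(0.0, fc_sd, n),
    })


def generate_protein_abundance_dataset(genes: pd.DataFrame, noise_sd: float,
                                       rng: np.random.Generator | int | None = None
                                       ) -> pd.DataFrame:
    """Simulated measured protein abundances: the rate-implied abundance
    times log-normal noise with log2-scale SD ``noise_sd``."""
    rng = np.random.default_rng(rng)
    noise = 2.0 ** rng.normal(0.0, noise_sd, len(genes)) if noise_sd > 0 else 1.0
    return pd.DataFrame({"id": genes["id"], "p_measured": genes["p"].to_numpy() * noise})
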