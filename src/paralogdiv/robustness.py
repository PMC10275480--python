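"""Monte-Carlo robustness studies of the divergence estimates.

Three confounders are emulated: Gaussian relative measurement error on
mRNA-seq and ribosome-footprint abundances, unmodeled gene-to-gene
variation in mRNA decay, and the spurious correlations expected merely
because mRNA abundance enters both rate calculations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .rates import Constants, DEFAULT_CONSTANTS

__all__ = [
    "NoiseSimConfig",
    "simulate_noisy_divergence",
    "noise_ratio_grid",
    "spurious_correlation_null",
    "protein_fc_validation",
]

# cv grids and fold-change SD scenarios mirroring the noise studies:
# transcription-dominant truth, translation-dominant truth, and equal
# contributions at the same total variance
DEFAULT_CV_GRID = (0.0, 0.1, 0.2, 0.3)
DEFAULT_SIGMA_SCENARIOS = {
    "transcription_dominant": (2.29, 1.11),
    "translation_dominant": (1.11, 2.29),
    "equal": (np.sqrt((2.29 ** 2 + 1.11 ** 2) / 2),) * 2,
}


@dataclass
class NoiseSimConfig:
    n_pairs: int = 10_000
    sigma_dbm: float = 2.29          # SD of true log2 fold changes, transcription
    sigma_dbp: float = 1.11          # SD of true log2 fold changes, translation
    cv_bm: float = 0.0               # relative measurement error on m
    cv_bp: float = 0.0               # relative measurement error on s
    decay_dataset: Optional[pd.DataFrame] = None   # columns alpha_m, dfc
    rate_pool: Optional[pd.DataFrame] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.sigma_dbm < 0 or self.sigma_dbp < 0:
            raise ValueError("fold-change SDs must be non-negative")
        if not (0 <= self.cv_bm < 1 and 0 <= self.cv_bp < 1):
            raise ValueError("cv values must lie in [0, 1)")


def _relative_noise(x: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """x * (1 + eps), eps ~ N(0, cv); non-positive draws are redrawn so
    measurements stay positive (truncation, not clipping)."""
    if cv == 0:
        return x.copy()
    out = x * (1.0 + rng.normal(0.0, cv, x.shape))
    bad = out <= 0
    while bad.any():
        out[bad] = x[bad] * (1.0 + rng.normal(0.0, cv, int(bad.sum())))
        bad = out <= 0
    return out


def simulate_noisy_divergence(cfg: NoiseSimConfig,
                              constants: Constants = DEFAULT_CONSTANTS) -> dict:
    """Apparent vs true divergence under measurement noise.

    Paralog-1 rates are sampled from the rate pool; true log2 fold changes
    build paralog 2.  Exact measurements are m (proportional to beta_m
    under constant decay) and s = beta_p * m; Gaussian relative errors are
    added, apparent rates recomputed, and the transcription/translation
    divergence ratio median(fc_bm)/median(fc_bp) compared with its true
    value.  With a decay dataset, true abundances use gene-specific decay
    (m = beta_m / alpha_m_i) while apparent rates assume constant decay.
    """
    if cfg.rate_pool is None or len(cfg.rate_pool) == 0:
        raise ValueError("config needs a non-empty rate pool")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    idx = rng.integers(0, len(cfg.rate_pool), n)
    bm1 = cfg.rate_pool["beta_m"].to_numpy(float)[idx]
    bp1 = cfg.rate_pool["beta_p"].to_numpy(float)[idx]
    dbm = rng.normal(0.0, cfg.sigma_dbm, n)
    dbp = rng.normal(0.0, cfg.sigma_dbp, n)
    bm2 = bm1 * 2.0 ** dbm
    bp2 = bp1 * 2.0 ** dbp

    if cfg.decay_dataset is None:
        m1, m2 = bm1 / constants.alpha_m, bm2 / constants.alpha_m
    else:
        dd = cfg.decay_dataset
        j = rng.integers(0, len(dd), n)
        am1 = dd["alpha_m"].to_numpy(float)[j]
        am2 = am1 * 2.0 ** dd["dfc"].to_numpy(float)[j]
        m1, m2 = bm1 / am1, bm2 / am2
    s1, s2 = bp1 * m1, bp2 * m2

    m1n = _relative_noise(m1, cfg.cv_bm, rng)
    m2n = _relative_noise(m2, cfg.cv_bm, rng)
    s1n = _relative_noise(s1, cfg.cv_bp, rng)
    s2n = _relative_noise(s2, cfg.cv_bp, rng)

    # apparent rates assume constant decay: beta_m ∝ m, beta_p = s / m
    fc_bm_true = np.abs(dbm)
    fc_bp_true = np.abs(dbp)
    fc_bm_app = np.abs(np.log2(m1n / m2n))
    fc_bp_app = np.abs(np.log2((s1n / m1n) / (s2n / m2n)))
    true_ratio = float(np.median(fc_bm_true) / np.median(fc_bp_true))
    apparent_ratio = float(np.median(fc_bm_app) / np.median(fc_bp_app))
    return {
        "true_ratio": true_ratio,
        "apparent_ratio": apparent_ratio,
        "fc_bm_true": fc_bm_true, "fc_bp_true": fc_bp_true,
        "fc_bm_apparent": fc_bm_app, "fc_bp_apparent": fc_bp_app,
    }


def noise_ratio_grid(rate_pool: pd.DataFrame, sigma_dbm: float, sigma_dbp: float,
                     cv_grid=DEFAULT_CV_GRID, n_pairs: int = 10_000,
                     seed: int = 0, decay_dataset: Optional[pd.DataFrame] = None,
                     constants: Constants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """True/apparent divergence ratios over a (cv_bm, cv_bp) grid."""
    rows = []
    for i, cv_m in enumerate(cv_grid):
        for j, cv_p in enumerate(cv_grid):
            cfg = NoiseSimConfig(n_pairs=n_pairs, sigma_dbm=sigma_dbm,
                                 sigma_dbp=sigma_dbp, cv_bm=cv_m, cv_bp=cv_p,
                                 decay_dataset=decay_dataset,
                                 rate_pool=rate_pool,
                                 seed=seed * 1000 + i * len(cv_grid) + j)
            res = simulate_noisy_divergence(cfg, constants)
            rows.append({"cv_bm": cv_m, "cv_bp": cv_p,
                         "true_ratio": res["true_ratio"],
                         "apparent_ratio": res["apparent_ratio"]})
    return pd.DataFrame(rows)


def spurious_correlation_null(n: int, r_ms: float,
                              seed: int | np.random.Generator | None = None,
                              sigma_log_m: float = 1.0,
                              scale: str = "log") -> tuple[float, float]:
    """Divergence correlations expected from the shared-m construction
    alone (pseudo beta_m = m, pseudo beta_p = s / m), with no evolution.

    For r_ms > 0 on the log scale, footprints are modeled as s = m * e
    with an independent log-normal efficiency e whose spread is solved
    from corr(log m, log s) = r_ms; for r_ms = 0, m and s are independent
    with equal log spreads; r_ms < 0 uses a direct bivariate normal.
    As r_ms -> 1 the pseudo-translation fold changes collapse to zero and
    the correlations are undefined (returned as NaN).
    """
    if n < 10:
        raise ValueError("need n >= 10 pairs")
    if not -1.0 <= r_ms <= 1.0:
        raise ValueError("r_ms must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    sm = sigma_log_m
    if scale == "log":
        if r_ms > 0:
            log_m = rng.normal(0.0, sm, (n, 2))
            sig_e = sm * np.sqrt(max(1.0 / r_ms ** 2 - 1.0, 0.0))
            log_s = log_m + rng.normal(0.0, sig_e, (n, 2))
        else:
            z = rng.standard_normal((n, 2, 2))
            log_m = sm * z[:, :, 0]
            log_s = sm * (r_ms * z[:, :, 0] + np.sqrt(1 - r_ms ** 2) * z[:, :, 1])
        x = (log_m[:, 0] - log_m[:, 1]) / np.log(2.0)            # pseudo beta_m sfc
        y = ((log_s[:, 0] - log_m[:, 0]) - (log_s[:, 1] - log_m[:, 1])) / np.log(2.0)
    elif scale == "linear":
        # positive-truncated normal abundances on the linear scale
        m = np.abs(rng.normal(1.0, 0.3, (n, 2))) + 1e-9
        if r_ms > 0:
            e = np.abs(rng.normal(1.0, 0.3 * np.sqrt(max(1 / r_ms ** 2 - 1, 0)),
                                  (n, 2))) + 1e-9
            s = m * e
        else:
            s = np.abs(rng.normal(1.0, 0.3, (n, 2))) + 1e-9
        x = np.log2(m[:, 0] / m[:, 1])
        y = np.log2((s[:, 0] / m[:, 0]) / (s[:, 1] / m[:, 1]))
    else:
        raise ValueError("scale must be 'log' or 'linear'")

    if np.ptp(y) < 1e-12 or np.std(y) < 1e-9 * np.std(x):
        return float("nan"), float("nan")
    rho_abs = float(stats.spearmanr(np.abs(x), np.abs(y)).statistic)
    x_dup = np.concatenate([x, -x])
    y_dup = np.concatenate([y, -y])
    rho_signed = float(stats.spearmanr(x_dup, y_dup).statistic)
    return rho_abs, rho_signed


def protein_fc_validation(genes: pd.DataFrame, pairs: pd.DataFrame,
                          measured: pd.DataFrame,
                          protein_decay: Optional[pd.DataFrame] = None,
                          n_shuffles: int = 10_000,
                          seed: int | np.random.Generator | None = None,
                          constants: Constants = DEFAULT_CONSTANTS) -> dict:
    """Validate rate-implied protein fold changes against measured ones.

    Estimated fold changes use p_i = m_i * beta_p_i / alpha_p_i, with
    gene-specific protein decay when a ``protein_decay`` table (columns
    id, alpha_p) is supplied and the genome-wide median otherwise; the
    null distribution re-pairs beta_p rates by shuffling across genes.
    Returns the observed Pearson r on log2 fold changes and its empirical
    quantile in the n_shuffles-strong null.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs with complete data")
    rng = np.random.default_rng(seed)
    g = genes.set_index("id")
    meas = measured.set_index("id")["p_measured"]
    i1 = pairs["gene1"].to_numpy()
    i2 = pairs["gene2"].to_numpy()
    m = (g["beta_m"] / constants.alpha_m).to_numpy(float)
    bp = g["beta_p"].to_numpy(float)
    if protein_decay is not None:
        ap = protein_decay.set_index("id")["alpha_p"].reindex(g.index).to_numpy(float)
        if np.isnan(ap).any():
            raise ValueError("protein decay table does not cover all genes")
    else:
        ap = np.full(len(g), constants.alpha_p)
    loc1 = g.index.get_indexer(i1)
    loc2 = g.index.get_indexer(i2)
    meas_fc = np.log2(meas.reindex(i1).to_numpy(float)
                      / meas.reindex(i2).to_numpy(float))
    if np.isnan(meas_fc).any():
        raise ValueError("measured abundances do not cover all paired genes")

    def est_fc(bp_vec: np.ndarray) -> np.ndarray:
        p = m * bp_vec / ap
        return np.log2(p[loc1] / p[loc2])

    r_obs = float(np.corrcoef(est_fc(bp), meas_fc)[0, 1])
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = np.corrcoef(est_fc(rng.permutation(bp)), meas_fc)[0, 1]
    quantile = float(np.mean(null < r_obs))
    return {"r_obs": r_obs, "null_quantile": quantile, "null": null}
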