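"""Evaluation of simulation runs against a reference divergence pattern.

A run is summarized by three two-sample KS statistics (simulated vs
reference |log2 fold change| of transcription, translation and protein
abundance), their mean, the matching Mood's median p-values, and the two
divergence correlations.  Replicates are combined into grand means; grid
searches locate the mutational-effect SD minimizing the grand mean KS.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import mood_median_pvalue, signed_fold_changes
from .evolve import MutationModel, SimulationConfig, SimulationResult, run_simulation

__all__ = [
    "RunSummary",
    "summarize_run",
    "grand_mean_ks",
    "grid_search",
    "correlation_replication_check",
    "expression_space_summary",
]


@dataclass(frozen=True)
class RunSummary:
    ks_bm: float
    ks_bp: float
    ks_p: float
    mood_bm: float
    mood_bp: float
    mood_p: float
    rho_abs: float
    rho_signed: float
    mean_ks: float
    n_pairs: int
    seed: int


def _spearman(x, y) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def summarize_run(div: pd.DataFrame, reference: dict[str, np.ndarray],
                  seed: int = 0) -> RunSummary:
    """Summary statistics of a final divergence table vs a reference.

    ``reference`` maps 'fc_bm', 'fc_bp', 'fc_p' to |log2 fold change|
    samples.  Correlations are computed on the simulated pairs (signed one
    on the orientation-duplicated rows).
    """
    if len(div) == 0:
        raise ValueError("empty run")
    ks = {}
    mood = {}
    for key in ("fc_bm", "fc_bp", "fc_p"):
        sim = div[key].to_numpy(float)
        ref = np.asarray(reference[key], dtype=float)
        ks[key] = float(stats.ks_2samp(sim, ref).statistic)
        mood[key] = mood_median_pvalue(sim, ref)
    dup = signed_fold_changes(div)
    return RunSummary(
        ks_bm=ks["fc_bm"], ks_bp=ks["fc_bp"], ks_p=ks["fc_p"],
        mood_bm=mood["fc_bm"], mood_bp=mood["fc_bp"], mood_p=mood["fc_p"],
        rho_abs=_spearman(div["fc_bm"], div["fc_bp"]),
        rho_signed=_spearman(dup["sfc_bm"], dup["sfc_bp"]),
        mean_ks=float(np.mean([ks["fc_bm"], ks["fc_bp"], ks["fc_p"]])),
        n_pairs=int(len(div)), seed=seed)


def grand_mean_ks(summaries: Iterable[RunSummary]) -> float:
    """Mean of the per-replicate mean KS statistics."""
    vals = [s.mean_ks for s in summaries]
    if not vals:
        raise ValueError("no summaries")
    return float(np.mean(vals))


def grid_search(sigma_grid: Sequence[float], ratio_grid: Sequence[float],
                models: Sequence[str], n_eff: float,
                reference: dict[str, np.ndarray], seeds: Sequence[int],
                rate_pool: pd.DataFrame, n_pairs: int = 250,
                max_rounds: int = 100_000,
                family: str = "normal") -> tuple[pd.DataFrame, dict]:
    """Replicate simulations over a (model, sigma_mut, target-size ratio)
    grid; returns the per-replicate table and the cell minimizing the
    grand mean KS statistic.

    Each cell runs one simulation per replicate seed with the shared seed
    set; per-cell seeding makes results independent of evaluation order.
    """
    rows = []
    for model in models:
        for sigma in sigma_grid:
            for ratio in ratio_grid:
                for seed in seeds:
                    mm = MutationModel(family=family, sigma_mut=sigma,
                                       p_bm=float(ratio), p_bp=1.0)
                    cfg = SimulationConfig(model=model, n_eff=n_eff,
                                           n_pairs=n_pairs, mutation_model=mm,
                                           reference_fc=np.asarray(reference["fc_p"]),
                                           seed=int(seed), max_rounds=max_rounds)
                    res = run_simulation(cfg, rate_pool)
                    summ = summarize_run(res.divergence_frame(), reference, seed=int(seed))
                    row = {"model": model, "sigma_mut": sigma, "ratio": ratio,
                           "stopped": res.stopped, "rounds": res.rounds_used}
                    row.update(asdict(summ))
                    rows.append(row)
    table = pd.DataFrame(rows)
    cells = (table.groupby(["model", "sigma_mut", "ratio"], as_index=False)
             .agg(grand_mean_ks=("mean_ks", "mean"),
                  all_stopped=("stopped", "all")))
    best = cells.loc[cells["grand_mean_ks"].idxmin()]
    argmin = {"model": best["model"], "sigma_mut": float(best["sigma_mut"]),
              "ratio": float(best["ratio"]),
              "grand_mean_ks": float(best["grand_mean_ks"])}
    return table, argmin


def correlation_replication_check(run_summaries: pd.DataFrame,
                                  empirical_ci: dict) -> pd.DataFrame:
    """Flag parameter combinations whose correlations replicate the
    empirical ones: replicated iff at least one of the replicates falls
    inside the supplied 95% CI.  ``empirical_ci`` maps 'rho_abs' and
    'rho_signed' to (low, high)."""
    for key in ("rho_abs", "rho_signed"):
        lo, hi = empirical_ci[key]
        if lo > hi:
            raise ValueError(f"malformed CI for {key}: low > high")
    group_cols = [c for c in ("model", "sigma_mut", "ratio") if c in run_summaries.columns]
    out = []
    for keys, grp in run_summaries.groupby(group_cols):
        rec = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        for key in ("rho_abs", "rho_signed"):
            lo, hi = empirical_ci[key]
            vals = grp[key].to_numpy(float)
            rec[f"{key}_mean"] = float(np.nanmean(vals))
            rec[f"{key}_replicated"] = bool(np.any((vals >= lo) & (vals <= hi)))
        out.append(rec)
    return pd.DataFrame(out)


def expression_space_summary(results: Sequence[SimulationResult],
                             gene_pool: pd.DataFrame,
                             boundary: tuple[float, float] | None = None,
                             bins: int = 40) -> dict:
    """Pooled (beta_m, beta_p) distribution of simulated paralogs vs the
    gene pool, as log10-scale 2D histograms, plus the fraction of
    simulated genes below an optional diagonal boundary
    log10(beta_p) = slope * log10(beta_m) + intercept."""
    bm = np.concatenate([np.concatenate([r.population.bm1, r.population.bm2])
                         for r in results])
    bp = np.concatenate([np.concatenate([r.population.bp1, r.population.bp2])
                         for r in results])
    pool_bm = gene_pool["beta_m"].to_numpy(float)
    pool_bp = gene_pool["beta_p"].to_numpy(float)
    lo_x = min(np.log10(bm).min(), np.log10(pool_bm).min())
    hi_x = max(np.log10(bm).max(), np.log10(pool_bm).max())
    lo_y = min(np.log10(bp).min(), np.log10(pool_bp).min())
    hi_y = max(np.log10(bp).max(), np.log10(pool_bp).max())
    rng = [[lo_x, hi_x], [lo_y, hi_y]]
    h_sim, xe, ye = np.histogram2d(np.log10(bm), np.log10(bp), bins=bins, range=rng)
    h_pool, _, _ = np.histogram2d(np.log10(pool_bm), np.log10(pool_bp), bins=bins, range=rng)
    out = {"hist_sim": h_sim, "hist_pool": h_pool, "x_edges": xe, "y_edges": ye,
           "n_sim": int(bm.size), "n_pool": int(pool_bm.size)}
    if boundary is not None:
        slope, intercept = boundary
        below = np.log10(bp) < slope * np.log10(bm) + intercept
        out["frac_below_boundary"] = float(below.mean())
    return out
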