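"""Within-pair divergence statistics and distribution-comparison tests.

The magnitude of relative divergence of a trait theta within a paralog pair
is the non-negative log2-fold change log2(max(theta1, theta2) /
min(theta1, theta2)); the signed variant keeps the orientation and is
computed in both orientations (a "duplicated" dataset of 2n rows), which
makes the signed correlation invariant to the arbitrary labeling of the two
genes in a pair.  The divergence ratio

    D = log2( (max(bm)/min(bm)) / (max(bp)/min(bp)) )

is positive when a pair diverged more in transcription than in translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .rates import Constants, DEFAULT_CONSTANTS, protein_abundance

__all__ = [
    "CorrelationResult",
    "log2_fold_change",
    "signed_fold_changes",
    "divergence_ratio",
    "pair_divergence_table",
    "divergence_correlations",
    "compare_distributions",
    "mood_median_pvalue",
    "summarize_divergence",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with a percentile-bootstrap 95% CI."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False


def log2_fold_change(theta1, theta2):
    """Non-negative log2 ratio of the larger over the smaller value."""
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("fold changes need strictly positive values")
    out = np.abs(np.log2(t1) - np.log2(t2))
    return float(out) if out.ndim == 0 else out


def divergence_ratio(bm1, bm2, bp1, bp2):
    """Divergence ratio D; > 0 means transcription-biased divergence."""
    return log2_fold_change(bm1, bm2) - log2_fold_change(bp1, bp2)


def pair_divergence_table(genes: pd.DataFrame, pairs: pd.DataFrame,
                          constants: Constants = DEFAULT_CONSTANTS,
                          decay: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-pair divergence records from a gene table and a pair table.

    Parameters
    ----------
    genes
        Gene table with columns id, beta_m, beta_p (see ``read_gene_table``).
    pairs
        Pair table with columns gene1, gene2, dup_type.
    decay
        Optional table (id, alpha_m) of gene-specific mRNA decay rates in
        1/h; when given, beta_m is recomputed as m * alpha_m_i, with
        m = beta_m / alpha_m (the abundance implied by the constant-decay
        rates).

    Returns
    -------
    DataFrame with one row per pair: fc_bm, fc_bp, fc_p (non-negative log2
    fold changes of transcription, translation and protein abundance),
    sfc_bm, sfc_bp (signed, orientation gene1/gene2) and the divergence
    ratio D.
    """
    g = genes.set_index("id")
    for col in ("gene1", "gene2"):
        unknown = set(pairs[col]) - set(g.index)
        if unknown:
            raise ValueError(f"pair table references unknown gene(s): {sorted(unknown)[:5]}")
    bm1 = g.loc[pairs["gene1"], "beta_m"].to_numpy(float)
    bm2 = g.loc[pairs["gene2"], "beta_m"].to_numpy(float)
    bp1 = g.loc[pairs["gene1"], "beta_p"].to_numpy(float)
    bp2 = g.loc[pairs["gene2"], "beta_p"].to_numpy(float)
    if decay is not None:
        d = decay.set_index("id")["alpha_m"]
        am1 = d.reindex(pairs["gene1"]).to_numpy(float)
        am2 = d.reindex(pairs["gene2"]).to_numpy(float)
        if np.isnan(am1).any() or np.isnan(am2).any():
            raise ValueError("decay table does not cover all paired genes")
        # recompute beta_m = m * alpha_m_i from the constant-decay abundance
        bm1 = bm1 / constants.alpha_m * am1
        bm2 = bm2 / constants.alpha_m * am2
    p1 = protein_abundance(bm1, bp1, constants.alpha_m, constants.alpha_p)
    p2 = protein_abundance(bm2, bp2, constants.alpha_m, constants.alpha_p)
    out = pd.DataFrame({
        "gene1": pairs["gene1"].to_numpy(),
        "gene2": pairs["gene2"].to_numpy(),
        "dup_type": pairs["dup_type"].to_numpy(),
        "sfc_bm": np.log2(bm1 / bm2),
        "sfc_bp": np.log2(bp1 / bp2),
    })
    out["fc_bm"] = np.abs(out["sfc_bm"])
    out["fc_bp"] = np.abs(out["sfc_bp"])
    out["fc_p"] = log2_fold_change(p1, p2)
    out["D"] = out["fc_bm"] - out["fc_bp"]
    return out


def signed_fold_changes(div: pd.DataFrame) -> pd.DataFrame:
    """Orientation-duplicated signed fold changes (2n rows; each pair
    contributes (x, y) and (-x, -y))."""
    for col in ("sfc_bm", "sfc_bp"):
        if col not in div.columns:
            raise ValueError("input must carry signed fold-change columns sfc_bm/sfc_bp")
        if div[col].isna().any():
            raise ValueError("missing member rates in signed fold changes")
    fwd = div[["sfc_bm", "sfc_bp"]].copy()
    rev = -fwd
    return pd.concat([fwd, rev], ignore_index=True)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def _bootstrap_spearman(x: np.ndarray, y: np.ndarray, idx: np.ndarray,
                        duplicate: bool) -> np.ndarray:
    xs, ys = x[idx], y[idx]
    if duplicate:
        xs = np.concatenate([xs, -xs], axis=1)
        ys = np.concatenate([ys, -ys], axis=1)
    rx = stats.rankdata(xs, axis=1)
    ry = stats.rankdata(ys, axis=1)
    return _rowwise_pearson(rx, ry)


def divergence_correlations(div: pd.DataFrame, n_boot: int = 10_000,
                            rng: np.random.Generator | int | None = None
                            ) -> tuple[CorrelationResult, CorrelationResult]:
    """Spearman correlations between transcriptional and translational
    divergence, for magnitudes (n pairs) and signed changes (2n
    orientation-duplicated rows).

    Bootstrap CIs (percentile, 2.5/97.5) resample *pairs* with replacement
    — not duplicated rows — so the dependence between the two orientations
    of one pair is respected; orientations are re-duplicated within each
    resample.  Note the signed correlation's p-value is computed on the 2n
    duplicated rows and therefore overstates the information content; the
    reported ``n`` makes this explicit.
    """
    n = len(div)
    if n < 3:
        raise ValueError("need at least 3 pairs for divergence correlations")
    rng = np.random.default_rng(rng)
    fb, fp = div["fc_bm"].to_numpy(float), div["fc_bp"].to_numpy(float)
    sb, sp = div["sfc_bm"].to_numpy(float), div["sfc_bp"].to_numpy(float)

    if np.ptp(fb) == 0 or np.ptp(fp) == 0:
        abs_res = CorrelationResult(np.nan, np.nan, np.nan, np.nan, n, degenerate=True)
    else:
        rho_a, p_a = stats.spearmanr(fb, fp)
        abs_res = None
    if np.ptp(sb) == 0 or np.ptp(sp) == 0:
        signed_res = CorrelationResult(np.nan, np.nan, np.nan, np.nan, 2 * n, degenerate=True)
    else:
        dup = signed_fold_changes(div)
        rho_s, p_s = stats.spearmanr(dup["sfc_bm"], dup["sfc_bp"])
        signed_res = None

    if abs_res is None or signed_res is None:
        idx = rng.integers(0, n, size=(n_boot, n))
        if abs_res is None:
            boots = _bootstrap_spearman(fb, fp, idx, duplicate=False)
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            abs_res = CorrelationResult(float(rho_a), float(p_a), float(lo), float(hi), n)
        if signed_res is None:
            boots = _bootstrap_spearman(sb, sp, idx, duplicate=True)
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            signed_res = CorrelationResult(float(rho_s), float(p_s), float(lo), float(hi), 2 * n)
    return abs_res, signed_res


def mood_median_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Fast Mood's median test p-value (2x2 chi-square, no continuity
    correction; values equal to the grand median counted as 'below').

    Matches scipy.stats.median_test(ties='below', correction=False).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gm = np.median(np.concatenate([x, y]))
    a = float(np.count_nonzero(x > gm))   # x above
    b = float(np.count_nonzero(y > gm))   # y above
    c = x.size - a
    d = y.size - b
    ntot = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        return 1.0
    chi2 = ntot * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return float(stats.chi2.sf(chi2, df=1))


def compare_distributions(x, y) -> dict:
    """Two-sample comparison battery: Mann-Whitney-Wilcoxon (two-sided),
    Mood's median test (grand-median 2x2 chi-square), and the two-sample
    KS statistic (sup |ECDF difference|) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    mww = stats.mannwhitneyu(x, y, alternative="two-sided")
    ks = stats.ks_2samp(x, y)
    try:
        _, mood_p, _, _ = stats.median_test(x, y, ties="below", correction=False)
    except ValueError:  # all observations on one side of the grand median
        mood_p = 1.0
    return {"mww_p": float(mww.pvalue), "mood_p": float(mood_p),
            "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def summarize_divergence(div: pd.DataFrame, n_boot: int = 10_000,
                         rng: np.random.Generator | int | None = None) -> dict:
    """Summary of a divergence table: medians, fold-change spreads, the
    transcription-vs-translation test battery, and both correlations."""
    abs_res, signed_res = divergence_correlations(div, n_boot=n_boot, rng=rng)
    tests = compare_distributions(div["fc_bm"], div["fc_bp"])
    med_bm = float(div["fc_bm"].median())
    med_bp = float(div["fc_bp"].median())
    return {
        "n_pairs": int(len(div)),
        "median_fc_bm": med_bm,
        "median_fc_bp": med_bp,
        "median_fc_p": float(div["fc_p"].median()),
        "median_ratio_bm_bp": med_bm / med_bp if med_bp > 0 else float("inf"),
        "sd_sfc_bm": float(div["sfc_bm"].std(ddof=1)),
        "sd_sfc_bp": float(div["sfc_bp"].std(ddof=1)),
        "frac_transcription_biased": float((div["D"] > 0).mean()),
        "median_D": float(div["D"].median()),
        "tests_bm_vs_bp": tests,
        "rho_abs": abs_res.__dict__,
        "rho_signed": signed_res.__dict__,
    }
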