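"""Molecular rate calculus and domain types for gene expression phenotypes.

Every gene is described by two rates of the central dogma in budding yeast:
a transcription rate ``beta_m`` (mRNAs synthesized per hour) and a
translation rate ``beta_p`` (proteins produced per mRNA per hour).  Together
with mRNA and protein decay rates (``alpha_m``, ``alpha_p``, in 1/h) they
determine the steady-state protein abundance

    p = beta_m * beta_p / (alpha_m * alpha_p).

The functions here convert sequencing-level measurements (mRNA-seq RPKM and
ribosome-footprint RPKM) into these rates, and back into abundances.  All
internal computation is in hours; decay constants supplied in other time
units must be converted at ingestion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Constants",
    "DEFAULT_CONSTANTS",
    "GeneRecord",
    "DuplicationType",
    "ParalogPair",
    "mrna_abundance_from_rpkm",
    "transcription_rate",
    "translation_rate",
    "protein_abundance",
    "decay_with_dilution",
    "read_gene_table",
    "write_gene_table",
    "read_pair_table",
    "write_pair_table",
]


@dataclass(frozen=True)
class Constants:
    """Cell-level constants for S. cerevisiae.

    Attributes
    ----------
    n_m : float
        Total transcripts per cell.
    n_p : float
        Total proteins per cell.
    alpha_m : float
        Median mRNA decay rate, 1/h (includes dilution).
    alpha_p : float
        Median protein decay rate, 1/h (includes dilution).
    mu : float
        Maximal growth rate, 1/h; also the fitness at an expression optimum.
    cv0 : float
        Noise floor: minimal coefficient of variation of protein abundance
        in a clonal population (dimensionless).
    l_m : float
        Median pre-mRNA length, nucleotides.
    c_m : float
        Fitness cost of transcription per nucleotide synthesized per hour,
        1/nt.
    t_div : float
        Cell division time, minutes (dilution term ln(2)/t_div).
    q_max : float
        Theoretical maximum of the noise-sensitivity parameter Q
        (curvature of the fitness parabola per squared protein deviation).
    delta_opt : float
        Post-duplication optimum of cumulative protein abundance, as a
        multiple of the ancestral single-gene optimum.
    """

    n_m: float = 60_000.0
    n_p: float = 1.1e8
    alpha_m: float = 5.10
    alpha_p: float = 1.34
    mu: float = 0.42
    cv0: float = 0.1
    l_m: float = 1350.0
    c_m: float = 1.2e-9
    t_div: float = 99.0
    q_max: float = 6.8588e-6
    delta_opt: float = 1.87

    def __post_init__(self) -> None:
        for name in ("n_m", "n_p", "alpha_m", "alpha_p", "mu", "cv0",
                     "l_m", "c_m", "t_div", "q_max", "delta_opt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be strictly positive")
        if not self.cv0 < 1:
            raise ValueError("noise floor cv0 must be < 1")
        if not 1.0 < self.delta_opt < 2.0:
            raise ValueError("delta_opt must lie strictly between 1 and 2")

    @property
    def q_scale(self) -> float:
        """c_m * alpha_m * l_m — prefactor linking Q to the beta_m/beta_p ratio."""
        return self.c_m * self.alpha_m * self.l_m


DEFAULT_CONSTANTS = Constants()


@dataclass
class GeneRecord:
    """Expression phenotype of one gene.

    Rates must be strictly positive when present.  ``p`` is derived from the
    rates under whichever decay constants are in force.
    """

    id: str
    beta_m: float
    beta_p: float
    m: Optional[float] = None
    r: Optional[float] = None
    s: Optional[float] = None
    alpha_m_i: Optional[float] = None
    alpha_p_i: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("beta_m", "beta_p", "m", "r", "s", "alpha_m_i", "alpha_p_i"):
            val = getattr(self, name)
            if val is not None and val <= 0 and name not in ("r", "s"):
                raise ValueError(f"{name} must be strictly positive, got {val}")

    def protein_abundance(self, constants: Constants = DEFAULT_CONSTANTS) -> float:
        """Steady-state protein abundance, using gene-specific decay when available."""
        am = self.alpha_m_i if self.alpha_m_i is not None else constants.alpha_m
        ap = self.alpha_p_i if self.alpha_p_i is not None else constants.alpha_p
        return protein_abundance(self.beta_m, self.beta_p, am, ap)


class DuplicationType(str, enum.Enum):
    WGD = "WGD"
    SSD = "SSD"


@dataclass(frozen=True)
class ParalogPair:
    """Two paralogous gene ids plus the mechanism that created them."""

    gene1: str
    gene2: str
    dup_type: DuplicationType = DuplicationType.WGD

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError("a paralog pair needs two distinct genes")
        object.__setattr__(self, "dup_type", DuplicationType(self.dup_type))


# ---------------------------------------------------------------------------
# Rate calculus
# ---------------------------------------------------------------------------

def mrna_abundance_from_rpkm(r, n_m: float = DEFAULT_CONSTANTS.n_m) -> np.ndarray:
    """Convert mRNA-seq RPKM shares into mRNA copies per cell.

    m_i = n_m * r_i / sum_j r_j, so the copies sum exactly to the cellular
    transcript pool ``n_m``.  Normalization runs over exactly the genes
    supplied: subsetting the table changes absolute abundances.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0 or np.any(r < 0) or not np.any(r > 0):
        raise ValueError("RPKM values must be non-negative with at least one positive entry")
    return n_m * r / r.sum()


def transcription_rate(m, alpha) -> np.ndarray | float:
    """beta_m = m * alpha_m for mRNA abundance m and decay rate alpha (1/h)."""
    m = np.asarray(m, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(m <= 0) or np.any(alpha <= 0):
        raise ValueError("mRNA abundance and decay rate must be strictly positive")
    out = m * alpha
    return float(out) if out.ndim == 0 else out


def translation_rate(s, m, n_p: float = DEFAULT_CONSTANTS.n_p,
                     alpha_p: float = DEFAULT_CONSTANTS.alpha_p) -> np.ndarray:
    """Translation rates from ribosome-footprint RPKM shares.

    The total translational flux n_p * alpha_p (proteins/h at steady state)
    is split among genes according to their footprint share and divided by
    mRNA abundance:

        beta_p_i = (n_p * alpha_p / m_i) * s_i / sum_j s_j

    which conserves the flux: sum_i beta_p_i * m_i = n_p * alpha_p.
    """
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    if s.size == 0 or np.any(s < 0) or not np.any(s > 0):
        raise ValueError("footprint RPKMs must be non-negative with at least one positive entry")
    if np.any((s > 0) & (m <= 0)):
        raise ValueError("every gene with footprints needs a positive mRNA abundance")
    return n_p * alpha_p * (s / s.sum()) / m


def protein_abundance(beta_m, beta_p,
                      alpha_m: float = DEFAULT_CONSTANTS.alpha_m,
                      alpha_p: float = DEFAULT_CONSTANTS.alpha_p):
    """Steady-state protein abundance p = beta_m * beta_p / (alpha_m * alpha_p)."""
    beta_m = np.asarray(beta_m, dtype=float)
    beta_p = np.asarray(beta_p, dtype=float)
    if np.any(beta_m <= 0) or np.any(beta_p <= 0) or np.any(np.asarray(alpha_m) <= 0) \
            or np.any(np.asarray(alpha_p) <= 0):
        raise ValueError("rates and decay constants must be strictly positive")
    out = beta_m * beta_p / (alpha_m * alpha_p)
    return float(out) if out.ndim == 0 else out


def decay_with_dilution(gamma, t_div: float = DEFAULT_CONSTANTS.t_div):
    """Total decay rate (1/h) from an active decay constant plus dilution.

    Experimental decay constants often exclude the dilution of molecules by
    cell growth; the total decay in a culture dividing every ``t_div``
    minutes is gamma + ln(2) / (t_div / 60).
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("active decay constant cannot be negative")
    if t_div <= 0:
        raise ValueError("division time must be positive")
    out = gamma + np.log(2.0) / (t_div / 60.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["id", "beta_m", "beta_p", "r", "s", "m", "alpha_m", "alpha_p", "p"]


def read_gene_table(path) -> pd.DataFrame:
    """Read a tab-separated gene table (columns id, beta_m, beta_p, optional
    r, s, m, alpha_m, alpha_p, p; '.' or empty marks a missing value)."""
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"id": str})
    missing = {"id", "beta_m", "beta_p"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks required column(s): {sorted(missing)}")
    if (df["beta_m"] <= 0).any() or (df["beta_p"] <= 0).any():
        raise ValueError("gene table contains non-positive rates")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in _GENE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, na_rep=".", columns=cols)


def read_pair_table(path) -> pd.DataFrame:
    """Read a tab-separated paralog-pair table (gene1, gene2, dup_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene1", "gene2", "dup_type"} - set(df.columns)
    if missing:
        raise ValueError(f"pair table lacks required column(s): {sorted(missing)}")
    bad = ~df["dup_type"].isin([t.value for t in DuplicationType])
    if bad.any():
        raise ValueError(f"unknown duplication type(s): {df.loc[bad, 'dup_type'].unique()}")
    if (df["gene1"] == df["gene2"]).any():
        raise ValueError("pair table contains self-pairs")
    return df


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["gene1", "gene2", "dup_type"])
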