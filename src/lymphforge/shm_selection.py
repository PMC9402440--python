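"""On-target vs off-target germinal-centre mutagenesis and selection.

Somatic hypermutation (SHM) concentrates on the productive IGHV gene,
but the same germinal-centre reaction leaves off-target SBS9 mutations
genome-wide. This module computes the descriptive quantities relating
the two: the SHM rate (mutated fraction of the productive IGHV gene),
the genome-wide SBS9 burden and per-bp rate over the callable genome
(3.1 Gb minus the regions excluded from variant calling), the on/off
target density fold, the off-target-per-on-target ratio, simple linear
associations (SBS9 vs SHM rate, SBS9 vs telomere length), and the
conversion of an externally estimated dN/dS ratio into the fraction of
non-synonymous mutations under positive selection — computed after
masking the Ig loci, whose programmed hypermutation violates the
neutral-rate assumptions of the dN/dS machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOME_SIZE = 3.1e9
EXCLUDED_BP = 383e3  # average span excluded from variant calling per genome
CALLABLE_BP = GENOME_SIZE - EXCLUDED_BP

# Ig loci to mask before dN/dS (GRCh37, 1-based inclusive)
IG_MASK = (
    ("chr14", 106_304_735, 107_283_226),
    ("chr2", 89_160_078, 90_274_237),
    ("chr22", 22_385_390, 23_263_607),
)


@dataclass
class GCSummary:
    """Per-cell germinal-centre mutagenesis summary."""

    shm_rate: float  # mutated fraction of the productive IGHV gene
    sbs9_count: float
    sbs9_rate: float  # per bp of callable genome
    density_fold: float
    offtarget_ratio: float  # SBS9 mutations per on-target IGHV mutation
    capped: bool = False


def shm_rate(n_ighv_variants: int, gene_length: int) -> tuple[float, bool]:
    """Mutated fraction of the productive IGHV gene, capped at 1.

    Returns ``(rate, capped)``; the cap fires only if the variant count
    exceeds the gene length (which indicates an upstream unit problem).
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if n_ighv_variants < 0:
        raise ValueError("variant count must be non-negative")
    rate = n_ighv_variants / gene_length
    if rate > 1.0:
        return 1.0, True
    return rate, False


def sbs9_genome_rate(
    sbs9_proportion: float, snv_burden: float, callable_bp: float = CALLABLE_BP
) -> tuple[float, float]:
    """Genome-wide SBS9 count and per-bp rate.

    count = proportion x burden; rate = count / callable genome size.
    """
    if not 0 <= sbs9_proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    if callable_bp <= 0:
        raise ValueError("callable genome size must be positive")
    count = sbs9_proportion * snv_burden
    return count, count / callable_bp


def density_fold(shm_rate_: float, sbs9_rate: float) -> float:
    """How much denser mutation is at IGHV than genome-wide (plain ratio)."""
    if sbs9_rate <= 0:
        return float("nan")
    return shm_rate_ / sbs9_rate


def offtarget_ratio(sbs9_count: float, ighv_count: float) -> float:
    """Off-target SBS9 mutations per on-target IGHV mutation."""
    if ighv_count <= 0:
        return float("nan")
    return sbs9_count / ighv_count


def gc_summary(
    n_ighv_variants: int,
    gene_length: int,
    sbs9_proportion: float,
    snv_burden: float,
    callable_bp: float = CALLABLE_BP,
) -> GCSummary:
    """Assemble the per-cell summary from its raw ingredients."""
    rate, capped = shm_rate(n_ighv_variants, gene_length)
    count, per_bp = sbs9_genome_rate(sbs9_proportion, snv_burden, callable_bp)
    return GCSummary(
        shm_rate=rate,
        sbs9_count=count,
        sbs9_rate=per_bp,
        density_fold=density_fold(rate, per_bp),
        offtarget_ratio=offtarget_ratio(count, n_ighv_variants),
        capped=capped,
    )


def linear_association(x: np.ndarray, y: np.ndarray) -> dict:
    """Ordinary least squares of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "slope_se": float(res.stderr),
    }


def driver_fraction(omega: float) -> float:
    """Fraction of non-synonymous mutations under positive selection.

    With dN/dS = omega, the excess of non-synonymous mutations over the
    neutral expectation is (omega - 1)/omega of the observed
    non-synonymous mutations; clamped at 0 for omega <= 1.
    """
    if omega <= 0:
        raise ValueError("dN/dS ratio must be positive")
    return max((omega - 1.0) / omega, 0.0)


def apply_ig_mask(
    variants: pd.DataFrame,
    mask: tuple = IG_MASK,
    chrom_col: str = "chrom",
    pos_col: str = "pos",
) -> tuple[pd.DataFrame, int]:
    """Remove variants inside the Ig loci (1-based inclusive intervals).

    Returns the retained variants and the number removed.
    """
    if variants.empty:
        return variants.copy(), 0
    drop = np.zeros(len(variants), dtype=bool)
    chroms = variants[chrom_col].to_numpy()
    pos = variants[pos_col].to_numpy()
    for c, lo, hi in mask:
        drop |= (chroms == c) & (pos >= lo) & (pos <= hi)
    return variants[~drop].copy(), int(drop.sum())


def summary_table(summaries: dict[str, GCSummary]) -> pd.DataFrame:
    rows = []
    for cell, s in summaries.items():
        rows.append(
            {
                "cell": cell,
                "shm_rate": s.shm_rate,
                "sbs9_count": s.sbs9_count,
                "sbs9_rate": s.sbs9_rate,
                "density_fold": s.density_fold,
                "offtarget_ratio": s.offtarget_ratio,
                "capped": s.capped,
            }
        )
    return pd.DataFrame(rows)
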