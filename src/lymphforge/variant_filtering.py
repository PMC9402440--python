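"""Germline / artifact / somatic separation across the colonies of a donor.

Clonally expanded colonies from one donor share germline heterozygous
variants (VAF ~0.5 in every colony) while true clonal somatic variants
segregate — present at VAF ~0.5 in the carrier colonies and absent from
the rest — and sequencing artifacts appear at low, colony-independent
VAF everywhere. Three count-based tests exploit this structure:

* a mean-VAF screen (mean VAF > 40% across colonies → germline);
* a one-sided exact binomial test on summed alt/total reads against the
  heterozygous proportion (0.5 on autosomes, 0.95 on male sex
  chromosomes), with germline called on *failure* to reject at a
  Benjamini–Hochberg q of 1e-6;
* a beta-binomial overdispersion test per variant per donor, retaining
  only variants whose VAF is highly over-dispersed between colonies,
  with the score cutoff located at the valley of the score
  distribution, per donor.

Per-colony genotypes (present iff >= 2 alternate reads and VAF >= 20%)
and germline-recall sensitivity complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .synthetic_data import ReadCountMatrix

MIN_ALT_READS = 2
MIN_VAF = 0.20
GERMLINE_MEAN_VAF = 0.40
GERMLINE_Q = 1e-6
DEFAULT_RHO_GRID = np.geomspace(1e-4, 0.999, 30)
MAX_SCORE = 300.0


def call_genotype(alt: int, depth: int) -> bool:
    """Presence call for one variant in one colony.

    Present iff the colony has at least ``MIN_ALT_READS`` alternate
    reads and a VAF of at least ``MIN_VAF``. Zero depth is absent.
    """
    if alt > depth:
        raise ValueError(f"alt reads ({alt}) exceed depth ({depth})")
    if depth <= 0:
        return False
    return alt >= MIN_ALT_READS and alt / depth >= MIN_VAF


def genotype_matrix(alt: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Vectorised genotype calls (sites x colonies boolean)."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    if (alt > depth).any():
        raise ValueError("alt reads exceed depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    return (alt >= MIN_ALT_READS) & (vaf >= MIN_VAF) & (depth > 0)


def mean_vaf_screen(alt: np.ndarray, depth: np.ndarray) -> str:
    """Screen one variant across colonies: 'drop' if mean VAF > 40%.

    The mean runs over colonies with non-zero depth; if no colony has
    coverage the call is 'indeterminate'.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    covered = depth > 0
    if not covered.any():
        return "indeterminate"
    mean_vaf = float(np.mean(alt[covered] / depth[covered]))
    return "drop" if mean_vaf > GERMLINE_MEAN_VAF else "keep"


def aggregate_binomial_test(sum_alt: int, sum_depth: int, p0: float = 0.5) -> float:
    """One-sided exact binomial test of pooled reads against p0.

    Tests the alternative that the success proportion is *less* than
    p0 (0.5 for autosomes and female X, 0.95 for male sex chromosomes):
    p = P(X <= sum_alt | Binomial(sum_depth, p0)).
    """
    if sum_depth <= 0:
        raise ValueError("sum_depth must be positive")
    if not 0 <= sum_alt <= sum_depth:
        raise ValueError("sum_alt must lie in [0, sum_depth]")
    return float(stats.binom.cdf(sum_alt, sum_depth, p0))


def classify_germline(pvalues: np.ndarray, q_threshold: float = GERMLINE_Q) -> pd.DataFrame:
    """Call variants germline on failure to reject the pooled-binomial null.

    Benjamini–Hochberg q-values are computed within the donor; a variant
    is germline iff q >= ``q_threshold`` (the heterozygous-proportion
    null was not rejected).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p": [], "q": [], "germline": []})
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"p": p, "q": q, "germline": q >= q_threshold})


def _betabinom_loglik(
    alt: np.ndarray, depth: np.ndarray, mu: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial log-likelihood summed over colonies, per site.

    Mean/overdispersion parameterisation: alpha = mu (1-rho)/rho,
    beta = (1-mu)(1-rho)/rho; rho -> 0 recovers the binomial.
    """
    s = (1.0 - rho) / rho
    a = np.clip(mu * s, 1e-12, None)[:, None]
    b = np.clip((1.0 - mu) * s, 1e-12, None)[:, None]
    k, n = alt, depth
    ll = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )
    return ll.sum(axis=1)


def _binom_loglik(alt: np.ndarray, depth: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)[:, None]
    k, n = alt, depth
    ll = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(mu) + (n - k) * np.log1p(-mu)
    )
    return ll.sum(axis=1)


def _profile_mu(
    alt: np.ndarray, depth: np.ndarray, rho: float, iters: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Golden-section maximisation of the shared mean, vectorised per site."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    lo = np.full(alt.shape[0], 1e-6)
    hi = np.full(alt.shape[0], 1.0 - 1e-6)
    for _ in range(iters):
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1 = _betabinom_loglik(alt, depth, x1, rho)
        f2 = _betabinom_loglik(alt, depth, x2, rho)
        take_left = f1 > f2
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
    mu = (lo + hi) / 2.0
    return mu, _betabinom_loglik(alt, depth, mu, rho)


def betabinom_overdispersion(
    alt: np.ndarray,
    depth: np.ndarray,
    rho_grid: np.ndarray = DEFAULT_RHO_GRID,
) -> tuple[float, float]:
    """ML overdispersion of one variant's counts across colonies.

    Fits a beta-binomial with a shared mean across colonies, maximising
    over ``rho`` on a fixed grid in (0, 1) with the mean profiled out,
    and returns ``(rho_hat, lrt)`` where ``lrt`` is the log-likelihood
    ratio statistic against the binomial (rho -> 0) fit at its ML mean.
    """
    alt = np.atleast_2d(np.asarray(alt, dtype=float))
    depth = np.atleast_2d(np.asarray(depth, dtype=float))
    rho, lrt = betabinom_overdispersion_batch(alt, depth, rho_grid)
    return float(rho[0]), float(lrt[0])


def betabinom_overdispersion_batch(
    alt: np.ndarray,
    depth: np.ndarray,
    rho_grid: np.ndarray = DEFAULT_RHO_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`betabinom_overdispersion` over a site matrix."""
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.shape != depth.shape:
        raise ValueError("alt and depth shapes differ")
    covered = depth > 0
    if (covered.sum(axis=1) < 3).any():
        raise ValueError("need >= 3 colonies with coverage per variant")
    n_sites = alt.shape[0]
    # null: binomial at the pooled-mean ML estimate
    mu0 = alt.sum(axis=1) / depth.sum(axis=1)
    ll0 = _binom_loglik(alt, depth, mu0)
    best_ll = ll0.copy()
    best_rho = np.zeros(n_sites)
    for rho in np.asarray(rho_grid, dtype=float):
        _, ll = _profile_mu(alt, depth, rho)
        better = ll > best_ll + 1e-9
        best_ll = np.where(better, ll, best_ll)
        best_rho = np.where(better, rho, best_rho)
    zero = alt.sum(axis=1) == 0
    best_rho[zero] = 0.0
    best_ll[zero] = ll0[zero]
    lrt = np.maximum(2.0 * (best_ll - ll0), 0.0)
    return best_rho, lrt


def overdispersion_score(lrt: np.ndarray) -> np.ndarray:
    """-log10 tail probability of the boundary-corrected chi-square LRT.

    The null value rho = 0 lies on the boundary of the parameter space,
    so the LRT reference distribution is an equal mixture of a point
    mass at zero and chi-square(1); the tail probability is halved.
    """
    lrt = np.asarray(lrt, dtype=float)
    with np.errstate(divide="ignore"):
        p = 0.5 * stats.chi2.sf(lrt, df=1)
        score = np.where(p > 0, -np.log10(np.maximum(p, 1e-320)), MAX_SCORE)
    return np.minimum(score, MAX_SCORE)


def valley_threshold(
    scores: np.ndarray,
    fallback: float | None = None,
    grid_size: int = 512,
) -> tuple[float, bool]:
    """Score cutoff at the valley of a bimodal score distribution.

    A Gaussian kernel-density estimate (Silverman bandwidth) is
    evaluated on a regular grid; the cutoff is the deepest local
    minimum lying between the two largest modes (ties broken toward
    the smaller score). If the density is unimodal the configured
    ``fallback`` is returned with the fallback flag raised.

    Returns ``(cutoff, used_fallback)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 50:
        raise ValueError(f"need >= 50 scores for a reliable density, got {scores.size}")
    if fallback is None:
        fallback = float(np.median(scores))
    if np.ptp(scores) == 0:
        return float(fallback), True
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    pad = 0.05 * np.ptp(scores)
    grid = np.linspace(scores.min() - pad, scores.max() + pad, grid_size)
    dens = kde(grid)
    interior = dens[1:-1]
    maxima = np.where((interior > dens[:-2]) & (interior >= dens[2:]))[0] + 1
    if len(maxima) < 2:
        return float(fallback), True
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    between = np.arange(left + 1, right)
    if len(between) == 0:
        return float(fallback), True
    minima = between[
        (dens[between] < dens[between - 1]) & (dens[between] <= dens[between + 1])
    ]
    if len(minima) == 0:
        minima = between
    cut_idx = minima[np.argmin(dens[minima])]
    # a genuine valley must dip well below the smaller mode; shallow dips
    # are KDE wiggle on a unimodal sample
    if dens[cut_idx] > 0.8 * min(dens[left], dens[right]):
        return float(fallback), True
    return float(grid[cut_idx]), False


def germline_recall_sensitivity(
    genotypes: np.ndarray, germline_mask: np.ndarray
) -> np.ndarray:
    """Per-colony sensitivity as the fraction of germline variants detected.

    ``genotypes`` is the sites x colonies presence matrix; the germline
    truth set is given by ``germline_mask`` over sites.
    """
    germline_mask = np.asarray(germline_mask, dtype=bool)
    if germline_mask.sum() == 0:
        raise ValueError("germline set is empty")
    sub = np.asarray(genotypes)[germline_mask]
    return sub.mean(axis=0)


@dataclass
class FilterResult:
    """Outcome of the per-donor filtering cascade."""

    labels: pd.Series  # germline | somatic | artifact per site
    score: pd.Series  # -log10 overdispersion tail probability
    p_aggregate: pd.Series
    q_aggregate: pd.Series
    cutoff: float
    cutoff_fallback: bool
    genotypes: pd.DataFrame  # sites x colonies presence
    sensitivity: pd.Series  # per-colony germline recall

    def __post_init__(self) -> None:
        order = np.argsort(self.p_aggregate.to_numpy())
        q = self.q_aggregate.to_numpy()[order]
        if (np.diff(q) < -1e-12).any():
            raise ValueError("q-values are not monotone in p")


def filter_donor(
    rc: ReadCountMatrix,
    p0: float = 0.5,
    fallback_cutoff: float = 10.0,
    rho_grid: np.ndarray = DEFAULT_RHO_GRID,
    subclonal: pd.Series | None = None,
    blacklist: pd.Series | None = None,
) -> FilterResult:
    """Run the full filtering cascade on one donor's read-count matrix.

    Order of evidence: the mean-VAF screen and the pooled exact-binomial
    test identify germline variants; among the remainder, variants whose
    between-colony overdispersion score clears the per-donor valley
    cutoff are somatic and the rest are rejected as artifacts. An
    optional external ``subclonal`` boolean series (e.g. from a
    subclonality caller) is AND-ed with the overdispersion pass; an
    optional ``blacklist`` rejects sites outright.
    """
    alt = rc.alt.to_numpy(dtype=float)
    depth = rc.total.to_numpy(dtype=float)
    sites = rc.alt.index

    covered = depth > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(covered, alt / np.maximum(depth, 1), np.nan)
    mean_vaf = np.nanmean(np.where(covered, vaf, np.nan), axis=1)
    vaf_drop = mean_vaf > GERMLINE_MEAN_VAF

    p_agg = stats.binom.cdf(alt.sum(axis=1), depth.sum(axis=1), p0)
    germ_tab = classify_germline(p_agg)
    germline = vaf_drop | germ_tab["germline"].to_numpy()

    rho, lrt = betabinom_overdispersion_batch(alt, depth, rho_grid)
    score = overdispersion_score(lrt)

    candidate_scores = score[~germline]
    if candidate_scores.size >= 50:
        cutoff, used_fallback = valley_threshold(candidate_scores, fallback_cutoff)
    else:
        cutoff, used_fallback = fallback_cutoff, True

    passed = score >= cutoff
    if subclonal is not None:
        passed &= subclonal.reindex(sites).fillna(False).to_numpy(dtype=bool)
    if blacklist is not None:
        passed &= ~blacklist.reindex(sites).fillna(False).to_numpy(dtype=bool)

    labels = np.where(germline, "germline", np.where(passed, "somatic", "artifact"))
    genotypes = genotype_matrix(alt, depth)
    sens = germline_recall_sensitivity(genotypes, germline)

    return FilterResult(
        labels=pd.Series(labels, index=sites, name="label"),
        score=pd.Series(score, index=sites, name="score"),
        p_aggregate=pd.Series(p_agg, index=sites, name="p"),
        q_aggregate=pd.Series(germ_tab["q"].to_numpy(), index=sites, name="q"),
        cutoff=cutoff,
        cutoff_fallback=used_fallback,
        genotypes=pd.DataFrame(genotypes, index=sites, columns=rc.alt.columns),
        sensitivity=pd.Series(sens, index=rc.alt.columns, name="sensitivity"),
    )


def analytic_genotype_sensitivity(depth: int, het_vaf: float = 0.5) -> float:
    """Detection probability of a heterozygous variant at fixed depth.

    Under alt ~ Binomial(depth, het_vaf), a variant is detected when the
    genotype rule fires: alt >= MIN_ALT_READS and alt/depth >= MIN_VAF.
    """
    k = np.arange(depth + 1)
    detected = (k >= MIN_ALT_READS) & (k / depth >= MIN_VAF)
    return float(stats.binom.pmf(k[detected], depth, het_vaf).sum())


def write_filter_report(result: FilterResult, path) -> None:
    """TSV report: per-variant labels/statistics plus per-colony sensitivity."""
    tab = pd.DataFrame(
        {
            "label": result.labels,
            "score": result.score,
            "p_aggregate": result.p_aggregate,
            "q_aggregate": result.q_aggregate,
        }
    )
    tab.to_csv(path, sep="\t", index_label="site")


def write_filtered_vcf(rc: ReadCountMatrix, result: FilterResult, path) -> None:
    """Minimal VCF 4.2 with GERMLINE / ARTEFACT_BB / PASS filter tags."""
    tag = {"germline": "GERMLINE", "artifact": "ARTEFACT_BB", "somatic": "PASS"}
    cols = list(rc.alt.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=GERMLINE,Description="Pooled reads consistent with germline">\n')
        fh.write('##FILTER=<ID=ARTEFACT_BB,Description="Not overdispersed between colonies">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cols) + "\n")
        for sid in rc.alt.index:
            s = rc.sites.loc[sid]
            ads = "\t".join(
                f"{int(rc.total.loc[sid, c] - rc.alt.loc[sid, c])},{int(rc.alt.loc[sid, c])}"
                for c in cols
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt_allele}\t.\t"
                f"{tag[result.labels.loc[sid]]}\t.\tAD\t{ads}\n"
            )
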