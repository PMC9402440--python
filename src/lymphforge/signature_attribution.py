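"""Mutational-signature exposure estimation and attribution.

A signature catalogue is a set of probability distributions over the 96
trinucleotide substitution channels; a sample's catalogue of mutation
counts is modelled as Multinomial(n, sum_s w_s S_s) where the exposures
w live on the simplex. Point estimates are maximum likelihood (EM for
mixture proportions); uncertainty comes from a seeded multinomial
bootstrap whose 90% percentile interval drives the display rule
(signatures whose 90% lower bound is below 1% are masked per sample).
A two-pass rule removes signatures at nominal frequency — below 10%
exposure in every sample — and refits on the reduced catalogue.

Attribution descends from sample to variant: the posterior probability
that signature s generated a mutation in channel c is
w_s S_s[c] / sum_t w_t S_t[c]. Per-variant posteriors aggregate into
fine (10-kb) bins under their parent 1-Mb window's exposures, and into
per-gene enrichment t-tests against the genome-wide mean attribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CHANNELS_96

NOMINAL_EXPOSURE = 0.10  # two-pass exclusion: below this in every sample
DISPLAY_LOWER_BOUND = 0.01  # 90%-interval lower-bound display rule
WINDOW_INCLUSION = 0.5  # mean attribution a fine bin needs for inclusion

DEFAULT_SIGNATURE_NAMES = (
    "SBSblood",
    "SBS1",
    "SBS5",
    "SBS7a",
    "SBS8",
    "SBS9",
    "SBS13",
    "SBS17b",
    "SBS18",
    "SBS19",
    "SHM",
)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two 96-channel spectra (scale-invariant)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def make_synthetic_signatures(
    names: tuple[str, ...] = DEFAULT_SIGNATURE_NAMES, seed: int = 20_220_831
) -> pd.DataFrame:
    """Deterministic synthetic signature catalogue (signatures x 96).

    Sparse Dirichlet draws stand in for a real catalogue: each synthetic
    signature concentrates on a small set of channels, so signatures are
    mutually distinguishable (pairwise cosine similarity well below the
    0.85 identity threshold). Rows sum to 1.
    """
    rng = np.random.default_rng(seed)
    S = rng.dirichlet(np.full(96, 0.08), size=len(names))
    return pd.DataFrame(S, index=list(names), columns=list(CHANNELS_96))


def load_signature_catalog(path=None) -> pd.DataFrame:
    """Load a catalogue TSV (96 rows x S signature columns) as signatures x 96.

    Defaults to the packaged synthetic stand-in catalogue.
    """
    if path is None:
        path = resources.files("lymphforge.data") / "synthetic_signatures_96.tsv"
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS_96):
        raise ValueError("catalogue rows must be the 96 channels in canonical order")
    sigs = df.T
    rowsum = sigs.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-4):
        raise ValueError("each signature must sum to 1 over the 96 channels")
    return sigs.div(rowsum, axis=0)


def save_signature_catalog(sigs: pd.DataFrame, path) -> None:
    sigs.T.to_csv(path, sep="\t", index_label="channel", float_format="%.8g")


@dataclass
class ExposureVector:
    """Per-signature mixing proportions with bootstrap 90% intervals."""

    names: list[str]
    proportions: np.ndarray
    lower: np.ndarray  # 5th percentile
    upper: np.ndarray  # 95th percentile
    burden: int

    def __post_init__(self) -> None:
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-6):
            raise ValueError("exposures must sum to 1")
        if ((self.lower > self.proportions + 1e-9) | (self.proportions > self.upper + 1e-9)).any():
            raise ValueError("interval bounds must bracket the point estimate")

    @property
    def counts(self) -> np.ndarray:
        return self.proportions * self.burden

    @property
    def display_mask(self) -> np.ndarray:
        """True where the 90% lower bound reaches 1%."""
        return self.lower >= DISPLAY_LOWER_BOUND

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.names)


def _em_exposures(counts: np.ndarray, S: np.ndarray, tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
    """ML mixture proportions for Multinomial(n, w @ S) by EM."""
    K = S.shape[0]
    w = np.full(K, 1.0 / K)
    n = counts.sum()
    for _ in range(max_iter):
        mix = w @ S  # (96,)
        mix = np.clip(mix, 1e-300, None)
        resp = (w[:, None] * S) / mix  # (K, 96) posterior per channel
        w_new = resp @ counts / n
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    return w / w.sum()


def fit_exposures(
    catalog: np.ndarray,
    sigs: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
) -> ExposureVector:
    """Estimate signature exposures for one sample's 96-channel counts.

    Point estimate by maximum likelihood under the multinomial mixture;
    a seeded multinomial bootstrap (``n_boot`` refits of resampled
    catalogues) gives the 90% percentile interval per signature.
    """
    counts = np.asarray(catalog, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"catalogue must have 96 channels, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("negative catalogue counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty catalogue")
    S = np.asarray(sigs, dtype=float)
    w = _em_exposures(counts, S)
    rng = np.random.default_rng(seed)
    p = counts / n
    boots = np.empty((n_boot, len(w)))
    for b in range(n_boot):
        resampled = rng.multinomial(int(n), p)
        boots[b] = _em_exposures(resampled.astype(float), S, tol=1e-8, max_iter=500)
    lower = np.minimum(np.percentile(boots, 5, axis=0), w)
    upper = np.maximum(np.percentile(boots, 95, axis=0), w)
    return ExposureVector(
        names=list(sigs.index), proportions=w, lower=lower, upper=upper, burden=int(n)
    )


def exclude_and_refit(
    catalogs: pd.DataFrame,
    sigs: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    nominal: float = NOMINAL_EXPOSURE,
) -> tuple[pd.DataFrame, dict[str, ExposureVector]]:
    """Two-pass exposure estimation over a cohort of samples.

    First pass fits all signatures per sample (rows of ``catalogs`` are
    samples, columns the 96 channels). Signatures whose exposure stays
    below ``nominal`` (10%) in *every* sample are dropped, and exposures
    are refitted against the reduced catalogue. Returns the reduced
    signature matrix and the per-sample refitted exposures.
    """
    first = {}
    for i, (sample, row) in enumerate(catalogs.iterrows()):
        first[sample] = fit_exposures(row.to_numpy(), sigs, n_boot=1, seed=seed + i)
    exp_mat = np.vstack([first[s].proportions for s in catalogs.index])
    keep = (exp_mat >= nominal).any(axis=0)
    if not keep.any():
        raise ValueError("exclusion rule removed every signature")
    reduced = sigs.iloc[keep]
    refit = {}
    for i, (sample, row) in enumerate(catalogs.iterrows()):
        refit[sample] = fit_exposures(
            row.to_numpy(), reduced, n_boot=n_boot, seed=seed + 1000 + i
        )
    return reduced, refit


def per_variant_attribution(
    channel: int, exposures: np.ndarray, sigs: pd.DataFrame
) -> np.ndarray:
    """Posterior P(signature | channel) under the fitted exposures."""
    w = np.asarray(exposures, dtype=float)
    S = np.asarray(sigs, dtype=float)
    if not 0 <= channel < 96:
        raise ValueError(f"channel index {channel} outside 0..95")
    num = w * S[:, channel]
    total = num.sum()
    if total <= 0:
        raise ValueError(f"channel {channel} has zero probability under every active signature")
    return num / total


def attribution_matrix(exposures: np.ndarray, sigs: pd.DataFrame) -> np.ndarray:
    """P(signature | channel) for all 96 channels (signatures x 96)."""
    w = np.asarray(exposures, dtype=float)
    S = np.asarray(sigs, dtype=float)
    num = w[:, None] * S
    denom = num.sum(axis=0)
    # channels unreachable under the active signatures become NaN; callers
    # must only look them up for observed mutations (then it is an error)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)


def window_attribution(
    mutations: pd.DataFrame,
    window_exposures: dict[object, np.ndarray],
    sigs: pd.DataFrame,
    bin_col: str = "bin",
    window_col: str = "window",
    channel_col: str = "channel",
) -> pd.DataFrame:
    """Distribute mutations over signatures within fine genomic bins.

    Each mutation contributes its per-variant posterior — computed under
    the exposures of its parent coarse window — to its fine bin, so the
    per-bin signature counts sum exactly to the raw per-bin mutation
    count. A fine bin is *included* for a signature iff the mean
    attribution over its mutations exceeds 1/2 (guards against small
    attributions riding on high overall mutation rates).

    Returns a table indexed by fine bin with, per signature, the
    attributed count and the inclusion flag, plus the raw count.
    """
    sig_names = list(sigs.index)
    missing = set(mutations[window_col]) - set(window_exposures)
    if missing:
        raise ValueError(f"mutations fall in windows without exposures: {sorted(missing)[:3]}")
    att_by_window = {
        wname: attribution_matrix(wexp, sigs) for wname, wexp in window_exposures.items()
    }
    rows = {}
    for (b, wname), grp in mutations.groupby([bin_col, window_col], sort=True):
        A = att_by_window[wname]  # (K, 96)
        post = A[:, grp[channel_col].to_numpy()]  # (K, n_mut)
        if np.isnan(post).any():
            bad = int(grp[channel_col].to_numpy()[np.isnan(post).any(axis=0)][0])
            raise ValueError(
                f"channel {bad} has zero probability under window {wname!r} exposures"
            )
        entry = rows.setdefault(b, {"raw_count": 0, "post_sum": np.zeros(len(sig_names))})
        entry["raw_count"] += len(grp)
        entry["post_sum"] += post.sum(axis=1)
    out = []
    for b, entry in rows.items():
        rec = {"bin": b, "raw_count": entry["raw_count"]}
        mean_att = entry["post_sum"] / entry["raw_count"]
        for j, s in enumerate(sig_names):
            rec[f"{s}_count"] = entry["post_sum"][j]
            rec[f"{s}_included"] = mean_att[j] > WINDOW_INCLUSION
        out.append(rec)
    return pd.DataFrame(out).set_index("bin")


def gene_signature_enrichment(
    attributions: pd.DataFrame,
    gene_col: str = "gene",
    value_col: str = "attribution",
) -> pd.DataFrame:
    """Per-gene mean attribution and two-sided t-test vs genomic background.

    The background is the genome-wide mean attribution over all
    variants; each gene with >= 2 variants gets a one-sample two-sided
    t-test of its variants' attributions against that mean. Genes with a
    single variant are reported with NaN p and a flag.
    """
    background = float(attributions[value_col].mean())
    rows = []
    for gene, grp in attributions.groupby(gene_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            rows.append(
                {"gene": gene, "n": len(vals), "mean_attribution": float(vals.mean()),
                 "p": np.nan, "testable": False}
            )
            continue
        if np.ptp(vals) == 0:
            # degenerate: all attributions identical; t is 0/0
            p = 1.0 if np.isclose(vals[0], background) else 0.0
        else:
            _, p = stats.ttest_1samp(vals, background)
        rows.append(
            {"gene": gene, "n": len(vals), "mean_attribution": float(vals.mean()),
             "p": float(p), "testable": True}
        )
    out = pd.DataFrame(rows)
    out["background"] = background
    return out
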