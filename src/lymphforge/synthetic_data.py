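"""Synthetic data generators with known ground truth.

Every generator here emulates one layer of a colony-based whole-genome
sequencing study of lymphocytes and haematopoietic stem/progenitor
cells: highly clonal colonies grown from single cells, sequenced at
moderate depth, sharing germline variants at VAF ~0.5 and carrying
clonal somatic variants private to subsets of colonies. Generators are
pure functions of their configuration (including the seed) and emit the
generating truth alongside each dataset, so every downstream stage can
be scored against known labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import CELL_TYPES
from .contexts import CHANNELS_96

logger = logging.getLogger(__name__)

# Generating values for the burden model: accumulation slopes
# (SNV/cell/year), differentiation-associated offsets relative to HSPC
# (SNV/cell), within-donor residual s.d. per cell type and between-donor
# s.d. (SNV/cell). Naive-cell residual s.d. is not separately
# characterised for this system; 150 sits between the stem-cell and
# memory-cell scales.
DEFAULT_SLOPES = {
    "HSPC": 16.0,
    "naive_B": 15.0,
    "memory_B": 17.0,
    "naive_T": 22.0,
    "memory_T": 25.0,
}
DEFAULT_OFFSETS = {
    "HSPC": 0.0,
    "naive_B": 110.0,
    "memory_B": 1034.0,
    "naive_T": 59.0,
    "memory_T": 277.0,
}
DEFAULT_RESID_SD = {
    "HSPC": 70.0,
    "naive_B": 150.0,
    "memory_B": 820.0,
    "naive_T": 150.0,
    "memory_T": 592.0,
}
DEFAULT_DONOR_SD = 60.0
DEFAULT_AGES = (25.0, 38.0, 55.0, 77.0, 63.0, 81.0, 29.0, 48.0)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration cannot produce data."""


@dataclass
class SimConfig:
    """Configuration shared by the colony-level generators.

    Parameters mirror the quantities the downstream models estimate:
    per-cell-type accumulation slopes and differentiation offsets, the
    within-donor residual and between-donor standard deviations, the
    sequencing depth, and the composition of the simulated site set.
    """

    seed: int = 0
    n_donors: int = 4
    ages: tuple[float, ...] | None = None
    cell_types: tuple[str, ...] = CELL_TYPES
    slope_per_type: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    offset_per_type: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    resid_sd_per_type: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RESID_SD))
    donor_sd: float = DEFAULT_DONOR_SD
    depth_mean: float = 20.0
    genome_length: int = 10_000_000
    n_colonies: int = 30
    n_colonies_per_group: int = 10
    n_germline_sites: int = 6000
    n_somatic_sites: int = 3000
    n_artifact_sites: int = 1000
    private_fraction: float = 0.8  # somatic variants private to one colony

    def __post_init__(self) -> None:
        if self.ages is None:
            self.ages = tuple(DEFAULT_AGES[i % len(DEFAULT_AGES)] for i in range(self.n_donors))
        self.ages = tuple(float(a) for a in self.ages)
        if len(self.ages) != self.n_donors:
            raise ConfigurationError(
                f"ages has {len(self.ages)} entries for {self.n_donors} donors"
            )
        if not self.cell_types:
            raise ConfigurationError("cell_types must be non-empty")
        for name, value in [
            ("donor_sd", self.donor_sd),
            ("depth_mean", self.depth_mean),
            ("genome_length", self.genome_length),
            ("n_germline_sites", self.n_germline_sites),
            ("n_somatic_sites", self.n_somatic_sites),
            ("n_artifact_sites", self.n_artifact_sites),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {value}")
        for t in self.cell_types:
            for m, label in [
                (self.slope_per_type, "slope_per_type"),
                (self.offset_per_type, "offset_per_type"),
                (self.resid_sd_per_type, "resid_sd_per_type"),
            ]:
                if t not in m:
                    raise ConfigurationError(f"{label} missing cell type {t!r}")
                if m[t] < 0 and label != "offset_per_type":
                    raise ConfigurationError(f"{label}[{t!r}] must be non-negative")
        if not 0.0 <= self.private_fraction <= 1.0:
            raise ConfigurationError("private_fraction must lie in [0, 1]")


@dataclass
class ReadCountMatrix:
    """Per-site x per-colony alternate and total read counts."""

    alt: pd.DataFrame  # sites x colonies, integer alt reads
    total: pd.DataFrame  # sites x colonies, integer depth
    sites: pd.DataFrame  # chrom, pos, ref, alt_allele per site

    def __post_init__(self) -> None:
        if self.alt.shape != self.total.shape:
            raise ValueError("alt and total matrices differ in shape")
        if (self.alt.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("alt counts exceed depth")

    @property
    def vaf(self) -> pd.DataFrame:
        """Variant allele fraction, NaN where depth is zero."""
        total = self.total.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(total > 0, self.alt.to_numpy(dtype=float) / total, np.nan)
        return pd.DataFrame(v, index=self.alt.index, columns=self.alt.columns)


@dataclass
class TruthBundle:
    """Generating truth emitted alongside each synthetic dataset."""

    site_labels: pd.Series | None = None  # germline | somatic | artifact per site
    somatic_carriers: dict[str, np.ndarray] | None = None  # site -> colony indices
    per_colony_somatic_count: pd.Series | None = None
    per_variant_signature: pd.Series | None = None
    per_bin_expected: np.ndarray | None = None
    sv_mechanism: pd.Series | None = None  # RAG | CSR | other
    placement_probabilities: np.ndarray | None = None


def _truncated_poisson_depth(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    """Per-site depth ~ Poisson(mean), truncated at >=1."""
    return np.maximum(1, rng.poisson(mean, size=size))


def simulate_colony_readcounts(
    config: SimConfig, donor: str = "donor1"
) -> tuple[ReadCountMatrix, pd.DataFrame, TruthBundle]:
    """Simulate read counts for the colonies of one donor.

    Germline heterozygous sites draw alternate reads at VAF 0.5 in every
    colony; each clonal somatic site does so only in its carrier
    colonies (private to one colony with probability
    ``private_fraction``, otherwise shared by a random clade of
    colonies); artifact sites draw from a binomial with a small
    site-specific error probability that is *shared* across colonies, so
    they show no between-colony overdispersion.

    Returns the read-count matrix, colony metadata and the truth bundle.
    """
    n_col = config.n_colonies
    n_sites = config.n_germline_sites + config.n_somatic_sites + config.n_artifact_sites
    if n_col <= 0 or n_sites <= 0:
        raise ConfigurationError("need at least one colony and one site")
    rng = np.random.default_rng(config.seed)

    positions = np.sort(
        rng.choice(config.genome_length, size=n_sites, replace=False)
    ) + 1  # 1-based
    labels = np.array(
        ["germline"] * config.n_germline_sites
        + ["somatic"] * config.n_somatic_sites
        + ["artifact"] * config.n_artifact_sites
    )
    rng.shuffle(labels)

    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, n_sites)]
    alt_allele = np.array(
        [bases[(np.where(bases == r)[0][0] + rng.integers(1, 4)) % 4] for r in ref]
    )

    depth = _truncated_poisson_depth(rng, config.depth_mean, (n_sites, n_col))
    p = np.zeros((n_sites, n_col))
    carriers: dict[str, np.ndarray] = {}
    site_ids = [f"chr1:{pos}" for pos in positions]

    germ_mask = labels == "germline"
    p[germ_mask, :] = 0.5

    som_idx = np.where(labels == "somatic")[0]
    for i in som_idx:
        if n_col == 1 or rng.random() < config.private_fraction:
            cset = rng.integers(0, n_col, size=1)
        else:
            k = rng.integers(2, max(3, n_col // 3) + 1)
            cset = rng.choice(n_col, size=min(k, n_col), replace=False)
        carriers[site_ids[i]] = np.sort(cset)
        p[i, cset] = 0.5

    art_idx = np.where(labels == "artifact")[0]
    err = rng.uniform(0.01, 0.05, size=len(art_idx))
    p[art_idx, :] = err[:, None]

    alt = rng.binomial(depth, p)

    colonies = [f"{donor}_c{j:03d}" for j in range(n_col)]
    rc = ReadCountMatrix(
        alt=pd.DataFrame(alt, index=site_ids, columns=colonies),
        total=pd.DataFrame(depth, index=site_ids, columns=colonies),
        sites=pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "ref": ref, "alt_allele": alt_allele},
            index=site_ids,
        ),
    )
    age = config.ages[0]
    meta = pd.DataFrame(
        {
            "colony": colonies,
            "donor": donor,
            "age": age,
            "cell_type": [config.cell_types[j % len(config.cell_types)] for j in range(n_col)],
            "mean_depth": depth.mean(axis=0),
        }
    )
    som_count = pd.Series(0, index=colonies, name="true_somatic_count")
    for sid, cset in carriers.items():
        for c in cset:
            som_count.iloc[c] += 1
    truth = TruthBundle(
        site_labels=pd.Series(labels, index=site_ids, name="true_label"),
        somatic_carriers=carriers,
        per_colony_somatic_count=som_count,
    )
    return rc, meta, truth


def simulate_burden_table(config: SimConfig) -> pd.DataFrame:
    """Simulate per-colony adjusted mutation burdens.

    burden = slope_type * age + offset_type + donor_effect + residual,
    with donor_effect ~ N(0, donor_sd^2) drawn per donor-by-cell-type
    group and residual ~ N(0, resid_sd_type^2) per colony. Negative
    draws are clamped to zero and flagged (burdens are counts).
    """
    if config.n_donors < 2:
        raise ConfigurationError("need >=2 donors for an identifiable design")
    if len(set(config.ages)) < 2:
        warnings.warn("all donors share one age; the slope is unidentifiable", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    rows = []
    for d in range(config.n_donors):
        donor = f"donor{d + 1}"
        age = config.ages[d]
        for ct in config.cell_types:
            donor_effect = rng.normal(0.0, config.donor_sd)
            resid = rng.normal(0.0, config.resid_sd_per_type[ct], size=config.n_colonies_per_group)
            burden = (
                config.slope_per_type[ct] * age
                + config.offset_per_type[ct]
                + donor_effect
                + resid
            )
            for j, b in enumerate(burden):
                rows.append(
                    {
                        "colony": f"{donor}_{ct}_c{j:03d}",
                        "donor": donor,
                        "age": age,
                        "cell_type": ct,
                        "burden": b,
                        "clamped": b < 0,
                    }
                )
    table = pd.DataFrame(rows)
    n_neg = int(table["clamped"].sum())
    if n_neg:
        logger.warning("clamped %d negative simulated burdens to zero", n_neg)
        table.loc[table["clamped"], "burden"] = 0.0
    return table


def simulate_catalog(
    exposures: Sequence[float],
    signatures: pd.DataFrame,
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw a 96-channel mutation catalogue from a signature mixture.

    ``signatures`` holds one signature per row (rows sum to 1 over the
    96 channels); ``exposures`` are the mixing proportions. Counts are
    Multinomial(n, sum_s w_s S_s), so the total is exactly ``n``.
    """
    w = np.asarray(exposures, dtype=float)
    if (w < 0).any():
        raise ValueError("exposures must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"exposures must sum to 1, got {w.sum():.6f}")
    S = np.asarray(signatures, dtype=float)
    if S.shape != (len(w), 96):
        raise ValueError(f"signatures must be {len(w)} x 96, got {S.shape}")
    if not np.allclose(S.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each signature must sum to 1 over the 96 channels")
    probs = w @ S
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(n), probs / probs.sum())


def simulate_feature_bins(
    n_bins: int,
    link: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    seed: int,
    beta0: float = np.log(5.0),
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Simulate genomic bins whose mutation count depends on features.

    Feature values are i.i.d. standard normal per bin; the per-bin count
    is Poisson(exp(beta0 + sum_f g_f(x_f))) for the smooth link
    functions ``g_f``. The true log-rate is recorded per bin.
    """
    if not link:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    features = list(link)
    X = rng.standard_normal((n_bins, len(features)))
    eta = np.full(n_bins, float(beta0))
    for j, f in enumerate(features):
        eta = eta + np.asarray(link[f](X[:, j]), dtype=float)
    rate = np.exp(eta)
    counts = rng.poisson(rate)
    table = pd.DataFrame(X, columns=features)
    table.insert(0, "chrom", "chr1")
    table.insert(1, "start", np.arange(n_bins) * bin_size)
    table.insert(2, "end", (np.arange(n_bins) + 1) * bin_size)
    table["count"] = counts
    table["true_log_rate"] = eta
    return table


RSS_HEPTAMER = "CACAGTG"
CSR_MOTIFS = ("AGCT", "TGCA")


def simulate_reference_and_svs(
    genome_length: int,
    n_svs: int,
    rag_fraction: float,
    csr_fraction: float,
    seed: int,
    igtcr_fraction: float = 0.1,
) -> tuple[str, pd.DataFrame, TruthBundle]:
    """Simulate a reference sequence and SV breakpoints with planted motifs.

    RAG-true deletions carry an exact RSS heptamer (CACAGTG) planted
    within 50 bp interior to one breakpoint; CSR-true SVs carry a
    cluster of AGCT/TGCA occurrences (gaps <= 100 bp) within 1,000 bp of
    a breakpoint; the remaining sequence is i.i.d. uniform A/C/G/T. The
    interval [1, igtcr_fraction * genome_length] on the synthetic contig
    is designated the Ig-TCR region.
    """
    if not (0 <= rag_fraction <= 1 and 0 <= csr_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if rag_fraction + csr_fraction > 1 + 1e-12:
        raise ValueError("rag_fraction + csr_fraction must be <= 1")
    span_needed = n_svs * 5000 + 4000
    if genome_length < span_needed:
        raise ValueError(
            f"genome of {genome_length} bp too short for {n_svs} SVs (need >= {span_needed})"
        )
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=genome_length)
    bases = np.array(["A", "C", "G", "T"])

    n_rag = int(round(rag_fraction * n_svs))
    n_csr = int(round(csr_fraction * n_svs))
    mech = np.array(["RAG"] * n_rag + ["CSR"] * n_csr + ["other"] * (n_svs - n_rag - n_csr))
    rng.shuffle(mech)

    ig_end = int(igtcr_fraction * genome_length)
    rows = []
    # non-overlapping deletion footprints on a regular grid, jittered
    slot = (genome_length - 4000) // max(n_svs, 1)
    base_idx = {b: i for i, b in enumerate(bases)}

    def plant(motif: str, start0: int) -> None:
        for k, b in enumerate(motif):
            seq[start0 + k] = base_idx[b]

    for i in range(n_svs):
        a = 2000 + i * slot + int(rng.integers(0, max(1, slot // 4)))
        length = int(rng.integers(1000, 4000))
        b = a + length
        m = mech[i]
        if m == "RAG":
            offset = int(rng.integers(5, 44))  # interior to the deletion
            plant(RSS_HEPTAMER, a - 1 + offset)  # a is 1-based
        elif m == "CSR":
            n_rep = int(rng.integers(2, 6))
            pos0 = a - 1 + int(rng.integers(10, 800))
            for _ in range(n_rep):
                motif = CSR_MOTIFS[int(rng.integers(0, 2))]
                plant(motif, pos0)
                pos0 += len(motif) + int(rng.integers(5, 90))
        ins = ""
        ins_p = 0.45 if m == "RAG" else 0.20
        if rng.random() < ins_p:
            ins = "".join(bases[rng.integers(0, 4, size=int(rng.integers(1, 12)))])
        rows.append(
            {
                "chrom1": "chrS",
                "pos1": a,
                "strand1": "+",
                "chrom2": "chrS",
                "pos2": b,
                "strand2": "-",
                "svclass": "deletion",
                "region": "IgTCR" if (a <= ig_end or b <= ig_end) else "other",
                "insseq": ins,
            }
        )
    svs = pd.DataFrame(rows)
    reference = "".join(bases[seq])
    truth = TruthBundle(sv_mechanism=pd.Series(mech, name="true_mechanism"))
    return reference, svs, truth


def simulate_epigenome_tracks(
    n_tracks: int,
    n_windows: int,
    placement_track: int,
    n_mutations: int,
    seed: int,
    autocorr: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, TruthBundle]:
    """Simulate smooth epigenome tracks and mutations placed by one of them.

    Tracks are independent positive AR(1) series over genomic windows
    (exponentiated, so strictly positive and autocorrelated). Mutations
    are multinomially placed across windows with probability
    proportional to exp of the z-scored placement track — a monotone
    transform, so windows high in the placement track collect more
    mutations.
    """
    if n_windows < 10:
        raise ValueError("need >= 10 windows for cross-validated evaluation")
    if not 0 <= placement_track < n_tracks:
        raise ValueError(f"placement_track {placement_track} outside 0..{n_tracks - 1}")
    rng = np.random.default_rng(seed)
    z = np.empty((n_windows, n_tracks))
    z[0] = rng.standard_normal(n_tracks)
    innov_sd = np.sqrt(1 - autocorr**2)
    for t in range(1, n_windows):
        z[t] = autocorr * z[t - 1] + innov_sd * rng.standard_normal(n_tracks)
    tracks = np.exp(z)  # smooth, positive
    zp = (z[:, placement_track] - z[:, placement_track].mean()) / z[:, placement_track].std()
    probs = np.exp(zp)
    probs /= probs.sum()
    counts = (
        rng.multinomial(int(n_mutations), probs)
        if n_mutations > 0
        else np.zeros(n_windows, dtype=int)
    )
    truth = TruthBundle(placement_probabilities=probs)
    return tracks, counts, truth


# ---------------------------------------------------------------------------
# plain-text writers


def write_readcounts_tsv(rc: ReadCountMatrix, path) -> None:
    """Write site rows with paired <colony>.alt / <colony>.total columns."""
    out = rc.sites.copy()
    for col in rc.alt.columns:
        out[f"{col}.alt"] = rc.alt[col]
        out[f"{col}.total"] = rc.total[col]
    out.to_csv(path, sep="\t", index=False)


def read_readcounts_tsv(path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t")
    site_ids = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    alt_cols = [c for c in df.columns if c.endswith(".alt")]
    colonies = [c[: -len(".alt")] for c in alt_cols]
    alt = pd.DataFrame(
        {c: df[f"{c}.alt"].to_numpy() for c in colonies}, index=site_ids
    )
    total = pd.DataFrame(
        {c: df[f"{c}.total"].to_numpy() for c in colonies}, index=site_ids
    )
    sites = df[["chrom", "pos", "ref", "alt_allele"]].set_index(site_ids)
    return ReadCountMatrix(alt=alt, total=total, sites=sites)


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedpe(svs: pd.DataFrame, path) -> None:
    """BEDPE (0-based half-open breakpoint intervals) with class/region/insseq."""
    with open(path, "w") as fh:
        for _, r in svs.iterrows():
            fh.write(
                f"{r.chrom1}\t{r.pos1 - 1}\t{r.pos1}\t{r.chrom2}\t{r.pos2 - 1}\t{r.pos2}"
                f"\t{r.svclass}\t.\t{r.strand1}\t{r.strand2}\t{r.region}\t{r.insseq}\n"
            )


def read_bedpe(path) -> pd.DataFrame:
    names = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "svclass", "score", "strand1", "strand2", "region", "insseq",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, keep_default_na=False)
    df["pos1"] = df["end1"].astype(int)
    df["pos2"] = df["end2"].astype(int)
    df["insseq"] = df["insseq"].astype(str).replace({"nan": "", ".": ""})
    return df[["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
               "svclass", "region", "insseq"]]


def write_bedgraph(values: np.ndarray, path, chrom: str = "chrS", bin_size: int = 1_000_000) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def write_config(config: SimConfig, path) -> None:
    """Flat key=value dump of the configuration."""
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            fh.write(f"{key}={value}\n")


def catalog_dataframe(counts: np.ndarray, name: str = "sample") -> pd.DataFrame:
    """Wrap a 96-vector of counts with canonical channel labels."""
    return pd.DataFrame({name: np.asarray(counts)}, index=list(CHANNELS_96))
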