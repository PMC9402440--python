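"""RAG and CSR motif enrichment at structural-variant breakpoints.

V(D)J recombination is initiated by RAG1/2 cutting at recombination
signal sequences (RSS): a conserved heptamer (consensus CACAGTG) and
nonamer (consensus ACAAAAACC) separated by a 12- or 23-bp spacer.
Class-switch recombination is initiated by AID at clusters of AGCT /
TGCA repeats in switch regions. Off-target activity of either machinery
leaves these motifs next to structural-variant breakpoints, so the
fraction of breakpoints with a motif — after subtracting the genomic
background rate estimated from random control positions — measures the
fraction of SVs attributable to each mechanism.

Motif hits use position-weight matrices built from the consensus (0.85
on the consensus base, 0.05 elsewhere) with hit p-values computed by
exact enumeration of the PWM score distribution under a uniform
background; a hit requires p < 1e-4, scanning both strands of the 50 bp
flanking each breakpoint (1,000 bp for CSR clusters, which need >= 2
motif occurrences with gaps <= 100 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import reverse_complement

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"
CSR_MOTIFS = ("AGCT", "TGCA")
RSS_WINDOW = 50
CSR_WINDOW = 1000
CSR_MAX_GAP = 100
PWM_P_THRESHOLD = 1e-4
SPACERS = (12, 23)
SPACER_TOL = 1  # biological 12/23-rule variability

# Ig loci (GRCh37, 1-based inclusive): IGH on chr14, IGK on chr2, IGL on chr22
IG_INTERVALS = (
    ("chr14", 106_304_735, 107_283_226),
    ("chr2", 89_160_078, 90_274_237),
    ("chr22", 22_385_390, 23_263_607),
)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def load_tcr_intervals(path=None) -> list[tuple[str, int, int]]:
    """TCR locus intervals (editable TSV fixture: locus, chrom, start, end)."""
    if path is None:
        path = resources.files("lymphforge.data") / "tcr_intervals_grch37.tsv"
    df = pd.read_csv(path, sep="\t")
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def classify_region(
    chrom: str,
    pos: int,
    intervals: list[tuple[str, int, int]] | None = None,
    known_chroms: set[str] | None = None,
) -> str:
    """'IgTCR' iff the position falls in an Ig or TCR interval (1-based incl.)."""
    if intervals is None:
        intervals = list(IG_INTERVALS) + load_tcr_intervals()
    if known_chroms is not None and chrom not in known_chroms:
        raise ValueError(f"unknown chromosome {chrom!r}")
    for c, lo, hi in intervals:
        if chrom == c and lo <= pos <= hi:
            return "IgTCR"
    return "other"


def classify_sv_region(
    sv_row, intervals: list[tuple[str, int, int]] | None = None
) -> str:
    """'IgTCR' iff either breakpoint of the SV lies in a configured interval."""
    a = classify_region(sv_row["chrom1"], sv_row["pos1"], intervals)
    b = classify_region(sv_row["chrom2"], sv_row["pos2"], intervals)
    return "IgTCR" if "IgTCR" in (a, b) else "other"


class PWM:
    """Consensus-derived position-weight matrix with an exact null tail.

    Column probabilities put ``match_p`` on the consensus base and
    ``(1 - match_p)/3`` elsewhere; scores are log-odds against a uniform
    background, and the null score distribution is enumerated exactly by
    convolving the per-position score distributions.
    """

    def __init__(self, consensus: str, match_p: float = 0.85):
        self.consensus = consensus.upper()
        self.length = len(self.consensus)
        mismatch_p = (1.0 - match_p) / 3.0
        self.scores = np.full((self.length, 4), np.log(mismatch_p / 0.25))
        for i, b in enumerate(self.consensus):
            self.scores[i, _BASE_IDX[b]] = np.log(match_p / 0.25)
        self._tail = self._enumerate_tail()

    def _enumerate_tail(self) -> tuple[np.ndarray, np.ndarray]:
        dist = {0.0: 1.0}
        for i in range(self.length):
            new: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = round(s + self.scores[i, b], 9)
                    new[key] = new.get(key, 0.0) + p * 0.25
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        tail = np.cumsum(probs[::-1])[::-1]  # P(S >= s)
        return scores, tail

    def pvalue(self, score: float) -> float:
        """Exact P(S >= score) under the uniform background."""
        scores, tail = self._tail
        idx = np.searchsorted(scores, score - 1e-6, side="left")
        return float(tail[idx]) if idx < len(scores) else 0.0

    @property
    def threshold_score(self) -> float:
        """Smallest score whose exact tail probability is < 1e-4."""
        scores, tail = self._tail
        ok = np.where(tail < PWM_P_THRESHOLD)[0]
        if len(ok) == 0:
            return np.inf
        return float(scores[ok[0]])

    def hit_probability(self) -> float:
        """Per-position probability of a hit under the uniform background."""
        scores, tail = self._tail
        ok = np.where(tail < PWM_P_THRESHOLD)[0]
        return float(tail[ok[0]]) if len(ok) else 0.0

    def scan(self, seq: str) -> list[tuple[int, float]]:
        """(offset, score) for every window with exact p < 1e-4, + strand."""
        seq = seq.upper()
        n = len(seq) - self.length + 1
        if n <= 0:
            return []
        enc = np.array([_BASE_IDX.get(b, 0) for b in seq])
        valid = np.array([b in _BASE_IDX for b in seq])
        win = np.lib.stride_tricks.sliding_window_view(enc, self.length)
        ok = np.lib.stride_tricks.sliding_window_view(valid, self.length).all(axis=1)
        sc = self.scores[np.arange(self.length), win].sum(axis=1)
        thr = self.threshold_score - 1e-6  # guard against enumeration rounding
        return [(int(i), float(s)) for i, s in enumerate(sc) if ok[i] and s >= thr]


HEPTAMER_PWM = PWM(RSS_HEPTAMER)
NONAMER_PWM = PWM(RSS_NONAMER)


@dataclass
class MotifHit:
    """A motif occurrence relative to a breakpoint.

    ``position`` is signed: positive offsets are interior to a deletion,
    negative exterior.
    """

    kind: str  # RSS-heptamer | RSS-full | CSR-cluster
    position: int
    strand: str
    score: float
    spacer: int | None = None


def _scan_rss_strand(seq: str) -> list[tuple[int, float, int | None]]:
    """Heptamer hits with optional full-RSS spacer on one strand of seq."""
    hits = []
    hept = dict(HEPTAMER_PWM.scan(seq))
    nona = dict(NONAMER_PWM.scan(seq))
    for i, s in hept.items():
        spacer_found = None
        for spacer in SPACERS:
            for d in range(-SPACER_TOL, SPACER_TOL + 1):
                j = i + HEPTAMER_PWM.length + spacer + d
                if j in nona:
                    spacer_found = spacer + d
                    break
            if spacer_found is not None:
                break
        hits.append((i, s, spacer_found))
    return hits


def scan_rss(
    reference: str,
    breakpoint_pos: int,
    window: int = RSS_WINDOW,
    interior_sign: int = +1,
) -> list[MotifHit]:
    """Scan both strands of the ±``window`` bp around a breakpoint for RSS.

    ``breakpoint_pos`` is 1-based; ``interior_sign`` is +1 when
    increasing coordinates point into the deleted segment (left
    breakpoint of a deletion) and -1 otherwise. Windows overrunning the
    contig are truncated.
    """
    start = max(0, breakpoint_pos - 1 - window)
    end = min(len(reference), breakpoint_pos - 1 + window + HEPTAMER_PWM.length)
    sub = reference[start:end]
    hits: list[MotifHit] = []
    for i, s, spacer in _scan_rss_strand(sub):
        offset = (start + i) - (breakpoint_pos - 1)
        kind = "RSS-full" if spacer is not None else "RSS-heptamer"
        hits.append(MotifHit(kind, interior_sign * offset, "+", s, spacer))
    rc = reverse_complement(sub)
    for i, s, spacer in _scan_rss_strand(rc):
        # motif start i on the reverse strand ends at len(sub)-1-i forward
        fwd = len(sub) - i - HEPTAMER_PWM.length
        offset = (start + fwd) - (breakpoint_pos - 1)
        kind = "RSS-full" if spacer is not None else "RSS-heptamer"
        hits.append(MotifHit(kind, interior_sign * offset, "-", s, spacer))
    return hits


def scan_csr(reference: str, breakpoint_pos: int, window: int = CSR_WINDOW) -> bool:
    """AGCT/TGCA cluster within ±``window`` bp: >= 2 matches, gaps <= 100 bp."""
    start = max(0, breakpoint_pos - 1 - window)
    end = min(len(reference), breakpoint_pos - 1 + window + 4)
    sub = reference[start:end].upper()
    positions = sorted(
        i for motif in CSR_MOTIFS for i in _find_all(sub, motif)
    )
    run = 1
    for a, b in zip(positions, positions[1:]):
        if b - a <= CSR_MAX_GAP:
            run += 1
            if run >= 2:
                return True
        else:
            run = 1
    return False


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def sv_has_rss(reference: str, sv_row, window: int = RSS_WINDOW) -> bool:
    """Any RSS heptamer/full hit within ``window`` bp of either breakpoint."""
    hits = scan_rss(reference, sv_row["pos1"], window, interior_sign=+1)
    if hits:
        return True
    # interior points leftward at the right breakpoint of a deletion
    sign2 = -1 if sv_row["svclass"] == "deletion" else +1
    return bool(scan_rss(reference, sv_row["pos2"], window, interior_sign=sign2))


def sv_has_csr(reference: str, sv_row, window: int = CSR_WINDOW) -> bool:
    return scan_csr(reference, sv_row["pos1"], window) or scan_csr(
        reference, sv_row["pos2"], window
    )


def annotate_svs(
    reference: str,
    svs: pd.DataFrame,
    window: int = RSS_WINDOW,
    csr_window: int = CSR_WINDOW,
) -> pd.DataFrame:
    """Add rss_hit / csr_cluster / has_insertion columns to an SV table."""
    out = svs.copy()
    out["rss_hit"] = [sv_has_rss(reference, r, window) for _, r in svs.iterrows()]
    out["csr_cluster"] = [sv_has_csr(reference, r, csr_window) for _, r in svs.iterrows()]
    ins = svs["insseq"].fillna("") if "insseq" in svs else pd.Series("", index=svs.index)
    out["has_insertion"] = ins.astype(str).str.len() > 0
    return out


def genomic_background(
    reference: str,
    callable_mask: np.ndarray,
    n_sets: int = 100,
    set_size: int = 100,
    seed: int = 0,
    scan: str = "rss",
    window: int | None = None,
) -> tuple[float, np.ndarray]:
    """Median per-set motif hit proportion over random control positions.

    ``callable_mask`` lists candidate 1-based positions (regions not
    excluded from variant calling). Each of ``n_sets`` control sets
    draws ``set_size`` positions and is scanned exactly like real
    breakpoints; the background is the median of the per-set hit
    proportions. Returns ``(median, per_set_proportions)``.
    """
    positions = np.asarray(callable_mask)
    if positions.size == 0:
        raise ValueError("callable mask is empty")
    if positions.size < set_size:
        raise ValueError(f"mask has {positions.size} positions < set_size {set_size}")
    rng = np.random.default_rng(seed)
    if window is None:
        window = RSS_WINDOW if scan == "rss" else CSR_WINDOW
    props = np.empty(n_sets)
    for k in range(n_sets):
        draw = rng.choice(positions, size=set_size, replace=False)
        if scan == "rss":
            hits = [len(scan_rss(reference, int(p), window)) > 0 for p in draw]
        else:
            hits = [scan_csr(reference, int(p), window) for p in draw]
        props[k] = np.mean(hits)
    return float(np.median(props)), props


def rag_attributable_fraction(p_obs: float, p_bg: float) -> float:
    """Background-corrected fraction of SVs attributable to RAG.

    max(p_obs - p_bg, 0): the observed motif rate minus the genomic
    background rate, clamped at zero.
    """
    if not (0 <= p_obs <= 1 and 0 <= p_bg <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    return max(p_obs - p_bg, 0.0)


def motif_distance_profile(
    reference: str,
    svs: pd.DataFrame,
    bin_width: int = 10,
    max_distance: int = 200,
    background: float | None = None,
) -> pd.DataFrame:
    """Proportion of deletions with an RSS hit per signed-distance bin.

    Positive distances are interior to the deletion, negative exterior;
    both breakpoints of every deletion contribute. An optional
    ``background`` level is attached as a column for overlay.
    """
    dels = svs[svs["svclass"] == "deletion"]
    edges = np.arange(-max_distance, max_distance + bin_width, bin_width)
    if dels.empty:
        return pd.DataFrame({"bin_left": [], "bin_right": [], "proportion": []})
    counts = np.zeros(len(edges) - 1)
    for _, r in dels.iterrows():
        offs = set()
        for pos, sign in ((r["pos1"], +1), (r["pos2"], -1)):
            for h in scan_rss(reference, pos, window=max_distance, interior_sign=sign):
                offs.add(h.position)
        if not offs:
            continue
        seen = np.zeros(len(edges) - 1, dtype=bool)
        for o in offs:
            b = np.searchsorted(edges, o, side="right") - 1
            if 0 <= b < len(seen):
                seen[b] = True
        counts += seen
    prof = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "proportion": counts / len(dels)}
    )
    if background is not None:
        prof["background"] = background
    return prof


def insertion_enrichment(svs: pd.DataFrame) -> tuple[np.ndarray, float, float]:
    """Non-templated insertion presence by RSS-hit status.

    Returns the 2x2 contingency table [[hit&ins, hit&no-ins],
    [no-hit&ins, no-hit&no-ins]], the odds ratio and the two-sided
    Fisher exact p. Empty margins yield NaN statistics.
    """
    if "rss_hit" not in svs or "has_insertion" not in svs:
        raise ValueError("annotate_svs first (need rss_hit and has_insertion)")
    hit = svs["rss_hit"].to_numpy(dtype=bool)
    ins = svs["has_insertion"].to_numpy(dtype=bool)
    table = np.array(
        [
            [int((hit & ins).sum()), int((hit & ~ins).sum())],
            [int((~hit & ins).sum()), int((~hit & ~ins).sum())],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return table, float("nan"), float("nan")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)
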