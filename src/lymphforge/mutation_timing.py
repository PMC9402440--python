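"""Epigenome-based timing of mutational processes.

The regional density of somatic mutations mirrors the chromatin state
of the cell in which they arose, so the epigenome that best predicts a
signature's genome-wide mutation distribution points to the cell state
active when those mutations were laid down. Mutations are assigned to
their most likely signature, aggregated into 1-Mb windows, and each
candidate epigenome's histone-mark profiles (H3K27me3, H3K36me3,
H3K4me1, H3K9me3) are used as features of a random-forest regression of
the window counts, scored by the LogCosh distance between observed and
predicted profiles in ten-fold cross-validation. Epigenomes are
compared by a paired two-sided Wilcoxon test on the per-fold distances;
a matched-count control subsamples the larger of two profiles so the
comparison is not driven by mutation numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

MIN_MEAN_PER_WINDOW = 1.0  # eligibility: signatures below this are not evaluated
DEFAULT_FOLDS = 10
# family-level default; rankings on the synthetic generator are stable
# from ~100 trees upward
N_TREES = 300


def attribute_and_bin(
    windows: np.ndarray,
    attributions: pd.DataFrame,
    n_windows: int,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Assign each mutation to its argmax signature and count per window.

    ``windows`` gives the 0-based 1-Mb window index per mutation;
    ``attributions`` the per-variant signature posteriors (rows align
    with ``windows``, columns are signatures). Ties go to the
    lexicographically first signature and are counted in the returned
    flag. Signatures averaging fewer than one mutation per window are
    marked ineligible.

    Returns ``(counts, eligible, n_ties)`` where ``counts`` is
    windows x signatures.
    """
    windows = np.asarray(windows)
    if windows.min() < 0 or windows.max() >= n_windows:
        raise ValueError("mutation outside the window grid")
    sig_names = sorted(attributions.columns)
    A = attributions[sig_names].to_numpy(dtype=float)
    best = A.argmax(axis=1)  # argmax takes the first maximum: lexicographic tie-break
    is_tie = (A == A[np.arange(len(A)), best][:, None]).sum(axis=1) > 1
    counts = np.zeros((n_windows, len(sig_names)), dtype=int)
    np.add.at(counts, (windows, best), 1)
    counts = pd.DataFrame(counts, columns=sig_names)
    eligible = pd.Series(
        counts.mean(axis=0) >= MIN_MEAN_PER_WINDOW, name="eligible"
    )
    return counts, eligible, int(is_tie.sum())


def logcosh_distance(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean over windows of log(cosh(observed - predicted)).

    Behaves like half the squared error for small residuals and like
    the absolute error for large ones, so single extreme windows do not
    dominate the score.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    r = np.abs(obs - pred)
    # log cosh r = r + log1p(exp(-2r)) - log 2, stable for large r
    return float(np.mean(r + np.log1p(np.exp(-2.0 * r)) - np.log(2.0)))


@dataclass
class EpigenomeScore:
    """Cross-validated fit of one epigenome to a mutation profile."""

    epigenome: str
    fold_distances: np.ndarray
    mean_distance: float


def _common_window_mask(tracks: dict[str, np.ndarray]) -> np.ndarray:
    """Windows with non-zero coverage in every compared track set."""
    masks = [np.asarray(t).sum(axis=1) > 0 for t in tracks.values()]
    return np.logical_and.reduce(masks)


def epigenome_match(
    profile: np.ndarray,
    tracks: dict[str, np.ndarray],
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> tuple[list[EpigenomeScore], str, pd.DataFrame]:
    """Rank epigenomes by how well their marks predict the profile.

    For each epigenome, window counts are regressed on that epigenome's
    histone-mark features with a seeded random forest in ``folds``-fold
    cross-validation; the per-fold held-out LogCosh distances are the
    scores. The best match has the lowest mean distance; all pairs are
    compared with a paired two-sided Wilcoxon test on the fold values.

    Returns ``(scores, best_epigenome, pairwise_p)``.
    """
    y = np.asarray(profile, dtype=float)
    mask = _common_window_mask(tracks)
    y = y[mask]
    if len(y) < folds * 5:
        raise ValueError(f"need >= {folds * 5} eligible windows, got {len(y)}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: list[EpigenomeScore] = []
    for name in sorted(tracks):
        X = np.asarray(tracks[name], dtype=float)[mask]
        dists = np.empty(folds)
        for k, (tr, te) in enumerate(kf.split(X)):
            rf = RandomForestRegressor(
                n_estimators=n_trees, random_state=seed, n_jobs=1
            )
            rf.fit(X[tr], y[tr])
            dists[k] = logcosh_distance(y[te], rf.predict(X[te]))
        scores.append(EpigenomeScore(name, dists, float(dists.mean())))
    best = min(scores, key=lambda s: s.mean_distance).epigenome
    names = [s.epigenome for s in scores]
    P = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(scores):
        for j, b in enumerate(scores):
            if j <= i:
                continue
            diff = a.fold_distances - b.fold_distances
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                _, p = stats.wilcoxon(
                    a.fold_distances, b.fold_distances, alternative="two-sided"
                )
            P.iloc[i, j] = P.iloc[j, i] = p
    return scores, best, P


def subsample_profile(profile: np.ndarray, target_total: int, seed: int = 0) -> np.ndarray:
    """Hypergeometric subsample of per-window counts to a target total.

    Draws ``target_total`` mutations without replacement from the
    profile's mutations, so expected subsampled counts are proportional
    to the originals. Subsampling to the profile's own total is the
    identity.
    """
    counts = np.asarray(profile, dtype=int)
    total = int(counts.sum())
    if target_total > total:
        raise ValueError(f"cannot subsample {total} mutations up to {target_total}")
    if target_total == total:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, target_total)


def matched_count_control(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    tracks: dict[str, np.ndarray],
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> dict:
    """Compare two profiles' epigenome fits at equal mutation numbers.

    The larger profile is subsampled (per-window hypergeometric) to the
    smaller profile's total, both are matched against the epigenomes,
    and the best-fit fold distances are compared with an unpaired
    two-sided Wilcoxon rank-sum test.
    """
    a = np.asarray(profile_a, dtype=int)
    b = np.asarray(profile_b, dtype=int)
    ta, tb = int(a.sum()), int(b.sum())
    if ta == 0 or tb == 0:
        raise ValueError("profiles must contain mutations")
    target = min(ta, tb)
    a_s = subsample_profile(a, target, seed=seed)
    b_s = subsample_profile(b, target, seed=seed + 1)
    scores_a, best_a, _ = epigenome_match(a_s, tracks, folds, seed, n_trees)
    scores_b, best_b, _ = epigenome_match(b_s, tracks, folds, seed, n_trees)
    da = next(s.fold_distances for s in scores_a if s.epigenome == best_a)
    db = next(s.fold_distances for s in scores_b if s.epigenome == best_b)
    stat, p = stats.ranksums(da, db)
    return {
        "target_total": target,
        "best_a": best_a,
        "best_b": best_b,
        "scores_a": scores_a,
        "scores_b": scores_b,
        "p": float(p),
    }


def scores_table(scores: list[EpigenomeScore], pairwise: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten epigenome scores into a report table."""
    rows = []
    for s in sorted(scores, key=lambda s: s.mean_distance):
        row = {"epigenome": s.epigenome, "mean_distance": s.mean_distance}
        for k, d in enumerate(s.fold_distances):
            row[f"fold{k}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
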