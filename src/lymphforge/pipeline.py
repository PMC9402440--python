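"""End-to-end pipeline over synthetic fixtures with provenance.

Stages run in dependency order: variant filtering feeds the burden
model and signature attribution; attribution feeds the feature
regression, mutation timing and germinal-centre summaries; the SV motif
stage is independent. A single global seed fans out to per-stage seeds
by fixed offsets, so stages are reproducible independently and jointly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import (
    burden_model,
    feature_regression,
    mutation_timing,
    shm_selection,
    signature_attribution,
    sv_motif,
    synthetic_data,
    variant_filtering,
)

logger = logging.getLogger("lymphforge.pipeline")

# fixed per-stage seed offsets
STAGE_SEEDS = {
    "simulate": 11,
    "filter": 23,
    "burden": 37,
    "signatures": 41,
    "features": 53,
    "svmotif": 67,
    "timing": 71,
    "gc": 83,
}


@dataclass
class PipelineConfig:
    """Validated configuration for a demo-scale pipeline run."""

    seed: int = 0
    assembly: str = "synthetic"
    n_colonies: int = 12
    n_germline_sites: int = 600
    n_somatic_sites: int = 300
    n_artifact_sites: int = 100
    n_donors: int = 3
    n_colonies_per_group: int = 8
    cell_types: tuple[str, ...] = ("HSPC", "memory_B", "memory_T")
    n_signature_samples: int = 4
    mutations_per_sample: int = 4000
    n_feature_bins: int = 3000
    sv_genome_length: int = 1_200_000
    n_svs: int = 120
    rag_fraction: float = 0.4
    csr_fraction: float = 0.2
    n_epigenome_tracks: int = 3
    n_timing_windows: int = 400
    n_timing_mutations: int = 4000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "cell_types" in data:
            data = {**data, "cell_types": tuple(data["cell_types"])}
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on synthetic fixtures; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {k: config.seed * 1000 + v for k, v in STAGE_SEEDS.items()}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=True)
        written.append(p)
        return p

    # --- simulate + filter -------------------------------------------------
    logger.info("[filter] simulating colony read counts")
    sim = synthetic_data.SimConfig(
        seed=seeds["simulate"],
        n_colonies=config.n_colonies,
        n_germline_sites=config.n_germline_sites,
        n_somatic_sites=config.n_somatic_sites,
        n_artifact_sites=config.n_artifact_sites,
        cell_types=config.cell_types,
    )
    rc, meta, truth = synthetic_data.simulate_colony_readcounts(sim)
    result = variant_filtering.filter_donor(rc)
    vcf = out / "filtered.vcf"
    variant_filtering.write_filtered_vcf(rc, result, vcf)
    written.append(vcf)
    report = pd.DataFrame(
        {"label": result.labels, "true_label": truth.site_labels}
    )
    emit("filter_report.tsv", report)
    emit("sensitivity.tsv", result.sensitivity.to_frame())

    # --- burden ------------------------------------------------------------
    logger.info("[burden] fitting age x cell-type mixed model")
    bsim = synthetic_data.SimConfig(
        seed=seeds["burden"],
        n_donors=config.n_donors,
        cell_types=config.cell_types,
        n_colonies_per_group=config.n_colonies_per_group,
    )
    table = synthetic_data.simulate_burden_table(bsim)
    fit = burden_model.fit_burden_age_model(table)
    emit("burden_slopes.tsv", fit.slopes.set_index("cell_type"))
    emit("burden_offsets.tsv", fit.offsets.set_index("cell_type"))

    # --- signatures --------------------------------------------------------
    logger.info("[signatures] two-pass exposure estimation")
    sigs = signature_attribution.load_signature_catalog()
    rng = np.random.default_rng(seeds["signatures"])
    catalogs = {}
    for i in range(config.n_signature_samples):
        w = rng.dirichlet(np.ones(3))
        active = rng.choice(len(sigs), size=3, replace=False)
        expo = np.zeros(len(sigs))
        expo[active] = w
        catalogs[f"sample{i}"] = synthetic_data.simulate_catalog(
            expo, sigs, config.mutations_per_sample, seed=seeds["signatures"] + i
        )
    cat_df = pd.DataFrame(catalogs).T
    reduced, refits = signature_attribution.exclude_and_refit(
        cat_df, sigs, n_boot=50, seed=seeds["signatures"]
    )
    expo_tab = pd.DataFrame(
        {s: ev.as_series() for s, ev in refits.items()}
    ).T
    emit("exposures.tsv", expo_tab)

    # --- feature regression -------------------------------------------------
    logger.info("[features] penalised additive regression")
    links = {
        "replication_timing": lambda x: 0.6 * np.tanh(x),
        "h3k4me1": lambda x: np.zeros_like(x),
        "lad": lambda x: np.zeros_like(x),
    }
    bins = synthetic_data.simulate_feature_bins(
        config.n_feature_bins, links, seed=seeds["features"]
    )
    reg_table = feature_regression.assemble_regression_table(
        bins, seed=seeds["features"], included_col=None
    )
    afit = feature_regression.fit_penalized_additive(
        reg_table, list(links), seed=seeds["features"]
    )
    ranking = feature_regression.rank_features(reg_table, list(links))
    ranking["selected"] = ranking["feature"].isin(afit.selected)
    ranking["full_model_r2"] = afit.r2
    emit("feature_selection.tsv", ranking.set_index("feature"))

    # --- SV motifs ----------------------------------------------------------
    logger.info("[svmotif] RSS/CSR annotation and background")
    ref, svs, sv_truth = synthetic_data.simulate_reference_and_svs(
        config.sv_genome_length,
        config.n_svs,
        config.rag_fraction,
        config.csr_fraction,
        seed=seeds["svmotif"],
    )
    annotated = sv_motif.annotate_svs(ref, svs)
    annotated["true_mechanism"] = sv_truth.sv_mechanism.to_numpy()
    mask = np.arange(2000, config.sv_genome_length - 2000, 37)
    bg, _ = sv_motif.genomic_background(
        ref, mask, n_sets=20, set_size=60, seed=seeds["svmotif"]
    )
    corrected = sv_motif.rag_attributable_fraction(
        float(annotated["rss_hit"].mean()), bg
    )
    annotated.attrs["background"] = bg
    annotated.attrs["rag_fraction"] = corrected
    emit("sv_annotated.tsv", annotated)
    emit(
        "sv_background.tsv",
        pd.DataFrame(
            {"quantity": ["rss_background", "rag_corrected_fraction"],
             "value": [bg, corrected]}
        ).set_index("quantity"),
    )

    # --- timing -------------------------------------------------------------
    logger.info("[timing] epigenome matching")
    tracks, counts, _ = synthetic_data.simulate_epigenome_tracks(
        config.n_epigenome_tracks,
        config.n_timing_windows,
        placement_track=0,
        n_mutations=config.n_timing_mutations,
        seed=seeds["timing"],
    )
    track_sets = {f"epi{j}": tracks[:, [j]] for j in range(tracks.shape[1])}
    scores, best, pairwise = mutation_timing.epigenome_match(
        counts, track_sets, folds=5, seed=seeds["timing"], n_trees=100
    )
    st = mutation_timing.scores_table(scores)
    st["best"] = st["epigenome"] == best
    emit("timing_scores.tsv", st.set_index("epigenome"))

    # --- germinal centre summary ---------------------------------------------
    logger.info("[gc] germinal-centre summaries")
    grng = np.random.default_rng(seeds["gc"])
    summaries = {}
    for i in range(8):
        ighv = int(grng.integers(5, 40))
        summaries[f"memB{i}"] = shm_selection.gc_summary(
            n_ighv_variants=ighv,
            gene_length=350,
            sbs9_proportion=float(grng.uniform(0.2, 0.5)),
            snv_burden=float(grng.uniform(800, 2500)),
        )
    emit("gc_summary.tsv", shm_selection.summary_table(summaries).set_index("cell"))

    # --- manifest -----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(manifest["config"], fh, indent=2, sort_keys=True)
    return manifest


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write a small synthetic bundle exercising every stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_data.SimConfig(
        seed=seed,
        n_donors=3,
        n_colonies=10,
        n_germline_sites=1200,
        n_somatic_sites=600,
        n_artifact_sites=200,
    )
    rc, meta, truth = synthetic_data.simulate_colony_readcounts(cfg)
    paths = {}
    synthetic_data.write_readcounts_tsv(rc, out / "readcounts.tsv")
    paths["readcounts"] = out / "readcounts.tsv"
    meta.to_csv(out / "colony_meta.tsv", sep="\t", index=False)
    paths["colony_meta"] = out / "colony_meta.tsv"
    truth.site_labels.to_csv(out / "truth_labels.tsv", sep="\t")
    paths["truth_labels"] = out / "truth_labels.tsv"
    table = synthetic_data.simulate_burden_table(cfg)
    table.to_csv(out / "burden_table.tsv", sep="\t", index=False)
    paths["burden_table"] = out / "burden_table.tsv"
    ref, svs, sv_truth = synthetic_data.simulate_reference_and_svs(
        800_000, 80, 0.4, 0.2, seed=seed + 1
    )
    synthetic_data.write_fasta({"chrS": ref}, out / "reference.fa")
    paths["reference"] = out / "reference.fa"
    synthetic_data.write_bedpe(svs, out / "svs.bedpe")
    paths["svs"] = out / "svs.bedpe"
    tracks, counts, _ = synthetic_data.simulate_epigenome_tracks(
        4, 200, placement_track=0, n_mutations=2000, seed=seed + 2
    )
    for j in range(tracks.shape[1]):
        synthetic_data.write_bedgraph(tracks[:, j], out / f"track_epi{j}.bedgraph")
        paths[f"track_epi{j}"] = out / f"track_epi{j}.bedgraph"
    synthetic_data.write_bedgraph(counts, out / "window_counts.bedgraph")
    paths["window_counts"] = out / "window_counts.bedgraph"
    synthetic_data.write_config(cfg, out / "sim_config.txt")
    paths["config"] = out / "sim_config.txt"
    return paths
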