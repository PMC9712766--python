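"""End-to-end orchestration of the analysis on one cohort.

``run_all`` wires the stages together: simulate (or load) a cohort,
center-normalize site and protein intensities, protein-correct, log2,
differential-test every configured comparison, cluster SD-screened sites into
expression patterns, discover motifs from significant sites, predict kinase
substrates, score kinase activity by preranked GSEA, run Fisher term
enrichment, and build both networks per comparison.  Every output is written
as TSV/FASTA/GMT/GraphML under one directory plus a JSON run manifest
recording the seed, thresholds, library versions and SHA-256 of each output —
identical seeds reproduce every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx
import numpy
import pandas
import scipy

from . import __version__, cluster, enrichment, io, kinase, motif, network, quant
from .core import SampleDesign
from .simulate import SimulationConfig, simulate_cohort, synthetic_pathway_sets

logger = logging.getLogger("phosphonet")

DEFAULT_COMPARISONS = [("SLE_S", "HC"), ("SLE_A", "HC"), ("SLE_A", "SLE_S")]


@dataclass
class PipelineConfig:
    """Thresholds and switches of the full run (defaults are the pipeline's
    standard operating point)."""

    comparisons: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_COMPARISONS))
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    use_protein_correction: bool = True
    sd_threshold: float = cluster.SD_THRESHOLD
    n_clusters: int = cluster.N_CLUSTERS
    motif_min_count: int = motif.MIN_COUNT
    motif_p_max: float = motif.P_MAX
    ksea_n_perm: int = kinase.N_PERM
    ksea_weight_exponent: float = 1.0
    ksea_min_set_size: int = kinase.MIN_SET_SIZE
    top_k: int = network.TOP_K


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    pipe_config: PipelineConfig | None = None,
) -> dict:
    """Run the whole pipeline on a seeded synthetic cohort; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or SimulationConfig(seed=seed)
    pc = pipe_config or PipelineConfig()

    # --- cohort -----------------------------------------------------------
    site_table, site_mat, prot_mat, design, seqs, truth = simulate_cohort(cfg)
    io.write_site_table(out / "sites.tsv", site_table, site_mat)
    io.write_protein_table(out / "proteins.tsv", prot_mat)
    io.write_design(out / "design.tsv", design)
    io.write_fasta(out / "proteins.fasta", seqs)
    truth.to_json(out / "ground_truth.json")

    # --- normalization ----------------------------------------------------
    site_centered = quant.center_normalize(site_mat)
    prot_centered = quant.center_normalize(prot_mat)
    if pc.use_protein_correction:
        corrected = quant.protein_correct(site_centered, prot_centered, site_table)
    else:
        corrected = site_centered
    log2_mat = quant.log2_transform(corrected)
    log2_mat.values.to_csv(out / "normalized_log2.tsv", sep="\t", na_rep="NA")

    # --- differential tests ----------------------------------------------
    diffs: dict[str, pandas.DataFrame] = {}
    for a, b in pc.comparisons:
        d = quant.differential_test(
            log2_mat, design, a, b,
            p_threshold=pc.p_threshold, fc_threshold=pc.fc_threshold,
        )
        label = f"{a}_vs_{b}"
        diffs[label] = d
        d.to_csv(out / f"diff_{label}.tsv", sep="\t", index=False, na_rep="NA")

    # --- clustering -------------------------------------------------------
    kept = cluster.filter_by_sd(log2_mat, pc.sd_threshold)
    cluster_members: dict[str, list[str]] = {}
    if len(kept) >= pc.n_clusters:
        sub = quant.RatioMatrix(log2_mat.values.loc[kept], stage="log2")
        profiles = cluster.standardize_rows(cluster.group_profiles(sub, design))
        fc = cluster.fuzzy_cmeans(profiles, c=pc.n_clusters, seed=seed)
        fc.memberships.to_csv(out / "cluster_memberships.tsv", sep="\t")
        fc.centers.to_csv(out / "cluster_centers.tsv", sep="\t")
        cluster_members, mean_prof = cluster.assign_and_summarize(fc, profiles)
        pandas.DataFrame(
            [(c, s) for c, ids in cluster_members.items() for s in ids],
            columns=["cluster", "site_id"],
        ).to_csv(out / "cluster_assignments.tsv", sep="\t", index=False)
        mean_prof.to_csv(out / "cluster_mean_profiles.tsv", sep="\t", na_rep="NA")
    else:
        logger.warning("clustering skipped: only %d sites pass SD screen", len(kept))

    # --- windows, motifs --------------------------------------------------
    windows = motif.extract_windows(site_table, seqs, h=cfg.window_halfwidth)
    all_motifs = []
    for label, d in diffs.items():
        up, down = quant.significant_sites(d, pc.fc_threshold, pc.p_threshold)
        sig = up | down
        fg_table = windows[windows["site_id"].isin(sig)]
        for center in "STY":
            fg = list(fg_table.loc[fg_table["residue"] == center, "window"])
            bg = list(windows.loc[windows["residue"] == center, "window"])
            for m in motif.motifx(fg, bg, center, pc.motif_min_count, pc.motif_p_max):
                all_motifs.append((label, m))
    rep = motif.motif_report([m for _, m in all_motifs])
    rep.insert(0, "comparison", [lbl for lbl, _ in all_motifs])
    rep.to_csv(out / "motifs.tsv", sep="\t", index=False, na_rep="NA")

    # --- kinase-substrate prediction and activity -------------------------
    pssms = [
        kinase.pssm_from_motif_spec(k, spec, h=cfg.window_halfwidth)
        for k, spec in sorted(cfg.motif_specs.items())
    ]
    ks_map = kinase.score_substrates(windows, pssms)
    io.write_gmt(out / "kinase_substrates.gmt", kinase.substrate_sets_to_gmt(ks_map))

    terms = synthetic_pathway_sets(site_table, truth, seed=seed)
    io.write_gmt(out / "pathways.gmt", terms)
    universe = set(site_table["protein_id"])

    activities: dict[str, pandas.DataFrame] = {}
    for label, d in diffs.items():
        ranked = kinase.rank_sites(d)
        act = kinase.ksea(
            ranked, ks_map, weight_exponent=pc.ksea_weight_exponent,
            n_perm=pc.ksea_n_perm, min_set_size=pc.ksea_min_set_size, seed=seed,
        )
        activities[label] = act
        act.to_csv(out / f"ksea_{label}.tsv", sep="\t", index=False, na_rep="NA")

    # --- enrichment and networks -----------------------------------------
    for label, d in diffs.items():
        up, down = quant.significant_sites(d, pc.fc_threshold, pc.p_threshold)
        fg_proteins = enrichment.sites_to_proteins(up | down, site_table)
        enr = enrichment.fisher_enrich(fg_proteins, universe, terms, pc.p_threshold)
        enr.to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False, na_rep="NA")

        ksn = network.kinase_substrate_network(activities[label], d, ks_map)
        io.write_network(ksn, out / f"kinase_substrate_{label}.graphml", "graphml")
        io.write_network(ksn, out / f"kinase_substrate_{label}.sif", "sif")

        top = kinase.top_kinases(activities[label], k=pc.top_k)
        enr_m = network.attach_members(enr, terms)
        quad = network.quadripartite_network(
            top, activities[label], d, ks_map, site_table, enr_m, pc.p_threshold
        )
        io.write_network(quad, out / f"quadripartite_{label}.graphml", "graphml")
        io.write_network(quad, out / f"quadripartite_{label}.tables", "tables")

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "generator": "numpy.random.default_rng (PCG64)",
        "versions": {
            "phosphonet": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "thresholds": {
            "p_threshold": pc.p_threshold,
            "fc_threshold": pc.fc_threshold,
            "sd_threshold": pc.sd_threshold,
            "n_clusters": pc.n_clusters,
            "motif_min_count": pc.motif_min_count,
            "motif_p_max": pc.motif_p_max,
            "ksea_n_perm": pc.ksea_n_perm,
            "ksea_min_set_size": pc.ksea_min_set_size,
            "top_k": pc.top_k,
        },
        "comparisons": [f"{a}_vs_{b}" for a, b in pc.comparisons],
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
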