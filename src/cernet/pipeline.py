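"""Configuration-driven orchestration of the full screen.

``run_simulate`` writes a self-contained synthetic bundle (two case/control
cohorts for lncRNA and mRNA, one miRNA cohort, interaction tables, scored
PPI edges, gene sets, the time-course matrix, and the planted truth) to a
directory. ``run_all`` consumes such a bundle — or any directory with the
same file layout — and executes every stage in order:

1. moderated-t differential expression per cohort, threshold screen,
   per-class combination of the two cohorts' DE lists;
2. id normalization, >=3-database evidence filtering, sign-consistent
   ceRNA triple assembly, network build and hub ranking;
3. PPI thresholding (combined score >= 0.7) restricted to the ceRNA mRNAs,
   with degree hubs;
4. Fisher over-representation of the ceRNA mRNAs against the gene sets;
5. time-course profile means, SD filter, standardization, fuzzy c-means,
   trend classification, and intersections of trend gene lists with the
   ceRNA mRNAs and the DE mRNAs.

Every stage's output is written as TSV/SIF/GraphML under the output
directory; a JSON manifest records the configuration, seed and SHA-256 of
every file written. Stage outputs are pure functions of inputs plus
configuration, so a rerun reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .cerna import (
    assemble_triples,
    build_network,
    filter_by_evidence,
    normalize_ids,
    rank_hubs,
    triples_to_frame,
)
from .diffexpr import combine_de, intersect_de, moderated_t_test, screen_de
from .enrichment import GeneSetCollection, fisher_enrich
from .ppi import network_summary, threshold_edges
from .simulate import (
    SimulationConfig,
    generate_cohort,
    generate_genesets,
    generate_interaction_dbs,
    generate_ppi,
    generate_timecourse,
    generate_truth,
)
from .timeseries import (
    classify_trends,
    cluster_gene_sets,
    estimate_fuzzifier,
    fuzzy_cmeans,
    profile_means,
    sd_filter,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs of the analysis stages."""

    p_threshold: float = 0.05
    lfc_threshold: float = 0.585
    min_db: int = 3
    min_score: float = 0.7
    min_sd: float = 0.05
    membership_threshold: float = 0.5
    n_clusters: int = 10
    fuzzifier: float | str = "auto"  # "auto" -> estimate_fuzzifier
    hub_k: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: dict, files: list[Path]) -> None:
    manifest = {
        "config": config,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run_simulate(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full synthetic bundle plus planted truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    written: list[Path] = []

    cohorts = {
        1: generate_cohort(config, truth, cohort=1)[0],
        2: generate_cohort(config, truth, n_case=3, n_control=3, cohort=2)[0],
    }
    for idx, mats in cohorts.items():
        for cls, em in mats.items():
            if cls == "miRNA" and idx == 2:
                continue  # single miRNA cohort, as in the emulated design
            tag = {"lncRNA": "lnc", "miRNA": "mir", "mRNA": "mrna"}[cls]
            e = outdir / f"expr_{tag}_cohort{idx}.tsv"
            s = outdir / f"samples_{tag}_cohort{idx}.tsv"
            cio.write_expression(em, e, s)
            written += [e, s]

    mir_mrna, lnc_mir = generate_interaction_dbs(truth, config)
    cio.write_interactions(mir_mrna, outdir / "interactions_mir_mrna.tsv")
    cio.write_interactions(lnc_mir, outdir / "interactions_lnc_mir.tsv")
    written += [
        outdir / "interactions_mir_mrna.tsv",
        outdir / "interactions_lnc_mir.tsv",
    ]

    tc, truth = generate_timecourse(config, truth)
    cio.write_expression(
        tc, outdir / "expr_timecourse.tsv", outdir / "samples_timecourse.tsv"
    )
    written += [outdir / "expr_timecourse.tsv", outdir / "samples_timecourse.tsv"]

    mrna_ids = sorted(cohorts[1]["mRNA"].feature_ids)
    ppi = generate_ppi(mrna_ids, config)
    cio.write_table(ppi, outdir / "ppi_edges.tsv")
    written.append(outdir / "ppi_edges.tsv")

    cerna_mrnas = sorted({g for (_, _, g) in truth.triples})
    genesets, truth = generate_genesets(mrna_ids, config, cerna_mrnas, truth)
    genesets.to_gmt(outdir / "gene_sets.gmt")
    written.append(outdir / "gene_sets.gmt")

    truth_de = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "class": r.feature_class,
                "direction": r.direction,
                "log2fc": r.log2fc,
            }
            for r in sorted(truth.de_features.values())
        ],
        columns=["feature", "class", "direction", "log2fc"],
    )
    cio.write_table(truth_de, outdir / "truth_de.tsv")
    truth_triples = pd.DataFrame(
        truth.triples, columns=["lncrna", "mirna", "mrna"]
    )
    cio.write_table(truth_triples, outdir / "truth_triples.tsv")
    truth_trends = pd.DataFrame(
        sorted(truth.trend_class.items()), columns=["feature", "trend_class"]
    )
    cio.write_table(truth_trends, outdir / "truth_trends.tsv")
    truth_sets = pd.DataFrame({"set_id": sorted(truth.enriched_sets)})
    cio.write_table(truth_sets, outdir / "truth_enriched_sets.tsv")
    written += [
        outdir / "truth_de.tsv",
        outdir / "truth_triples.tsv",
        outdir / "truth_trends.tsv",
        outdir / "truth_enriched_sets.tsv",
    ]

    cfg = dataclasses.asdict(config)
    cfg["samples_per_timepoint"] = list(config.samples_per_timepoint)
    cfg["timepoint_labels"] = list(config.timepoint_labels)
    _write_manifest(outdir, cfg, written)
    return {
        "n_de_planted": len(truth.de_features),
        "n_triples_planted": len(truth.triples),
        "n_trend_genes": sum(
            1 for c in truth.trend_class.values() if c != "flat"
        ),
        "files": sorted(p.name for p in written),
    }


def _de_stage(bundle: Path, outdir: Path, cfg: PipelineConfig, written):
    """Screen each cohort, then combine per class across cohorts."""
    de_lists: dict[str, list] = {}
    conflicts: dict[str, list] = {}
    per_cohort_counts = []
    per_cohort = {"lnc": [], "mrna": [], "mir": []}
    for tag, cls in (("lnc", "lncRNA"), ("mir", "miRNA"), ("mrna", "mRNA")):
        for idx in (1, 2):
            expr = bundle / f"expr_{tag}_cohort{idx}.tsv"
            if not expr.exists():
                continue
            em = cio.read_expression(expr, bundle / f"samples_{tag}_cohort{idx}.tsv")
            fit = moderated_t_test(em)
            recs = screen_de(fit, cls, cfg.p_threshold, cfg.lfc_threshold)
            per_cohort[tag].append(recs)
            per_cohort_counts.append(
                {
                    "dataset": f"{tag}_cohort{idx}",
                    "class": cls,
                    "down": sum(r.direction == "down" for r in recs),
                    "up": sum(r.direction == "up" for r in recs),
                    "total": len(recs),
                }
            )
    for tag, cls in (("lnc", "lncRNA"), ("mir", "miRNA"), ("mrna", "mRNA")):
        lists = per_cohort[tag]
        if len(lists) >= 2:
            combined, confl = combine_de(*lists)
            common = intersect_de(lists[0], lists[1])
            cio.write_de_records(common, outdir / f"de_{tag}_common.tsv")
            written.append(outdir / f"de_{tag}_common.tsv")
        else:
            combined, confl = lists[0], []
        de_lists[cls] = combined
        conflicts[cls] = confl
        cio.write_de_records(combined, outdir / f"de_{tag}_combined.tsv")
        written.append(outdir / f"de_{tag}_combined.tsv")
        cio.write_table(
            pd.DataFrame(confl, columns=["feature", "directions"]),
            outdir / f"de_{tag}_conflicts.tsv",
        )
        written.append(outdir / f"de_{tag}_conflicts.tsv")
        per_cohort_counts.append(
            {
                "dataset": f"{tag}_combined",
                "class": cls,
                "down": sum(r.direction == "down" for r in combined),
                "up": sum(r.direction == "up" for r in combined),
                "total": len(combined),
            }
        )
    counts = pd.DataFrame(per_cohort_counts)
    cio.write_table(counts, outdir / "de_counts.tsv")
    written.append(outdir / "de_counts.tsv")
    return de_lists, counts


def run_all(
    bundle_dir: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute every analysis stage on a bundle directory.

    Returns a summary dictionary (also written as ``summary.json``). Any
    stage failure aborts with the stage name in the exception message;
    earlier stages' outputs are left on disk.
    """
    cfg = config or PipelineConfig()
    bundle = Path(bundle_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}

    stage = "differential-expression"
    try:
        de_lists, de_counts = _de_stage(bundle, outdir, cfg, written)
        summary["de_counts"] = {
            row["dataset"]: {
                "down": int(row["down"]),
                "up": int(row["up"]),
                "total": int(row["total"]),
            }
            for _, row in de_counts.iterrows()
        }

        stage = "cerna-network"
        mir_mrna = normalize_ids(
            cio.read_interactions(bundle / "interactions_mir_mrna.tsv")
        )
        lnc_mir = normalize_ids(
            cio.read_interactions(bundle / "interactions_lnc_mir.tsv")
        )
        mm_pairs = filter_by_evidence(mir_mrna, cfg.min_db)
        triples = assemble_triples(
            de_lists["lncRNA"],
            de_lists["miRNA"],
            de_lists["mRNA"],
            lnc_mir,
            mm_pairs,
        )
        tdf = triples_to_frame(triples)
        cio.write_table(tdf, outdir / "triples.tsv")
        net = build_network(triples)
        cio.write_sif(net, outdir / "cerna_network.sif")
        cio.write_graphml(net, outdir / "cerna_network.graphml")
        hubs = rank_hubs(net, cfg.hub_k)
        cio.write_table(
            pd.DataFrame(hubs, columns=["node", "degree"]),
            outdir / "cerna_hubs.tsv",
        )
        written += [
            outdir / "triples.tsv",
            outdir / "cerna_network.sif",
            outdir / "cerna_network.graphml",
            outdir / "cerna_hubs.tsv",
        ]
        summary["n_triples"] = len(triples)
        summary["triples_by_polarity"] = (
            tdf["polarity"].value_counts().sort_index().to_dict()
            if len(tdf)
            else {}
        )
        cerna_mrnas = sorted({t.mrna for t in triples})
        summary["n_cerna_mrnas"] = len(cerna_mrnas)

        stage = "ppi"
        ppi_edges = pd.read_csv(bundle / "ppi_edges.tsv", sep="\t")
        keep = ppi_edges["protein1"].isin(cerna_mrnas) & ppi_edges[
            "protein2"
        ].isin(cerna_mrnas)
        ppi_net = threshold_edges(ppi_edges[keep], cfg.min_score)
        n_nodes, n_edges = network_summary(ppi_net)
        cio.write_sif(ppi_net, outdir / "ppi_network.sif")
        cio.write_graphml(ppi_net, outdir / "ppi_network.graphml")
        ppi_hubs = rank_hubs(ppi_net, cfg.hub_k)
        cio.write_table(
            pd.DataFrame(ppi_hubs, columns=["node", "degree"]),
            outdir / "ppi_hubs.tsv",
        )
        cio.write_table(
            pd.DataFrame([{"nodes": n_nodes, "edges": n_edges}]),
            outdir / "ppi_summary.tsv",
        )
        written += [
            outdir / "ppi_network.sif",
            outdir / "ppi_network.graphml",
            outdir / "ppi_hubs.tsv",
            outdir / "ppi_summary.tsv",
        ]
        summary["ppi"] = {"nodes": n_nodes, "edges": n_edges}

        stage = "enrichment"
        # universe = all genes measured on the mRNA platform
        platform = pd.read_csv(
            bundle / "expr_mrna_cohort1.tsv", sep="\t", index_col=0
        ).index
        coll = GeneSetCollection.from_gmt(
            bundle / "gene_sets.gmt", universe=platform
        )
        if cerna_mrnas and set(cerna_mrnas) & coll.universe:
            enr = fisher_enrich(cerna_mrnas, coll)
        else:
            enr = pd.DataFrame()
        cio.write_table(enr, outdir / "enrichment.tsv")
        written.append(outdir / "enrichment.tsv")
        summary["n_enriched_q05"] = (
            int((enr["q"] < 0.05).sum()) if "q" in enr else 0
        )

        stage = "timeseries"
        tc = cio.read_expression(
            bundle / "expr_timecourse.tsv", bundle / "samples_timecourse.tsv"
        )
        profiles = profile_means(tc)
        kept = sd_filter(profiles, cfg.min_sd)
        std = standardize(kept)
        m = (
            estimate_fuzzifier(std)
            if cfg.fuzzifier == "auto"
            else float(cfg.fuzzifier)
        )
        clustering = fuzzy_cmeans(std, c=cfg.n_clusters, m=m, seed=cfg.seed)
        labels = classify_trends(clustering)
        gene_sets = cluster_gene_sets(
            clustering, labels, cfg.membership_threshold
        )
        cio.write_table(
            clustering.membership, outdir / "tc_membership.tsv", index=True
        )
        cio.write_table(
            clustering.centroids, outdir / "tc_centroids.tsv", index=True
        )
        cio.write_table(
            pd.DataFrame(sorted(labels.items()), columns=["cluster", "trend"]),
            outdir / "tc_trends.tsv",
        )
        de_mrna_ids = sorted(r.feature for r in de_lists["mRNA"])
        inter_rows = []
        for lab in sorted(gene_sets):
            genes = gene_sets[lab]
            inter_rows.append(
                {
                    "trend_class": lab,
                    "n_genes": len(genes),
                    "n_in_cerna": len(set(genes) & set(cerna_mrnas)),
                    "cerna_genes": ",".join(sorted(set(genes) & set(cerna_mrnas))),
                    "n_in_de_mrna": len(set(genes) & set(de_mrna_ids)),
                }
            )
        cio.write_table(
            pd.DataFrame(inter_rows), outdir / "tc_intersections.tsv"
        )
        genes_long = pd.DataFrame(
            [
                {"trend_class": lab, "feature": g}
                for lab in sorted(gene_sets)
                for g in gene_sets[lab]
            ],
            columns=["trend_class", "feature"],
        )
        cio.write_table(genes_long, outdir / "tc_trend_genes.tsv")
        written += [
            outdir / "tc_membership.tsv",
            outdir / "tc_centroids.tsv",
            outdir / "tc_trends.tsv",
            outdir / "tc_intersections.tsv",
            outdir / "tc_trend_genes.tsv",
        ]
        summary["timeseries"] = {
            "n_filtered": int(len(kept)),
            "fuzzifier": m,
            "converged": bool(clustering.converged),
            "trend_sizes": {lab: len(g) for lab, g in sorted(gene_sets.items())},
        }
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfgd = dataclasses.asdict(cfg)
    _write_manifest(outdir, cfgd, written)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
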