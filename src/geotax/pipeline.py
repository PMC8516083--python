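"""End-to-end orchestration: stats → indices → matrices → thresholds →
clusters → tree concordance → reassignment proposals.

Every numeric output is reproducible bit-exactly given fixed inputs,
parameters and seed; run.log records every default (filters, linkage,
tie-breaks) so a run is self-describing.  Percentages in TSV output carry one
decimal; JSON retains full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .demarcation import (
    GENUS_THRESHOLDS,
    SPECIES_THRESHOLDS,
    SimilarityMatrix,
    build_matrix,
    classify_genome,
    cluster_and_cut,
    index_regression,
    infer_threshold,
)
from .genomes import GenomeRecord, ProteomeRecord, find_orfs, stats_table
from .indices import compute_16s_identity, compute_aai, compute_anib, compute_pocp
from .phylo import check_monophyly, consensus_reassignment, nj_tree, read_newick
from .align import k2p_distance


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    genomes: dict[str, GenomeRecord]
    proteomes: dict[str, ProteomeRecord] = field(default_factory=dict)
    ssu: dict[str, str] = field(default_factory=dict)
    tree_newick: str | None = None  # externally built tree; NJ on 16S otherwise
    genus_labels: dict[str, str] = field(default_factory=dict)
    family_labels: dict[str, str] = field(default_factory=dict)
    genus_thresholds: dict[str, float] = field(default_factory=lambda: dict(GENUS_THRESHOLDS))
    species_thresholds: dict[str, float] = field(default_factory=lambda: dict(SPECIES_THRESHOLDS))
    index_params: dict[str, dict] = field(default_factory=dict)
    outdir: Path = Path("geotax_out")
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (*self.genus_thresholds.values(), *self.species_thresholds.values()):
            if not (0.0 < t < 100.0):
                raise ValueError("thresholds must lie in (0, 100)")
        if len(self.genomes) < 2:
            raise ValueError("pipeline needs at least two genomes")


def _fmt(matrix: SimilarityMatrix, path: Path) -> None:
    df = matrix.to_dataframe().round(1)
    df.to_csv(path, sep="\t", index_label="genome_id")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the results dict.

    Stages degrade gracefully: indices whose inputs are missing are skipped
    and noted; any hard stage failure aborts with the stage named.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("geotax")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("geotax %s", __version__)
    log.info(
        "defaults: ANIb fragments 1020 bp, filters 30%%/70%%; AAI RBH 30%%/70%% "
        "(coverage of the shorter); POCP evalue<1e-5, id>40%%, cov>50%% of query; "
        "clustering: average linkage on 100-similarity, lexicographic tie-break; "
        "NJ: Saitou-Nei, smallest-label-pair tie-break; "
        "global alignment +1/-2 affine(5,2); local BLOSUM62 affine(11,1)"
    )
    log.info("thresholds: genus %s species %s seed %d",
             config.genus_thresholds, config.species_thresholds, config.seed)
    results: dict = {}
    stage = "genome_stats"
    try:
        genomes = config.genomes
        stats = stats_table(genomes.values())
        stats.to_csv(out / "genome_stats.tsv", sep="\t", index=False)
        if config.genus_labels:
            stats["genus"] = stats["genome_id"].map(config.genus_labels)
            ranges = stats.groupby("genus").agg(
                gc_min=("gc_percent", "min"), gc_max=("gc_percent", "max"),
                size_min=("size_bp", "min"), size_max=("size_bp", "max"),
            )
            ranges["gc_range"] = (ranges.gc_max - ranges.gc_min).round(1)
            ranges.to_csv(out / "group_ranges.tsv", sep="\t")
        results["stats"] = stats

        stage = "proteomes"
        proteomes = dict(config.proteomes)
        for gid in genomes:
            if gid not in proteomes:
                log.info("no proteome for %s; calling ORFs internally", gid)
                proteomes[gid] = find_orfs(genomes[gid])

        stage = "matrices"
        matrices: dict[str, SimilarityMatrix] = {}
        matrices["ANI"] = build_matrix(
            genomes, "ANI", compute_anib, **config.index_params.get("ANI", {})
        )
        usable = {g: p for g, p in proteomes.items() if p.proteins}
        if len(usable) >= 2:
            matrices["AAI"] = build_matrix(
                usable, "AAI", compute_aai, **config.index_params.get("AAI", {})
            )
            matrices["POCP"] = build_matrix(
                usable, "POCP", compute_pocp, **config.index_params.get("POCP", {})
            )
        else:
            log.warning("fewer than two proteomes; AAI and POCP skipped")
        if len(config.ssu) >= 2:
            matrices["SSU"] = build_matrix(
                config.ssu,
                "SSU",
                lambda a, b: compute_16s_identity(a, b),
            )
        for kind, m in matrices.items():
            _fmt(m, out / f"matrix_{kind.lower()}.tsv")
        results["matrices"] = matrices

        stage = "thresholds"
        thresholds = {}
        if config.genus_labels:
            for kind, m in matrices.items():
                if kind == "SSU":
                    continue
                rep = infer_threshold(m, config.genus_labels)
                thresholds[kind] = {
                    "threshold": rep.threshold,
                    "min_intra": rep.min_intra,
                    "max_inter": rep.max_inter,
                    "n_violations": rep.n_violations,
                }
            (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
        results["thresholds"] = thresholds

        stage = "clusters"
        cluster_kind = "AAI" if "AAI" in matrices else "ANI"
        cut = config.genus_thresholds.get(cluster_kind, 70.0)
        clusters, _ = cluster_and_cut(matrices[cluster_kind], cut)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("genome_id\tcluster\n")
            for g in sorted(clusters):
                fh.write(f"{g}\t{clusters[g]}\n")
        results["clusters"] = clusters

        stage = "regression"
        regression = {}
        for x, y in (("ANI", "AAI"), ("ANI", "POCP"), ("AAI", "POCP")):
            if x in matrices and y in matrices:
                slope, intercept, r2 = index_regression(matrices[x], matrices[y])
                regression[f"{y}~{x}"] = {
                    "slope": slope, "intercept": intercept, "r_squared": r2
                }
        (out / "regression.json").write_text(json.dumps(regression, indent=2))
        results["regression"] = regression

        stage = "phylogeny"
        tree = None
        if config.tree_newick:
            tree = read_newick(config.tree_newick)
        elif "SSU" in matrices:
            m = matrices["SSU"]
            dist = np.zeros_like(m.values)
            labels = m.labels
            for i in range(len(labels)):
                for j in range(i):
                    d = k2p_distance(*_pair_alignment(config.ssu[labels[i]],
                                                      config.ssu[labels[j]]))
                    dist[i, j] = dist[j, i] = d
            tree = nj_tree(dist, labels)
            tree.write(str(out / "tree_nj_16s.nwk"))
        results["tree"] = tree

        stage = "monophyly"
        proposals = []
        if tree is not None and config.genus_labels:
            tips = {t.name for t in tree.tips()}
            labeling = {g: config.genus_labels[g] for g in tips}
            verdicts = check_monophyly(tree, labeling)
            with open(out / "monophyly.tsv", "w") as fh:
                fh.write("genus\tmonophyletic\tblocking_leaves\n")
                for genus, v in sorted(verdicts.items()):
                    fh.write(f"{genus}\t{v.monophyletic}\t{','.join(v.blocking_leaves)}\n")
            results["monophyly"] = verdicts

            stage = "proposals"
            tree_clusters = {g: c for g, c in clusters.items() if g in tips}
            if set(tree_clusters) == tips:
                evidence = {
                    g: [f"{k}: best {np.nanmax(np.delete(m.values[m.labels.index(g)], m.labels.index(g))):.1f}"
                        for k, m in matrices.items() if g in m.labels]
                    for g in sorted(tips)
                }
                proposals = consensus_reassignment(
                    tree_clusters, tree, labeling,
                    config.family_labels or None, evidence,
                )
                with open(out / "proposals.tsv", "w") as fh:
                    fh.write("genome_id\toriginal_genus\tproposal\tevidence\n")
                    for p in proposals:
                        fh.write(f"{p.genome_id}\t{p.original_genus}\t{p.proposal}\t"
                                 f"{'; '.join(p.evidence)}\n")
        results["proposals"] = proposals
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results


def _pair_alignment(a: str, b: str) -> tuple[str, str]:
    """Global-align two SSU sequences and return the two gapped rows."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])
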