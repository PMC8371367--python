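"""End-to-end orchestration: one config in, a report bundle out.

Stage order is fixed: exclusion -> category assignment -> within/cross
similarity -> families / overlap / reconciliation -> composition
clustering / PCA -> glycosylation -> trees -> (optional) gene rescue.
Each stage's outputs are written before the next starts, so a failure
leaves the completed stages on disk next to a ``FAILED`` marker.  Reruns
with identical inputs are byte-identical: the run log records stages,
input checksums and counts but no wall-clock data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from cementome import align, classify, composition, families, generescue, glyco, seqio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, scoring/clustering/glyco parameters and the output directory."""

    fasta_a: str
    fasta_b: str
    annotations_a: str
    annotations_b: str
    outdir: str
    species_a: str = "A"
    species_b: str = "B"
    gap_open: int = 11
    gap_extend: int = 1
    matrix: str = "BLOSUM62"
    evalue_threshold: float = 1e-4
    k_clusters: int = 4
    scaling: str = "zscore_by_residue"
    enrichment_margin: float = 1.5
    glyco_window: int = 5
    glyco_min_frac: float = 0.4
    rescue_contig: str | None = None
    rescue_query: str | None = None  # accession in proteome A
    catalog_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)

    def scoring_params(self) -> align.ScoringParams:
        return align.ScoringParams(
            matrix_name=self.matrix,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            evalue_threshold=self.evalue_threshold,
        )


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output bundle directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        logger.info(line)
        log_lines.append(line)

    try:
        _run_stages(config, out, log)
    except Exception as exc:  # partial outputs retained next to a FAILED marker
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED: {exc}\n")
        raise
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _run_stages(config: PipelineConfig, out: Path, log) -> None:
    params = config.scoring_params()
    catalog = (
        classify.DomainCatalog.from_yaml(config.catalog_path)
        if config.catalog_path
        else classify.DomainCatalog.default()
    )
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    for name in ("fasta_a", "fasta_b", "annotations_a", "annotations_b"):
        log("inputs", f"{name} sha256:{_checksum(getattr(config, name))}")

    # --- load + exclusion + categories ---------------------------------------
    recs = {
        "A": seqio.read_fasta(config.fasta_a, "protein"),
        "B": seqio.read_fasta(config.fasta_b, "protein"),
    }
    anns = {
        "A": seqio.read_annotations(config.annotations_a),
        "B": seqio.read_annotations(config.annotations_b),
    }
    assignments = {}
    retained = {}
    for sp in ("A", "B"):
        assignments[sp] = classify.classify_proteome(recs[sp], anns[sp], catalog)
        assignments[sp].to_csv(out / f"categories_{sp}.tsv", sep="\t")
        retained[sp] = [r for r in recs[sp] if not assignments[sp].loc[r.id, "excluded"]]
        log("classify", f"species {sp}: {len(recs[sp])} proteins, "
                        f"{int(assignments[sp]['excluded'].sum())} excluded, {len(retained[sp])} retained")

    # --- similarity tables ----------------------------------------------------
    cross = align.all_vs_all(retained["A"], retained["B"], params)
    within = {sp: align.all_vs_all(retained[sp], None, params) for sp in ("A", "B")}
    cross.to_dataframe().to_csv(out / "similarity_cross.tsv", sep="\t", index=False)
    for sp in ("A", "B"):
        within[sp].to_dataframe().to_csv(out / f"similarity_within_{sp}.tsv", sep="\t", index=False)
    log("align", f"cross hits: {len(cross)}; within A: {len(within['A'])}; within B: {len(within['B'])}")

    # --- overlap + families + reconciliation ---------------------------------
    venn = families.cross_species_overlap(cross)
    with open(out / "venn.json", "w") as fh:
        json.dump(
            {
                "total_A": venn.total_A, "total_B": venn.total_B,
                "matched_A": venn.matched_A, "matched_B": venn.matched_B,
                "percent_A": venn.percent_A, "percent_B": venn.percent_B,
            },
            fh, indent=1, sort_keys=True,
        )
    log("overlap", f"matched {venn.matched_A}/{venn.total_A} ({venn.percent_A}%) A, "
                   f"{venn.matched_B}/{venn.total_B} ({venn.percent_B}%) B")

    bulk = {
        sp: [r for r in retained[sp] if assignments[sp].loc[r.id, "category"] == "bulk"]
        for sp in ("A", "B")
    }
    fams = {}
    for sp in ("A", "B"):
        bulk_ids = [r.id for r in bulk[sp]]
        bulk_table = align.SimilarityTable(
            rows=[r for r in within[sp] if r.query_id in set(bulk_ids) and r.subject_id in set(bulk_ids)],
            m_total=len(bulk_ids), n_total=len(bulk_ids),
        )
        fams[sp] = families.build_families(bulk_table, bulk_ids)
        pd.DataFrame(
            [{"family": f.family_id, "member": m, "provenance": f.provenance,
              "split_flagged": f.split_flagged}
             for f in fams[sp] for m in sorted(f.members)]
        ).to_csv(out / f"families_{sp}.tsv", sep="\t", index=False)
    lengths = {sp: {r.id: len(r) for r in recs[sp]} for sp in ("A", "B")}
    signal = {sp: {a: anns[sp][a].signal_peptide for a in anns[sp]} for sp in ("A", "B")}
    table = families.reconcile_table(
        fams["A"], cross, lengths_a=lengths["A"], lengths_b=lengths["B"], signal_peptide=signal["A"],
    )
    table.to_csv(out / "family_table.tsv", sep="\t", index=False)
    log("families", f"{len(fams['A'])} A families, {len(fams['B'])} B families")

    summary = {}
    for sp, other in (("A", "B"), ("B", "A")):
        matched = cross.matched_queries() if sp == "A" else cross.matched_subjects()
        cat = classify.category_summary(assignments[sp], matched_in_adhesive=matched)
        cat.to_csv(out / f"category_summary_{sp}.csv")
        summary[sp] = cat["total"].to_dict()

    # --- composition ----------------------------------------------------------
    group_labels = {}
    for sp in ("A", "B"):
        profiles = [composition.aa_composition(r) for r in bulk[sp]]
        composition.profiles_to_matrix(profiles).to_csv(out / f"composition_{sp}.csv")
        k = min(config.k_clusters, len(profiles))
        if k >= 2:
            clusters, linkage, accs = composition.cluster_compositions(profiles, k, config.scaling)
            labels = composition.label_enrichment_groups(clusters, profiles, config.enrichment_margin)
            group_labels[sp] = {acc: labels[cid].value for acc, cid in clusters.items()}
            pd.DataFrame(
                sorted(
                    ({"accession": acc, "cluster": cid, "group": labels[cid].value}
                     for acc, cid in clusters.items()),
                    key=lambda r: r["accession"],
                )
            ).to_csv(out / f"composition_groups_{sp}.csv", index=False)
        else:
            group_labels[sp] = {}
        if len(profiles) >= 3:
            pca = composition.pca_composition(profiles)
            pca.scores.to_csv(out / f"pca_scores_{sp}.csv")
            pca.loadings.to_csv(out / f"pca_loadings_{sp}.csv")
            pca.contributions.to_csv(out / f"pca_contributions_{sp}.csv")
    if group_labels["A"] and group_labels["B"]:
        composition.group_overlap_venn(group_labels["A"], group_labels["B"], cross).to_csv(
            out / "group_overlap.csv", index=False
        )
    log("composition", f"groups A: {sorted(set(group_labels['A'].values()))}; "
                       f"B: {sorted(set(group_labels['B'].values()))}")

    # --- glycosylation --------------------------------------------------------
    for sp in ("A", "B"):
        preds = [glyco.predict_glyco(r, config.glyco_window, config.glyco_min_frac)
                 for r in retained[sp]]
        rows = [{"accession": p.accession, "type": t, "position": pos}
                for p in preds for t, sites in (("N", p.n_sites), ("O", p.o_sites)) for pos in sites]
        with open(out / f"glyco_sites_{sp}.tsv", "w") as fh:
            fh.write(glyco.HEURISTIC_NOTE + "\n")
            pd.DataFrame(rows, columns=["accession", "type", "position"]).to_csv(fh, sep="\t", index=False)
        if group_labels[sp]:
            summary_df = glyco.group_glyco_summary(preds, group_labels[sp])
            with open(out / f"glyco_summary_{sp}.csv", "w") as fh:
                fh.write(glyco.HEURISTIC_NOTE + "\n")
                summary_df.to_csv(fh, index=False)
    log("glyco", "site predictions and group summaries written")

    # --- pheromone distance tree ----------------------------------------------
    pher = [r for sp in ("A", "B") for r in retained[sp]
            if assignments[sp].loc[r.id, "category"] == "pheromone"]
    if len(pher) >= 2:
        tree = families.build_distance_tree(pher, params)
        seqio.write_newick(tree, out / "pheromone_tree.nwk")
        log("trees", f"pheromone tree over {len(pher)} proteins")
    else:
        log("trees", "fewer than 2 pheromone proteins; no tree")

    # --- optional gene rescue -------------------------------------------------
    if config.rescue_contig and config.rescue_query:
        contig = seqio.read_fasta(config.rescue_contig, "dna")[0]
        query = next(r for r in recs["A"] if r.id == config.rescue_query)
        hits = generescue.scan_contig(query, contig, params)
        generescue.hits_to_dataframe(hits).to_csv(out / "rescue_hits.tsv", sep="\t", index=False)
        report = generescue.report_gap_structure(hits, len(query))
        with open(out / "rescue_gaps.json", "w") as fh:
            json.dump({"nt_gaps": report.nt_gaps, "aa_gaps": report.aa_gaps,
                       "query_coverage_union": round(report.query_coverage_union, 1)},
                      fh, indent=1, sort_keys=True)
        log("rescue", f"{len(hits)} hits, nt gaps {report.nt_gaps}")

    # --- summary --------------------------------------------------------------
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "counts": {sp: {k: int(v) for k, v in summary[sp].items()} for sp in summary},
                "overlap": {"matched_A": venn.matched_A, "matched_B": venn.matched_B,
                            "percent_A": venn.percent_A, "percent_B": venn.percent_B},
                "families": {sp: len(fams[sp]) for sp in fams},
            },
            fh, indent=1, sort_keys=True,
        )
    log("done", "bundle complete")
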