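"""Protein families, cross-species overlap and distance trees.

Families are single-linkage clusters: connected components of the graph
whose edges are within-species protein pairs passing the E-value threshold.
Named seed sets (previously described cement-protein families such as CP19
or CP100) propagate their names onto any component containing a seed
member; a component absorbing seeds with different names is flagged for
manual splitting, mirroring how conflicting historical family assignments
are handled in practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from cementome.align import ScoringParams, SimilarityTable, score_local
from cementome.seqio import SequenceRecord, TreeNode

logger = logging.getLogger(__name__)


@dataclass
class Family:
    """A named set of proteins of one species connected at the threshold."""

    family_id: str
    members: frozenset[str]
    provenance: str = "de_novo"  # or "seeded"
    split_flagged: bool = False


@dataclass(frozen=True)
class VennCounts:
    """Protein-level overlap between two proteomes.

    ``matched_A`` counts species-A proteins with at least one passing hit
    in species B (and vice versa); the two matched counts may legitimately
    differ because one protein can align to several partners.
    """

    total_A: int
    total_B: int
    matched_A: int
    matched_B: int

    def __post_init__(self) -> None:
        if not (0 <= self.matched_A <= self.total_A and 0 <= self.matched_B <= self.total_B):
            raise ValueError("matched counts must lie within totals")

    @property
    def percent_A(self) -> int:
        return percent(self.matched_A, self.total_A)

    @property
    def percent_B(self) -> int:
        return percent(self.matched_B, self.total_B)


def percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer, halves rounding up."""
    if denominator == 0:
        return 0
    return math.floor(100.0 * numerator / denominator + 0.5)


def build_families(
    within_species: SimilarityTable,
    proteins: list[str],
    seeds: dict[str, set[str]] | None = None,
) -> list[Family]:
    """Single-linkage families from a within-species similarity table.

    ``proteins`` is the full accession list (so unmatched proteins become
    singleton families).  ``seeds`` maps family names to accession sets;
    seed accessions absent from the proteome are ignored with a warning.
    De novo families are named ``F001, F002, ...`` in order of their
    lexicographically smallest member, making the output independent of
    input order and edge direction.
    """
    seeds = seeds or {}
    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    known = set(proteins)
    for row in within_species:
        if row.query_id in known and row.subject_id in known:
            graph.add_edge(row.query_id, row.subject_id)
    seed_of: dict[str, str] = {}
    for name, accs in seeds.items():
        for acc in accs:
            if acc not in known:
                logger.warning("seed accession %r for family %r absent from proteome; ignored", acc, name)
                continue
            seed_of[acc] = name
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    families: list[Family] = []
    counter = 0
    for comp in components:
        names = sorted({seed_of[a] for a in comp if a in seed_of})
        if names:
            fid = "/".join(names)
            families.append(
                Family(fid, frozenset(comp), provenance="seeded", split_flagged=len(names) > 1)
            )
            if len(names) > 1:
                logger.warning("component %s contains seeds of families %s; flagged for manual split", sorted(comp), names)
        else:
            counter += 1
            families.append(Family(f"F{counter:03d}", frozenset(comp)))
    return families


def cross_species_overlap(cross: SimilarityTable) -> VennCounts:
    """Protein-level overlap counts from a cross-species similarity table.

    The table must be built over the post-exclusion proteomes with species
    A as the queries; totals come from the table's stored set sizes.
    """
    return VennCounts(
        total_A=cross.m_total,
        total_B=cross.n_total,
        matched_A=len(cross.matched_queries()),
        matched_B=len(cross.matched_subjects()),
    )


def reconcile_table(
    families_a: list[Family],
    cross: SimilarityTable,
    lengths_a: dict[str, int] | None = None,
    lengths_b: dict[str, int] | None = None,
    signal_peptide: dict[str, bool] | None = None,
    identified_by_ms: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Family reconciliation table: best cross-species hit per A-family member.

    One row per member of each species-A family, reporting the best species-B
    hit with its alignment metrics; members without a passing hit get an
    explicit no-match row with empty metrics.  Several members best-hitting
    the same B protein each keep their row (many-to-one collapses are
    visible, not merged).  Signal-peptide and identified-by-MS booleans are
    carried through as input columns when provided.
    """
    lengths_a = lengths_a or {}
    lengths_b = lengths_b or {}
    signal_peptide = signal_peptide or {}
    identified_by_ms = identified_by_ms or {}
    rows = []
    for fam in sorted(families_a, key=lambda f: f.family_id):
        for member in sorted(fam.members):
            best = cross.best_hit(member)
            row = {
                "family": fam.family_id,
                "member": member,
                "member_length": lengths_a.get(member, pd.NA),
                "member_signal_peptide": signal_peptide.get(member, pd.NA),
                "member_identified_by_ms": identified_by_ms.get(member, pd.NA),
            }
            if best is None:
                row.update({"partner": "", "partner_length": pd.NA, "evalue": pd.NA,
                            "percent_identity": pd.NA, "query_coverage": pd.NA})
            else:
                row.update(
                    {
                        "partner": best.subject_id,
                        "partner_length": lengths_b.get(best.subject_id, pd.NA),
                        "evalue": best.evalue,
                        "percent_identity": round(best.percent_identity, 1),
                        "query_coverage": round(best.query_coverage, 1),
                    }
                )
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["family", "member", "member_length", "member_signal_peptide",
                 "member_identified_by_ms", "partner", "partner_length",
                 "evalue", "percent_identity", "query_coverage"],
    )


def build_distance_tree(members: list[SequenceRecord], params: ScoringParams | None = None) -> TreeNode:
    """UPGMA tree over proteins with distance ``1 - identity/100``.

    Pairwise percent identity comes from the optimal local alignment of each
    pair (a pair with no alignment gets distance 1).  Average-linkage
    agglomeration yields an ultrametric tree; ties are broken
    deterministically by sorting leaves lexicographically first.  The tree
    is a pairwise-distance stand-in for a tree built from a multiple
    sequence alignment; with strong signal the qualitative grouping
    (by family vs by species) is the same.
    """
    if len(members) < 2:
        raise ValueError("a distance tree needs at least 2 members")
    if params is None:
        params = ScoringParams()
    members = sorted(members, key=lambda r: r.id)
    n = len(members)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = score_local(members[i], members[j], params)
            d = 1.0 if res is None else 1.0 - res.percent_identity / 100.0
            dist[i, j] = dist[j, i] = max(d, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return _linkage_to_tree(linkage, [m.id for m in members])


def _linkage_to_tree(linkage: np.ndarray, labels: list[str]) -> TreeNode:
    """Convert a scipy linkage matrix to an ultrametric TreeNode."""
    n = len(labels)
    heights: dict[int, float] = {}
    nodes: dict[int, TreeNode] = {}
    for i, label in enumerate(labels):
        nodes[i] = TreeNode(name=label)
        heights[i] = 0.0
    for k, (a, b, d, _) in enumerate(linkage):
        a, b = int(a), int(b)
        h = d / 2.0  # UPGMA node height
        for child_idx in (a, b):
            nodes[child_idx].branch_length = h - heights[child_idx]
        nodes[n + k] = TreeNode(children=[nodes[a], nodes[b]])
        heights[n + k] = h
    return nodes[n + len(linkage) - 1]
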