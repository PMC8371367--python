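import numpy as np
import pytest

from cementome import align, families
from cementome.families import VennCounts, percent
from cementome.seqio import SequenceRecord
from cementome.synthetic import mutate_sequence, pheromone_tree_fixture

from conftest import make_hit, random_protein


def table(edges, nodes=None):
    rows = [make_hit(a, b) for a, b in edges]
    n = len(nodes or [])
    return align.SimilarityTable(rows=rows, m_total=n, n_total=n)


class TestBuildFamilies:
    def test_transitive_single_linkage(self):
        fams = families.build_families(table([("a", "b"), ("b", "c")]), ["a", "b", "c"])
        assert len(fams) == 1 and fams[0].members == {"a", "b", "c"}

    def test_no_edges_gives_singletons(self):
        fams = families.build_families(table([]), list("abcde"))
        assert len(fams) == 5 and all(len(f.members) == 1 for f in fams)

    def test_matches_brute_force_components_on_random_graphs(self):
        """Single-linkage families equal DFS connected components, 50 graphs."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(2, 31))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.08
            ]
            # brute-force DFS oracle
            adj = {v: set() for v in nodes}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            seen, comps = set(), []
            for v in nodes:
                if v in seen:
                    continue
                stack, comp = [v], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend(adj[u] - comp)
                seen |= comp
                comps.append(frozenset(comp))
            got = {f.members for f in families.build_families(table(edges), nodes)}
            assert got == set(comps)

    def test_invariant_to_input_order_and_edge_direction(self):
        edges = [("a", "b"), ("c", "d"), ("b", "e")]
        f1 = families.build_families(table(edges), list("abcde"))
        f2 = families.build_families(table([(b, a) for a, b in reversed(edges)]), list("edcba"))
        assert {f.members for f in f1} == {f.members for f in f2}
        assert {f.family_id: f.members for f in f1} == {f.family_id: f.members for f in f2}

    def test_seed_names_propagate(self):
        fams = families.build_families(
            table([("a", "b")]), ["a", "b", "c"], seeds={"CP19": {"a"}}
        )
        by_id = {f.family_id: f for f in fams}
        assert by_id["CP19"].members == {"a", "b"}
        assert by_id["CP19"].provenance == "seeded"

    def test_conflicting_seeds_joined_and_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            fams = families.build_families(
                table([("a", "b")]), ["a", "b"], seeds={"CP52-1": {"a"}, "CP52-2": {"b"}}
            )
        (fam,) = fams
        assert fam.family_id == "CP52-1/CP52-2" and fam.split_flagged

    def test_absent_seed_ignored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fams = families.build_families(table([]), ["a"], seeds={"CP19": {"zzz"}})
        assert fams[0].family_id != "CP19"
        assert "ignored" in caplog.text


class TestOverlap:
    def test_study_scale_percentages(self):
        """71 of 87 and 132 of 161 matched proteins both round to 82%."""
        venn = VennCounts(total_A=87, total_B=161, matched_A=71, matched_B=132)
        assert venn.percent_A == 82
        assert venn.percent_B == 82

    def test_percent_rounds_half_up(self):
        assert percent(1, 8) == 13  # 12.5 -> 13
        assert percent(0, 10) == 0 and percent(10, 10) == 100

    def test_empty_table(self):
        venn = families.cross_species_overlap(align.SimilarityTable(m_total=5, n_total=7))
        assert (venn.matched_A, venn.matched_B) == (0, 0)
        assert venn.percent_A == 0

    def test_planted_overlap_counts(self, uniform_analysis):
        """Every planted shared protein and no unique protein is matched."""
        d = uniform_analysis["bundle"]
        venn = families.cross_species_overlap(uniform_analysis["cross"])
        for species, matched, total in (
            ("A", venn.matched_A, venn.total_A),
            ("B", venn.matched_B, venn.total_B),
        ):
            expected = sum(
                1 for t in d.truth.proteins.values()
                if t["species"] == species and t["family_id"] and t["category"] != "cellular_excluded"
            )
            assert matched == expected
            assert total == sum(
                1 for t in d.truth.proteins.values()
                if t["species"] == species and t["category"] != "cellular_excluded"
            )


class TestReconcileTable:
    def test_no_hit_member_gets_empty_metrics_row(self):
        fams = [families.Family("CP19", frozenset({"a1", "a2"}))]
        cross = align.SimilarityTable(rows=[make_hit("a1", "b9", pident=42.0)], m_total=2, n_total=1)
        out = families.reconcile_table(fams, cross)
        assert len(out) == 2
        no_hit = out[out["member"] == "a2"].iloc[0]
        assert no_hit["partner"] == "" and no_hit.isna()["evalue"]
        hit = out[out["member"] == "a1"].iloc[0]
        assert hit["partner"] == "b9" and hit["percent_identity"] == 42.0

    def test_many_to_one_collapse_preserved(self):
        fams = [families.Family("CP100", frozenset({"a1", "a2"}))]
        cross = align.SimilarityTable(
            rows=[make_hit("a1", "b1", evalue=1e-50), make_hit("a2", "b1", evalue=1e-40)],
            m_total=2, n_total=1,
        )
        out = families.reconcile_table(fams, cross)
        assert list(out["partner"]) == ["b1", "b1"]

    def test_planted_one_to_one_pairing_recovered(self, uniform_analysis):
        d = uniform_analysis["bundle"]
        cross = uniform_analysis["cross"]
        for a_acc, b_acc in d.truth.homologue_pairs():
            best = cross.best_hit(a_acc)
            assert best is not None and best.subject_id == b_acc, (a_acc, b_acc)


class TestDistanceTree:
    def test_closest_pair_joins_first(self, params):
        rng = np.random.default_rng(1)
        base = random_protein(rng, 150, "a").sequence
        recs = [
            SequenceRecord(id="a", sequence=base),
            SequenceRecord(id="b", sequence=mutate_sequence(base, 0.9, rng)),
            SequenceRecord(id="c", sequence=mutate_sequence(base, 0.4, rng)),
        ]
        tree = families.build_distance_tree(recs, params)
        cherries = [set(c.leaf_names()) for c in tree.children if not c.is_leaf]
        assert {"a", "b"} in cherries or any(
            set(n.leaf_names()) == {"a", "b"} for n in _walk(tree)
        )

    def test_identical_sequences_zero_length_cherry(self, params):
        rng = np.random.default_rng(2)
        base = random_protein(rng, 100, "x").sequence
        recs = [SequenceRecord(id="x1", sequence=base), SequenceRecord(id="x2", sequence=base),
                SequenceRecord(id="y", sequence=random_protein(rng, 100, "y").sequence)]
        tree = families.build_distance_tree(recs, params)
        cherry = next(n for n in _walk(tree) if set(n.leaf_names()) == {"x1", "x2"})
        assert all(abs(c.branch_length) < 1e-12 for c in cherry.children)

    def test_fewer_than_two_members_rejected(self, params):
        with pytest.raises(ValueError):
            families.build_distance_tree([SequenceRecord(id="a", sequence="MKLV")], params)

    def test_ultrametric_root_to_leaf_paths(self, params):
        records, _, _ = pheromone_tree_fixture("family", seed=3, n_families=3)
        tree = families.build_distance_tree(records, params)
        depths = _leaf_depths(tree, 0.0)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_alpha_macroglobulin_like_set_groups_by_family(self, params):
        records, family_of, _ = pheromone_tree_fixture("family", seed=0)
        tree = families.build_distance_tree(records, params)
        for fam in set(family_of.values()):
            members = {acc for acc, f in family_of.items() if f == fam}
            assert any(set(n.leaf_names()) == members for n in _walk(tree)), fam

    def test_wsp_like_set_groups_by_species(self, params):
        records, _, species_of = pheromone_tree_fixture("species", seed=0)
        tree = families.build_distance_tree(records, params)
        for sp in set(species_of.values()):
            members = {acc for acc, s in species_of.items() if s == sp}
            assert any(set(n.leaf_names()) == members for n in _walk(tree)), sp


def _walk(node):
    yield node
    for child in node.children:
        yield from _walk(child)


def _leaf_depths(node, depth):
    depth += node.branch_length
    if node.is_leaf:
        return {node.name: depth}
    out = {}
    for child in node.children:
        out.update(_leaf_depths(child, depth))
    return out
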