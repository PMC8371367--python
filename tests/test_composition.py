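from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cementome import align, composition
from cementome.seqio import AMINO_ACIDS, SequenceRecord
from cementome.synthetic import SyntheticConfig, generate_proteome_pair, _class_freqs

from conftest import make_hit


def protein(acc, seq):
    return SequenceRecord(id=acc, sequence=seq)


def sample_class(rng, comp_class, length=300, acc="p"):
    freqs = _class_freqs(comp_class)
    return protein(acc, "".join(rng.choice(list(AMINO_ACIDS), size=length, p=freqs)))


class TestComposition:
    def test_homopolymer(self):
        prof = composition.aa_composition(protein("p", "GGGG"))
        assert prof.as_dict()["G"] == 100.0
        assert sum(prof.percentages) == pytest.approx(100.0)

    def test_equal_quarters(self):
        prof = composition.aa_composition(protein("p", "GALM")).as_dict()
        assert all(prof[aa] == 25.0 for aa in "GALM")

    def test_x_excluded_from_both_sides(self):
        prof = composition.aa_composition(protein("p", "GXXG")).as_dict()
        assert prof["G"] == 100.0

    def test_all_x_is_hard_error(self):
        with pytest.raises(ValueError, match="canonical"):
            composition.aa_composition(protein("p", "XXXX"))

    def test_random_500mers_match_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=500))
            prof = composition.aa_composition(protein("p", seq)).as_dict()
            counts = Counter(seq)
            assert sum(prof.values()) == pytest.approx(100.0)
            for aa in AMINO_ACIDS:
                assert prof[aa] == pytest.approx(100.0 * counts[aa] / 500)

    def test_invariant_under_shuffling(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
        shuffled = "".join(rng.permutation(list(seq)))
        assert (composition.aa_composition(protein("p", seq)).percentages
                == composition.aa_composition(protein("p", shuffled)).percentages)


class TestClustering:
    def two_class_profiles(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        recs = [sample_class(rng, "GrCP", acc=f"g{i}") for i in range(n)]
        recs += [sample_class(rng, "LrCP", acc=f"l{i}") for i in range(n)]
        return [composition.aa_composition(r) for r in recs]

    def test_two_planted_classes_split_perfectly(self):
        profiles = self.two_class_profiles()
        clusters, _, _ = composition.cluster_compositions(profiles, k=2)
        groups = {}
        for acc, cid in clusters.items():
            groups.setdefault(cid, set()).add(acc[0])
        assert sorted(groups.values(), key=sorted) == [{"g"}, {"l"}]

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            composition.cluster_compositions(self.two_class_profiles(n=3), k=1)

    def test_order_invariance(self):
        profiles = self.two_class_profiles(n=10)
        rng = np.random.default_rng(3)
        shuffled = [profiles[i] for i in rng.permutation(len(profiles))]
        c1, _, _ = composition.cluster_compositions(profiles, k=2)
        c2, _, _ = composition.cluster_compositions(shuffled, k=2)
        # cluster ids may permute; membership partition must be identical
        part1 = {frozenset(a for a, c in c1.items() if c == cid) for cid in set(c1.values())}
        part2 = {frozenset(a for a, c in c2.items() if c == cid) for cid in set(c2.values())}
        assert part1 == part2

    def test_identical_profiles_deterministic(self):
        profiles = [composition.CompositionProfile(f"p{i}", tuple([5.0] * 20)) for i in range(4)]
        c1, _, _ = composition.cluster_compositions(profiles, k=2, scaling="none")
        c2, _, _ = composition.cluster_compositions(profiles, k=2, scaling="none")
        assert c1 == c2


class TestEnrichmentLabels:
    def planted(self, seed=0, n=12, with_cys=True):
        rng = np.random.default_rng(seed)
        recs = [sample_class(rng, "GrCP", acc=f"g{i}") for i in range(n)]
        recs += [sample_class(rng, "LrCP", acc=f"l{i}") for i in range(n)]
        if with_cys:
            recs += [sample_class(rng, "CrCP", acc=f"c{i}") for i in range(max(3, n // 3))]
        return [composition.aa_composition(r) for r in recs]

    def test_label_recovery_on_planted_classes(self):
        """Planted Gly-, Leu- and Cys-rich classes get the matching labels."""
        profiles = self.planted()
        clusters, _, _ = composition.cluster_compositions(profiles, k=3)
        labels = composition.label_enrichment_groups(clusters, profiles)
        for acc, cid in clusters.items():
            expected = {"g": "GrCP", "l": "LrCP", "c": "CrCP"}[acc[0]]
            assert labels[cid].value.startswith(expected), (acc, labels[cid])

    def test_same_base_labels_numbered_by_strength(self):
        def profile(acc, g_pct):
            rest = (100.0 - g_pct) / 19.0
            return composition.CompositionProfile(
                acc, tuple(g_pct if aa == "G" else rest for aa in AMINO_ACIDS))

        # two Gly-rich clusters at different strengths plus a flat background
        profiles = (
            [profile(f"s{i}", 30.0 + (0.5 if i % 2 else -0.5)) for i in range(4)]
            + [profile(f"w{i}", 20.0 + (0.5 if i % 2 else -0.5)) for i in range(4)]
            + [profile(f"u{i}", 5.0 + (0.3 if i % 2 else -0.3)) for i in range(4)]
        )
        clusters = {p.accession: {"s": 1, "w": 2, "u": 3}[p.accession[0]] for p in profiles}
        labels = composition.label_enrichment_groups(clusters, profiles)
        assert labels[1].value == "GrCP1"
        assert labels[2].value == "GrCP2"
        assert labels[3].value.startswith("minor")

    def test_flat_profiles_all_minor(self):
        # identical flat compositions carry no enrichment signal at all
        profiles = [composition.CompositionProfile(f"u{i}", tuple([5.0] * 20))
                    for i in range(8)]
        clusters, _, _ = composition.cluster_compositions(profiles, k=2, scaling="none")
        labels = composition.label_enrichment_groups(clusters, profiles)
        assert all(l.value.startswith("minor") for l in labels.values())


class TestPCA:
    def test_two_class_separation_driven_by_g_and_l(self):
        rng = np.random.default_rng(0)
        profiles = [composition.aa_composition(sample_class(rng, c, acc=f"{c}{i}"))
                    for c in ("GrCP", "LrCP") for i in range(15)]
        res = composition.pca_composition(profiles)
        pc1 = res.loadings["PC1"]
        top = set(pc1.abs().sort_values(ascending=False).index[:2]) | {
            pc1.idxmax(), pc1.idxmin()}
        assert "G" in top and "L" in top
        assert np.sign(pc1["G"]) != np.sign(pc1["L"])

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        profiles = [composition.aa_composition(sample_class(rng, "uniform", acc=f"p{i}"))
                    for i in range(10)]
        res = composition.pca_composition(profiles, n_components=10)
        data = composition.profiles_to_matrix(profiles).to_numpy()
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean
        assert np.allclose(approx, data, atol=1e-8)

    def test_identical_profiles_hard_error(self):
        profiles = [composition.CompositionProfile(f"p{i}", tuple([5.0] * 20)) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            composition.pca_composition(profiles)

    def test_contributions_sum_to_100_and_variance_monotone(self):
        rng = np.random.default_rng(8)
        profiles = [composition.aa_composition(sample_class(rng, "GrCP", acc=f"p{i}"))
                    for i in range(12)]
        res = composition.pca_composition(profiles, n_components=3)
        assert np.allclose(res.contributions.sum(axis=0), 100.0)
        assert all(x >= y for x, y in zip(res.variance_explained, res.variance_explained[1:]))
        assert res.variance_explained.sum() <= 1.0 + 1e-9


class TestGroupOverlap:
    def test_one_to_two_homology(self):
        labels_a = {"a1": "GrCP1"}
        labels_b = {"b1": "GrCP1", "b2": "GrCP1"}
        cross = align.SimilarityTable(
            rows=[make_hit("a1", "b1"), make_hit("a1", "b2")], m_total=1, n_total=2)
        out = composition.group_overlap_venn(labels_a, labels_b, cross)
        row = out[(out["group_A"] == "GrCP1") & (out["group_B"] == "GrCP1")].iloc[0]
        assert row["matched_A"] == 1 and row["matched_B"] == 2

    def test_no_cross_edges_zero_overlap(self):
        out = composition.group_overlap_venn(
            {"a": "GrCP1"}, {"b": "GrCP1"}, align.SimilarityTable(m_total=1, n_total=1))
        row = out.iloc[0]
        assert row["matched_A"] == 0 and row["matched_B"] == 0

    def test_cross_group_matches_reported_separately(self):
        labels_a = {"a1": "GrCP1"}
        labels_b = {"b1": "LrCP1"}
        cross = align.SimilarityTable(rows=[make_hit("a1", "b1")], m_total=1, n_total=1)
        out = composition.group_overlap_venn(labels_a, labels_b, cross)
        row = out[(out["group_A"] == "GrCP1") & (out["group_B"] == "LrCP1")].iloc[0]
        assert not row["same_group"] and row["matched_A"] == 1

    def test_label_permutation_invariance(self):
        labels_a = {"a1": "GrCP1", "a2": "LrCP1"}
        labels_b = {"b1": "GrCP1", "b2": "LrCP1"}
        cross = align.SimilarityTable(
            rows=[make_hit("a1", "b1"), make_hit("a2", "b2")], m_total=2, n_total=2)
        out1 = composition.group_overlap_venn(labels_a, labels_b, cross)
        rename = {"GrCP1": "X", "LrCP1": "Y"}
        out2 = composition.group_overlap_venn(
            {k: rename[v] for k, v in labels_a.items()},
            {k: rename[v] for k, v in labels_b.items()}, cross)
        out1["group_A"] = out1["group_A"].map(rename)
        out1["group_B"] = out1["group_B"].map(rename)
        pd.testing.assert_frame_equal(
            out1.sort_values(["group_A", "group_B"]).reset_index(drop=True),
            out2.sort_values(["group_A", "group_B"]).reset_index(drop=True))


def test_five_group_structure_emerges_on_acorn_like_fixture():
    """A fixture carrying Gly-, Leu- and Cys-rich classes yields the expected
    major enrichment groups when cut at k=5."""
    rng = np.random.default_rng(20)
    recs = (
        [sample_class(rng, "GrCP", acc=f"g{i}") for i in range(14)]
        + [sample_class(rng, "LrCP", acc=f"l{i}") for i in range(14)]
        + [sample_class(rng, "CrCP", acc=f"c{i}") for i in range(6)]
        + [sample_class(rng, "uniform", acc=f"u{i}") for i in range(8)]
    )
    profiles = [composition.aa_composition(r) for r in recs]
    clusters, _, _ = composition.cluster_compositions(profiles, k=5)
    labels = composition.label_enrichment_groups(clusters, profiles)
    bases = {l.value.rstrip("123") for l in labels.values()}
    assert {"GrCP", "LrCP", "CrCP"} <= bases
    # planted class members never land in a cluster labelled with another base
    for acc, cid in clusters.items():
        base = {"g": "GrCP", "l": "LrCP", "c": "CrCP", "u": "minor"}[acc[0]]
        got = labels[cid].value
        if base != "minor":
            assert got.startswith(base), (acc, got)
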