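"""Species-group construction, taxonomy consensus, abundance
normalization, genome gating/dereplication, and ordination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from lakemeta import community as cm
from lakemeta.records import CoverageRecord, GenomeRecord, MarkerHit, TaxonomyEvidence


def _hit(pid, score):
    return MarkerHit(pid, "rps3", score, 1e-20)


class TestScreenMarkerSequences:
    def test_threshold_is_inclusive_at_40(self):
        hits = [_hit("a", 39.9), _hit("b", 40.0), _hit("c", 55.1)]
        assert cm.screen_marker_sequences(hits) == {"b", "c"}

    def test_empty_and_all_below(self):
        assert cm.screen_marker_sequences([]) == set()
        assert cm.screen_marker_sequences([_hit("a", 10.0)]) == set()


class TestPairwiseIdentity:
    def test_identical_and_unrelated(self):
        assert cm.pairwise_identity("MKT" * 40, "MKT" * 40) == 1.0
        assert cm.pairwise_identity("", "MKT") == 0.0

    def test_single_substitution_identity(self):
        a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
        b = a[:60] + "W" + a[61:]
        assert cm.pairwise_identity(a, b) == pytest.approx(119 / 120)


class TestClusterSpeciesGroups:
    def test_identical_sequences_form_one_group(self):
        groups = cm.cluster_species_groups({"a": "MKTAYIAK" * 20, "b": "MKTAYIAK" * 20})
        assert len(groups) == 1
        assert sorted(groups[0].member_ids) == ["a", "b"]

    def test_unrelated_sequences_stay_separate(self):
        groups = cm.cluster_species_groups({"a": "MKWY" * 30, "b": "CHDE" * 30})
        assert len(groups) == 2

    def test_derived_three_sequence_example(self):
        # A 120 aa; B differs by 1 substitution (identity 119/120 ~ 0.992);
        # C differs from A at 12 positions (identity 0.90)
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aa), size=120))
        b = a[:50] + ("W" if a[50] != "W" else "Y") + a[51:]
        c = list(a)
        for pos in rng.choice(120, size=12, replace=False):
            c[pos] = next(x for x in aa if x != c[pos])
        c = "".join(c)
        groups = cm.cluster_species_groups({"A": a, "B": b, "C": c}, identity_threshold=0.99)
        members = sorted(sorted(g.member_ids) for g in groups)
        assert members == [["A", "B"], ["C"]]

    def test_threshold_one_all_distinct_gives_singletons(self):
        seqs = {f"s{i}": "MKTA" * 20 + "ACDE" * i for i in range(1, 5)}
        groups = cm.cluster_species_groups(seqs, identity_threshold=1.0)
        assert len(groups) == len(seqs)

    def test_threshold_zero_gives_one_group(self):
        seqs = {"a": "MKWY" * 30, "b": "CHDE" * 30, "c": "PGST" * 30}
        groups = cm.cluster_species_groups(seqs, identity_threshold=0.0)
        assert len(groups) == 1

    def test_representative_is_longest_member(self):
        long = "MKTAYIAK" * 25
        groups = cm.cluster_species_groups({"short": long[:190], "long": long})
        assert groups[0].representative_protein_id == "long"

    def test_fragmented_members_on_one_scaffold_keep_longer_fragment(self):
        base = "MKTAYIAK" * 25
        groups = cm.cluster_species_groups(
            {"frag_long": base, "frag_short": base[:196]},
            scaffold_of={"frag_long": "scafX", "frag_short": "scafX"},
        )
        assert groups[0].representative_protein_id == "frag_long"


class TestFilterShortRepresentatives:
    def test_derived_sample_sd_cutoff(self):
        lengths = {"a": 100, "b": 98, "c": 96, "d": 60}
        # mean 88.5, sample SD ~19.07, cutoff ~69.43
        assert cm.filter_short_representatives(lengths) == {"a", "b", "c"}

    def test_equal_lengths_all_retained(self):
        lengths = {"a": 100, "b": 100, "c": 100}
        assert cm.filter_short_representatives(lengths) == {"a", "b", "c"}

    def test_single_sequence_retained(self):
        assert cm.filter_short_representatives({"only": 55}) == {"only"}


class TestScaffoldConsensusTaxonomy:
    def test_modal_phylum(self):
        hits = [("P", 0.9, 1e-20), ("P", 0.8, 1e-15), ("A", 0.9, 1e-12)]
        assert cm.scaffold_consensus_taxonomy(hits) == "P"

    def test_tie_is_unresolved(self):
        hits = [("P", 0.9, 1e-20), ("P", 0.8, 1e-15), ("A", 0.9, 1e-12), ("A", 0.8, 1e-11)]
        assert cm.scaffold_consensus_taxonomy(hits) is None

    def test_low_coverage_hits_are_filtered_out(self):
        hits = [("P", 0.5, 1e-20), ("A", 0.5, 1e-20)]
        assert cm.scaffold_consensus_taxonomy(hits) is None

    def test_evalue_filter(self):
        hits = [("P", 0.9, 1e-5), ("A", 0.9, 1e-11)]
        assert cm.scaffold_consensus_taxonomy(hits) == "A"


class TestConsensusTaxonomy:
    @pytest.mark.parametrize(
        "lines,expected",
        [
            (("Actinobacteria", "Actinobacteria", "Proteobacteria"), "Actinobacteria"),
            (("A", "B", "C"), None),
            ((None, "A", "A"), "A"),
            ((None, None, "A"), None),
        ],
    )
    def test_two_of_three_rule(self, lines, expected):
        ev = TaxonomyEvidence(*lines)
        assert cm.consensus_taxonomy(ev) == expected

    def test_order_invariance(self):
        for lines in itertools.permutations(("A", "A", "B")):
            assert cm.consensus_taxonomy(TaxonomyEvidence(*lines)) == "A"
        for lines in itertools.permutations((None, "A", "A")):
            assert cm.consensus_taxonomy(TaxonomyEvidence(*lines)) == "A"


class TestDetectAndNormalize:
    def _recs(self, covs, breadths, sample="s1"):
        return [
            CoverageRecord(f"g{i}", sample, c, b)
            for i, (c, b) in enumerate(zip(covs, breadths))
        ]

    def test_all_present_normalization(self):
        ab = cm.detect_and_normalize(self._recs((2, 3, 5), (0.9, 0.9, 0.9)))
        assert ab["s1"].tolist() == [0.2, 0.3, 0.5]

    def test_undetected_entity_leaves_the_denominator(self):
        ab = cm.detect_and_normalize(self._recs((2, 3, 5), (0.9, 0.4, 0.9)))
        assert ab["s1"].tolist() == pytest.approx([2 / 7, 0.0, 5 / 7])

    def test_breadth_exactly_half_counts_as_present(self):
        ab = cm.detect_and_normalize(self._recs((4, 4), (0.5, 1.0)))
        assert ab["s1"].tolist() == [0.5, 0.5]

    def test_columns_sum_to_one_or_zero(self, small_community):
        _, _, _, coverage, _ = small_community
        ab = cm.detect_and_normalize(coverage)
        sums = ab.sum(axis=0)
        assert ((np.abs(sums - 1.0) < 1e-12) | (sums == 0.0)).all()

    def test_missing_pairs_treated_as_absent(self):
        recs = [
            CoverageRecord("gA", "s1", 5.0, 0.9),
            CoverageRecord("gA", "s2", 5.0, 0.9),
            CoverageRecord("gB", "s2", 5.0, 0.9),
        ]
        ab = cm.detect_and_normalize(recs)
        assert ab.at["gB", "s1"] == 0.0
        assert ab.at["gA", "s1"] == 1.0


class TestQualityGate:
    def test_boundary_inclusive_at_70(self):
        g70 = GenomeRecord("a", completeness=70.0)
        g699 = GenomeRecord("b", completeness=69.9)
        assert cm.quality_gate([g70, g699]) == [g70]

    def test_marker_arithmetic(self):
        comp, red = cm.marker_completeness(43, 38, 2)
        assert comp == pytest.approx(88.372, abs=0.001)
        assert red == pytest.approx(4.651, abs=0.001)


class TestDereplicate:
    def _genomes(self):
        return [
            GenomeRecord("A", completeness=90.0, redundancy=2.0),
            GenomeRecord("B", completeness=80.0, redundancy=1.0),
            GenomeRecord("C", completeness=85.0, redundancy=1.0),
        ]

    def test_single_linkage_clusters(self):
        ani = {("A", "B"): 96.0, ("A", "C"): 90.0, ("B", "C"): 91.0}
        clusters = cm.dereplicate(self._genomes(), ani)
        assert set(clusters) == {"A", "C"}
        assert [g.genome_id for g in clusters["A"]] == ["A", "B"]

    def test_no_pairs_above_threshold_all_singletons(self):
        clusters = cm.dereplicate(self._genomes(), {("A", "B"): 90.0})
        assert set(clusters) == {"A", "B", "C"}

    def test_representative_is_most_complete(self):
        ani = {("A", "B"): 97.0}
        clusters = cm.dereplicate(self._genomes(), ani)
        assert "A" in clusters  # completeness 90 beats 80

    def test_asymmetric_ani_is_error(self):
        ani = {("A", "B"): 96.0, ("B", "A"): 99.0}
        with pytest.raises(ValueError, match="asymmetric"):
            cm.dereplicate(self._genomes(), ani)

    def test_transitive_chain_merges(self):
        ani = {("A", "B"): 96.0, ("B", "C"): 96.0}
        clusters = cm.dereplicate(self._genomes(), ani)
        assert len(clusters) == 1


class TestBrayCurtis:
    def test_identical_profiles_distance_zero(self):
        m = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]})
        assert cm.bray_curtis(m).at["s1", "s2"] == 0.0

    def test_disjoint_profiles_distance_one(self):
        m = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]})
        assert cm.bray_curtis(m).at["s1", "s2"] == 1.0

    def test_derived_worked_example(self):
        m = pd.DataFrame({"u": [0.5, 0.5, 0.0], "v": [0.25, 0.25, 0.5]})
        assert cm.bray_curtis(m).at["u", "v"] == pytest.approx(0.5)

    def test_two_empty_profiles_defined_as_zero(self):
        m = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.0, 0.0]})
        d = cm.bray_curtis(m)
        assert d.at["s1", "s2"] == 0.0 and not d.isna().any().any()

    def test_matches_scipy_on_random_profiles(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0.01, 1.0, size=(10, 5)))
        ours = cm.bray_curtis(m).to_numpy()
        theirs = squareform(pdist(m.to_numpy().T, metric="braycurtis"))
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_output_in_unit_interval_and_symmetric(self, small_community):
        _, _, _, coverage, _ = small_community
        d = cm.bray_curtis(cm.detect_and_normalize(coverage))
        v = d.to_numpy()
        assert (v >= 0).all() and (v <= 1).all()
        np.testing.assert_allclose(v, v.T)
        assert np.diag(v).max() == 0.0


class TestPcoa:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords, explained = cm.pcoa(d, k=2)
        recovered = pdist(coords.to_numpy())
        np.testing.assert_allclose(recovered, [1.0, 1.0, 1.0], atol=1e-9)
        assert explained[0] == pytest.approx(explained[1], abs=1e-9)

    def test_euclidean_self_consistency(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        coords, _ = cm.pcoa(d, k=3)
        np.testing.assert_allclose(
            squareform(pdist(coords.to_numpy())), d.to_numpy(), atol=1e-9
        )

    def test_k_zero_returns_empty_coordinates(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        coords, explained = cm.pcoa(d, k=0)
        assert coords.shape == (3, 0) and len(explained) == 0

    def test_non_symmetric_input_is_error(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cm.pcoa(d)

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 4))
        d = squareform(pdist(pts))
        ours_coords, ours_explained = cm.pcoa(pd.DataFrame(d), k=3)
        theirs = skbio_pcoa(d)
        np.testing.assert_allclose(
            ours_explained, theirs.proportion_explained.values[:3], atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(ours_coords.to_numpy()),
            np.abs(theirs.samples.values[:, :3]),
            atol=1e-8,
        )
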