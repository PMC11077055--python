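"""Pairwise alignment statistics and homolog-family clustering."""

import random

import pytest

from abikit.homolog_families import (
    ClusteringParams,
    HomologFamilies,
    align_pair,
    build_homolog_graph,
    candidate_pairs,
    cluster_proteins,
    connected_components,
)
from abikit.proteome_io import PhageRecord, Protein, ProteomeSet

from .oracles import components_bfs, local_align_score


class TestAlignPair:
    def test_self_alignment(self):
        stats = align_pair("MKVLAATTRW", "MKVLAATTRW")
        assert stats.identity == 1.0
        assert stats.coverage_a == 1.0 and stats.coverage_b == 1.0

    def test_exact_prefix_pair(self):
        stats = align_pair("MKVLAATTRW", "MKVLAATT")
        assert stats.identity == 1.0
        assert stats.coverage_a == pytest.approx(0.8)
        assert stats.coverage_b == 1.0

    def test_symmetry(self):
        a, b = "MKVLAATTRW", "MKVLWAT"
        fwd, rev = align_pair(a, b), align_pair(b, a)
        assert fwd.identity == rev.identity
        assert fwd.score == rev.score
        assert (fwd.coverage_a, fwd.coverage_b) == (rev.coverage_b, rev.coverage_a)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_score_matches_dp_oracle(self, seed):
        rng = random.Random(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(aa) for _ in range(50))
        b = "".join(rng.choice(aa) for _ in range(50))
        stats = align_pair(a, b)
        assert stats.score == pytest.approx(local_align_score(a, b))
        # unrelated 50-mers never pass the joint identity + coverage criterion
        # (short local hits can reach moderate identity over few columns)
        assert not (
            stats.identity >= 0.3
            and stats.coverage_a >= 0.7
            and stats.coverage_b >= 0.7
        )
        assert stats.coverage_a < 0.5 and stats.coverage_b < 0.5

    def test_related_pair_scores_match_oracle(self):
        rng = random.Random(42)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(aa) for _ in range(60))
        b = list(a)
        for i in rng.sample(range(60), 6):
            b[i] = rng.choice(aa.replace(b[i], ""))
        b = "".join(b)
        stats = align_pair(a, b)
        assert stats.score == pytest.approx(local_align_score(a, b))
        assert stats.identity >= 0.8

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKVL")


def _tiny_set(seqs: dict[str, str]) -> ProteomeSet:
    phages = [PhageRecord("P")]
    proteins = [Protein(f"P|{k}", "P", v) for k, v in seqs.items()]
    return ProteomeSet(proteins, phages)


class TestCandidatePairs:
    def test_identical_sequences_yielded_in_both_modes(self):
        ps = _tiny_set({"x": "MKVLAATTRW" * 3, "y": "MKVLAATTRW" * 3})
        assert list(candidate_pairs(ps, exact=True)) == [("P|x", "P|y")]
        assert list(candidate_pairs(ps, exact=False)) == [("P|x", "P|y")]

    def test_disjoint_kmer_content_filtered_only_in_prefilter_mode(self):
        ps = _tiny_set({"x": "A" * 30, "y": "W" * 30})
        assert list(candidate_pairs(ps, exact=True)) == [("P|x", "P|y")]
        assert list(candidate_pairs(ps, exact=False)) == []

    def test_pairs_unique_and_bounded(self):
        ps = _tiny_set({"x": "MKVLAATTRW", "y": "MKVLAATTRW", "z": "MKVLAATTRW"})
        pairs = list(candidate_pairs(ps, exact=False))
        assert len(pairs) == len(set(pairs)) <= 3


class TestGraphAndComponents:
    def test_duplicate_protein_across_phages_makes_edge(self, toy_proteome_set):
        edges = build_homolog_graph(toy_proteome_set)
        assert ("A|p1", "B|p1") in edges

    def test_prefix_pair_edge_and_coverage_threshold(self):
        # coverage 0.8/1.0 passes at 0.7, fails when min_coverage = 0.9
        ps = _tiny_set({"long": "MKVLAATTRW", "short": "MKVLAATT"})
        assert build_homolog_graph(ps) == {("P|long", "P|short")}
        strict = ClusteringParams(min_coverage=0.9)
        assert build_homolog_graph(ps, strict) == set()

    def test_transitive_closure_single_family(self):
        fams = connected_components([("A", "B"), ("B", "C")], ["A", "B", "C"])
        assert fams.families == {"A": frozenset({"A", "B", "C"})}
        assert [frozenset(f) for f in fams.families.values()] == components_bfs(
            [("A", "B"), ("B", "C")], ["A", "B", "C"]
        )

    def test_no_edges_gives_singletons(self):
        fams = connected_components([], list("ABCD"))
        assert len(fams) == 4
        assert all(len(f) == 1 for f in fams.families.values())

    def test_duplicate_and_symmetric_edges_idempotent(self):
        edges = [("A", "B"), ("B", "A"), ("A", "B")]
        fams = connected_components(edges, ["A", "B", "C"])
        assert fams.family_of == {"A": "A", "B": "A", "C": "C"}

    def test_unknown_edge_endpoint_errors(self):
        with pytest.raises(ValueError):
            connected_components([("A", "Z")], ["A", "B"])

    @pytest.mark.parametrize("seed", [3, 14, 159])
    def test_components_match_bfs_oracle_on_random_graphs(self, seed):
        rng = random.Random(seed)
        nodes = [f"n{i}" for i in range(30)]
        edges = [tuple(sorted(rng.sample(nodes, 2))) for _ in range(25)]
        fams = connected_components(edges, nodes)
        assert sorted(fams.families.values(), key=min) == sorted(
            components_bfs(edges, nodes), key=min
        )


class TestClusterProteins:
    def test_zero_mutation_recovers_planted_families_exactly(self):
        from abikit.synthetic_data import ProteomeSimSpec, gen_proteomes

        spec = ProteomeSimSpec(
            n_clusters=3, phages_per_cluster=1, core_families=1,
            shared_families=0, singleton_fraction=0.0, substitution_rate=0.0,
            length_mean=60, length_sd=5, paralog_prob=0.0, seed=5,
        )
        ps, truth = gen_proteomes(spec)
        fams = cluster_proteins(ps)
        assert len(fams) == 3

    def test_recovers_planted_families_at_10pct_divergence(self, small_planted):
        ps, truth = small_planted
        fams = cluster_proteins(ps)
        planted = {}
        for pid, fam in truth["protein_family"].items():
            planted.setdefault(fam, set()).add(pid)
        recovered = {frozenset(m) for m in fams.families.values()}
        assert recovered == {frozenset(m) for m in planted.values()}

    def test_identity_threshold_one_keeps_only_exact_duplicates(self, small_planted):
        ps, _ = small_planted
        fams = cluster_proteins(ps, ClusteringParams(min_identity=1.0))
        for members in fams.families.values():
            seqs = {ps[pid].sequence for pid in members}
            assert len(seqs) == 1 or all(
                align_pair(ps[a].sequence, ps[b].sequence).identity == 1.0
                for a in members for b in members if a < b
            )

    def test_threshold_monotonicity_refines_partition(self, small_planted):
        ps, _ = small_planted
        loose = cluster_proteins(ps, ClusteringParams(min_identity=0.3))
        tight = cluster_proteins(ps, ClusteringParams(min_identity=0.6))
        # every tight family must sit inside one loose family
        for members in tight.families.values():
            assert len({loose.family_of[p] for p in members}) == 1

    def test_partition_invariant_under_input_order(self, small_planted):
        ps, _ = small_planted
        shuffled = ProteomeSet(list(reversed(ps.proteins)), ps.phages)
        assert cluster_proteins(ps).families == cluster_proteins(shuffled).families


class TestHomologFamiliesContainer:
    def test_partition_validation_catches_missing_protein(self):
        fams = HomologFamilies([{"A", "B"}])
        with pytest.raises(AssertionError):
            fams.validate_partition(["A", "B", "C"])

    def test_tsv_round_trip(self, tmp_path):
        fams = HomologFamilies([{"A", "B"}, {"C"}])
        path = tmp_path / "fams.tsv"
        fams.to_tsv(path)
        again = HomologFamilies.from_tsv(path)
        assert again.families == fams.families
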