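"""Hit admission, taxon assignment collection, counting workflows, consensus."""

import io
from collections import Counter

import numpy as np
import pytest

from pepotu import (
    GeneratorConfig,
    ProfileError,
    SyntheticCommunity,
    TaxonProfile,
    UnknownRankError,
    admit_hits,
    collect_assignments,
    count_all_taxa,
    count_unique_taxa,
    generate_mascot_export,
    generate_peptide_universe,
    group_other,
    map_to_taxa,
    read_mascot_csv,
    replicate_consensus,
    to_relative,
)
from pepotu.mascot import PeptideMatch, ProteinHit, ReplicateRun
from pepotu.profiling import OTHER


def make_run(hits_spec, rep=1):
    """hits_spec: list of (accessions tuple, acc→taxid, [(seq, score, bold)])."""
    hits = []
    for rank, (accs, taxids, peps) in enumerate(hits_spec, start=1):
        hits.append(
            ProteinHit(
                primary_accession=accs[0],
                sameset_accessions=tuple(accs[1:]),
                hit_rank=rank,
                peptides=tuple(PeptideMatch(s, sc, b, rep) for s, sc, b in peps),
                accession_taxids=taxids,
            )
        )
    return ReplicateRun(sample_id="s", replicate_index=rep, hits=tuple(hits))


class TestAdmitHits:
    def test_inclusive_score_threshold(self):
        run = make_run(
            [(("A",), {"A": 7}, [("AK", 5, True), ("CK", 10, True), ("DK", 15, True)])]
        )
        admitted = admit_hits(run, 10)
        assert [p.score for p in admitted.hits[0].peptides] == [10, 15]
        assert admitted.meta["score_dropped"] == 1

    def test_hit_without_surviving_bold_red_removed(self):
        run = make_run(
            [(("A",), {"A": 7}, [("AK", 4, True), ("CK", 30, False)])]
        )
        admitted = admit_hits(run, 10)
        assert admitted.hits == ()
        assert admitted.meta["score_dropped"] == 1
        assert admitted.meta["no_boldred_dropped"] == 1
        assert admitted.meta["retained_rows"] == 0

    def test_threshold_zero_keeps_all_but_boldless_hits(self):
        run = make_run(
            [
                (("A",), {"A": 7}, [("AK", 1, True)]),
                (("B",), {"B": 8}, [("CK", 99, False)]),
            ]
        )
        admitted = admit_hits(run, 0)
        assert len(admitted.hits) == 1 and admitted.hits[0].primary_accession == "A"

    def test_negative_threshold_is_error(self):
        with pytest.raises(ValueError):
            admit_hits(make_run([]), -1)


class TestCollectAssignments:
    def test_union_across_hits(self, gut_tree):
        run = make_run(
            [
                (("S1",), {"S1": 7}, [("AAK", 20, True)]),
                (("S2",), {"S2": 8}, [("AAK", 25, True), ("CCK", 30, True)]),
            ]
        )
        run = admit_hits(run, 10)
        a = {x.sequence: x for x in collect_assignments(run, gut_tree)}
        assert a["AAK"].taxid_set == {7, 8}
        assert a["CCK"].taxid_set == {8}
        assert a["AAK"].rank_sets["genus"] == {4}
        assert a["AAK"].rank_sets["species"] == {7, 8}

    def test_missing_rank_omitted_from_rank_set(self, gut_tree):
        # genus-level protein: its lineage has no species entry
        run = make_run([(("G",), {"G": 4}, [("AAK", 20, True)])])
        a = collect_assignments(admit_hits(run, 10), gut_tree)[0]
        assert a.rank_sets["species"] == frozenset()
        assert a.rank_sets["genus"] == {4}

    def test_fully_unmapped_peptides_dropped_and_counted(self, gut_tree):
        run = make_run(
            [
                (("X",), {}, [("AAK", 20, True)]),
                (("S1",), {"S1": 7}, [("CCK", 20, True)]),
            ]
        )
        run = admit_hits(run, 10)
        a = collect_assignments(run, gut_tree)
        assert [x.sequence for x in a] == ["CCK"]
        assert run.meta["unmapped_dropped"] == 1
        assert run.meta["retained_final"] == 1

    def test_matches_exhaustive_enumeration(self, gut_tree):
        """taxid_set equals a brute-force scan over (hit, accession, peptide)."""
        rng = np.random.default_rng(7)
        accs = {"LM1": 7, "LJ1": 8, "EF1": 9, "EC1": 10}
        names = list(accs)
        hits_spec = []
        seqs = [f"{'ACDEFG'[i % 6] * 5}K" for i in range(10)]
        for _ in range(8):
            k = int(rng.integers(1, 4))
            chosen = [names[int(i)] for i in rng.choice(len(names), size=k, replace=False)]
            peps = [
                (seqs[int(i)], 20.0, True)
                for i in rng.choice(len(seqs), size=int(rng.integers(1, 5)), replace=False)
            ]
            hits_spec.append((tuple(chosen), {a: accs[a] for a in chosen}, peps))
        run = admit_hits(make_run(hits_spec), 10)
        got = {a.sequence: a.taxid_set for a in collect_assignments(run, gut_tree)}
        expected = {}
        for hit in run.hits:
            for pep in hit.peptides:
                for acc in hit.accessions:
                    expected.setdefault(pep.sequence, set()).add(accs[acc])
        assert got == expected


def simple_assignments(gut_tree, spec):
    """spec: list of (seq, set of species taxids) → assignments via one hit each."""
    hits = []
    for i, (seq, taxa) in enumerate(spec):
        accs = tuple(f"H{i}A{t}" for t in sorted(taxa))
        hits.append((accs, {a: t for a, t in zip(accs, sorted(taxa))}, [(seq, 20.0, True)]))
    return collect_assignments(admit_hits(make_run(hits), 10), gut_tree)


class TestCountingWorkflows:
    def test_all_counts_every_matching_taxon(self, gut_tree):
        a = simple_assignments(gut_tree, [("AAK", {7, 8})])  # two species, one genus
        species = count_all_taxa(a, "species")
        assert species.counts == {7: 1, 8: 1}
        assert count_all_taxa(a, "genus").counts == {4: 1}

    def test_all_three_unique_peptides(self, gut_tree):
        a = simple_assignments(gut_tree, [("AAK", {7}), ("CCK", {7}), ("DDK", {7})])
        assert count_all_taxa(a, "species").counts == {7: 3}

    def test_unique_ignores_ambiguous_peptides(self, gut_tree):
        a = simple_assignments(gut_tree, [("AAK", {7, 8}), ("CCK", {7})])
        assert count_unique_taxa(a, "species").counts == {7: 1}
        # both species share the genus → the ambiguous peptide is genus-unique
        assert count_unique_taxa(a, "genus").counts == {4: 2}

    def test_unknown_rank_is_error(self, gut_tree):
        a = simple_assignments(gut_tree, [("AAK", {7})])
        with pytest.raises(UnknownRankError):
            count_all_taxa(a, "kingdom")
        with pytest.raises(UnknownRankError):
            count_unique_taxa(a, "kingdom")

    def test_matches_incidence_matrix_oracle(self, gut_tree):
        """All-matches counting equals a peptide×taxon incidence-matrix sum."""
        rng = np.random.default_rng(11)
        species = [7, 8, 9, 10]
        spec = []
        for i in range(30):
            k = int(rng.integers(1, 5))
            taxa = {species[int(j)] for j in rng.choice(4, size=k, replace=False)}
            spec.append((f"P{i:03d}K", taxa))
        a = simple_assignments(gut_tree, spec)
        for rank in ("species", "genus", "phylum"):
            profile = count_all_taxa(a, rank)
            oracle = Counter()
            for _, taxa in spec:
                projected = {gut_tree.ancestor_at_rank(t, rank) for t in taxa}
                for p in projected - {None}:
                    oracle[p] += 1
            assert profile.counts == dict(oracle)
            # unique-count oracle: singleton projections only
            b_oracle = Counter()
            for _, taxa in spec:
                projected = {gut_tree.ancestor_at_rank(t, rank) for t in taxa} - {None}
                if len(projected) == 1:
                    b_oracle[next(iter(projected))] += 1
            assert count_unique_taxa(a, rank).counts == dict(b_oracle)

    def test_unique_dominated_by_all_on_random_instances(self, gut_tree):
        rng = np.random.default_rng(5)
        species = [7, 8, 9, 10]
        for _ in range(25):
            spec = [
                (
                    f"Q{i}K",
                    {species[int(j)] for j in rng.choice(4, size=int(rng.integers(1, 5)), replace=False)},
                )
                for i in range(20)
            ]
            a = simple_assignments(gut_tree, spec)
            for rank in ("species", "genus", "phylum"):
                all_p = count_all_taxa(a, rank)
                uniq_p = count_unique_taxa(a, rank)
                for taxon in all_p.taxa() | uniq_p.taxa():
                    assert uniq_p.get(taxon) <= all_p.get(taxon)

    def test_occurrence_mode_counts_per_hit(self, gut_tree):
        # same sequence in two hits, both mapped to the same species
        run = make_run(
            [
                (("A1",), {"A1": 7}, [("AAK", 20, True)]),
                (("A2",), {"A2": 7}, [("AAK", 25, True)]),
            ]
        )
        a = collect_assignments(admit_hits(run, 10), gut_tree)
        assert count_all_taxa(a, "species").counts == {7: 1}
        assert count_all_taxa(a, "species", counting_mode="occurrence").counts == {7: 2}
        assert count_unique_taxa(a, "species", counting_mode="occurrence").counts == {7: 2}

    def test_zero_homology_makes_workflows_identical(self):
        cfg = GeneratorConfig(
            depth=400, proteins_per_species=20, peptides_per_protein=10,
            homology=0.0, dropout=0.0,
        )
        com = SyntheticCommunity.random(cfg, 3)
        uni = generate_peptide_universe(com)
        text = generate_mascot_export(com, uni, cfg, 1)
        run = map_to_taxa(read_mascot_csv(io.StringIO(text), "s", 1), uni.accession_taxid)
        a = collect_assignments(admit_hits(run, 10), com.tree)
        for rank in ("species", "genus", "phylum"):
            assert count_all_taxa(a, rank).counts == count_unique_taxa(a, rank).counts


def profile(counts, rank="genus", tag="all", sample="s"):
    return TaxonProfile(rank, counts, tag, sample)


class TestReplicateConsensus:
    def test_single_replicate_presence_removed(self):
        out = replicate_consensus([profile({4: 3}), profile({}), profile({})])
        assert out.counts == {}

    def test_stable_taxon_retained_with_mean(self):
        out = replicate_consensus([profile({4: 3}), profile({4: 3}), profile({4: 3})])
        assert out.counts == {4: 3.0}

    def test_mean_below_one_removed_divide_by_R(self):
        out = replicate_consensus([profile({4: 1}), profile({4: 1}), profile({})])
        assert out.counts == {}

    def test_nonzero_averaging_variant(self):
        out = replicate_consensus(
            [profile({4: 1}), profile({4: 1}), profile({})], average="nonzero"
        )
        assert out.counts == {4: 1.0}

    def test_mismatched_rank_or_tag_is_error(self):
        with pytest.raises(ProfileError):
            replicate_consensus([profile({4: 3}), profile({4: 3}, rank="species")])
        with pytest.raises(ProfileError):
            replicate_consensus([profile({4: 3}), profile({4: 3}, tag="unique")])

    def test_fewer_than_two_replicates_is_error(self):
        with pytest.raises(ProfileError):
            replicate_consensus([profile({4: 3})])


class TestRelativeAndOther:
    def test_to_relative(self):
        out = to_relative(profile({4: 3, 5: 1}))
        assert out.counts == {4: 0.75, 5: 0.25}

    def test_single_taxon_identity(self):
        assert to_relative(profile({4: 7})).counts == {4: 1.0}

    def test_empty_profile_is_error(self):
        with pytest.raises(ProfileError):
            to_relative(profile({}))

    def test_group_other_zero_fraction_is_identity(self):
        p = profile({4: 0.98, 5: 0.01, 6: 0.01})
        assert group_other(p, 0.0).counts == p.counts

    def test_group_other_merges_small_taxa(self):
        out = group_other(profile({4: 0.98, 5: 0.01, 6: 0.01}), 0.02)
        assert out.counts == {4: 0.98, OTHER: pytest.approx(0.02)}

    def test_group_other_conserves_total(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            counts = {i: float(c) for i, c in enumerate(rng.random(12) * 10)}
            p = profile(counts)
            out = group_other(p, float(rng.random() * 0.5))
            assert out.total() == pytest.approx(p.total(), abs=1e-12)

    def test_bad_fraction_is_error(self):
        with pytest.raises(ValueError):
            group_other(profile({4: 1}), 1.0)
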