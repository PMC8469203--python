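"""Per-clade primer design and the recursive tree-descent driver."""

import numpy as np
import pytest

from butqpcr import design, phylo, synthetic
from butqpcr.design import DesignConstraints
from butqpcr.insilico import predict_amplicons
from butqpcr.seqcore import DegenerateSeq, SequenceRecord, matches


def recs(*seqs):
    return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]


class TestWindowConsensus:
    def test_identical_members_give_concrete_window(self):
        msa = recs("ACGTACGT", "ACGTACGT", "ACGTACGT")
        w = design.window_consensus(msa, 0, 8)
        assert str(w) == "ACGTACGT" and w.degeneracy == 1

    def test_polymorphic_column_becomes_ambiguity_code(self):
        msa = recs("AAAA", "ACAA")
        assert str(design.window_consensus(msa, 0, 4)) == "AMAA"

    def test_gap_in_window_fails(self):
        msa = recs("AC-T", "ACTT")
        assert design.window_consensus(msa, 0, 4) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            design.window_consensus(recs("ACGT"), 2, 4)


class TestTmGc:
    @pytest.mark.parametrize(
        "p,lo,hi",
        [("ACGT", 12, 12), ("RT", 4, 6), ("GGGG", 16, 16)],
    )
    def test_wallace_range(self, p, lo, hi):
        assert design.primer_tm_range(DegenerateSeq(p)) == (lo, hi)

    def test_range_matches_expansion_extremes(self, rng):
        from conftest import random_degenerate

        for _ in range(20):
            p = random_degenerate(rng, 4, 10, max_logdeg=8)
            tms = [
                2 * sum(b in "AT" for b in v) + 4 * sum(b in "GC" for b in v)
                for v in p.expand()
            ]
            assert design.primer_tm_range(p) == (min(tms), max(tms))


def _relaxed(**kw):
    base = dict(
        primer_len=(18, 23),
        max_primer_degeneracy=256,
        max_pair_degeneracy=2048,
        product_len=(400, 800),
        tm_range=(0.0, 200.0),
        max_pair_delta_tm=200.0,
        gc_range=(0.0, 1.0),
        three_prime_clamp=0,
        min_coverage=1.0,
    )
    base.update(kw)
    return DesignConstraints(**base)


class TestScanCandidates:
    def test_identical_members_every_window_returned(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        msa = recs(seq, seq, seq)
        cands = design.scan_candidates(msa, _relaxed(), "F")
        n_expected = sum(100 - L + 1 for L in range(18, 24))
        assert len(cands) == n_expected

    def test_degeneracy_cap_excludes_polymorphic_windows(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        other = seq[:30] + ("A" if seq[30] != "A" else "C") + seq[31:]
        msa = recs(seq, other)
        cands = design.scan_candidates(
            msa, _relaxed(max_primer_degeneracy=1), "F"
        )
        assert all(c.end <= 30 or c.start > 30 for c in cands)

    def test_single_conserved_island_yields_only_island_windows(self, rng):
        # two sequences, random and unrelated except a shared 30-mer island
        island = "".join(rng.choice(list("ACGT"), size=30))
        a = "".join(rng.choice(list("ACGT"), size=40)) + island + "".join(
            rng.choice(list("ACGT"), size=40)
        )
        b = "".join(rng.choice(list("ACGT"), size=40)) + island + "".join(
            rng.choice(list("ACGT"), size=40)
        )
        msa = recs(a, b)
        cands = design.scan_candidates(
            msa, _relaxed(max_primer_degeneracy=4), "F"
        )
        # brute-force oracle: windows with <= 2 polymorphic columns
        for c in cands:
            assert matches(c.primer, a[c.start : c.end], 2)[0]
        island_cands = [c for c in cands if 40 <= c.start and c.end <= 70]
        assert island_cands, "conserved island must yield candidates"

    def test_reverse_orientation_is_revcomp_with_clamp(self):
        msa = recs("A" * 10 + "ACGTTGCAACGTTGCAACG" + "C" * 10)
        cands = design.scan_candidates(
            msa, _relaxed(three_prime_clamp=2, primer_len=(19, 19)), "R"
        )
        for c in cands:
            window = msa[0].seq[c.start : c.end]
            assert c.primer == DegenerateSeq(window).revcomp()


class TestDesignForCluster:
    def test_single_sequence_succeeds_with_concrete_pair(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=800))
        res = design.design_for_cluster(recs(seq), _relaxed())
        assert res.success
        assert res.pair.pair_degeneracy == 1
        assert 400 <= res.pair.expected_len <= 800
        # the designed pair must amplify its own template at the stated length
        hits = predict_amplicons(res.pair, SequenceRecord("t", seq))
        assert any(h.product_len == res.pair.expected_len for h in hits)

    def test_unrelated_sequences_fail_with_diagnostics(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=600))
        b = "".join(rng.choice(list("ACGT"), size=600))
        res = design.design_for_cluster(recs(a, b), DesignConstraints())
        assert not res.success
        assert res.pair is None
        # essentially every window is killed by the degeneracy cap
        assert res.diagnostics["degeneracy"] > 1000
        assert res.diagnostics["n_fwd_candidates"] <= 3

    def test_infeasible_product_range_fails(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        res = design.design_for_cluster(
            recs(seq), _relaxed(product_len=(10, 20))
        )
        assert not res.success

    def test_deterministic_output(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=700))
        msa = recs(seq, seq)
        r1 = design.design_for_cluster(msa, DesignConstraints())
        r2 = design.design_for_cluster(msa, DesignConstraints())
        assert r1.pair == r2.pair


class TestRecursiveDesign:
    def test_identical_leaves_one_cluster_at_root(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=800))
        msa = [SequenceRecord(n, seq) for n in "ABCD"]
        tree = phylo.parse_newick("((A,B),(C,D));")
        out = design.recursive_design(tree, msa)
        assert len(out.results) == 1
        assert out.results[0].members == frozenset("ABCD")
        assert out.attempts == 1

    def test_two_divergent_families_two_clusters(self, two_clade_family):
        spec, records, tree, islands = two_clade_family
        out = design.recursive_design(tree, records)
        assert sorted(map(sorted, out.clusters)) == [
            ["c0_l0", "c0_l1", "c0_l2"],
            ["c1_l0", "c1_l1", "c1_l2"],
        ]
        assert out.undesignable == []
        # oracle: a design attempt over the whole family must fail
        root_res = design.design_for_cluster(records, design.DesignConstraints())
        assert not root_res.success

    def test_emitted_clades_partition_leaves(self, two_clade_family):
        spec, records, tree, islands = two_clade_family
        out = design.recursive_design(tree, records)
        emitted = [m for r in out.results for m in r.members]
        assert sorted(emitted + out.undesignable) == sorted(tree.leaf_names())
        assert len(emitted) == len(set(emitted))

    def test_every_pair_matches_all_members_at_binding_site(self, two_clade_family):
        spec, records, tree, islands = two_clade_family
        out = design.recursive_design(tree, records)
        by_id = {r.id: r for r in records}
        for r in out.results:
            for m in r.members:
                hits = predict_amplicons(r.pair, by_id[m], max_mismatch=0)
                assert hits, f"pair {r.pair.cluster} misses member {m}"

    def test_leaf_mismatch_rejected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        tree = phylo.parse_newick("(A,B);")
        with pytest.raises(ValueError, match="differ"):
            design.recursive_design(tree, [SequenceRecord("A", seq)])

    def test_relaxing_degeneracy_never_increases_cluster_count(self):
        spec = synthetic.clade_family_spec(2, seed=5, within_prob=0.08)
        records, tree, _ = synthetic.simulate_family(spec)
        counts = []
        for cap in (4, 64, 1024):
            out = design.recursive_design(
                tree, records, DesignConstraints(max_primer_degeneracy=cap)
            )
            counts.append(len(out.results) + len(out.undesignable))
        assert counts == sorted(counts, reverse=True)


def test_packaged_panel_passes_primer_level_screen(primer_panel):
    """Self-consistency: default constraints admit every packaged primer."""
    cns = DesignConstraints()
    for e in primer_panel:
        for primer in (e.fwd, e.rev):
            assert cns.primer_len[0] <= len(primer) <= cns.primer_len[1]
            assert primer.degeneracy <= cns.max_primer_degeneracy
            lo, hi = design.primer_tm_range(primer)
            assert cns.tm_range[0] <= lo and hi <= cns.tm_range[1]
            assert (
                cns.gc_range[0]
                <= design.primer_gc_mean(primer)
                <= cns.gc_range[1]
            )
            # concrete 3' terminus on every panel primer
            clamp = primer.seq[-cns.three_prime_clamp :]
            assert DegenerateSeq(clamp).degeneracy == 1
        assert e.pair_degeneracy <= cns.max_pair_degeneracy
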