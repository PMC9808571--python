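"""Cleavage-site rules: seed g2-g7, >=10 pairs in g8-g21, responder at t1-9."""

import numpy as np
import pytest

from pirnaflow.io_formats import PrecursorTranscript
from pirnaflow.target_prediction import (
    CleavageSite,
    PiRNA,
    SiteParams,
    find_sites,
    pair_profile,
    predict_network,
    verify_responder,
)

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_profile(guide: str, target: str, t1: int, wobble: bool = False):
    """Literal position-by-position application of the pairing criteria."""

    def paired(i):
        g, t = guide[i - 1], target[t1 - (i - 1) - 1]
        if t == COMP[g]:
            return True
        return wobble and i >= 8 and {g, t} == {"G", "U"}

    seed = all(paired(i) for i in range(2, 8))
    pairs = sum(paired(i) for i in range(8, 22))
    return seed, pairs


def brute_sites(guide: str, target: str, min_pairs: int = 10, wobble: bool = False):
    out = []
    for t1 in range(21, len(target) + 1):
        seed, pairs = brute_profile(guide, target, t1, wobble)
        if seed and pairs >= min_pairs:
            out.append((t1, pairs))
    return out


def perfect_target(guide: str, t1: int, total_len: int, rng) -> str:
    """Random target carrying the reverse complement of guide g1-g21 at t1."""
    bases = list(rng.choice(list("ACGU"), size=total_len))
    for i in range(1, 22):
        bases[t1 - (i - 1) - 1] = COMP[guide[i - 1]]
    return "".join(bases)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestPairProfile:
    def test_perfect_complement(self, rng):
        guide = rand_seq(rng, 28)
        target = perfect_target(guide, 40, 60, rng)
        assert pair_profile(guide, target, 40) == (True, 14)

    def test_single_seed_mismatch_breaks_seed(self, rng):
        guide = rand_seq(rng, 28)
        target = list(perfect_target(guide, 40, 60, rng))
        pos = 40 - (5 - 1)  # position opposite g5
        target[pos - 1] = guide[4]  # same base as the guide: never pairs
        assert pair_profile(guide, "".join(target), 40) == (False, 14)

    def test_five_mismatches_in_8_21_count_nine_pairs(self, rng):
        guide = rand_seq(rng, 28)
        target = list(perfect_target(guide, 40, 60, rng))
        for i in (9, 12, 15, 18, 21):
            pos = 40 - (i - 1)
            target[pos - 1] = guide[i - 1]
        assert pair_profile(guide, "".join(target), 40) == (True, 9)

    def test_out_of_range_anchor_raises(self, rng):
        guide = rand_seq(rng, 26)
        with pytest.raises(ValueError):
            pair_profile(guide, rand_seq(rng, 50), 20)
        with pytest.raises(ValueError):
            pair_profile(guide, rand_seq(rng, 50), 51)

    def test_wobble_counts_in_8_21_but_never_in_seed(self, rng):
        guide = "A" * 7 + "G" * 14 + "AAAAA"  # g2-g7 = A, g8-g21 = G
        target = list(perfect_target(guide, 40, 60, rng))
        for i in range(8, 22):  # replace every C opposite g8-g21 with U (G:U)
            target[40 - (i - 1) - 1] = "U"
        t = "".join(target)
        assert pair_profile(guide, t, 40, allow_wobble=False) == (True, 0)
        assert pair_profile(guide, t, 40, allow_wobble=True) == (True, 14)
        # a G:U opposite a seed G is still a seed mismatch
        guide2 = "AGGGGGG" + "A" * 14 + "AAAAA"
        target2 = list(perfect_target(guide2, 40, 60, rng))
        target2[40 - 1 - 1] = "U"  # opposite g2 (G): U instead of C
        assert pair_profile(guide2, "".join(target2), 40, allow_wobble=True)[0] is False


class TestFindSites:
    def test_embedded_perfect_site_coordinates(self, rng):
        guide = rand_seq(rng, 30)
        target = PrecursorTranscript("t", perfect_target(guide, 31, 60, rng))
        pirna = PiRNA(guide, "src")
        sites = find_sites(pirna, target)
        brute = brute_sites(guide, target.sequence)
        assert [(s.t1, s.pairs_8_21) for s in sites] == brute
        perfect = [s for s in sites if s.t1 == 31]
        assert len(perfect) == 1
        (site,) = perfect
        assert site.responder_5p == 22
        assert site.cleavage_bond == (21, 22)

    def test_nine_pair_decoy_rejected(self, rng):
        guide = rand_seq(rng, 27)
        target = list(perfect_target(guide, 35, 70, rng))
        for i in (8, 10, 13, 16, 20):
            target[35 - (i - 1) - 1] = guide[i - 1]
        t = PrecursorTranscript("t", "".join(target))
        assert all(s.t1 != 35 for s in find_sites(PiRNA(guide, "src"), t))

    def test_short_guide_skipped_with_warning(self, rng, caplog):
        t = PrecursorTranscript("t", rand_seq(rng, 50))
        with caplog.at_level("WARNING"):
            assert find_sites(PiRNA(rand_seq(rng, 20), "src"), t) == []
        assert "skipped" in caplog.text

    @pytest.mark.parametrize("wobble", [False, True])
    def test_agrees_with_brute_force_oracle(self, wobble):
        rng = np.random.default_rng(7)
        for _ in range(200):
            guide = rand_seq(rng, int(rng.integers(21, 31)))
            tlen = int(rng.integers(21, 101))
            target = list(rng.choice(list("ACGU"), size=tlen))
            if rng.random() < 0.5 and tlen >= 40:  # embed a near-perfect site
                t1 = int(rng.integers(21, tlen + 1))
                for i in range(2, 22):
                    if rng.random() < 0.85:
                        target[t1 - (i - 1) - 1] = COMP[guide[i - 1]]
            tseq = "".join(target)
            params = SiteParams(min_pairs=10, allow_wobble=wobble)
            got = [
                (s.t1, s.pairs_8_21)
                for s in find_sites(PiRNA(guide, "g"), PrecursorTranscript("t", tseq), params)
            ]
            assert got == brute_sites(guide, tseq, 10, wobble)

    def test_lowering_min_pairs_never_removes_sites(self, rng):
        guide = rand_seq(rng, 28)
        target = PrecursorTranscript("t", perfect_target(guide, 50, 90, rng))
        pirna = PiRNA(guide, "src")
        prev: set = set()
        for min_pairs in range(14, -1, -1):
            cur = {s.t1 for s in find_sites(pirna, target, SiteParams(min_pairs))}
            assert prev <= cur
            prev = cur

    def test_ten_nt_overlap_signature(self, rng):
        # guide g1-g10 must occupy target positions responder_5p..responder_5p+9
        guide = rand_seq(rng, 26)
        target = PrecursorTranscript("t", perfect_target(guide, 45, 80, rng))
        for s in find_sites(PiRNA(guide, "src"), target):
            positions = [s.t1 - (i - 1) for i in range(1, 11)]
            assert sorted(positions) == list(
                range(s.responder_5p, s.responder_5p + 10)
            )


class TestVerifyResponder:
    def make_site(self, t1=31):
        return CleavageSite("A" * 21, "src", "t", "tgt", t1, True, 14)

    def test_exact_match_verifies(self):
        site = verify_responder(self.make_site(), {"tgt": {22}})
        assert site.verified

    def test_off_by_one_does_not_verify(self):
        assert not verify_responder(self.make_site(), {"tgt": {23}}).verified

    def test_empty_observed_set(self):
        assert not verify_responder(self.make_site(), {}).verified


class TestPredictNetwork:
    def test_aggregation_two_guides_one_edge(self, rng):
        g1 = rand_seq(rng, 26)
        g2 = rand_seq(rng, 26)
        # one target carrying a perfect site for each guide
        bases = list(perfect_target(g1, 40, 120, rng))
        for i in range(1, 22):
            bases[90 - (i - 1) - 1] = COMP[g2[i - 1]]
        target = PrecursorTranscript("t", "".join(bases), source_gene="tgt")
        guides = [PiRNA(g1, "src"), PiRNA(g2, "src")]
        ends = {"tgt": {31, 81}}
        edges, summary = predict_network(guides, [target], ends)
        assert len(edges) == 1
        assert edges[0].n_guides == 2
        assert summary["n_source_genes"] == 1 and summary["n_target_genes"] == 1

    def test_no_verified_sites_gives_empty_summary(self, rng):
        target = PrecursorTranscript("t", rand_seq(rng, 60), source_gene="tgt")
        edges, summary = predict_network(
            [PiRNA(rand_seq(rng, 26), "src")], [target], {"tgt": set()}
        )
        assert edges == []
        assert summary["n_distinct_guides"] == 0
        assert summary["n_edges"] == 0

    def test_gene_in_both_classes_excluded(self, rng, caplog):
        g = rand_seq(rng, 26)
        target = PrecursorTranscript("t", perfect_target(g, 40, 80, rng), source_gene="dup")
        with caplog.at_level("WARNING"):
            edges, _ = predict_network([PiRNA(g, "dup")], [target], {"dup": {31}})
        assert edges == []
        assert "both" in caplog.text

    def test_duplicate_guide_species_counts_summed(self, rng):
        g = rand_seq(rng, 26)
        target = PrecursorTranscript("t", perfect_target(g, 40, 80, rng), source_gene="tgt")
        guides = [
            PiRNA(g, "src", {"WT": 3}),
            PiRNA(g, "src", {"WT": 4}),
        ]
        edges, summary = predict_network(guides, [target], {"tgt": {31}})
        assert summary["n_distinct_guides"] == 1
        assert len(edges) == 1 and edges[0].n_guides == 1
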