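"""Pocket construction, matching / feature-relevance statistics, PSSM parsing."""

import numpy as np
import pytest

from xdta.explain_eval import (AnnotatedSites, PSSMProfile, build_pockets,
                               feature_relevance,
                               filter_motifs_outside_binding_region, matching,
                               parse_pssm, pssm_motif_positions, write_pssm)
from xdta.gradram import LocalizationMap


def sites(positions, pid="p", kind="binding"):
    return AnnotatedSites(pair_id=pid, positions=tuple(positions), kind=kind)


def loc(values):
    return LocalizationMap(values=np.asarray(values, dtype=float),
                           branch="protein", variant="GMP-G")


def brute_force_matching(maps, pockets_per_pair):
    """Literal weighted-average evaluation of the matching formula."""
    B = [len(ps.pockets) for ps in pockets_per_pair]
    total = sum(B)
    acc = 0.0
    for loc_, ps, b in zip(maps, pockets_per_pair, B):
        hits = sum(1 for (_, lo, hi) in ps.pockets
                   if any(v > 0 for v in loc_.values[lo - 1:hi]))
        acc += (b / total) * (hits / b)
    return 100.0 * acc


def brute_force_relevance(maps, pockets_per_pair, lam):
    """Literal weighted-average evaluation of the feature-relevance formula."""
    per_pair = []
    for loc_, ps in zip(maps, pockets_per_pair):
        pos = sorted([v for v in loc_.values if v > 0], reverse=True)
        k = int(np.floor(lam * len(pos)))
        thresh = pos[k - 1] if k >= 1 else None
        pocket_vals = [v for (_, lo, hi) in ps.pockets
                       for v in loc_.values[lo - 1:hi] if v > 0]
        n_in = sum(1 for v in pocket_vals if thresh is not None and v >= thresh)
        per_pair.append((len(pocket_vals), n_in))
    total = sum(f for f, _ in per_pair)
    if total == 0:
        return 0.0
    return 100.0 * sum((f / total) * (n / f) for f, n in per_pair if f > 0)


class TestBuildPockets:
    def test_window_zero_is_exact_site(self):
        ps = build_pockets(sites([4, 9]), 0, 12)
        assert ps.pockets == ((4, 4, 4), (9, 9, 9))

    def test_single_site_closed_window(self):
        ps = build_pockets(sites([10]), 2, 20)
        assert ps.pockets == ((10, 8, 12),)

    def test_midpoint_truncation_between_neighbors(self):
        ps = build_pockets(sites([10, 14]), 5, 20)
        assert ps.pockets == ((10, 5, 12), (14, 13, 19))

    def test_clipping_at_sequence_bounds(self):
        ps = build_pockets(sites([2, 19]), 4, 20)
        assert ps.pockets[0][1] == 1 and ps.pockets[1][2] == 20

    def test_pockets_disjoint_and_exclude_other_sites(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            seq_len = int(rng.integers(10, 40))
            n = int(rng.integers(1, 6))
            pos = sorted(rng.choice(seq_len, size=min(n, seq_len), replace=False) + 1)
            ps = build_pockets(sites(pos), int(rng.integers(0, 6)), seq_len)
            spans = [(lo, hi) for (_, lo, hi) in ps.pockets]
            for (p, lo, hi) in ps.pockets:
                assert lo <= p <= hi
                assert not any(lo <= q <= hi for q in pos if q != p)
            for a, b in zip(spans, spans[1:]):
                assert a[1] < b[0]

    def test_strict_open_variant(self):
        assert build_pockets(sites([5]), 0, 10, strict_open=True).pockets == ()
        ps = build_pockets(sites([5]), 2, 10, strict_open=True)
        assert ps.pockets == ((5, 4, 6),)

    def test_site_beyond_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_pockets(sites([25]), 1, 20)


class TestMatching:
    def test_everywhere_positive_is_100(self):
        maps = [loc(np.ones(10)), loc(np.ones(10))]
        pockets = [build_pockets(sites([3]), 1, 10), build_pockets(sites([5, 8]), 0, 10)]
        assert matching(maps, pockets) == 100.0

    def test_all_zero_maps_is_0(self):
        maps = [loc(np.zeros(10))]
        assert matching(maps, [build_pockets(sites([3]), 1, 10)]) == 0.0

    def test_weighted_average_by_hand(self):
        # pair 1: B=2 pockets, 1 hit; pair 2: B=3 pockets, 2 hits -> 3/5
        m1 = loc([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])   # hit at site 1 only
        m2 = loc([1, 0, 0, 1, 0, 0, 0, 0, 0, 0])   # hits at sites 1 and 4
        p1 = build_pockets(sites([1, 6]), 0, 10)
        p2 = build_pockets(sites([1, 4, 8]), 0, 10)
        assert matching([m1, m2], [p1, p2]) == pytest.approx(60.0)

    def test_pair_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matching([loc([1])], [])


class TestFeatureRelevance:
    def test_lambda_one_counts_all_positive_pocket_values(self):
        maps = [loc([5, 4, 3, 2, 1, 0])]
        pockets = [build_pockets(sites([2]), 1, 6)]
        assert feature_relevance(maps, pockets, 1.0) == 100.0

    def test_pocket_exactly_top_set(self):
        values = [10, 9, 1, 2, 3, 4, 5, 6, 7, 8]
        maps = [loc(values)]
        pockets = [build_pockets(sites([1, 2]), 0, 10)]
        # lam=0.2 -> top-2 = {10, 9} = the pocket values
        assert feature_relevance(maps, pockets, 0.2) == 100.0

    def test_rank_by_hand(self):
        maps = [loc([5, 4, 3, 2, 1])]
        pockets = [build_pockets(sites([1, 5]), 0, 5)]  # pocket values {5, 1}
        # lam=0.4 -> top-2 = {5, 4}; of pocket values only 5 qualifies
        assert feature_relevance(maps, pockets, 0.4) == pytest.approx(50.0)

    def test_boundary_ties_included(self):
        maps = [loc([5, 4, 4, 3, 0])]
        pockets = [build_pockets(sites([2, 3]), 0, 5)]  # pocket values {4, 4}
        # lam=0.5, n_pos=4 -> k=2 -> threshold value 4; both tied 4s qualify
        assert feature_relevance(maps, pockets, 0.5) == pytest.approx(100.0)

    def test_no_positive_pocket_values_warns_and_returns_zero(self):
        maps = [loc([1, 0, 0, 0, 0])]
        pockets = [build_pockets(sites([4]), 0, 5)]
        with pytest.warns(UserWarning):
            assert feature_relevance(maps, pockets, 0.5) == 0.0

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            feature_relevance([], [], 0.0)


class TestStatisticsProperties:
    def random_instance(self, rng, n_pairs=10):
        maps, site_sets, lens = [], [], []
        for p in range(n_pairs):
            length = int(rng.integers(8, 31))
            values = np.maximum(rng.normal(0.2, 1.0, size=length), 0.0)
            maps.append(loc(values))
            n_sites = int(rng.integers(1, 5))
            pos = sorted(rng.choice(length, size=min(n_sites, length),
                                    replace=False) + 1)
            site_sets.append(sites(pos, pid=f"p{p}"))
            lens.append(length)
        return maps, site_sets, lens

    @pytest.mark.parametrize("seed", range(10))
    def test_matching_and_relevance_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        maps, site_sets, lens = self.random_instance(rng)
        s_w = int(rng.integers(0, 6))
        pockets = [build_pockets(s, s_w, L) for s, L in zip(site_sets, lens)]
        assert matching(maps, pockets) == pytest.approx(
            brute_force_matching(maps, pockets))
        for lam in (0.1, 0.4, 0.7, 1.0):
            assert feature_relevance(maps, pockets, lam) == pytest.approx(
                brute_force_relevance(maps, pockets, lam))

    @pytest.mark.parametrize("seed", range(5))
    def test_matching_nondecreasing_in_window(self, seed):
        rng = np.random.default_rng(100 + seed)
        maps, site_sets, lens = self.random_instance(rng)
        values = [matching(maps, [build_pockets(s, w, L)
                                  for s, L in zip(site_sets, lens)])
                  for w in range(6)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_relevance_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(7)
        maps, site_sets, lens = self.random_instance(rng, n_pairs=5)
        pockets = [build_pockets(s, 2, L) for s, L in zip(site_sets, lens)]
        base = feature_relevance(maps, pockets, 0.3)
        scaled = [loc(m.values * 7.5) for m in maps]
        assert feature_relevance(scaled, pockets, 0.3) == pytest.approx(base)
        assert matching(scaled, pockets) == pytest.approx(matching(maps, pockets))


class TestPSSM:
    def profile(self):
        rng = np.random.default_rng(0)
        seq = "ACDEFG"
        scores = rng.integers(-4, 5, size=(6, 20)).astype(float)
        return PSSMProfile(scores=scores, consensus=seq)

    def test_write_parse_roundtrip(self, tmp_path):
        prof = self.profile()
        write_pssm(tmp_path / "toy.pssm", prof)
        back = parse_pssm(tmp_path / "toy.pssm")
        assert back.consensus == prof.consensus
        np.testing.assert_array_equal(back.scores, prof.scores)

    def test_parse_errors_carry_line_numbers(self, tmp_path):
        path = tmp_path / "bad.pssm"
        path.write_text("title\n" + " " * 10 + "  ".join("ARNDCQEGHILKMFPSTWYV") + "\n"
                        "    1 A " + " ".join(["1"] * 19) + "\n")
        with pytest.raises(ValueError, match="bad.pssm:3"):
            parse_pssm(path)

    def test_threshold_selection_by_hand(self):
        # own-residue scores per position: 3, 5, 7, 9, 2, 10
        seq = "AAAAAA"
        scores = np.full((6, 20), -5.0)
        scores[:, 0] = [3, 5, 7, 9, 2, 10]  # column A
        prof = PSSMProfile(scores=scores, consensus=seq)
        assert pssm_motif_positions(prof, 7).positions == (3, 4, 6)
        assert pssm_motif_positions(prof, 11).positions == ()
        assert pssm_motif_positions(prof, float("-inf")).positions == tuple(range(1, 7))

    def test_sequence_length_mismatch(self):
        with pytest.raises(ValueError):
            pssm_motif_positions(self.profile(), 5, sequence="ACD")


class TestMotifFiltering:
    def test_inside_span_removed(self):
        out = filter_motifs_outside_binding_region(
            sites([12, 15], kind="motif"), sites([10, 20]))
        assert out.positions == ()

    def test_strictly_outside_kept(self):
        out = filter_motifs_outside_binding_region(
            sites([5, 15, 25], kind="motif"), sites([10, 20]))
        assert out.positions == (5, 25)

    def test_empty_motifs(self):
        out = filter_motifs_outside_binding_region(sites([], kind="motif"),
                                                   sites([3]))
        assert out.positions == ()

    def test_empty_binding_rejected(self):
        with pytest.raises(ValueError):
            filter_motifs_outside_binding_region(sites([1]), sites([]))
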