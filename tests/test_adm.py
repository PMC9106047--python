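import itertools

import numpy as np
import pytest

from foldadm import (
    SequenceRecord,
    build_adm,
    calibrate_cutoffs,
    detect_regions,
    eta,
    range_of,
)
from foldadm.adm import ADMap
from foldadm.distance_stats import DistanceStatsTable


def table_from(entries: dict) -> DistanceStatsTable:
    t = DistanceStatsTable()
    for (a, b, m), row in entries.items():
        t.entries[DistanceStatsTable.key(a, b, m)] = row
    return t


def map_from_pairs(n, pairs):
    plot = np.zeros((n, n), dtype=bool)
    for i, j in pairs:  # 1-based
        plot[i - 1, j - 1] = True
    return ADMap(n=n, plot=plot, cutoffs={})


class TestCalibrate:
    def test_degenerate_distribution_full_target(self):
        t = table_from({("A", "A", 1): (6.0, 0.5, 10), ("A", "L", 1): (6.0, 0.4, 5)})
        cut = calibrate_cutoffs(t, {1: 1.0})
        assert cut[1] >= 6.0
        adm = build_adm(SequenceRecord("q", "AALA"), t, cut)
        iu, ju = np.triu_indices(4, 1)
        assert adm.plot[iu, ju].all()

    def test_zero_target_no_plots(self):
        t = table_from({("A", "A", 1): (6.0, 0.5, 10)})
        cut = calibrate_cutoffs(t, {1: 0.0})
        assert cut[1] < 6.0
        adm = build_adm(SequenceRecord("q", "AAAA"), t, cut)
        assert not adm.plot.any()

    def test_quantile_within_entry_granularity(self):
        """Achieved count-weighted plot fraction brackets the target within
        one table entry, verified by exhaustive enumeration."""
        rng = np.random.default_rng(7)
        letters = "ACDEF"
        t = DistanceStatsTable()
        for a, b in itertools.combinations_with_replacement(letters, 2):
            t.entries[(a, b, 1)] = (float(rng.uniform(4, 14)), 0.5, int(rng.integers(1, 50)))
        target = 0.4
        cut = calibrate_cutoffs(t, {1: target})[1]
        rows = sorted((mean, cnt) for (_, _, m), (mean, _, cnt) in t.entries.items() if m == 1)
        total = sum(c for _, c in rows)
        below = sum(c for mean, c in rows if mean < cut)
        granularity = max(c for _, c in rows) / total
        assert below / total >= target - 1e-12
        assert below / total - target <= granularity + 1e-12

    def test_absent_range_inherits_lower(self):
        t = table_from({("A", "A", 1): (6.0, 0.5, 10)})
        with pytest.warns(UserWarning, match="inherit"):
            cut = calibrate_cutoffs(t, {1: 1.0, 2: 0.5})
        assert cut[2] == cut[1]


class TestBuildADM:
    def test_homopolymer_uniform_within_range(self):
        t = table_from({("A", "A", 1): (5.0, 0.5, 9), ("A", "A", 2): (9.0, 1.0, 9)})
        adm = build_adm(SequenceRecord("q", "A" * 15), t, {1: 6.0, 2: 8.0})
        for i, j in itertools.combinations(range(15), 2):
            m = range_of(j - i)
            assert adm.plot[i, j] == (m == 1)

    def test_zero_cutoffs_empty(self):
        t = table_from({("A", "A", 1): (5.0, 0.5, 9)})
        adm = build_adm(SequenceRecord("q", "AAAA"), t, {1: 0.0})
        assert not adm.plot.any()

    def test_two_letter_hand_enumeration(self):
        """12-residue two-letter sequence against an independent pair loop."""
        seq = "ABABBAABABBA".replace("B", "L")
        t = table_from(
            {
                ("A", "A", 1): (5.0, 0.5, 4),
                ("A", "L", 1): (7.0, 0.5, 4),
                ("L", "L", 1): (9.0, 0.5, 4),
                ("A", "A", 2): (11.0, 0.5, 4),
            }
        )
        cutoffs = {1: 8.0, 2: 10.0}
        adm = build_adm(SequenceRecord("q", seq), t, cutoffs)
        for i, j in itertools.combinations(range(12), 2):
            m = range_of(j - i)
            mean = t.mean(seq[i], seq[j], m)
            expected = mean is not None and mean < cutoffs[m]
            assert adm.plot[i, j] == expected

    def test_nonstandard_residue_never_plots(self):
        t = table_from({("A", "A", 1): (5.0, 0.5, 9)})
        adm = build_adm(SequenceRecord("q", "AXAA"), t, {1: 6.0})
        assert not adm.plot[1, :].any() and not adm.plot[:, 1].any()

    def test_purity(self, toy_corpus):
        from foldadm import compute_stats, contact_density_by_range

        t = compute_stats(toy_corpus)
        cut = calibrate_cutoffs(t, contact_density_by_range(toy_corpus, 8.0))
        seq = SequenceRecord("q", toy_corpus[0].sequence)
        a, b = build_adm(seq, t, cut), build_adm(seq, t, cut)
        assert np.array_equal(a.plot, b.plot)

    def test_cutoff_monotonicity(self, toy_corpus):
        from foldadm import compute_stats

        t = compute_stats(toy_corpus)
        seq = SequenceRecord("q", toy_corpus[1].sequence)
        lo = build_adm(seq, t, {m: 6.0 for m in t.ranges()})
        hi = build_adm(seq, t, {m: 9.0 for m in t.ranges()})
        assert (hi.plot | lo.plot == hi.plot).all()  # raising cutoffs only adds
        assert hi.density() >= lo.density()


class TestEta:
    def test_full_block(self):
        adm = map_from_pairs(6, [(i, j) for i in range(1, 7) for j in range(i + 1, 7)])
        assert eta(adm, 1, 6) == 1.0

    def test_empty_block(self):
        assert eta(map_from_pairs(6, []), 1, 6) == 0.0

    def test_partial_block(self):
        adm = map_from_pairs(5, [(1, 2), (1, 3), (2, 4), (4, 5)])
        assert eta(adm, 1, 5) == pytest.approx(0.4)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            eta(map_from_pairs(5, []), 3, 3)


def exhaustive_regions(adm, min_len, margin):
    """Independent exhaustive-enumeration oracle for detect_regions."""
    thr = adm.density() + margin
    cands = []
    for s in range(1, adm.n - min_len + 2):
        for e in range(s + min_len - 1, adm.n + 1):
            d = eta(adm, s, e)
            if d >= thr:
                cands.append((d, s, e))
    cands.sort(key=lambda t: (-t[0], t[1], -t[2]))
    chosen = []
    for d, s, e in cands:
        if all(e < s2 or s > e2 for _, s2, e2 in chosen):
            chosen.append((d, s, e))
    chosen.sort(key=lambda t: (-t[0], t[1]))
    return chosen


class TestDetectRegions:
    def _planted(self, n=40, block=(10, 21), dense=0.85, sparse=0.08, seed=5):
        rng = np.random.default_rng(seed)
        plot = np.triu(rng.random((n, n)) < sparse, 1)
        s, e = block
        for i in range(s - 1, e):
            for j in range(i + 1, e):
                plot[i, j] = rng.random() < dense
        return ADMap(n=n, plot=np.triu(plot, 1), cutoffs={})

    def test_planted_block_recovered(self):
        adm = self._planted(dense=1.0)
        regions = detect_regions(adm, min_len=8, margin=0.05)
        primary = regions[0]
        assert (primary.start, primary.end) == (10, 21)
        assert primary.eta == 1.0

    def test_noisy_block_overlaps_primary(self):
        adm = self._planted(dense=0.85)
        regions = detect_regions(adm, min_len=8, margin=0.05)
        oracle = exhaustive_regions(adm, 8, 0.05)
        assert [(r.eta, r.start, r.end) for r in regions] == [
            (pytest.approx(d), s, e) for d, s, e in oracle
        ]
        s, e = regions[0].start, regions[0].end
        inter = max(0, min(e, 21) - max(s, 10) + 1)
        union = max(e, 21) - min(s, 10) + 1
        assert inter / union >= 0.5

    def test_uniform_map_no_regions(self):
        n = 30
        plot = np.triu(np.ones((n, n), dtype=bool), 1)
        assert detect_regions(ADMap(n=n, plot=plot, cutoffs={}), margin=0.05) == []

    def test_two_blocks_ranked_by_eta(self):
        rng = np.random.default_rng(11)
        n = 50
        plot = np.zeros((n, n), dtype=bool)
        for (s, e), dens in [((5, 16), 0.9), ((30, 41), 0.6)]:
            for i in range(s - 1, e):
                for j in range(i + 1, e):
                    plot[i, j] = rng.random() < dens
        adm = ADMap(n=n, plot=plot, cutoffs={})
        regions = detect_regions(adm, min_len=8, margin=0.05)
        assert len(regions) >= 2
        assert regions[0].rank == 1
        assert regions[0].start < 20 < regions[1].start
        assert regions[0].eta > regions[1].eta

    def test_non_overlap_and_threshold(self):
        adm = self._planted(seed=9)
        regions = detect_regions(adm, min_len=8, margin=0.02)
        thr = adm.density() + 0.02
        spans = []
        for r in regions:
            assert r.eta >= thr
            assert eta(adm, r.start, r.end) == pytest.approx(r.eta)
            spans.append((r.start, r.end))
        for (s1, e1), (s2, e2) in itertools.combinations(spans, 2):
            assert e1 < s2 or e2 < s1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        adm = self._planted(n=35, seed=seed)
        regions = detect_regions(adm, min_len=8, margin=0.03)
        oracle = exhaustive_regions(adm, 8, 0.03)
        assert [(r.start, r.end) for r in regions] == [(s, e) for _, s, e in oracle]
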