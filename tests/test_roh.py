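import numpy as np
import pytest

import vespagen as vg
from reference_impls import naive_detect_roh


def _positions(n, spacing):
    return np.arange(1, n + 1) * spacing


def random_instance(seed, n_max=500):
    """Random small ROH instance: blocky het/missing placement, random params."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(60, n_max + 1))
    # blocks of low/high heterozygosity to create realistic runs
    calls = np.empty(n, dtype=np.int8)
    j = 0
    while j < n:
        width = int(rng.integers(10, 120))
        het_rate = float(rng.choice([0.0, 0.02, 0.1, 0.4]))
        block = rng.choice([0, 2], size=width)
        block[rng.random(width) < het_rate] = 1
        calls[j : j + min(width, n - j)] = block[: n - j]
        j += width
    calls[rng.random(n) < 0.03] = vg.MISSING
    gaps = rng.integers(200, 4000, size=n)
    if rng.random() < 0.3:  # occasionally plant a window-splitting gap
        gaps[rng.integers(10, n - 10)] = 700_000
    pos = np.cumsum(gaps)
    n_chrom2 = int(rng.integers(0, n // 2))
    chrom = np.array(["chr1"] * (n - n_chrom2) + ["chr2"] * n_chrom2)
    pos[n - n_chrom2 :] = np.cumsum(gaps[n - n_chrom2 :])
    params = vg.ROHParams(
        window_snps=int(rng.choice([10, 25, 50])),
        window_het_max=int(rng.choice([0, 1, 2])),
        window_missing_max=int(rng.choice([2, 5])),
        min_snps=int(rng.choice([10, 25, 50])),
        min_length_kb=float(rng.choice([50, 200, 500])),
        density_kb_per_snp=float(rng.choice([10, 60])),
        gap_kb=float(rng.choice([100, 500])),
        segment_het_max=None if rng.random() < 0.7 else int(rng.integers(0, 5)),
    )
    return calls, chrom, pos, params


def as_tuples(segments):
    return [(s.chrom, s.start, s.end, s.n_snps, s.n_het) for s in segments]


class TestDetectRoh:
    def test_all_heterozygous_yields_nothing(self):
        n = 200
        segs = vg.detect_roh(np.ones(n, dtype=np.int8), np.full(n, "chr1"),
                             _positions(n, 1000))
        assert segs == []

    def test_fully_homozygous_chromosome_is_one_segment(self):
        n = 2000
        pos = _positions(n, 1000)
        segs = vg.detect_roh(np.zeros(n, dtype=np.int8), np.full(n, "chr1"), pos)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end) == (pos[0], pos[-1])
        assert seg.n_snps == n and seg.n_het == 0

    def test_short_chromosome_yields_no_flags(self):
        n = 30  # below the 50-SNP window
        segs = vg.detect_roh(np.zeros(n, dtype=np.int8), np.full(n, "chr1"),
                             _positions(n, 1000))
        assert segs == []

    def test_unsorted_positions_rejected(self):
        pos = np.array([1000, 500, 2000])
        with pytest.raises(vg.DataError):
            vg.detect_roh(np.zeros(3, dtype=np.int8), np.full(3, "chr1"), pos)

    @pytest.mark.parametrize("seed_block", range(10))
    def test_matches_naive_oracle(self, seed_block):
        """Optimized detector identical to the literal five-step reference."""
        for seed in range(seed_block * 10, seed_block * 10 + 10):
            calls, chrom, pos, params = random_instance(seed)
            got = as_tuples(vg.detect_roh(calls, chrom, pos, params))
            expected = naive_detect_roh(calls, chrom, pos, params)
            assert got == expected, f"divergence at seed {seed}"

    def test_no_accepted_segment_spans_a_large_gap(self):
        for seed in (3, 17, 31):
            calls, chrom, pos, params = random_instance(seed)
            for seg in vg.detect_roh(calls, chrom, pos, params):
                sel = (chrom == seg.chrom) & (pos >= seg.start) & (pos <= seg.end)
                assert np.diff(pos[sel]).max(initial=0) <= params.gap_kb * 1000


class TestRohMax:
    def test_dense_chromosome_spans_first_to_last(self):
        n = 5000
        pos = _positions(n, 2000)  # 10 Mb at 2 kb spacing
        total = vg.roh_max(np.full(n, "chr1"), pos)
        assert total == pos[-1] - pos[0] + 1

    def test_large_gap_splits_into_two_segments(self):
        pos = np.concatenate([_positions(1000, 2000), 2_600_000 + _positions(1000, 2000)])
        total = vg.roh_max(np.full(2000, "chr1"), pos, vg.ROHParams(gap_kb=500))
        left = pos[999] - pos[0] + 1
        right = pos[1999] - pos[1000] + 1
        assert total == left + right

    def test_chromosomes_below_length_floor_contribute_zero(self):
        n = 100
        pos = _positions(n, 1000)  # 100 kb < 500 kb floor
        assert vg.roh_max(np.full(n, "chr1"), pos) == 0


class TestFroh:
    def test_fully_homozygous_sample_is_exactly_one(self):
        n = 3000
        pos = _positions(n, 2000)
        val = vg.froh(np.full(n, 2, dtype=np.int8), np.full(n, "chr1"), pos)
        assert val == 1.0

    def test_fully_heterozygous_sample_is_zero(self):
        n = 3000
        pos = _positions(n, 2000)
        assert vg.froh(np.ones(n, dtype=np.int8), np.full(n, "chr1"), pos) == 0.0

    def test_undefined_when_roh_max_zero(self):
        n = 60
        pos = _positions(n, 1000)
        with pytest.raises(vg.UndefinedStatisticError):
            vg.froh(np.zeros(n, dtype=np.int8), np.full(n, "chr1"), pos)

    def test_planted_tracts_recovered(self, filtered_panel):
        _, gm, _, truth = filtered_panel
        for sid, target in truth.planted_fraction.items():
            if target == 0:
                continue
            val = vg.froh(gm.calls[gm.sample_index(sid)], gm.chrom, gm.pos,
                          vg.ROHParams(min_length_kb=500))
            assert val == pytest.approx(target, abs=0.05)


@pytest.fixture(scope="module")
def profiles(filtered_panel):
    import pandas as pd

    _, gm, meta, _ = filtered_panel
    return filtered_panel, pd.concat(
        [vg.froh_profile(gm, meta, snp_set=mode)
         for mode in ("pooled", "within_population")],
        ignore_index=True,
    )


class TestFrohProfile:
    def test_males_absent(self, profiles):
        (_, _, meta, _), table = profiles
        males = set(meta[meta["sex"] == "male"]["sample_id"])
        assert not males & set(table["sample"])

    def test_monotone_in_length_threshold(self, profiles):
        _, table = profiles
        for (_, _), sub in table.groupby(["sample", "snp_set"]):
            froh_by_len = sub.set_index("min_length_kb")["froh"]
            assert froh_by_len[2000] <= froh_by_len[1000] + 1e-12
            assert froh_by_len[1000] <= froh_by_len[500] + 1e-12

    def test_froh_bounded(self, profiles):
        _, table = profiles
        assert ((table["froh"] >= 0) & (table["froh"] <= 1)).all()

    def test_within_population_not_above_pooled_on_average(self, profiles):
        """Sites fixed within a population (including cross-population fixed
        differences) are always homozygous there, so dropping them lowers the
        detectable-homozygosity fraction."""
        _, table = profiles
        at500 = table[table["min_length_kb"] == 500]
        pooled = at500[at500["snp_set"] == "pooled"].set_index("sample")["froh"]
        within = at500[at500["snp_set"] == "within_population"].set_index("sample")["froh"]
        assert within.mean() <= pooled.mean() + 1e-9


def test_froh_group_bins():
    assert vg.froh_group(0.0) == "zero"
    assert vg.froh_group(0.01) == "intermediate"
    assert vg.froh_group(0.05) == "high"
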