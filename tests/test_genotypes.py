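import numpy as np
import pandas as pd
import pytest

import vespagen as vg
from conftest import make_matrix
from reference_impls import naive_genotype_filter, naive_hard_filter

VCF_TEXT = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                      "INFO", "FORMAT", "s1", "s2", "s3"])
VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=QD,Number=1,Type=Float,Description="q">
##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
""" + VCF_TEXT + "\n"


def _vcf(tmp_path, records):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + "".join("\t".join(r) + "\n" for r in records))
    return str(path)


class TestReadVcf:
    def test_dosage_is_alt_allele_count(self, tmp_path):
        path = _vcf(tmp_path, [
            ["chr1", "100", ".", "A", "G", ".", ".", ".", "GT", "0/0", "0/1", "1/1"],
        ])
        gm = vg.read_vcf(path)
        assert gm.calls.tolist() == [[0], [1], [2]]
        assert gm.pos.tolist() == [100] and gm.chrom.tolist() == ["chr1"]

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        path = _vcf(tmp_path, [
            ["chr1", "100", ".", "A", "G", ".", ".", ".", "GT", "0/0", "0/1", "1/1"],
            ["chr1", "200", ".", "A", "G,T", ".", ".", ".", "GT", "0/0", "0/1", "1/1"],
            ["chr1", "300", ".", "AT", "A", ".", ".", ".", "GT", "0/0", "0/1", "1/1"],
        ])
        gm = vg.read_vcf(path)
        assert gm.n_sites == 1 and gm.pos.tolist() == [100]

    def test_missing_call_becomes_sentinel(self, tmp_path):
        path = _vcf(tmp_path, [
            ["chr1", "100", ".", "A", "G", ".", ".", ".", "GT", "./.", "0/1", "1/1"],
        ])
        gm = vg.read_vcf(path)
        assert gm.calls.tolist() == [[vg.MISSING], [1], [2]]

    def test_empty_vcf_is_an_error(self, tmp_path):
        path = _vcf(tmp_path, [])
        with pytest.raises(vg.DataError):
            vg.read_vcf(path)


class TestRoundTrip:
    def test_simulated_panel_round_trips(self, fixture_panel, tmp_path):
        _, gm, _, _ = fixture_panel
        path = str(tmp_path / "rt.vcf")
        vg.write_vcf(gm, path)
        back = vg.read_vcf(path)
        assert back.sample_ids == gm.sample_ids
        assert np.array_equal(back.calls, gm.calls)
        assert np.array_equal(back.pos, gm.pos)
        assert np.array_equal(back.chrom, gm.chrom)
        assert np.array_equal(back.depth, gm.depth)
        assert np.array_equal(back.gq, gm.gq)

    def test_depth_and_gq_emitted_in_format(self, fixture_panel, tmp_path):
        _, gm, _, _ = fixture_panel
        path = tmp_path / "fmt.vcf"
        vg.write_vcf(gm.take_sites([0, 1]), str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert all(l.split("\t")[8] == "GT:DP:GQ" for l in body)

    def test_empty_site_set_gives_header_only_vcf(self, fixture_panel, tmp_path):
        _, gm, _, _ = fixture_panel
        path = tmp_path / "empty.vcf"
        vg.write_vcf(gm.take_sites([]), str(path))
        assert all(l.startswith("#") for l in path.read_text().splitlines())


class TestFilterGenotypes:
    def test_site_with_over_ten_percent_missing_dropped(self):
        # 10 samples: 1 missing call = 10% (kept), 2 missing = 20% (dropped)
        calls = np.ones((10, 2), dtype=np.int8)
        calls[0, 0] = vg.MISSING
        calls[0, 1] = calls[1, 1] = vg.MISSING
        gm = make_matrix(calls)
        out = vg.filter_genotypes(gm, min_gq=0, max_missing_frac=0.10, min_depth=0)
        assert out.pos.tolist() == [1000]

    def test_all_passing_input_unchanged(self):
        calls = np.tile([0, 1, 2], (4, 1)).astype(np.int8)
        gm = make_matrix(calls, depth=np.full((4, 3), 30), gq=np.full((4, 3), 99))
        out = vg.filter_genotypes(gm)
        assert np.array_equal(out.calls, gm.calls) and out.n_sites == gm.n_sites

    def test_matches_naive_reference_on_planted_fixture(self):
        rng = np.random.default_rng(42)
        n, m = 12, 200
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        calls[rng.random((n, m)) < 0.05] = vg.MISSING
        gq = rng.integers(0, 99, size=(n, m))
        depth = rng.integers(0, 30, size=(n, m))
        gm = make_matrix(calls, depth=depth, gq=gq)
        out = vg.filter_genotypes(gm, min_gq=20, max_missing_frac=0.10, min_depth=3)
        expected = naive_genotype_filter(
            calls.tolist(), gq.tolist(), depth.tolist(), 20, 0.10, 3
        )
        assert out.pos.tolist() == [(j + 1) * 1000 for j in expected]

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        gm = make_matrix(calls, depth=rng.integers(0, 10, (8, 50)),
                         gq=rng.integers(0, 99, (8, 50)))
        once = vg.filter_genotypes(gm)
        twice = vg.filter_genotypes(once)
        assert np.array_equal(once.calls, twice.calls)
        assert np.array_equal(once.pos, twice.pos)

    def test_negative_threshold_rejected(self, fixture_panel):
        _, gm, _, _ = fixture_panel
        with pytest.raises(vg.ConfigError):
            vg.filter_genotypes(gm, min_gq=-1)


class TestHardFilter:
    def _gm(self, info_rows):
        info = pd.DataFrame(
            [{k: row.get(k, np.nan) for k in
              ("QUAL", "QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")}
             for row in info_rows]
        )
        calls = np.zeros((2, len(info_rows)), dtype=np.int8)
        return make_matrix(calls, info=info)

    def test_low_qd_site_dropped(self):
        gm = self._gm([{"QD": 1.9}, {"QD": 2.0}])
        assert vg.gatk_hard_filter(gm).pos.tolist() == [2000]

    def test_all_passing_site_retained(self):
        gm = self._gm([{"QUAL": 50.0, "QD": 10.0, "SOR": 1.0, "FS": 5.0,
                        "MQ": 60.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}])
        assert vg.gatk_hard_filter(gm).n_sites == 1

    def test_one_failing_field_per_site_matches_reference(self):
        rows = [
            {"QD": 1.0}, {"QUAL": 10.0}, {"SOR": 3.5}, {"FS": 61.0},
            {"MQ": 39.0}, {"MQRankSum": -13.0}, {"ReadPosRankSum": -9.0},
            {"QD": 5.0, "MQ": 55.0},  # passes
            {},  # untested fields -> retained
        ]
        gm = self._gm(rows)
        out = vg.gatk_hard_filter(gm)
        expected = naive_hard_filter(rows)
        assert out.pos.tolist() == [(j + 1) * 1000 for j in expected]

    def test_idempotent(self):
        gm = self._gm([{"QD": 1.0}, {"QD": 5.0}, {}])
        once = vg.gatk_hard_filter(gm)
        assert np.array_equal(vg.gatk_hard_filter(once).pos, once.pos)


class TestSubset:
    def test_exclude_populations(self, fixture_panel):
        _, gm, meta, _ = fixture_panel
        keep_pops = sorted(set(meta["population"]) - {"pop1", "pop2"})
        out = vg.subset(gm, meta, populations=keep_pops)
        pops = meta.set_index("sample_id").loc[out.sample_ids, "population"]
        assert set(pops) == set(keep_pops) and out.n_sites == gm.n_sites

    def test_subset_to_all_is_identity(self, fixture_panel):
        _, gm, meta, _ = fixture_panel
        out = vg.subset(gm, meta, sample_ids=gm.sample_ids)
        assert out.sample_ids == gm.sample_ids

    def test_nest_females_match_truth(self, fixture_panel):
        cfg, gm, meta, truth = fixture_panel
        nest = "pop1_nest1"
        ids = [s for s, n in truth.nest.items() if n == nest]
        out = vg.subset(gm, meta, sample_ids=ids, sexes=["female"])
        # one mother + the configured number of daughters
        assert out.n_samples == cfg.daughters_per_nest + 1

    def test_unknown_label_is_an_error(self, fixture_panel):
        _, gm, meta, _ = fixture_panel
        with pytest.raises(vg.DataError):
            vg.subset(gm, meta, populations=["atlantis"])


class TestPolymorphicRestriction:
    def test_fixed_and_variable_sites(self):
        gm = make_matrix([[2, 0, 1], [2, 0, 0], [2, 0, 0]])
        out = vg.restrict_to_polymorphic(gm)
        assert out.pos.tolist() == [3000]
        assert out.n_samples == 3  # all samples retained

    def test_cross_population_fixed_differences(self, fixture_panel):
        """Sites fixed for opposite alleles between populations stay pooled-
        polymorphic but are dropped within either population."""
        calls = np.array([[0, 0, 1], [0, 0, 1], [2, 2, 1], [2, 2, 0]], dtype=np.int8)
        gm = make_matrix(calls)
        within_a = vg.restrict_to_polymorphic(gm, samples=["s1", "s2"])
        within_b = vg.restrict_to_polymorphic(gm, samples=["s3", "s4"])
        pooled = vg.restrict_to_polymorphic(gm)
        assert pooled.n_sites == 3
        assert within_a.pos.tolist() == [3000]
        assert within_b.pos.tolist() == [3000]
        assert within_a.n_sites <= pooled.n_sites

    def test_output_sites_subset_of_input(self, filtered_panel):
        _, gm, meta, _ = filtered_panel
        pop1 = meta[meta["population"] == "pop1"]["sample_id"].tolist()
        out = vg.restrict_to_polymorphic(gm, samples=pop1)
        assert set(map(tuple, zip(out.chrom, out.pos))) <= set(
            map(tuple, zip(gm.chrom, gm.pos))
        )


class TestSiteSubsample:
    def test_step_one_is_identity(self, fixture_panel):
        _, gm, _, _ = fixture_panel
        assert vg.site_subsample(gm, 1).n_sites == gm.n_sites

    def test_arithmetic(self):
        gm = make_matrix(np.zeros((1, 900), dtype=np.int8))
        out = vg.site_subsample(gm, 90)
        assert out.n_sites == 10
        assert out.pos.tolist() == [(j * 90 + 1) * 1000 for j in range(10)]

    def test_every_90th_of_full_scale_panel(self):
        # the documented whole-genome case: 111,215 unlinked loci -> 1,236 kept
        gm = make_matrix(np.zeros((1, 111_215), dtype=np.int8), spacing=100)
        assert vg.site_subsample(gm, 90).n_sites == 1236

    def test_bad_step_rejected(self, fixture_panel):
        _, gm, _, _ = fixture_panel
        with pytest.raises(vg.ConfigError):
            vg.site_subsample(gm, 0)


class TestMetadata:
    def test_round_trip(self, fixture_panel, tmp_path):
        _, _, meta, _ = fixture_panel
        path = str(tmp_path / "meta.tsv")
        vg.write_metadata(meta, path)
        back = vg.read_metadata(path)
        assert back["sample_id"].tolist() == meta["sample_id"].tolist()
        assert back["sex"].tolist() == meta["sex"].tolist()

    def test_bad_sex_label_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tpopulation\tsex\tnest\na\tp\tqueen\t\n")
        with pytest.raises(vg.DataError):
            vg.read_metadata(str(path))
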