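"""Burden metrics, gene-set tests, and the paired burden test suite."""

import numpy as np
import pytest

from cnvmeta import burden_analysis as ba
from cnvmeta import synthetic_data as sd
from cnvmeta.cnv_data import GeneModel
from cnvmeta.stratification import build_strata
from cnvmeta.qc_filters import filter_analysis_grade, filter_qualifying
from .conftest import make_call, make_sample


class TestSingletons:
    def test_lone_call_is_singleton(self):
        assert ba.mark_singletons([make_call()]) == [True]

    def test_identical_calls_in_two_samples_not_singletons(self):
        calls = [make_call(sample="A"), make_call(sample="B")]
        assert ba.mark_singletons(calls) == [False, False]

    def test_forty_percent_reciprocal_overlap_stays_singleton(self):
        a = make_call(sample="A", start=0, end=100_000)
        b = make_call(sample="B", start=60_000, end=160_000)  # 40% reciprocal
        assert ba.mark_singletons([a, b]) == [True, True]

    def test_same_sample_repeat_does_not_break_singleton(self):
        calls = [make_call(sample="A"), make_call(sample="A")]
        assert ba.mark_singletons(calls) == [True, True]


@pytest.fixture
def burden_genes():
    return [
        GeneModel("HI", "1", ((1_000_000, 1_010_000),), pli=0.97),
        GeneModel("HI2", "1", ((5_000_000, 5_010_000),), pli=0.999),
        GeneModel("LO", "2", ((1_000_000, 1_010_000),), pli=0.10),
    ]


class TestComputeBurden:
    def test_predicates_on_single_large_genic_del(self, burden_genes):
        call = make_call(sample="S1", chrom="1", start=500_000, end=2_000_000,
                         n_probes=100)
        args = ([call], burden_genes, {}, )
        for spec, expected in [
            (ba.BurdenMetricSpec("del", cnv_types=("DEL",)), 1),
            (ba.BurdenMetricSpec("genic_del", cnv_types=("DEL",), genic_filter="genic"), 1),
            (ba.BurdenMetricSpec("pli_del", cnv_types=("DEL",), pli_bin=">0.9"), 1),
            (ba.BurdenMetricSpec("big", size_range=(1_000_000, None)), 1),
            (ba.BurdenMetricSpec("dup", cnv_types=("DUP",)), 0),
            (ba.BurdenMetricSpec("small", size_range=(100_000, 1_000_000)), 0),
        ]:
            counts = ba.compute_burden(*args, spec, ["S1"])
            assert counts[0] == expected, spec.name

    def test_no_calls_gives_zero_vector(self, burden_genes):
        counts = ba.compute_burden([], burden_genes, {},
                                   ba.BurdenMetricSpec("all"), ["S1", "S2"])
        assert np.array_equal(counts, [0, 0])

    def test_intron_only_overlap_not_counted_in_pli_bin(self):
        gene = GeneModel("HI", "1", ((100_000, 101_000), (200_000, 201_000)), pli=0.99)
        call = make_call(start=101_000, end=200_000, n_probes=20)
        spec = ba.BurdenMetricSpec("pli", pli_bin=">0.9")
        assert ba.compute_burden([call], [gene], {}, spec, ["S1"])[0] == 0

    def test_unknown_gene_set_rejected(self, burden_genes):
        spec = ba.BurdenMetricSpec("gs", gene_set="nope")
        with pytest.raises(KeyError):
            ba.compute_burden([], burden_genes, {}, spec, ["S1"])

    def test_genic_plus_nongenic_decomposition(self, burden_genes, rng):
        calls = []
        for i in range(150):
            s = int(rng.integers(0, 9_000_000))
            calls.append(make_call(sample=f"S{i % 10}", chrom=str(rng.integers(1, 3)),
                                   start=s, end=s + int(rng.integers(50_000, 2_000_000)),
                                   cnv_type="DEL" if rng.random() < 0.5 else "DUP"))
        ids = [f"S{i}" for i in range(10)]
        for t in ("DEL", "DUP"):
            total = ba.compute_burden(calls, burden_genes, {},
                                      ba.BurdenMetricSpec("t", cnv_types=(t,)), ids)
            genic = ba.compute_burden(calls, burden_genes, {},
                                      ba.BurdenMetricSpec("g", cnv_types=(t,),
                                                          genic_filter="genic"), ids)
            nongenic = ba.compute_burden(calls, burden_genes, {},
                                         ba.BurdenMetricSpec("n", cnv_types=(t,),
                                                             genic_filter="nongenic"), ids)
            assert np.array_equal(total, genic + nongenic)

    def test_pli_bins_nest(self, burden_genes, rng):
        calls = []
        for i in range(100):
            s = int(rng.integers(0, 9_000_000))
            calls.append(make_call(sample=f"S{i % 10}", chrom="1", start=s,
                                   end=s + 500_000))
        ids = [f"S{i}" for i in range(10)]
        loose = ba.compute_burden(calls, burden_genes, {},
                                  ba.BurdenMetricSpec("a", pli_bin=">0.9"), ids)
        tight = ba.compute_burden(calls, burden_genes, {},
                                  ba.BurdenMetricSpec("b", pli_bin=">0.995"), ids)
        assert np.all(tight <= loose)


class TestGenesetCarrierFisher:
    def test_reproduces_printed_rate_table(self):
        """5 carriers among 5,202 cases vs 1 among 8,667 controls -> OR 8.34."""
        gene = GeneModel("DNV1", "1", ((1_000_000, 1_010_000),), pli=0.98)
        samples, calls = [], []
        for i in range(5202):
            sid = f"CASE{i}"
            samples.append(make_sample(sid=sid, status="case"))
            if i < 5:
                calls.append(make_call(sample=sid, chrom="1",
                                       start=990_000, end=1_020_000))
        for i in range(8667):
            sid = f"CTRL{i}"
            samples.append(make_sample(sid=sid, status="control"))
            if i < 1:
                calls.append(make_call(sample=sid, chrom="1",
                                       start=990_000, end=1_020_000))
        or_, p = ba.geneset_carrier_fisher(samples, calls, [gene], {"DNV1"}, "DEL")
        assert or_ == pytest.approx(8.34, abs=0.005)
        assert p == pytest.approx(0.03, abs=0.005)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            ba.geneset_carrier_fisher([], [], [], set())


class TestCompareCallSizes:
    def test_detects_shifted_lengths(self, rng):
        samples = [make_sample(sid=f"CA{i}", status="case") for i in range(200)]
        samples += [make_sample(sid=f"CO{i}", status="control") for i in range(200)]
        calls = []
        for i in range(200):
            calls.append(make_call(sample=f"CA{i}", start=0,
                                   end=int(rng.lognormal(np.log(400_000), 0.4))))
            calls.append(make_call(sample=f"CO{i}", start=0,
                                   end=int(rng.lognormal(np.log(200_000), 0.4))))
        _, p = ba.compare_call_sizes(calls, samples)
        assert p < 0.01

    def test_calibrated_under_identical_distributions(self, rng):
        ps = []
        for _ in range(40):
            samples = [make_sample(sid=f"CA{i}", status="case") for i in range(50)]
            samples += [make_sample(sid=f"CO{i}", status="control") for i in range(50)]
            calls = [make_call(sample=s.sample_id, start=0,
                               end=int(rng.lognormal(np.log(200_000), 0.4)))
                     for s in samples]
            ps.append(ba.compare_call_sizes(calls, samples)[1])
        # roughly uniform: no gross excess of small p
        assert np.mean(np.array(ps) < 0.05) < 0.25

    def test_empty_group_rejected(self):
        samples = [make_sample(sid="A", status="case")]
        calls = [make_call(sample="A")]
        with pytest.raises(ValueError):
            ba.compare_call_sizes(calls, samples)


class TestCatalogMatch:
    CATALOG = [ba.CatalogEntry("NDD1", "1", 1_000_000, 1_400_000, "DEL")]

    def test_full_span_hit(self):
        call = make_call(chrom="1", start=900_000, end=1_500_000)
        assert ba.match_known_cnvs([call], self.CATALOG) == [["NDD1"]]

    def test_thirty_percent_coverage_no_hit(self):
        call = make_call(chrom="1", start=1_000_000, end=1_120_000)
        assert ba.match_known_cnvs([call], self.CATALOG) == [[]]

    def test_type_mismatch_no_hit(self):
        call = make_call(chrom="1", start=900_000, end=1_500_000, cnv_type="DUP")
        assert ba.match_known_cnvs([call], self.CATALOG) == [[]]


def small_cohort(seed, planted_or=1.0):
    genes = [GeneModel(f"G{i}", "1", ((i * 200_000, i * 200_000 + 50_000),),
                       pli=0.97 if i % 2 else 0.1) for i in range(1, 10)]
    rng = np.random.default_rng(seed)
    samples, calls = [], []
    for j in range(600):
        status = "case" if j < 300 else "control"
        sex = "M" if j % 2 else "F"
        sid = f"S{j}"
        samples.append(make_sample(sid=sid, status=status, sex=sex, n_cnv_raw=2))
        # genic DEL carrier probability differs by status when planted_or > 1
        base = 0.10
        p_case = base * planted_or / (1 - base + base * planted_or)
        if rng.random() < (p_case if status == "case" else base):
            g = genes[int(rng.integers(0, len(genes)))]
            s = g.coding_intervals[0][0] - 10_000
            calls.append(make_call(sample=sid, chrom="1", start=max(0, s),
                                   end=g.coding_intervals[0][1] + 60_000,
                                   n_probes=25))
    return samples, calls, genes


class TestBurdenSuite:
    def test_zero_cnv_cohort_flags_every_spec(self):
        samples = [make_sample(sid=f"S{i}", status="case" if i < 30 else "control",
                               sex="M" if i % 2 else "F")
                   for i in range(60)]
        strata, _ = build_strata(samples, [0] * 60)
        rows = ba.run_burden_suite(samples, [], [], {},
                                   [ba.BurdenMetricSpec("all")], strata)
        assert rows[0].logistic is None
        assert rows[0].cmh is not None and rows[0].cmh.degenerate
        assert rows[0].error is not None

    def test_planted_genic_signal_detected_and_tests_agree(self):
        detections = 0
        for seed in range(8):
            samples, calls, genes = small_cohort(seed, planted_or=3.0)
            strata, _ = build_strata(samples, [0] * len(samples))
            rows = ba.run_burden_suite(
                samples, calls, genes, {},
                [ba.BurdenMetricSpec("genic_del", cnv_types=("DEL",),
                                     genic_filter="genic")],
                strata,
            )
            row = rows[0]
            assert row.logistic is not None and row.cmh is not None
            # both tests point the same direction
            assert (row.logistic.or_mh > 1) == (row.cmh.or_mh > 1)
            if row.cmh.p < 0.05:
                detections += 1
        assert detections >= 6

    def test_null_cohort_type_one_error_controlled(self):
        false_pos = 0
        for seed in range(10):
            samples, calls, genes = small_cohort(100 + seed, planted_or=1.0)
            strata, _ = build_strata(samples, [0] * len(samples))
            rows = ba.run_burden_suite(
                samples, calls, genes, {},
                [ba.BurdenMetricSpec("genic_del", cnv_types=("DEL",),
                                     genic_filter="genic")],
                strata,
            )
            if rows[0].cmh is not None and rows[0].cmh.p < 0.05:
                false_pos += 1
        assert false_pos <= 3


class TestLeaveOneOut:
    def _cohort(self):
        samples, calls = [], []
        for ds in ("D1", "D2", "D3"):
            for i in range(40):
                sid = f"{ds}_{i}"
                samples.append(make_sample(sid=sid, dataset=ds,
                                           status="case" if i < 20 else "control"))
                if ds == "D1" and i < 10:  # signal only in D1 cases
                    calls.append(make_call(sample=sid))
        return samples, calls

    def test_three_datasets_three_rows(self):
        samples, calls = self._cohort()
        out = ba.leave_one_out(samples, calls,
                               lambda s, c: (len(s), len(c)))
        assert sorted(out) == ["D1", "D2", "D3"]
        assert out["D1"] == (80, 0)  # excluding D1 removes all its calls

    def test_failing_exclusion_is_flagged_not_fatal(self):
        samples, calls = self._cohort()

        def runner(s, c):
            if not c:
                raise ValueError("no calls left")
            return "ok"

        out = ba.leave_one_out(samples, calls, runner)
        assert out["D1"].startswith("FAILED")
        assert out["D2"] == out["D3"] == "ok"

    def test_single_dataset_rejected(self):
        samples = [make_sample(sid="A", dataset="D1")]
        with pytest.raises(ValueError):
            ba.leave_one_out(samples, [], lambda s, c: None)
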