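"""Karyotype statistics: CI, arm ratio, relative length, reduction, averaging."""

import statistics

import numpy as np
import pytest

from karyodraw.karyostats import (
    arm_ratio,
    average_karyotypes,
    build_karyotype,
    centromere_index,
    reduce_karyotype,
)
from karyodraw.measure_core import MeasurementError, ScaleCalibration

from conftest import straight_metaphase


class TestFormulas:
    @pytest.mark.parametrize("Ls,L,expected", [
        (2, 10, 20.0),
        (5, 10, 50.0),   # metacentric
        (0, 10, 0.0),    # telocentric
    ])
    def test_centromere_index(self, Ls, L, expected):
        assert centromere_index(Ls, L) == pytest.approx(expected)

    def test_centromere_index_invalid(self):
        with pytest.raises(MeasurementError):
            centromere_index(1, 0)
        with pytest.raises(MeasurementError):
            centromere_index(11, 10)

    @pytest.mark.parametrize("Ls,Ll,expected", [
        (2, 8, 4.0),
        (5, 5, 1.0),
        (0, 8, None),    # telocentric: undefined, not an error
    ])
    def test_arm_ratio(self, Ls, Ll, expected):
        assert arm_ratio(Ls, Ll) == expected


class TestBuildKaryotype:
    def test_ordering_and_relative_length(self):
        k = build_karyotype(straight_metaphase([5, 10, 7]))
        assert [r.L for r in k.records] == [10, 7, 5]
        assert [r.RL for r in k.records] == pytest.approx(
            [1000 / 22, 700 / 22, 500 / 22])
        assert sum(r.RL for r in k.records) == pytest.approx(100, abs=1e-9)

    def test_single_chromosome_is_whole_complement(self):
        k = build_karyotype(straight_metaphase([42]))
        assert k.records[0].RL == pytest.approx(100.0)

    def test_ordering_matches_independent_sort_oracle(self, rng):
        lengths = list(rng.uniform(10, 200, size=20))
        k = build_karyotype(straight_metaphase(lengths))
        assert [r.L for r in k.records] == pytest.approx(
            sorted(lengths, reverse=True))
        assert [r.name for r in k.records] == [str(i + 1) for i in range(20)]

    def test_calibration_converts_to_um(self):
        cal = ScaleCalibration(bar_pixels=100, bar_physical=10)  # 10 px/µm
        k = build_karyotype(straight_metaphase([50], [40], calibration=cal))
        assert k.unit == "um"
        assert k.records[0].L == pytest.approx(5.0)
        assert k.records[0].Ls == pytest.approx(2.0)

    def test_scaling_lengths_leaves_ci_rl_unchanged(self, rng):
        lengths = list(rng.uniform(10, 100, size=8))
        cis = list(rng.uniform(10, 50, size=8))
        k1 = build_karyotype(straight_metaphase(lengths, cis))
        k2 = build_karyotype(straight_metaphase([3.7 * L for L in lengths], cis))
        for a, b in zip(k1.records, k2.records):
            assert b.L == pytest.approx(3.7 * a.L, rel=1e-9)
            assert b.CI == pytest.approx(a.CI, rel=1e-9)
            assert b.RL == pytest.approx(a.RL, rel=1e-9)
            if a.r is not None:
                assert b.r == pytest.approx(a.r, rel=1e-9)

    def test_holocentric_records_have_absent_arm_stats(self):
        k = build_karyotype(straight_metaphase([10, 20], [30, None]))
        holo = [r for r in k.records if r.CI is None]
        assert len(holo) == 1 and holo[0].Ls is None and holo[0].r is None

    def test_empty_metaphase_rejected(self):
        from karyodraw.measure_core import Metaphase

        with pytest.raises(MeasurementError):
            build_karyotype(Metaphase(id="x", measurements=[]))


def oracle_group_stats(values):
    """Independent mean/sample-SD via the statistics stdlib module."""
    mean = statistics.fmean(values)
    sd = 0.0 if len(values) == 1 else statistics.stdev(values)
    return mean, sd


class TestReduceKaryotype:
    def test_diploid_sixteen_to_eight(self, rng):
        lengths = list(np.repeat(rng.uniform(20, 100, size=8), 2))
        cis = list(rng.uniform(20, 50, size=16))
        red = reduce_karyotype(build_karyotype(straight_metaphase(lengths, cis)), 2)
        assert len(red.records) == 8
        assert all(r.n == 2 for r in red.records)

    def test_identical_homologs_have_zero_sd(self):
        k = build_karyotype(straight_metaphase([10, 10, 6, 6], [40, 40, 30, 30]))
        red = reduce_karyotype(k, 2)
        for r in red.records:
            assert r.sd_L == 0 and r.sd_CI == 0

    def test_matches_brute_force_groupwise_oracle(self, rng):
        lengths = list(rng.uniform(10, 100, size=12))
        cis = list(rng.uniform(10, 50, size=12))
        k = build_karyotype(straight_metaphase(lengths, cis))
        red = reduce_karyotype(k, 3)
        recs = sorted(k.records, key=lambda r: -r.L)
        for g, avg in enumerate(red.records):
            group = recs[3 * g:3 * g + 3]
            for attr, mattr, sattr in [("L", "mean_L", "sd_L"),
                                       ("CI", "mean_CI", "sd_CI"),
                                       ("Ls", "mean_Ls", "sd_Ls"),
                                       ("Ll", "mean_Ll", "sd_Ll")]:
                mean, sd = oracle_group_stats([getattr(r, attr) for r in group])
                assert getattr(avg, mattr) == pytest.approx(mean, rel=1e-12)
                assert getattr(avg, sattr) == pytest.approx(sd, rel=1e-9, abs=1e-12)

    def test_ploidy_one_is_identity_with_n_one(self):
        k = build_karyotype(straight_metaphase([10, 8, 6], [40, 30, 20]))
        red = reduce_karyotype(k, 1)
        for orig, avg in zip(k.records, red.records):
            assert avg.mean_L == pytest.approx(orig.L)
            assert avg.sd_L == 0 and avg.n == 1

    def test_indivisible_count_reports_remainder(self):
        k = build_karyotype(straight_metaphase([10] * 16, [40] * 16))
        with pytest.raises(MeasurementError, match="remainder 1"):
            reduce_karyotype(k, 3)


class TestAverageKaryotypes:
    def _karyos(self, rng, n_k=3, n_c=6, jitter=0.1):
        ks = []
        for i in range(n_k):
            lengths = [20 + 10 * j + rng.normal(0, jitter * 10) for j in range(n_c)]
            cis = list(rng.uniform(20, 50, size=n_c))
            ks.append(build_karyotype(
                straight_metaphase(lengths, cis, mp_id=f"m{i}"), keep_names=True))
        return ks

    def test_identical_karyotypes_average_to_themselves(self):
        k = build_karyotype(straight_metaphase([10, 8], [40, 30]))
        avg = average_karyotypes([k, k, k])
        for orig, a in zip(k.records, avg.records):
            assert a.mean_L == pytest.approx(orig.L)
            assert a.sd_L == 0 and a.n == 3

    def test_sample_sd_uses_n_minus_one(self):
        k1 = build_karyotype(straight_metaphase([10], mp_id="a"))
        k2 = build_karyotype(straight_metaphase([12], mp_id="b"))
        avg = average_karyotypes([k1, k2])
        assert avg.records[0].mean_L == pytest.approx(11.0)
        assert avg.records[0].sd_L == pytest.approx(2 ** 0.5)

    def test_matches_per_name_oracle(self, rng):
        ks = self._karyos(rng, n_k=5)
        avg = average_karyotypes(ks)
        by_name = {r.name: r for r in avg.records}
        names = {r.name for k in ks for r in k.records}
        for name in names:
            vals = [r.L for k in ks for r in k.records if r.name == name]
            mean, sd = oracle_group_stats(vals)
            assert by_name[name].mean_L == pytest.approx(mean, rel=1e-12)
            assert by_name[name].sd_L == pytest.approx(sd, rel=1e-9)
            assert by_name[name].n == len(vals)

    def test_permutation_invariant(self, rng):
        ks = self._karyos(rng)
        a = average_karyotypes(ks)
        b = average_karyotypes(ks[::-1])
        for ra, rb in zip(a.records, b.records):
            assert ra.name == rb.name
            assert ra.mean_L == pytest.approx(rb.mean_L)
            assert ra.sd_CI == pytest.approx(rb.sd_CI)

    def test_partially_present_chromosome_kept_with_warning(self):
        k1 = build_karyotype(straight_metaphase([10, 8], mp_id="a"))
        k2 = build_karyotype(straight_metaphase([10, 8, 6], mp_id="b"))
        with pytest.warns(UserWarning, match="only some"):
            avg = average_karyotypes([k1, k2])
        by_name = {r.name: r for r in avg.records}
        assert by_name["3"].n == 1

    def test_disjoint_names_rejected(self):
        k1 = build_karyotype(straight_metaphase([10]), keep_names=True)
        k1.records[0].name = "A"
        k2 = build_karyotype(straight_metaphase([10]), keep_names=True)
        k2.records[0].name = "B"
        with pytest.raises(MeasurementError, match="shared"):
            average_karyotypes([k1, k2])

    def test_mean_ci_stays_in_range(self, rng):
        ks = self._karyos(rng)
        avg = average_karyotypes(ks)
        for r in avg.records:
            assert 0 <= r.mean_CI <= 50
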