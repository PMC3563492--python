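import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvpath.popdiff import (CN_CATEGORIES, StateFrequencies, empirical_cutoff,
                             fst, fst_table, frequency_table,
                             polymorphism_frequency, state_frequencies)
from oracles import fst_brute_force


def sf(pop, counts):
    counts = np.asarray(counts, dtype=np.int64)
    return StateFrequencies(pop, counts, int(counts.sum()))


class TestStateFrequencies:
    def test_basic_counting(self, tiny_genotypes):
        f = state_frequencies(tiny_genotypes, "cnv1", "CEU")
        assert f.N == 4
        assert f.as_dict()["A2"] == pytest.approx(0.75)
        assert f.as_dict()["A3"] == pytest.approx(0.25)

    def test_high_cn_binned(self, tiny_genotypes):
        f = state_frequencies(tiny_genotypes, "cnv2", "CEU")
        # CN 5, 6, 7 all collapse into >A4
        assert f.as_dict()[">A4"] == pytest.approx(0.75)

    def test_missing_excluded_from_n(self, tiny_genotypes):
        f = state_frequencies(tiny_genotypes, "cnv2", "YRI")
        assert f.N == 3  # one NA dropped

    def test_all_missing_is_an_error(self, tiny_genotypes):
        tiny_genotypes.cn.loc["cnv2", ["ASN0", "ASN1"]] = None
        with pytest.raises(ValueError, match="no genotypes"):
            state_frequencies(tiny_genotypes, "cnv2", "ASN")


class TestFst:
    def test_identical_frequencies_zero(self):
        f = sf("CEU", [0, 10, 70, 20, 0, 0])
        assert fst(f, sf("YRI", [0, 10, 70, 20, 0, 0])).fst == 0.0

    def test_fixed_distinct_states_one(self):
        r = fst(sf("CEU", [0, 0, 100, 0, 0, 0]), sf("YRI", [0, 0, 0, 100, 0, 0]))
        assert r.fst == 1.0
        assert r.Ht == pytest.approx(0.5)
        assert r.Hs == 0.0

    def test_hand_derived_case(self):
        r = fst(sf("CEU", [0, 0, 80, 20, 0, 0]), sf("YRI", [0, 0, 20, 80, 0, 0]))
        assert r.Ht == pytest.approx(0.5, abs=1e-12)
        assert r.Hs == pytest.approx(0.32, abs=1e-12)
        assert r.fst == pytest.approx(0.36, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = sf("CEU", rng.integers(0, 50, size=6) + 1)
            b = sf("YRI", rng.integers(0, 50, size=6) + 1)
            assert fst(a, b).fst == fst(b, a).fst

    def test_matches_brute_force_oracle(self):
        from conftest import rand_freq_table
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            x, y, nx, ny = rand_freq_table(rng)
            fx = StateFrequencies("CEU", x * nx, nx)
            fy = StateFrequencies("YRI", y * ny, ny)
            r = fst(fx, fy)
            Ht, Hs, f = fst_brute_force(x, y, nx, ny)
            assert abs(r.fst - f) < 1e-12

    @given(st.integers(0, 1_000_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_fst_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = sf("CEU", rng.integers(0, 30, size=6) + [1, 0, 0, 0, 0, 0])
        b = sf("YRI", rng.integers(0, 30, size=6) + [1, 0, 0, 0, 0, 0])
        assert 0.0 <= fst(a, b).fst <= 1.0


class TestEmpiricalCutoff:
    def test_uniform_grid_rank(self):
        values = np.arange(100) / 100  # 0.00 .. 0.99
        raw, rounded = empirical_cutoff(values, 0.05)
        assert raw == pytest.approx(0.95)
        assert rounded == 0.95

    def test_constant_vector(self):
        raw, _ = empirical_cutoff(np.full(37, 0.42), 0.1)
        assert raw == pytest.approx(0.42)

    def test_cutoff_leaves_at_most_tail_fraction_above(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.random(int(rng.integers(10, 500)))
            for tail in (0.05, 0.01):
                raw, _ = empirical_cutoff(vals, tail)
                assert (vals >= raw).mean() <= tail or raw == vals.max()


class TestPolymorphismFrequency:
    def test_monomorphic_everywhere_zero(self, tiny_genotypes):
        tiny_genotypes.cn.loc["cnv1"] = 2
        for f in polymorphism_frequency(tiny_genotypes, "cnv1"):
            assert f.freq == 0.0
            assert f.major_state == "A2"

    def test_reference_major_state_drives_all_populations(self, tiny_genotypes):
        # CEU mostly CN2, YRI mostly CN3 -> major A2; YRI freq is high
        freqs = {f.population: f for f in
                 polymorphism_frequency(tiny_genotypes, "cnv1")}
        assert freqs["CEU"].major_state == "A2"
        assert freqs["CEU"].freq == pytest.approx(0.25)
        assert freqs["YRI"].freq == pytest.approx(0.75)

    def test_tie_breaks_to_lower_cn_state(self, tiny_genotypes):
        tiny_genotypes.cn.loc["cnv1", ["CEU0", "CEU1"]] = 1
        tiny_genotypes.cn.loc["cnv1", ["CEU2", "CEU3"]] = 3
        freqs = polymorphism_frequency(tiny_genotypes, "cnv1")
        assert freqs[0].major_state == "A1"

    def test_frequencies_in_unit_interval(self, small_sim):
        df = frequency_table(small_sim.genotypes)
        vals = df.to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        assert ((vals[ok] >= 0) & (vals[ok] <= 1)).all()
        # reference population always retains some mass on its major state
        assert (df["CEU"].dropna() < 1).all()


class TestFstTable:
    def test_balding_nichols_divergence_is_monotone(self):
        from cnvpath.data_io import CnvRecord
        from cnvpath.simulate import GroundTruth, SimConfig, simulate_genotypes

        cnvs = [CnvRecord(f"c{i}", "chr1", i * 1000, i * 1000 + 500)
                for i in range(60)]
        means = []
        for F in (0.05, 0.2, 0.4):
            cfg = SimConfig(seed=21, baseline_f=F, missing_rate=0.0,
                            pop_sizes={"CEU": 180, "YRI": 180})
            gm = simulate_genotypes(cfg, cnvs, GroundTruth())
            means.append(fst_table(gm, pairs=[("CEU", "YRI")])
                         ["fst_CEU_YRI"].mean())
        assert means[0] < means[1] < means[2]

    def test_undifferentiated_populations_have_low_fst(self):
        from cnvpath.data_io import CnvRecord
        from cnvpath.simulate import GroundTruth, SimConfig, simulate_genotypes

        cnvs = [CnvRecord(f"c{i}", "chr1", i * 1000, i * 1000 + 500)
                for i in range(100)]
        cfg = SimConfig(seed=5, baseline_f=0.0, missing_rate=0.0,
                        pop_sizes={"CEU": 180, "YRI": 180})
        gm = simulate_genotypes(cfg, cnvs, GroundTruth())
        assert fst_table(gm, pairs=[("CEU", "YRI")])["fst_CEU_YRI"].mean() < 0.02

    def test_diallelic_filter_drops_multistate(self, tiny_genotypes):
        # cnv2's CN 5/6/7 all bin into >A4, so it stays diallelic; adding a
        # CN 3 individual makes it three categories and drops it
        assert "cnv2" in fst_table(tiny_genotypes, diallelic_only=True).index
        tiny_genotypes.cn.loc["cnv2", "YRI0"] = 3
        df = fst_table(tiny_genotypes, diallelic_only=True)
        assert "cnv2" not in df.index
        assert "cnv1" in df.index
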