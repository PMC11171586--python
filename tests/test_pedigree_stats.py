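import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svcoseg.core_model import Individual, Pedigree, Phenotype, SegregationScheme
from svcoseg.pedigree_stats import (
    ExonicFraction,
    ObsProbability,
    SegProbability,
    bonferroni_factor,
    estimate_p_exvar,
    p_obs_multi,
    p_obs_single,
    p_seg_enumerate,
    p_seg_montecarlo,
    round_report,
)

from conftest import make_nuclear, oracle_pseg, random_small_pedigree


class FakeContext:
    def __init__(self, exonic):
        self.is_exonic = exonic


class TestEnumerate:
    def test_two_carriers_two_noncarriers(self):
        # Oracle: 2^4 equiprobable transmission outcomes, exactly one matches.
        ped, scheme = make_nuclear(n_children=4, carriers=2, noncarriers=2)
        sp = p_seg_enumerate(ped, scheme)
        assert sp.p_seg == 0.0625
        assert sp.method == "enumeration"
        assert sp.origin_founder in ("f", "m")

    def test_origin_founder_only(self):
        ped = Pedigree("W")
        ped.add(Individual("f", "W", genotyped=True, phenotype=Phenotype.GTS))
        s = SegregationScheme("s", frozenset({"f"}), frozenset())
        sp = p_seg_enumerate(ped, s)
        assert sp.p_seg == 1.0 and sp.origin_founder == "f"

    def test_one_carrier_one_noncarrier(self):
        ped, scheme = make_nuclear(n_children=2, carriers=1, noncarriers=1)
        assert p_seg_enumerate(ped, scheme).p_seg == 0.25

    def test_meiosis_cap(self):
        ped, scheme = make_nuclear(n_children=12, carriers=6, noncarriers=6)
        with pytest.raises(ValueError, match="[Mm]onte"):
            p_seg_enumerate(ped, scheme, max_meioses=22)
        # Above the default cap it still enumerates when allowed explicitly.
        assert p_seg_enumerate(ped, scheme, max_meioses=24).p_seg == 0.5**12

    def test_unreachable_pattern_gives_zero_with_warning(self, caplog):
        # Carriers in two branches that share no single founder.
        ped = Pedigree("U")
        for fid in ("f1", "m1", "f2", "m2"):
            ped.add(Individual(fid, "U"))
        ped.add(Individual("a", "U", father_id="f1", mother_id="m1", genotyped=True,
                           phenotype=Phenotype.GTS))
        ped.add(Individual("b", "U", father_id="f2", mother_id="m2", genotyped=True,
                           phenotype=Phenotype.GTS))
        s = SegregationScheme("s", frozenset({"a", "b"}), frozenset())
        sp = p_seg_enumerate(ped, s)
        assert sp.p_seg == 0.0 and sp.origin_founder is None

    def test_matches_bruteforce_oracle_on_random_pedigrees(self, rng):
        for _ in range(25):
            ped, scheme = random_small_pedigree(rng, max_nonfounders=5)
            assert p_seg_enumerate(ped, scheme, max_meioses=24).p_seg == pytest.approx(
                oracle_pseg(ped, scheme), abs=0
            )

    def test_informative_chain_powers_of_two(self):
        # Every printed study value is a power of two; an informative chain
        # of m constrained meioses must give exactly (1/2)^m.
        for m, expected in [(2, 0.250), (3, 0.125), (5, 0.03125), (10, 0.000976562)]:
            ped, scheme = make_nuclear(n_children=m, carriers=m // 2, noncarriers=m - m // 2)
            assert p_seg_enumerate(ped, scheme, max_meioses=2 * m).p_seg == pytest.approx(
                0.5**m, rel=1e-12
            )


class TestMonteCarlo:
    def test_agrees_with_enumeration(self):
        ped, scheme = make_nuclear(n_children=4, carriers=2, noncarriers=2)
        mc = p_seg_montecarlo(ped, scheme, n_draws=100_000, seed=11)
        assert mc.method == "monte_carlo" and mc.mc_stderr is not None
        assert abs(mc.p_seg - 0.0625) <= 3 * mc.mc_stderr

    def test_reproducible_under_seed(self):
        ped, scheme = make_nuclear()
        a = p_seg_montecarlo(ped, scheme, n_draws=2000, seed=5)
        b = p_seg_montecarlo(ped, scheme, n_draws=2000, seed=5)
        assert a.p_seg == b.p_seg

    def test_founder_only_all_draws_succeed(self):
        ped = Pedigree("W")
        ped.add(Individual("f", "W", genotyped=True, phenotype=Phenotype.GTS))
        s = SegregationScheme("s", frozenset({"f"}), frozenset())
        assert p_seg_montecarlo(ped, s, n_draws=1000, seed=0).p_seg == 1.0

    def test_rejects_tiny_draw_count(self):
        ped, scheme = make_nuclear()
        with pytest.raises(ValueError, match="1000"):
            p_seg_montecarlo(ped, scheme, n_draws=10, seed=0)

    def test_empty_carrier_scheme_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SegregationScheme("s", frozenset(), frozenset({"x"}))


class TestExonicFraction:
    def test_study_fraction(self):
        labels = [FakeContext(True)] * 388 + [FakeContext(False)] * 9612
        ef = estimate_p_exvar(labels)
        assert ef.p_exvar == pytest.approx(0.0388)
        assert (ef.n_exonic, ef.n_total) == (388, 10000)

    def test_all_and_none(self):
        assert estimate_p_exvar([FakeContext(True)] * 3).p_exvar == 1.0
        assert estimate_p_exvar([FakeContext(False)] * 3).p_exvar == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_p_exvar([])


class TestObsSingle:
    @pytest.mark.parametrize(
        "p_seg,expected",
        [(0.250, 0.0097), (0.03125, 0.0012), (0.0625, 0.0024), (0.125, 0.0049)],
    )
    def test_printed_values(self, p_seg, expected):
        assert round_report(p_obs_single(p_seg, 0.0388).p_obs) == expected

    def test_zero(self):
        assert p_obs_single(0.0, 0.5).p_obs == 0.0


class TestBonferroni:
    def test_pairs_and_triples_of_17(self):
        assert bonferroni_factor(17, 2) == 136
        assert bonferroni_factor(17, 3) == 680

    def test_full_subset(self):
        assert bonferroni_factor(9, 9) == 1

    def test_k_above_f(self):
        with pytest.raises(ValueError):
            bonferroni_factor(3, 4)


class TestObsMulti:
    def test_two_families(self):
        obs = p_obs_multi([0.250, 0.125], maf=0.0196, F=17)
        assert round_report(obs.p_obs) == 0.0833
        assert obs.bonferroni == 136 and obs.p_var == 0.0196

    def test_three_families(self):
        obs = p_obs_multi([0.0625, 0.0156, 0.0625], maf=0.0294, F=17)
        assert round_report(obs.p_obs) == 4e-05
        assert obs.bonferroni == 680

    def test_zero_maf_is_na_by_default(self):
        obs = p_obs_multi([0.25, 0.25], maf=0.0, F=17)
        assert math.isnan(obs.p_obs)

    def test_zero_maf_override(self):
        obs = p_obs_multi([0.25, 0.25], maf=0.0, F=17, zero_maf_pvar=0.0115)
        assert obs.p_obs == pytest.approx(0.25 * 0.25 * 0.0115 * 136)

    def test_single_family_rejected(self):
        with pytest.raises(ValueError, match="single"):
            p_obs_multi([0.5], maf=0.1, F=17)

    @given(
        p1=st.floats(0.01, 1.0),
        p2=st.floats(0.01, 1.0),
        maf=st.floats(0.001, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_argument(self, p1, p2, maf):
        base = p_obs_multi([p1, p2], maf=maf, F=17).p_obs
        assert p_obs_multi([min(1.0, p1 * 1.1), p2], maf=maf, F=17).p_obs >= base
        assert p_obs_multi([p1, p2], maf=min(0.99, maf * 1.1), F=17).p_obs >= base

    @given(
        p_segs=st.lists(st.floats(0.001, 1.0), min_size=2, max_size=5),
        maf=st.floats(0.0001, 0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_product_invariant(self, p_segs, maf):
        obs = p_obs_multi(p_segs, maf=maf, F=17)
        manual = math.prod(p_segs) * maf ** (len(p_segs) - 1) * bonferroni_factor(17, len(p_segs))
        assert abs(obs.p_obs - manual) <= 1e-12


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.00485, 0.0049),       # half rounds away from zero
            (0.002425, 0.0024),
            (0.1041666, 0.1042),
            (3.582e-05, 4e-05),      # below 1e-4: one significant digit
            (0.0, 0.0),
        ],
    )
    def test_report_rounding(self, value, expected):
        assert round_report(value) == expected


class TestDataclassInvariants:
    def test_segprob_stderr_requires_mc(self):
        with pytest.raises(ValueError):
            SegProbability("A", "s", 0.5, "f", "enumeration", mc_stderr=0.01)

    def test_exonic_fraction_consistency(self):
        with pytest.raises(ValueError):
            ExonicFraction(p_exvar=0.5, n_exonic=1, n_total=10)

    def test_obs_product_checked(self):
        sp = SegProbability("A", "s", 0.5, "f", "enumeration")
        with pytest.raises(ValueError, match="recompute"):
            ObsProbability(p_obs=0.9, p_segs=[sp], p_exvar=0.0388)

    def test_obs_requires_exactly_one_form(self):
        sp = SegProbability("A", "s", 0.5, "f", "enumeration")
        with pytest.raises(ValueError, match="exactly one"):
            ObsProbability(p_obs=0.5, p_segs=[sp])


class TestMonteCarloVsEnumerationProperty:
    def test_small_cohort_agreement(self, rng):
        # Scaled-down version of the acceptance property: 12 random
        # pedigrees, MC within 3 stderr of exact in >= 95% of non-degenerate
        # cases (here: all but at most one).
        misses = 0
        checked = 0
        for i in range(12):
            ped, scheme = random_small_pedigree(rng, max_nonfounders=5)
            exact = p_seg_enumerate(ped, scheme, max_meioses=24).p_seg
            mc = p_seg_montecarlo(ped, scheme, n_draws=20_000, seed=i)
            stderr = max(mc.mc_stderr, 1e-9)
            checked += 1
            if abs(mc.p_seg - exact) > 3 * stderr:
                misses += 1
        assert misses <= 1, f"{misses}/{checked} outside 3 stderr"
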