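"""Hypergeometric gene-set enrichment and K-S dPSI comparisons."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from spliceswitch import (
    DifferentialCall,
    SubstrateSet,
    hypergeometric_enrichment,
    ks_delta_psi,
)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct enumeration with exact binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


def ks_d_oracle(xs, ys):
    """Max ECDF gap scanned over every sample point (O(n^2))."""
    best = 0.0
    for t in list(xs) + list(ys):
        fx = sum(1 for v in xs if v <= t) / len(xs)
        fy = sum(1 for v in ys if v <= t) / len(ys)
        best = max(best, abs(fx - fy))
    return best


def _set(name, genes):
    return SubstrateSet(set_name=name, gene_ids=frozenset(genes))


def _call(event_id, gene_id, dpsi):
    return DifferentialCall(
        event_id=event_id, category="SE", gene_id=gene_id, bf=50.0,
        delta_psi_pooled=dpsi, replicate_delta_psis=(dpsi,) * 3,
        direction="included" if dpsi > 0 else "excluded", significant=True,
    )


class TestHypergeometric:
    def test_small_instance_exact_tail(self):
        universe = [f"g{i}" for i in range(10)]
        result = hypergeometric_enrichment(
            universe[:4], _set("s", universe[:5]), universe
        )
        # all 4 drawn genes inside the 5-member set: C(5,4)*C(5,0)/C(10,4)
        assert result.p_value == pytest.approx(hypergeom_tail_oracle(4, 10, 5, 4), abs=1e-12)
        assert result.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_no_differential_genes_gives_unit_p(self):
        universe = [f"g{i}" for i in range(8)]
        result = hypergeometric_enrichment([], _set("s", universe[:3]), universe)
        assert result.k == 0
        assert result.p_value == 1.0

    def test_saturated_set_gives_unit_p(self):
        universe = [f"g{i}" for i in range(8)]
        result = hypergeometric_enrichment(universe[:4], _set("s", universe), universe)
        assert result.k == result.n
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n,k", [(30, 10, 8, 5), (50, 20, 15, 10), (12, 6, 6, 2)])
    def test_matches_enumeration_oracle(self, N, K, n, k):
        universe = [f"g{i}" for i in range(N)]
        members = universe[:K]
        diff = members[:k] + universe[K : K + (n - k)]
        result = hypergeometric_enrichment(diff, _set("s", members), universe)
        assert (result.k, result.n, result.K, result.N) == (k, n, K, N)
        assert result.p_value == pytest.approx(
            hypergeom_tail_oracle(k, N, K, n), abs=1e-9
        )

    def test_pmf_sums_to_one_over_support(self):
        N, K, n = 40, 12, 9
        support = range(max(0, n + K - N), min(n, K) + 1)
        total = sum(stats.hypergeom.pmf(k, N, K, n) for k in support)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_set_intersected_with_universe(self):
        universe = ["g1", "g2", "g3", "g4"]
        result = hypergeometric_enrichment(
            ["g1"], _set("s", ["g1", "gX", "gY"]), universe
        )
        assert result.K == 1  # gX, gY outside the universe are dropped

    def test_differential_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["gZ"], _set("s", ["g1"]), ["g1", "g2"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], _set("s", ["g1"]), [])


class TestKsDeltaPsi:
    def test_identical_distributions_give_zero_d(self):
        calls = [_call(f"e{i}", f"gA{i}", 0.3) for i in range(5)]
        calls += [_call(f"f{i}", f"gB{i}", 0.3) for i in range(5)]
        res = ks_delta_psi(calls, _set("s", [f"gA{i}" for i in range(5)]))
        assert res.d_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_unit_d(self):
        calls = [_call(f"e{i}", f"gA{i}", 0.8) for i in range(6)]
        calls += [_call(f"f{i}", f"gB{i}", 0.1) for i in range(6)]
        res = ks_delta_psi(calls, _set("s", [f"gA{i}" for i in range(6)]))
        assert res.d_statistic == 1.0
        assert res.p_value < 0.01

    def test_matches_brute_force_ecdf_scan(self):
        xs = [0.12, 0.33, 0.41, 0.52, 0.63, 0.74]
        ys = [0.05, 0.31, 0.45, 0.58, 0.66, 0.91]
        calls = [_call(f"e{i}", f"gA{i}", v) for i, v in enumerate(xs)]
        calls += [_call(f"f{i}", f"gB{i}", v) for i, v in enumerate(ys)]
        res = ks_delta_psi(calls, _set("s", [f"gA{i}" for i in range(6)]))
        assert res.d_statistic == pytest.approx(ks_d_oracle(xs, ys), abs=1e-12)

    def test_signed_mode_separates_sign_flips(self):
        calls = [_call(f"e{i}", f"gA{i}", -0.4) for i in range(6)]
        calls += [_call(f"f{i}", f"gB{i}", 0.4) for i in range(6)]
        sub = _set("s", [f"gA{i}" for i in range(6)])
        assert ks_delta_psi(calls, sub, "absolute").d_statistic == 0.0
        assert ks_delta_psi(calls, sub, "signed").d_statistic == 1.0

    def test_empty_group_is_untested(self):
        calls = [_call(f"e{i}", f"gA{i}", 0.3) for i in range(4)]
        res = ks_delta_psi(calls, _set("s", ["gZ"]))
        assert math.isnan(res.p_value)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ks_delta_psi([], _set("s", ["g"]), "median")


class TestPlantedRecovery:
    def _sets(self, sim_main):
        gene_by_event = sim_main["gene_by_event"]
        sets = {}
        for rbp in ("hnRNPA2", "MSI2", "CELF1"):
            genes = {
                gene_by_event[t.event_id]
                for t in sim_main["truth"]
                if rbp in t.substrate_of
            }
            sets[rbp] = _set(rbp, genes)
        return sets

    def test_planted_substrate_enrichment_detected(self, sim_main):
        """All three RBP sets are planted with 3x membership odds among
        differentially spliced genes; a size-matched random set is not."""
        contrast = sim_main["treatment"]
        universe = {c.gene_id for c in contrast.calls if c.testable}
        diff_genes = {c.gene_id for c in contrast.significant_calls()}
        sets = self._sets(sim_main)
        for rbp, s in sets.items():
            res = hypergeometric_enrichment(diff_genes, s, universe)
            assert res.p_value <= 0.05, rbp
        rng = np.random.default_rng(7)
        control_genes = rng.choice(
            sorted(universe), size=len(sets["hnRNPA2"].gene_ids), replace=False
        )
        control = hypergeometric_enrichment(
            diff_genes, _set("control", control_genes), universe
        )
        assert control.p_value > 0.05

    def test_magnitude_shift_flags_only_hnrnpa2(self, sim_main):
        """Only hnRNPA2 substrates carry a planted |dpsi| shift, so the K-S
        magnitude test flags hnRNPA2 and neither of the other two sets."""
        calls = sim_main["treatment"].significant_calls()
        sets = self._sets(sim_main)
        res = {rbp: ks_delta_psi(calls, s) for rbp, s in sets.items()}
        assert res["hnRNPA2"].p_value <= 0.05
        assert res["MSI2"].p_value > 0.05
        assert res["CELF1"].p_value > 0.05
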