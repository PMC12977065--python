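import math

import numpy as np
import pytest

from racerts.errors import ValidationError
from racerts.metrics import (
    R_KCAL,
    ClusterStats,
    RmsdDistribution,
    TimingRecord,
    boltzmann_average,
    butina_cluster,
    combine_ensembles,
    comp_cost,
    delta_e_lowe,
    delta_e_marc,
    js_divergence,
    space_distribution,
    space_exploration,
    success_rate,
    top_n_accuracy,
    tukey_summary,
)
from racerts.pruning import rmsd
from racerts.structure_io import Ensemble, Member, Structure

from conftest import distinct_conformers, random_ensemble, random_structure
from helpers import brute_force_butina, direct_js, exhaustive_prune_rmsd


class TestCompCost:
    def test_self_is_one(self):
        t = {"r1": 10.0, "r2": 20.0}
        assert comp_cost(t, t) == pytest.approx(1.0)

    def test_mean_of_ratios(self):
        assert comp_cost({"a": 2.0, "b": 8.0}, {"a": 1.0, "b": 2.0}) == pytest.approx(3.0)

    def test_synthetic_table(self, rng):
        ref = {f"r{k}": float(rng.uniform(1, 10)) for k in range(5)}
        mine = {k: v * float(rng.uniform(0.5, 4)) for k, v in ref.items()}
        expected = np.mean([mine[k] / ref[k] for k in sorted(mine)])
        assert comp_cost(mine, ref) == pytest.approx(expected)

    def test_missing_pairing(self):
        with pytest.raises(ValidationError):
            comp_cost({"a": 1.0}, {"b": 1.0})

    def test_timing_record_validation(self):
        with pytest.raises(ValidationError):
            TimingRecord("m", "r", 0.0)


class TestCombineEnsembles:
    def test_idempotent_on_identical(self, rng):
        e = random_ensemble(rng, n_members=5)
        combined = combine_ensembles([e, e])
        alone = combine_ensembles([e])
        assert [m.energy for m in combined] == [m.energy for m in alone]

    def test_disjoint_union_within_window(self, rng):
        base = random_structure(rng, 5)
        a = Ensemble([Member(base.with_coords(base.coords + 0.0), 0.0, "a0")])
        far = base.with_coords(base.coords + rng.normal(scale=1.5, size=(5, 3)))
        b = Ensemble([Member(far, 1.0, "b0")])
        combined = combine_ensembles([a, b])
        assert {m.label for m in combined} == {"a0", "b0"}

    def test_overlapping_matches_exhaustive_oracle(self, rng):
        base = random_structure(rng, 5)
        ens = []
        for _ in range(3):
            ens.append(random_ensemble(rng, base=base, n_members=6, spread=0.1))
        combined = combine_ensembles(ens)
        members = sorted(
            (m for e in ens for m in e), key=lambda m: m.energy
        )
        emin = members[0].energy
        members = [m for m in members if m.energy - emin <= 6.0]
        oracle = exhaustive_prune_rmsd(members, rmsd, 0.125)
        assert [m.label for m in combined] == [m.label for m in oracle]

    def test_mixed_atom_lists_rejected(self, rng):
        a = Ensemble([Member(Structure(["C"], np.zeros((1, 3))), 0.0)])
        b = Ensemble([Member(Structure(["O"], np.zeros((1, 3))), 0.0)])
        with pytest.raises(ValidationError):
            combine_ensembles([a, b])


class TestButina:
    def _structs_at(self, rng, centers, scale=0.01):
        base = random_structure(rng, 4)
        out = []
        for c in centers:
            out.append(base.with_coords(base.coords + np.asarray(c)))
        return out

    def test_all_close_one_cluster(self, rng):
        mat = np.full((5, 5), 0.3)
        np.fill_diagonal(mat, 0.0)
        clusters = butina_cluster([None] * 5, 1.0, precomputed=mat)
        assert len(clusters) == 1 and sorted(clusters[0]) == [0, 1, 2, 3, 4]

    def test_all_far_singletons(self, rng):
        mat = np.full((4, 4), 5.0)
        np.fill_diagonal(mat, 0.0)
        clusters = butina_cluster([None] * 4, 1.0, precomputed=mat)
        assert len(clusters) == 4

    def test_partition_property(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(2, 9))
            pts = r.uniform(0, 4, size=(n, 2))
            mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            clusters = butina_cluster([None] * n, 1.0, precomputed=mat)
            flat = [i for c in clusters for i in c]
            assert sorted(flat) == list(range(n))

    def test_matches_brute_force_oracle(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(2, 9))
            pts = r.uniform(0, 3, size=(n, 2))
            mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            ours = butina_cluster([None] * n, 1.0, precomputed=mat)
            oracle = brute_force_butina(mat.tolist(), 1.0)
            assert ours == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            butina_cluster([], 1.0)


class TestSpaceExploration:
    def test_self_comparison_perfect(self, rng):
        base = random_structure(rng, 5)
        e = random_ensemble(rng, base=base, n_members=5, spread=0.8)
        combined = combine_ensembles([e])
        stats = space_exploration({"me": combined}, combined)["me"]
        assert stats.precision == 1.0
        assert stats.recall == 1.0
        assert stats.f1 == 1.0

    def test_partial_cluster_coverage_algebra(self, rng):
        # method matching c of C clusters with all members matched:
        # F1 = 2(c/C) / (1 + c/C)
        base = random_structure(rng, 5)
        members = [
            Member(s, float(k) * 0.5, f"c{k}")
            for k, s in enumerate(distinct_conformers(base, 4))
        ]
        combined = Ensemble(members)
        method = Ensemble(members[:2])
        stats = space_exploration({"m": method}, combined, cluster_threshold=1.0)["m"]
        c_over_C = 2 / 4
        assert stats.precision == 1.0
        assert stats.recall == pytest.approx(c_over_C)
        assert stats.f1 == pytest.approx(2 * c_over_C / (1 + c_over_C))

    def test_zero_matches_zero_f1(self, rng):
        base = random_structure(rng, 5)
        combined = Ensemble([Member(base, 0.0, "a")])
        off = base.with_coords(base.coords + rng.normal(scale=2.0, size=(5, 3)))
        method = Ensemble([Member(off, 50.0, "x")])
        stats = space_exploration({"m": method}, combined)["m"]
        assert stats.f1 == 0.0

    def test_empty_combined_rejected(self, rng):
        with pytest.raises(ValidationError):
            space_exploration({}, Ensemble([]))


class TestJsDivergence:
    def test_identical_zero(self):
        p = np.array([1, 2, 3, 4.0])
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_one(self):
        assert js_divergence([1, 0, 2, 0.0], [0, 3, 0, 1.0]) == pytest.approx(1.0)

    def test_half_overlap_vs_direct_oracle(self):
        p = np.array([2.0, 2.0, 0.0, 0.0])
        q = np.array([0.0, 2.0, 2.0, 0.0])
        assert js_divergence(p, q) == pytest.approx(direct_js(p, q), abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=8)
            q = rng.uniform(0, 1, size=8)
            a, b = js_divergence(p, q), js_divergence(q, p)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 1.0 + 1e-12

    def test_space_distribution_identical_zero(self, rng):
        d = RmsdDistribution(rng.uniform(0, 3, size=30))
        assert space_distribution(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_space_distribution_disjoint_one(self):
        a = RmsdDistribution(np.array([0.1, 0.2]))
        b = RmsdDistribution(np.array([2.1, 2.2]))
        assert space_distribution(a, b) == pytest.approx(1.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValidationError):
            RmsdDistribution(np.array([]))


class TestSuccessRate:
    def test_all_successful(self):
        assert success_rate([(3, 3), (2, 2)]).value == pytest.approx(1.0)

    def test_mean_fraction(self):
        sr = success_rate([(2, 2), (1, 2)])
        assert sr.value == pytest.approx(0.75)
        assert sr.n_reactions_with_success == 2

    def test_synthetic_table(self, rng):
        rows = [(int(rng.integers(0, 5)), 5) for _ in range(10)]
        sr = success_rate(rows)
        assert sr.value == pytest.approx(np.mean([a / b for a, b in rows]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            success_rate([(0, 0)])


class TestTopN:
    def _member(self, rng, energy, base=None, shift=0.0):
        base = base or random_structure(rng, 4)
        return Member(base.with_coords(base.coords + shift), energy, "x"), base

    def test_rank_one_hit(self, rng):
        m, base = self._member(rng, 0.0)
        rankings = {"a": [[m]]}
        assert top_n_accuracy(rankings, [m], 1)["a"] == 1.0
        assert top_n_accuracy(rankings, [m], 5)["a"] == 1.0

    def test_rank_four_top5_only(self, rng):
        best, base = self._member(rng, 0.0)
        decoys = [
            Member(s, 0.0, f"d{k}")
            for k, s in enumerate(distinct_conformers(base, 4)[1:])
        ]
        ranking = decoys + [best]
        out1 = top_n_accuracy({"a": [ranking]}, [best], 1)
        out5 = top_n_accuracy({"a": [ranking]}, [best], 5)
        assert out1["a"] == 0.0 and out5["a"] == 1.0

    def test_three_method_scenario_vs_bruteforce(self, rng):
        base = random_structure(rng, 4)
        best = Member(base, 0.0, "best")
        far = Member(base.with_coords(base.coords + 5.0), 9.0, "far")
        rankings = {
            "hit1": [[best, far]],
            "hit2": [[far, best]],
            "miss": [[far, far]],
        }
        out = top_n_accuracy(rankings, [best], 1)
        assert out == {"hit1": 1.0, "hit2": 0.0, "miss": 0.0}
        out5 = top_n_accuracy(rankings, [best], 5)
        assert out5 == {"hit1": 1.0, "hit2": 1.0, "miss": 0.0}

    def test_empty_ranking_is_miss(self, rng):
        m, _ = self._member(rng, 0.0)
        assert top_n_accuracy({"a": [[]]}, [m], 1)["a"] == 0.0


class TestBoltzmann:
    def test_single_energy(self):
        assert boltzmann_average([3.7]) == pytest.approx(3.7)

    def test_two_equal(self):
        assert boltzmann_average([0.0, 0.0]) == pytest.approx(0.0)

    def test_two_state_analytic(self):
        # closed form: <E> = dE / (1 + exp(dE/RT)) for states {0, dE}
        dE, T = 1.0, 298.15
        expected = dE / (1 + math.exp(dE / (R_KCAL * T)))
        assert boltzmann_average([0.0, dE], T) == pytest.approx(expected, abs=1e-12)

    def test_large_gap_collapses_to_min(self):
        assert boltzmann_average([0.0, 100.0], 298.15) == pytest.approx(0.0, abs=1e-10)

    def test_limits(self):
        e = [0.0, 1.0, 4.0]
        assert boltzmann_average(e, 1e-3) == pytest.approx(min(e), abs=1e-6)
        # finite-T deviation at 1e9 K is O(var(E)/RT) ~ 1e-6; allow for it
        assert boltzmann_average(e, 1e9) == pytest.approx(np.mean(e), abs=1e-5)
        assert boltzmann_average(e, 1e12) == pytest.approx(np.mean(e), abs=1e-6)

    def test_bounded_by_min_max(self, rng):
        for _ in range(20):
            e = rng.normal(scale=5, size=6)
            v = boltzmann_average(e, float(rng.uniform(10, 1000)))
            assert e.min() - 1e-9 <= v <= e.max() + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            boltzmann_average([])


class TestDeltaE:
    def test_lowe_holder_is_zero(self):
        out = delta_e_lowe({"a": 1.0, "b": 3.2}, 1.0)
        assert out["a"] == pytest.approx(0.0)
        assert out["b"] == pytest.approx(2.2)

    def test_lowe_excludes_invalid(self, caplog):
        out = delta_e_lowe({"a": None, "b": 2.0}, 1.0)
        assert "a" not in out and out["b"] == pytest.approx(1.0)

    def test_lowe_nonnegative_from_union(self, rng):
        lows = {f"m{k}": float(rng.normal()) for k in range(5)}
        overall = min(lows.values())
        out = delta_e_lowe(lows, overall)
        assert all(v >= 0 for v in out.values())
        medians = tukey_summary(list(out.values()))
        assert medians["median"] == pytest.approx(float(np.median(list(out.values()))))

    def test_marc_subset_equal_union_is_zero(self):
        union = [0.0, 1.0, 2.0]
        out = delta_e_marc({"a": union}, union)
        assert out["a"] == pytest.approx(0.0)

    def test_marc_single_conformer_reduces_to_difference(self):
        out = delta_e_marc({"a": [3.0]}, [1.0])
        assert out["a"] == pytest.approx(2.0)

    def test_marc_composes_boltzmann(self, rng):
        union = sorted(rng.normal(scale=2, size=8).tolist())
        sub = union[:3]
        expected = boltzmann_average(sub) - boltzmann_average(union)
        assert delta_e_marc({"a": sub}, union)["a"] == pytest.approx(expected, abs=1e-12)

    def test_marc_empty_union_rejected(self):
        with pytest.raises(ValidationError):
            delta_e_marc({"a": [1.0]}, [])


class TestClusterStats:
    def test_bounds(self):
        st = ClusterStats(2, 4, 1, 2)
        assert 0 <= st.precision <= 1
        assert 0 <= st.recall <= 1
        assert 0 <= st.f1 <= 1

    def test_f1_zero_iff_product_zero(self):
        assert ClusterStats(0, 5, 0, 3).f1 == 0.0
        assert ClusterStats(5, 5, 3, 3).f1 == 1.0
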