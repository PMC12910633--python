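"""Specialisation indices, overlap, and the auxiliary models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sympatry import niche_stats as ns


def _profile(counts):
    counts = pd.DataFrame(np.atleast_2d(counts))
    props = counts.div(counts.sum(axis=1), axis=0)
    q = counts.sum(axis=0) / counts.to_numpy().sum()
    return ns.HabitatUseProfile(counts=counts, proportions=props, q=q)


class TestProfiles:
    def test_single_habitat_individual(self):
        fixes = pd.DataFrame({"bird_id": "b1", "habitat": ["urban"] * 7})
        prof = ns.habitat_use_profile(fixes)
        assert prof.proportions.loc["b1", "urban"] == 1.0

    def test_proportions_sum_to_one_and_q_pooled(self):
        rng = np.random.default_rng(0)
        fixes = pd.DataFrame({
            "bird_id": rng.choice(["a", "b", "c"], 300),
            "habitat": rng.choice(["urban", "coastal", "marine"], 300),
        })
        prof = ns.habitat_use_profile(fixes)
        np.testing.assert_allclose(prof.proportions.sum(axis=1), 1.0)
        np.testing.assert_allclose(prof.q.sum(), 1.0)
        np.testing.assert_allclose(
            prof.q.to_numpy(),
            prof.counts.sum(axis=0).to_numpy() / prof.counts.to_numpy().sum(),
        )

    def test_matches_generator_truth_counts(self, landscape, sim_small):
        fixes, truth = sim_small
        use = truth.fixes[(truth.fixes.state == "search") & (~truth.fixes.bad_fix)]
        prof = ns.habitat_use_profile(use)
        pd.testing.assert_frame_equal(
            prof.counts.astype(int), truth.habitat_counts.astype(int),
            check_names=False,
        )


class TestProportionalSimilarity:
    def test_population_matching_individual_is_generalist(self):
        assert ns.ps_index([0.3, 0.5, 0.2], [0.3, 0.5, 0.2]) == pytest.approx(1.0)

    def test_specialist_against_uniform_five(self):
        assert ns.ps_index([1, 0, 0, 0, 0], [0.2] * 5) == pytest.approx(0.2)

    def test_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            brute = 1.0 - 0.5 * sum(abs(p[j] - q[j]) for j in range(k))
            assert abs(ns.ps_index(p, q) - brute) < 1e-12

    def test_monte_carlo_reproducible_and_resolution(self):
        rng = np.random.default_rng(2)
        prof = _profile(rng.integers(5, 60, size=(6, 4)))
        r1 = ns.proportional_similarity(prof, n_replicates=999, seed=5)
        r2 = ns.proportional_similarity(prof, n_replicates=999, seed=5)
        assert r1["p_value"] == r2["p_value"]
        assert (r1["p_value"] * 1000) == pytest.approx(round(r1["p_value"] * 1000))
        assert ((r1["psi"] >= 0) & (r1["psi"] <= 1)).all()

    def test_strong_specialists_detected(self):
        # each individual exclusively in its own habitat
        prof = _profile(np.eye(4, dtype=int) * 50)
        r = ns.proportional_similarity(prof, n_replicates=199, seed=0)
        assert r["p_value"] <= 0.01


class TestPianka:
    def test_identical_profiles_high(self):
        o, band = ns.pianka_overlap([0.4, 0.6], [0.4, 0.6])
        assert o == pytest.approx(1.0) and band == "high"

    def test_disjoint_profiles_low(self):
        o, band = ns.pianka_overlap([1, 0, 0], [0, 0, 1])
        assert o == 0.0 and band == "low"

    def test_half_overlap_hand_value_intermediate(self):
        o, band = ns.pianka_overlap([0.5, 0.5, 0], [0, 0.5, 0.5])
        assert o == pytest.approx(0.5, abs=1e-12) and band == "intermediate"

    def test_band_edges(self):
        assert ns.pianka_band(0.39) == "low"
        assert ns.pianka_band(0.395) == "low"
        assert ns.pianka_band(0.40) == "intermediate"
        assert ns.pianka_band(0.605) == "intermediate"
        assert ns.pianka_band(0.61) == "high"

    def test_symmetric_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = rng.integers(2, 8)
            a = rng.dirichlet(np.ones(k))
            b = rng.dirichlet(np.ones(k))
            brute = sum(a[j] * b[j] for j in range(k)) / np.sqrt(
                sum(x * x for x in a) * sum(x * x for x in b)
            )
            o1, _ = ns.pianka_overlap(a, b)
            o2, _ = ns.pianka_overlap(b, a)
            assert abs(o1 - brute) < 1e-12 and abs(o1 - o2) < 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ns.pianka_overlap([0, 0], [1, 0])


class TestKruskalWallis:
    def test_hand_ranked_two_groups(self):
        out = ns.compare_specialization({"a": [1, 2, 3], "b": [4, 5, 6]})
        # H = 12/(N(N+1)) * sum n_g rbar_g^2 - 3(N+1) with ranks 1..6
        assert out["H"] == pytest.approx(12 / 42 * (3 * 2**2 + 3 * 5**2) - 21)
        assert out["df"] == 1

    def test_all_tied_degenerate(self):
        out = ns.compare_specialization({"a": [2, 2], "b": [2, 2]})
        assert out["H"] == 0.0 and out["p_value"] == 1.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            ns.compare_specialization({"a": [1, 2, 3]})


class TestForagingRangeModel:
    def test_recovery_of_species_contrast(self):
        rng = np.random.default_rng(4)
        rows = []
        for sp, mu in [("A", 35.0), ("B", 22.0)]:
            for b in range(12):
                ab = rng.normal(0, 3)
                for _ in range(50):
                    rows.append({
                        "species": sp, "bird_id": f"{sp}{b}", "complete": True,
                        "d_max_km": mu + ab + rng.normal(0, 5),
                    })
        out = ns.foraging_range_model(pd.DataFrame(rows))
        est = out["contrasts"]["estimate_km"].iloc[0]
        assert est == pytest.approx(13.0, abs=2.0)
        assert out["contrasts"]["p"].iloc[0] < 0.001

    def test_identical_species_contrast_near_zero(self):
        rng = np.random.default_rng(5)
        base = rng.normal(20, 4, 200)
        rows = []
        for sp in ("A", "B"):
            for i, v in enumerate(base):
                rows.append({"species": sp, "bird_id": f"{sp}{i % 8}",
                             "complete": True, "d_max_km": v})
        out = ns.foraging_range_model(pd.DataFrame(rows))
        assert out["contrasts"]["estimate_km"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_translation_invariance_of_contrasts(self):
        rng = np.random.default_rng(6)
        rows = []
        for sp, mu in [("A", 30.0), ("B", 18.0)]:
            for b in range(6):
                for _ in range(20):
                    rows.append({"species": sp, "bird_id": f"{sp}{b}",
                                 "complete": True,
                                 "d_max_km": mu + rng.normal(0, 4)})
        tab = pd.DataFrame(rows)
        c1 = ns.foraging_range_model(tab)["contrasts"]["estimate_km"].iloc[0]
        tab2 = tab.assign(d_max_km=tab["d_max_km"] + 100.0)
        c2 = ns.foraging_range_model(tab2)["contrasts"]["estimate_km"].iloc[0]
        assert c1 == pytest.approx(c2, abs=1e-6)

    def test_incomplete_trips_excluded(self):
        tab = pd.DataFrame({
            "species": ["A"] * 4 + ["B"] * 4,
            "bird_id": ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"],
            "complete": [True, False] * 4,
            "d_max_km": [10, 999, 12, 999, 20, 999, 22, 999.0],
        })
        out = ns.foraging_range_model(tab)
        assert abs(out["contrasts"]["estimate_km"].iloc[0]) < 15  # 999s ignored


class TestHarbourLandings:
    def test_proportional_visits_significant(self):
        landings = np.linspace(1000, 9000, 24)
        tab = pd.DataFrame({
            "species": "HERGU", "harbour": "h1", "month": np.arange(24),
            "n_fixes": 0.01 * landings, "landings_kg": landings,
        })
        out = ns.harbour_landings_model(tab)
        assert out["p"].iloc[0] < 0.001
        assert out["slope"].iloc[0] == pytest.approx(0.01)

    def test_constant_visits_zero_slope(self):
        tab = pd.DataFrame({
            "species": "HERGU", "harbour": "h1", "month": np.arange(12),
            "n_fixes": 5.0, "landings_kg": np.linspace(100, 1200, 12),
        })
        out = ns.harbour_landings_model(tab)
        assert out["slope"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        cover = 0
        for rep in range(60):
            tab = pd.DataFrame({
                "species": "S", "harbour": "h", "month": np.arange(24),
                "n_fixes": rng.poisson(20, 24).astype(float),
                "landings_kg": rng.uniform(0, 1000, 24),
            })
            out = ns.harbour_landings_model(tab)
            lo = out["slope"].iloc[0] - 1.96 * out["se"].iloc[0]
            hi = out["slope"].iloc[0] + 1.96 * out["se"].iloc[0]
            cover += int(lo <= 0 <= hi)
        assert cover >= 50  # ~95% nominal

    def test_insufficient_data_rejected(self):
        tab = pd.DataFrame({
            "species": "S", "harbour": "h", "month": [1, 2],
            "n_fixes": [1.0, 2.0], "landings_kg": [10.0, 20.0],
        })
        with pytest.raises(ValueError):
            ns.harbour_landings_model(tab)
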