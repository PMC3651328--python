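"""Iterative precursor selection: matching probabilities, the combined ILP
and the acquisition loop."""

import math

import numpy as np
import pytest

from precsel.baselines import select_sps
from precsel.data_model import (
    FeatureMap,
    PSM,
    PeptideEntry,
    ProteinEntry,
    ValidationError,
    normalize_intensities,
)
from precsel.feature_ilp import build_feature_ilp, solve_feature_ilp
from precsel.ips import (
    IPSParams,
    IPSState,
    build_ips_model,
    build_match_sets,
    matching_probability,
    protein_indicator,
    protein_log_ratio,
    rt_matching_probability,
    run_ips,
    solve_ips_model,
)
from precsel.simulation import SimParams, generate_ground_truth, make_search_oracle

from conftest import make_feature, make_map, sps_equivalence_map


class TestRTMatchingProbability:
    def test_one_sigma_window(self):
        t = 500.0
        assert rt_matching_probability(t, t - 30.0, t + 30.0, mu=0.0, sigma=30.0) == \
            pytest.approx(0.6827, abs=1e-4)

    def test_infinite_window_is_one(self):
        assert rt_matching_probability(100.0, -1e9, 1e9, sigma=30.0) == \
            pytest.approx(1.0, abs=1e-12)

    def test_zero_width_window_is_zero(self):
        assert rt_matching_probability(100.0, 50.0, 50.0, sigma=30.0) == 0.0

    def test_nonzero_mean_shifts_the_window(self):
        # with mu = +30 the error is centred 30 s late: a window around
        # t_p - 30 captures the same +-1 sigma mass
        t = 500.0
        assert rt_matching_probability(t, t - 60.0, t, mu=30.0, sigma=30.0) == \
            pytest.approx(0.6827, abs=1e-4)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            rt_matching_probability(100.0, 0.0, 1.0, sigma=0.0)


class TestMatchingProbability:
    @pytest.mark.parametrize(
        "d,r,expected",
        [(0.0, 0.9, 0.0), (1.0, 0.4, 0.4), (0.5, 0.6827, 0.34135)],
    )
    def test_product(self, d, r, expected):
        assert matching_probability(d, r) == pytest.approx(expected, abs=1e-9)


class TestProteinIndicator:
    def test_threshold_boundary_is_identified(self):
        assert protein_indicator(0.95, 0.95) == 1

    def test_zero_probability(self):
        assert protein_indicator(0.0, 0.95) == 0
        assert protein_log_ratio(0.0, 0.95) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_above_one_when_identified(self):
        ratio = protein_log_ratio(0.99, 0.95)
        assert ratio == pytest.approx(math.log(0.01) / math.log(0.05), abs=1e-9)
        assert ratio > 1.0
        assert protein_indicator(0.99, 0.95) == 1


def _peptide(seq, d, rt, parents, mz=800.0):
    return PeptideEntry(
        sequence=seq, mz_theoretical=mz, predicted_rt=rt,
        detectability=d, parent_accessions=frozenset(parents),
    )


class TestBuildMatchSets:
    def _map(self):
        feats = [
            make_feature("exact", {0: 5.0}, mz=800.0),
            make_feature("close", {0: 4.0}, mz=800.0 + 800.0 * 5e-6),  # +5 ppm
            make_feature("far", {0: 3.0}, mz=810.0),
        ]
        return make_map(feats, 1, cap=3)

    def test_zero_ppm_matches_exact_only(self):
        prot = ProteinEntry("A", "M", peptides=[_peptide("AAAK", 0.5, 15.0, {"A"})])
        (mset,) = build_match_sets([prot], self._map(), ppm=0.0, sigma=30.0)
        assert [fid for fid, _ in mset.features] == ["exact"]

    def test_no_feature_in_window_gives_empty_set(self):
        prot = ProteinEntry("A", "M", peptides=[_peptide("AAAK", 0.5, 15.0, {"A"}, mz=1500.0)])
        (mset,) = build_match_sets([prot], self._map(), ppm=10.0, sigma=30.0)
        assert mset.features == ()

    def test_widening_ppm_never_shrinks_sets(self):
        rng = np.random.default_rng(9)
        prot = ProteinEntry("A", "M", peptides=[_peptide("AAAK", 0.5, 15.0, {"A"})])
        fmap = self._map()
        previous: set[str] = set()
        for ppm in [0.0, 2.0, 5.0, 20.0, 20000.0]:
            (mset,) = build_match_sets([prot], fmap, ppm=ppm, sigma=30.0)
            current = {fid for fid, _ in mset.features}
            assert previous <= current
            previous = current

    def test_probabilities_within_bounds(self):
        prot = ProteinEntry("A", "M", peptides=[_peptide("AAAK", 0.7, 15.0, {"A"})])
        (mset,) = build_match_sets([prot], self._map(), ppm=50.0, sigma=30.0)
        for _fid, m in mset.features:
            assert 0.0 <= m <= 0.7 + 1e-12


class TestIPSModel:
    def test_without_candidates_reduces_to_feature_ilp(self):
        """No protein evidence: the model is the feature ILP plus a budget row."""
        fmap = normalize_intensities(sps_equivalence_map())
        budget = 30
        state = IPSState()
        params = IPSParams(step_size=budget)
        model = build_ips_model(state, fmap, [], params)
        sel_ips, _ = solve_ips_model(model)
        ilp = build_feature_ilp(fmap, budget=budget)
        sel_ilp, _ = solve_feature_ilp(ilp)
        assert sel_ips.selected == sel_ilp.selected

    def test_identified_protein_discounts_matching_features(self):
        """Objective coefficient of a feature matching an identified protein
        drops by k3 * m_{p,j}."""
        feats = [
            make_feature("f1", {0: 100.0}, mz=800.0),
            make_feature("f2", {1: 50.0}, mz=800.0),
        ]
        fmap = normalize_intensities(make_map(feats, 2, cap=2))
        pep = _peptide("AAAK", 0.9, 45.0, {"A"}, mz=800.0)
        prot = ProteinEntry("A", "M", peptides=[pep], probability=0.99)
        state = IPSState(
            fragmented=[("f1", 0)],
            peptide_probs={"AAAK": 0.99},
            protein_probs={"A": 0.99},
            candidates={"A": prot},
        )
        params = IPSParams(k1=10.0, k2=1.0, k3=10.0, c=0.95, step_size=1)
        matches = build_match_sets([prot], fmap, ppm=10.0, sigma=30.0)
        (mset,) = matches
        m_by_fid = dict(mset.features)
        model = build_ips_model(state, fmap, matches, params)
        coefs = model.builder.objective
        v_f2 = model.x_vars[("f2", 1)]
        int_f2 = fmap.features[1].intensity_profile[1]
        expected = params.k2 * int_f2 - params.k3 * m_by_fid["f2"]
        assert coefs[v_f2] == pytest.approx(expected, abs=1e-9)

    def test_z_reaches_one_for_identified_protein(self):
        feats = [make_feature("f1", {0: 100.0})]
        fmap = normalize_intensities(make_map(feats, 1, cap=1))
        pep = _peptide("AAAK", 0.9, 15.0, {"A"}, mz=500.0)
        prot = ProteinEntry("A", "M", peptides=[pep])
        state = IPSState(
            peptide_probs={"AAAK": 0.99},
            protein_probs={"A": 0.99},
            candidates={"A": prot},
        )
        model = build_ips_model(state, fmap, [], IPSParams(step_size=1))
        sol = model.builder.solve()
        assert sol.value(model.z_vars["A"]) == pytest.approx(1.0, abs=1e-6)

    def test_candidate_z_limited_by_log_ratio_without_matches(self):
        feats = [make_feature("f1", {0: 100.0})]
        fmap = normalize_intensities(make_map(feats, 1, cap=1))
        pep = _peptide("AAAK", 0.9, 15.0, {"A"}, mz=500.0)
        prot = ProteinEntry("A", "M", peptides=[pep])
        p_i = 0.5
        state = IPSState(
            peptide_probs={"AAAK": p_i},
            protein_probs={"A": p_i},
            candidates={"A": prot},
        )
        model = build_ips_model(state, fmap, [], IPSParams(step_size=1))
        sol = model.builder.solve()
        assert sol.value(model.z_vars["A"]) == pytest.approx(
            protein_log_ratio(p_i, 0.95), abs=1e-6
        )


class TestRunIPS:
    def test_empty_map_gives_empty_history(self):
        empty = FeatureMap(features=(), n_fractions=1, fraction_rt={0: 15.0})
        assert run_ips(empty, [], lambda fid, s: None) == []

    def test_exclusion_trace_after_first_identification(self):
        """Once the only protein is identified, its second matching feature
        carries negative weight and an unmatched feature wins instead."""
        feats = [
            make_feature("f1", {0: 100.0}, mz=800.0),
            make_feature("f2", {1: 90.0}, mz=800.0),
            make_feature("f3", {1: 10.0}, mz=900.0),
        ]
        fmap = make_map(feats, 2, cap=2)
        pep = _peptide("AAAK", 0.9, 45.0, {"A"}, mz=800.0)
        database = [ProteinEntry("A", "M", peptides=[pep])]

        def oracle(fid, s):
            if fid in ("f1", "f2"):
                return PSM(precursor_ref=fid, peptide_sequence="AAAK",
                           probability=0.99, fraction=s)
            return None

        # small sigma: the error mass concentrates inside f2's RT span, so
        # m_{p,f2} is close to the peptide detectability 0.9
        params = IPSParams(k1=10.0, k2=1.0, k3=10.0, c=0.95, step_size=1,
                           ppm=10.0, rt_sigma=5.0)
        history = run_ips(fmap, database, oracle, params)
        order = [pair for rec in history for pair in rec.selections]
        assert order[0] == ("f1", 0)
        assert ("f2", 1) not in order
        assert ("f3", 1) in order
        assert history[0].identified == {"A"}

    def test_budget_conservation(self):
        params = SimParams(n_proteins=6, gradient_length=600.0, bin_width=30.0,
                           capacity=8)
        fmap, truth = generate_ground_truth(3, params)
        ips = IPSParams(step_size=5, max_iterations=10)
        history = run_ips(fmap, truth.proteins, make_search_oracle(truth), ips)
        for n, rec in enumerate(history, start=1):
            assert rec.precs_total <= n * ips.step_size
        flat = [p for rec in history for p in rec.selections]
        assert len(flat) == len(set(flat))

    def test_sps_prefix_equivalence_with_protein_terms_off(self):
        """k1 = k3 = 0: every iteration's cumulative selection equals the
        static intensity-sorted prefix of the same budget."""
        fmap = sps_equivalence_map()
        params = IPSParams(k1=0.0, k2=1.0, k3=0.0, step_size=20, max_iterations=5)
        history = run_ips(fmap, [], lambda fid, s: None, params)
        assert len(history) == 5
        cumulative: list[tuple[str, int]] = []
        for rec in history:
            cumulative.extend(rec.selections)
            prefix = select_sps(fmap, budget=len(cumulative)).selected
            assert sorted(cumulative) == sorted(prefix)


class TestSequentialIPS:
    def test_fraction_order_nondecreasing_and_frozen(self):
        params = SimParams(n_proteins=8, gradient_length=600.0, bin_width=30.0,
                           capacity=5)
        fmap, truth = generate_ground_truth(11, params)
        ips = IPSParams(step_size=5, max_iterations=60, sequential=True)
        history = run_ips(fmap, truth.proteins, make_search_oracle(truth), ips)
        assert history
        order = [s for rec in history for _fid, s in rec.selections]
        assert all(b >= a for a, b in zip(order, order[1:]))
        # totals of a fraction never change once a later fraction has begun
        seen_counts: dict[int, int] = {}
        closed: set[int] = set()
        current = order[0]
        for s in order:
            if s != current:
                closed.add(current)
                current = s
            assert s not in closed
            seen_counts[s] = seen_counts.get(s, 0) + 1
        for s, count in seen_counts.items():
            assert count <= fmap.capacity(s)
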