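"""Editing CTMC: tract enumeration, hazards, detail laws, rate matrices."""

import math

import numpy as np
import pytest

from gestaltree import (
    Allele,
    EditingParams,
    Indel,
    TargetStatus,
    TargetTract,
    build_status_rate_matrix,
    detail_log_probability,
    enumerate_tracts,
    total_status_hazard,
    tract_hazard,
    tract_of_indel,
    transition_probability_matrix,
)
from gestaltree.editing import (
    enumerate_details,
    indel_for_detail,
    truncated_poisson_logpmf,
)

from conftest import make_design, make_params


class TestEnumerateTracts:
    def test_single_target_single_tract(self):
        design = make_design(1)
        tracts = enumerate_tracts(TargetStatus.all_active(1), design)
        assert tracts == [TargetTract(1, 1, 1, 1)]

    def test_two_targets_all_active(self):
        """Singles at 1 (with/without long-right), singles at 2 (with/without
        long-left) and the double cut: 5 tracts (no long variants at the
        array ends).  Uses a geometry where both long-trim windows are
        non-empty (cut sites centred in 5-bp targets)."""
        design = make_design(2, width=5, cut_offset=2)
        tracts = set(enumerate_tracts(TargetStatus.all_active(2), design))
        expected = {TargetTract(1, 1, 1, 1), TargetTract(1, 1, 1, 2),
                    TargetTract(2, 2, 2, 2), TargetTract(1, 2, 2, 2),
                    TargetTract(1, 1, 2, 2)}
        assert tracts == expected

    def test_two_targets_first_inactive(self, design2):
        status = TargetStatus.all_active(2).deactivate([1])
        tracts = enumerate_tracts(status, design2)
        assert tracts == [TargetTract(2, 2, 2, 2)]

    def test_double_cut_over_inactive_inner_target(self, design3):
        """A double cut across an edited inner target stays available —
        this is the masking event."""
        status = TargetStatus.all_active(3).deactivate([2])
        tracts = enumerate_tracts(status, design3)
        assert TargetTract(1, 1, 3, 3) in tracts
        assert all(t.j != 2 and t.jp != 2 for t in tracts)


class TestTractHazard:
    def test_single_cut_short_short(self):
        params = make_params(2, cut_rates=(1.0, 1.0), double_cut_weight=0.5,
                             long_trim_left=0.0, long_trim_right=0.0)
        assert tract_hazard(TargetTract(1, 1, 1, 1), params) == pytest.approx(1.0)

    def test_double_cut_weighting(self):
        params = make_params(2, cut_rates=(1.0, 2.0), double_cut_weight=0.5,
                             long_trim_left=0.0, long_trim_right=0.0)
        assert tract_hazard(TargetTract(1, 1, 2, 2), params) == pytest.approx(1.5)

    def test_long_left_odds_one_half(self):
        """gamma0 = 1 makes the long and short left variants equally likely."""
        params = make_params(2, long_trim_left=1.0)
        short = tract_hazard(TargetTract(2, 2, 2, 2), params)
        long = tract_hazard(TargetTract(1, 2, 2, 2), params)
        assert short == pytest.approx(long)

    def test_status_hazard_matches_rate_matrix_diagonal(self, design3, params3):
        rm = build_status_rate_matrix(design3, params3)
        for status, diag in zip(rm.states, np.diag(rm.Q)):
            assert -diag == pytest.approx(
                total_status_hazard(status, design3, params3), abs=1e-12)


class TestDetailLaw:
    def test_normalizes_to_one_per_tract(self, design3, params3):
        for tract in enumerate_tracts(TargetStatus.all_active(3), design3):
            total = sum(math.exp(lp) for *_, lp in
                        enumerate_details(tract, design3, params3))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_insert_content_uniform(self, design3, params3):
        tract = TargetTract(1, 1, 1, 1)
        a = indel_for_detail(tract, design3, 1, 1, "A")
        b = indel_for_detail(tract, design3, 1, 1, "C")
        lp_a = detail_log_probability(a, tract, design3, params3)
        lp_b = detail_log_probability(b, tract, design3, params3)
        assert lp_a == pytest.approx(lp_b)

    def test_truncated_poisson_hand_value(self):
        """Mean 1.0 truncated to {0..3}: P(0) = 1 / (1 + 1 + 1/2 + 1/6)."""
        logp = truncated_poisson_logpmf(1.0, 0, 3)
        assert math.exp(logp[0]) == pytest.approx(1 / (1 + 1 + 0.5 + 1 / 6))

    def test_null_detail_excluded(self, design3, params3):
        """The no-trim no-insert outcome of a plain single cut is not an
        observable event and is excluded from the law's support."""
        details = list(enumerate_details(TargetTract(2, 2, 2, 2),
                                         design3, params3))
        assert (0, 0, 0) not in [(l, r, i) for l, r, i, _ in details]


class TestTractOfIndel:
    def test_focal_deletion(self, design3):
        ind = Indel(start=3, del_len=2, insert="", min_target=2, max_target=2)
        assert tract_of_indel(ind, design3) == TargetTract(2, 2, 2, 2)

    def test_spanning_deletion_ending_inside_target3(self, design3):
        """From inside target 1 through c(3), not reaching target 3's
        long-trim region on the right."""
        ind = Indel(start=0, del_len=8, insert="", min_target=1, max_target=3)
        assert tract_of_indel(ind, design3) == TargetTract(1, 1, 3, 3)

    def test_pure_insertion(self, design3):
        c2 = design3.cut_positions[1]
        ind = Indel(start=c2, del_len=0, insert="ACG", min_target=2, max_target=2)
        assert tract_of_indel(ind, design3) == TargetTract(2, 2, 2, 2)

    def test_long_left_trim_detected(self, design3):
        ind = indel_for_detail(TargetTract(1, 2, 2, 2), design3, 2, 1, "")
        assert tract_of_indel(ind, design3) == TargetTract(1, 2, 2, 2)


class TestTransitionMatrix:
    def test_t_zero_is_identity(self, design3, params3):
        rm = build_status_rate_matrix(design3, params3)
        P = transition_probability_matrix(rm, r=1.0, t=0.0)
        assert np.allclose(P, np.eye(len(rm.states)), atol=1e-12)

    def test_rows_sum_to_one(self, design3, rng):
        for _ in range(5):
            lam = tuple(rng.uniform(0.3, 2.0, 3))
            params = make_params(3, cut_rates=lam,
                                 double_cut_weight=float(rng.uniform(0.1, 1.0)))
            rm = build_status_rate_matrix(design3, params)
            P = transition_probability_matrix(rm, r=float(rng.uniform(0.1, 2)),
                                              t=float(rng.uniform(0, 3)))
            assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10
            assert P.min() > -1e-12 and P.max() < 1 + 1e-12

    def test_irreversibility_zeros(self, design3, params3):
        """Entries from more-edited to less-edited statuses are exactly 0."""
        rm = build_status_rate_matrix(design3, params3)
        P = transition_probability_matrix(rm, r=1.0, t=0.7)
        for i, si in enumerate(rm.states):
            for j, sj in enumerate(rm.states):
                if any(a and not b for a, b in zip(sj.active, si.active)):
                    assert P[i, j] == 0.0

    def test_single_target_survival_closed_form(self):
        design = make_design(1)
        params = make_params(1)
        rm = build_status_rate_matrix(design, params)
        h = total_status_hazard(TargetStatus.all_active(1), design, params)
        r, t = 0.8, 1.3
        P = transition_probability_matrix(rm, r, t)
        i = rm.index(TargetStatus.all_active(1))
        assert P[i, i] == pytest.approx(math.exp(-h * r * t), rel=1e-12)


def test_editing_params_validation():
    with pytest.raises(ValueError):
        EditingParams(clock_rate=-1.0)
    with pytest.raises(ValueError):
        EditingParams(cut_rates=(1.0, 0.0))
    p = EditingParams(cut_rates=(2.0, 1.0, 3.0)).with_mean_one_cut_rates()
    assert np.mean(p.cut_rates) == pytest.approx(1.0)


def test_params_dict_round_trip():
    p = make_params(3, cut_rates=(1.0, 0.5, 1.5))
    assert EditingParams.from_dict(p.to_dict()) == p
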