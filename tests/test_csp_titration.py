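"""Chemical-shift perturbation, significance flags and metal titrations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acpdyn.csp_titration import (CSPRecord, csp, paramagnetic_ratio,
                                  significance_flags, titration_trajectory)
from acpdyn.io_tables import ResidueID, ShiftRecord
from acpdyn.synthdata import (CA_LADDER_M, MN_LADDER_M, gen_ca_titration,
                              gen_mn_titration, gen_shift_tables, residue_id)


def shift(idx, aa, dH, dN, intensity=1.0):
    return ShiftRecord(ResidueID(idx, aa), dH, dN, intensity)


class TestCSP:
    def test_zero_difference_gives_zero(self):
        assert csp(shift(5, "L", 8.0, 120.0), shift(5, "L", 8.0, 120.0)).dd == 0.0

    def test_hand_case_non_glycine(self):
        # ddH=0.1, ddN=0.5, alpha=0.2 -> sqrt(0.5*(0.01+0.01)) = 0.100 ppm
        rec = csp(shift(5, "L", 8.0, 120.0), shift(5, "L", 8.1, 120.5))
        assert rec.dd == pytest.approx(0.100, abs=1e-12)

    def test_hand_case_glycine(self):
        # ddN=1.0, alpha=0.14 -> sqrt(0.5*0.0196) = 0.098995 ppm
        rec = csp(shift(12, "G", 8.0, 110.0), shift(12, "G", 8.0, 111.0))
        assert rec.dd == pytest.approx(np.sqrt(0.5 * 0.0196), abs=1e-12)
        assert rec.dd == pytest.approx(0.0990, abs=1e-4)

    def test_mismatched_residues_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            csp(shift(5, "L", 8, 120), shift(6, "L", 8, 120))

    def test_reference_swap_invariance(self):
        a, b = shift(5, "L", 8.0, 120.0), shift(5, "L", 8.07, 119.2)
        assert csp(a, b).dd == pytest.approx(csp(b, a).dd, abs=1e-15)

    @given(lam=st.floats(0.01, 100), ddH=st.floats(-1, 1), ddN=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_of_degree_one(self, lam, ddH, ddN):
        a = shift(5, "L", 8.0, 120.0)
        small = csp(a, shift(5, "L", 8.0 + ddH, 120.0 + ddN))
        big = csp(a, shift(5, "L", 8.0 + lam * ddH, 120.0 + lam * ddN))
        assert big.dd == pytest.approx(lam * small.dd, rel=1e-9, abs=1e-12)


class TestSignificance:
    def test_hand_threshold_case(self):
        recs = [CSPRecord(ResidueID(i, "A"), 0.1) for i in range(1, 10)]
        recs.append(CSPRecord(ResidueID(10, "A"), 1.0))
        flagged = [r for r in significance_flags(recs) if r.significant]
        assert [r.rid.index for r in flagged] == [10]

    def test_all_equal_none_flagged(self):
        recs = [CSPRecord(ResidueID(i, "A"), 0.2) for i in range(1, 6)]
        assert not any(r.significant for r in significance_flags(recs))

    def test_flags_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(0)
        recs = [CSPRecord(ResidueID(i, "A"), float(v))
                for i, v in enumerate(rng.gamma(1.0, 0.05, 40), start=1)]
        f1 = {r.rid.index for r in significance_flags(recs) if r.significant}
        scaled = [CSPRecord(r.rid, 13.0 * r.dd) for r in recs]
        f2 = {r.rid.index for r in significance_flags(scaled) if r.significant}
        assert f1 == f2

    def test_generated_sites_flagged_when_effect_dominates(self):
        ref, state, truth = gen_shift_tables(7)
        flagged = {r.rid.index
                   for r in significance_flags([csp(a, b) for a, b in zip(ref, state)])
                   if r.significant}
        assert flagged == set(truth.truths["site_residues"])


class TestParamagnetic:
    def test_identical_spectra_all_ones(self):
        ref = [shift(i, "A", 8, 120, 2.0) for i in range(1, 6)]
        assert set(paramagnetic_ratio(ref, ref).values()) == {1.0}

    def test_vanished_peak_gets_zero(self):
        ref = [shift(1, "A", 8, 120, 2.0)]
        gone = [ShiftRecord(ResidueID(1, "A"), 8, 120, None)]
        assert paramagnetic_ratio(ref, gone)[ResidueID(1, "A")] == 0.0

    def test_generated_attenuation_strictly_decreasing(self):
        states, truth = gen_mn_titration(3)
        ref = states[0]
        prev = {r.rid: 1.0 for r in ref}
        for state in states[1:]:
            ratios = paramagnetic_ratio(ref, state)
            for rid, r in ratios.items():
                assert r < prev[rid]
            prev = ratios

    def test_site_residues_attenuate_fastest(self):
        states, truth = gen_mn_titration(4)
        ratios = paramagnetic_ratio(states[0], states[3])  # 10 uM point
        sites = set(truth.truths["site_residues"])
        site_vals = [v for rid, v in ratios.items() if rid.index in sites]
        far_vals = [v for rid, v in ratios.items()
                    if rid.index not in sites
                    and rid.index not in set(truth.truths["near_site_residues"])]
        assert max(site_vals) < min(far_vals)


class TestTitrationTrajectory:
    def test_identical_states_zero_profile(self):
        ref = [shift(i, "A", 8, 120) for i in range(1, 6)]
        profiles = titration_trajectory([ref, ref], [0.0, 1.0])
        assert all(np.allclose(p.values, 0.0) for p in profiles)

    def test_fast_exchange_saturating_and_endpoint(self):
        states, truth = gen_ca_titration(5, noise_ppm=(0.0, 0.0))
        profiles = {p.rid.index: p for p in titration_trajectory(states, list(CA_LADDER_M))}
        fb = truth.truths["endpoint_bound_fraction"]
        ddH, ddN = truth.truths["dd_max"]
        expected_end = np.sqrt(0.5 * ((ddH * fb) ** 2 + (0.2 * ddN * fb) ** 2))
        for idx in truth.truths["site_residues"]:
            p = profiles[idx]
            assert p.monotonicity == pytest.approx(1.0)
            assert np.all(np.diff(p.values) > 0)
            assert p.values[-1] == pytest.approx(expected_end, rel=1e-9)

    def test_site_residues_rank_above_background_by_endpoint(self):
        states, truth = gen_ca_titration(6)
        profiles = titration_trajectory(states, list(CA_LADDER_M))
        sites = set(truth.truths["site_residues"])
        end = {p.rid.index: p.values[-1] for p in profiles}
        site_min = min(v for i, v in end.items() if i in sites)
        bg_max = max(v for i, v in end.items() if i not in sites)
        assert site_min > bg_max

    def test_length_mismatch_rejected(self):
        ref = [shift(1, "A", 8, 120)]
        with pytest.raises(ValueError):
            titration_trajectory([ref, ref], [0.0])
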