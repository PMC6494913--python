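"""Intensity-to-Γ₂ conversion, relative intensities and shift distances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from premix.peaks import (
    Gamma2Entry,
    Gamma2Set,
    HMQCSettings,
    MethylPeakRecord,
    PeakFlag,
    SIGNIFICANT_INTENSITY_REDUCTION,
    classify_significant,
    eq1_forward,
    gamma2_from_table,
    invert_eq1,
    read_gamma2_table,
    read_peak_table,
    relative_intensity,
    shift_distance,
    write_gamma2_table,
)


class TestForwardRatio:
    def test_zero_pre_gives_unit_ratio(self):
        assert eq1_forward(0.0, 30.0, 40.0) == pytest.approx(1.0)

    def test_pinned_scalar_value(self):
        # frozen from a direct scalar evaluation of the ratio equation
        assert eq1_forward(5.0, 30.0, 40.0, HMQCSettings(0.0069)) == pytest.approx(
            0.736067306427803, rel=1e-12
        )

    def test_large_pre_limit(self):
        assert eq1_forward(1e6, 30.0, 40.0) < 1e-12

    def test_strictly_decreasing(self):
        g = np.linspace(0.0, 200.0, 400)
        ratios = eq1_forward(g, 30.0, 40.0)
        assert np.all(np.diff(ratios) < 0)

    @pytest.mark.parametrize("rh,rhc", [(0.0, 40.0), (30.0, -1.0)])
    def test_nonpositive_rates_rejected(self, rh, rhc):
        with pytest.raises(ValueError):
            eq1_forward(1.0, rh, rhc)

    def test_negative_gamma2_rejected(self):
        with pytest.raises(ValueError):
            eq1_forward(-1.0, 30.0, 40.0)


class TestInversion:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        gamma2=st.floats(0.0, 200.0),
        r2h=st.floats(5.0, 100.0),
        r2hc=st.floats(5.0, 100.0),
    )
    def test_round_trip_recovers_gamma2(self, gamma2, r2h, r2hc):
        ratio = eq1_forward(gamma2, r2h, r2hc)
        rec = MethylPeakRecord("m", I_para=ratio, I_dia=1.0, R2_diaH=r2h, R2_diaHC=r2hc)
        entry = invert_eq1(rec, noise_floor=0.0)
        assert entry.flag in (PeakFlag.OK, PeakFlag.NONPOSITIVE)
        assert entry.gamma2 >= 0.0
        assert abs(entry.gamma2 - gamma2) < 1e-6

    def test_unit_ratio_maps_to_zero(self):
        rec = MethylPeakRecord("m", I_para=1.0, I_dia=1.0)
        assert invert_eq1(rec).gamma2 == 0.0

    def test_apparent_negative_pre_flagged_nonpositive(self):
        rec = MethylPeakRecord("m", I_para=1.1, I_dia=1.0)
        entry = invert_eq1(rec)
        assert entry.flag is PeakFlag.NONPOSITIVE
        assert entry.gamma2 == 0.0

    def test_noise_dominated_peak_flagged_unresolved(self):
        rec = MethylPeakRecord("m", I_para=-0.01, I_dia=1.0)
        entry = invert_eq1(rec, gamma2_cap=80.0)
        assert entry.flag is PeakFlag.UNRESOLVED
        assert entry.gamma2 == 80.0  # reported as a lower bound

    def test_below_noise_floor_flagged_unresolved(self):
        rec = MethylPeakRecord("m", I_para=0.02, I_dia=1.0, sigma_para=0.02)
        assert invert_eq1(rec, noise_floor=3.0).flag is PeakFlag.UNRESOLVED

    def test_error_propagation_grows_with_noise(self):
        base = eq1_forward(20.0, 30.0, 40.0)
        errs = []
        for sig in (0.005, 0.02):
            rec = MethylPeakRecord(
                "m", I_para=base, I_dia=1.0, sigma_para=sig, sigma_dia=sig
            )
            entry = invert_eq1(rec, noise_floor=0.0)
            assert entry.flag is PeakFlag.OK
            errs.append(entry.gamma2_err)
        assert 0 < errs[0] < errs[1]


class TestRelativeIntensity:
    def test_equal_intensities(self):
        assert relative_intensity(5.0, 5.0)[0] == pytest.approx(1.0)

    def test_pinned_quotient_error(self):
        ratio, err = relative_intensity(45.0, 50.0, 1.0, 1.0)
        assert ratio == pytest.approx(0.9)
        assert err == pytest.approx(0.02690724809414742, rel=1e-12)

    def test_significant_reduction_threshold(self):
        # entries below the 0.80 coloring threshold are the significant ones
        assert relative_intensity(0.75, 1.0)[0] < SIGNIFICANT_INTENSITY_REDUCTION
        assert relative_intensity(0.85, 1.0)[0] > SIGNIFICANT_INTENSITY_REDUCTION

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_intensity(1.0, 0.0)


class TestShiftDistance:
    @pytest.mark.parametrize(
        "dh,dc,expected",
        [
            (0.0, 0.0, 0.0),
            (0.03, 0.059, 0.03162277660168379),
            (0.12, 0.0, 0.12),
            (-0.12, 0.0, 0.12),
        ],
    )
    def test_combined_distance(self, dh, dc, expected):
        assert shift_distance(dh, dc).delta_combined == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dh=st.floats(-1, 1), dc=st.floats(-5, 5))
    def test_sign_symmetry_and_triangle_bound(self, dh, dc):
        d = shift_distance(dh, dc).delta_combined
        assert d == pytest.approx(shift_distance(-dh, -dc).delta_combined)
        assert d <= abs(dh) + abs(dc) / 5.9 + 1e-12


class TestSignificanceClassification:
    def test_strict_threshold_boundary(self):
        gset = Gamma2Set(
            "L366C-TEMPO",
            [
                Gamma2Entry("a", 4.99, 0.1),
                Gamma2Entry("b", 5.0, 0.1),
                Gamma2Entry("c", 5.01, 0.1),
            ],
        )
        significant, _ = classify_significant(gset, threshold=5.0)
        assert significant == ["c"]

    def test_reported_methyl_pattern(self):
        # the L366C-labeled experiment highlights four helical-domain methyls
        strong = ["I85d1", "L130d1", "L130d2", "V136g2"]
        entries = [Gamma2Entry(m, 8.0, 0.5) for m in strong]
        entries += [Gamma2Entry(m, 1.5, 0.5) for m in ["A41b", "L5d1", "I264d1"]]
        entries.append(Gamma2Entry("A299b", 90.0, math.inf, PeakFlag.UNRESOLVED))
        significant, unresolved = classify_significant(
            Gamma2Set("L366C-TEMPO", entries), threshold=5.0
        )
        assert significant == strong
        assert unresolved == ["A299b"]

    def test_all_zero_yields_empty(self):
        gset = Gamma2Set("s", [Gamma2Entry(f"m{i}", 0.0, 0.0) for i in range(5)])
        assert classify_significant(gset)[0] == []


class TestContainers:
    def test_duplicate_methyl_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Gamma2Set("s", [Gamma2Entry("m", 1.0, 0.1), Gamma2Entry("m", 2.0, 0.1)])

    def test_negative_gamma2_with_ok_flag_rejected(self):
        with pytest.raises(ValueError):
            Gamma2Set("s", [Gamma2Entry("m", -1.0, 0.1)])

    def test_record_validation(self):
        with pytest.raises(ValueError):
            MethylPeakRecord("m", I_para=1.0, I_dia=0.0)
        with pytest.raises(ValueError):
            MethylPeakRecord("m", I_para=1.0, I_dia=1.0, R2_diaH=-2.0)


def test_table_round_trip(tmp_path):
    df = pd.DataFrame(
        {
            "methyl_id": ["L130d1", "V136g2"],
            "I_para": [0.42, 0.77],
            "I_dia": [1.0, 0.95],
            "sigma_para": [0.02, 0.02],
            "sigma_dia": [0.02, 0.02],
            "R2_diaH": [30.0, 25.0],
            "R2_diaHC": [40.0, 35.0],
        }
    )
    path = tmp_path / "intensity.tsv"
    df.to_csv(path, sep="\t", index=False)
    records = read_peak_table(path)
    assert [r.methyl_id for r in records] == ["L130d1", "V136g2"]

    gset = gamma2_from_table(records, "L366C")
    out = tmp_path / "gamma2.tsv"
    write_gamma2_table(gset, out)
    back = read_gamma2_table(out, "L366C")
    for a, b in zip(gset.entries, back.entries):
        assert a.methyl_id == b.methyl_id
        assert a.gamma2 == pytest.approx(b.gamma2)
        assert a.flag == b.flag
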