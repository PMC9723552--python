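"""Wetmur melting-temperature model and stringency calculus."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genefishkit.errors import InvalidParameterError, ProbeUnstableWarning, StringencyWarning
from genefishkit.thermo import (
    DuplexParams,
    HybridizationConditions,
    max_mismatch,
    recommend_fa,
    stringency_envelope,
    wetmur_tm,
)

DUPLEX = st.builds(
    DuplexParams,
    gc_percent=st.floats(0, 100),
    length_bp=st.integers(50, 5000),
    mismatch_percent=st.floats(0, 100),
)
COND = st.builds(
    HybridizationConditions,
    na_molar=st.floats(0.01, 5.0),
    fa_percent=st.floats(0, 100),
    hyb_temp_c=st.floats(20, 80),
)


class TestWetmurTm:
    def test_hand_evaluated_reference_point(self):
        # 81.5 + 16.6*log10(1/1.7) + 0.41*50 - 500/500 - 0 - 0
        tm = wetmur_tm(
            DuplexParams(gc_percent=50, length_bp=500),
            HybridizationConditions(na_molar=1.0, fa_percent=0.0),
        )
        expected = 81.5 + 16.6 * math.log10(1.0 / 1.7) + 20.5 - 1.0
        assert tm == pytest.approx(expected, abs=1e-9)
        assert tm == pytest.approx(97.17, abs=0.01)

    @given(duplex=DUPLEX, cond=COND)
    def test_mismatch_coefficient_is_exactly_minus_one(self, duplex, cond):
        from dataclasses import replace

        d0 = replace(duplex, mismatch_percent=0.0)
        d10 = replace(duplex, mismatch_percent=10.0)
        assert wetmur_tm(d10, cond) - wetmur_tm(d0, cond) == pytest.approx(-10.0, abs=1e-9)

    @given(duplex=DUPLEX, cond=COND)
    def test_formamide_coefficient_is_exactly_minus_063(self, duplex, cond):
        from dataclasses import replace

        c0 = replace(cond, fa_percent=0.0)
        c20 = replace(cond, fa_percent=20.0)
        assert wetmur_tm(duplex, c20) - wetmur_tm(duplex, c0) == pytest.approx(-12.6, abs=1e-9)

    @given(duplex=DUPLEX, cond=COND)
    def test_gc_coefficient_is_exactly_041(self, duplex, cond):
        from dataclasses import replace

        d_lo = replace(duplex, gc_percent=30.0)
        d_hi = replace(duplex, gc_percent=40.0)
        assert wetmur_tm(d_hi, cond) - wetmur_tm(d_lo, cond) == pytest.approx(4.1, abs=1e-9)

    @given(duplex=DUPLEX, cond=COND, dna=st.floats(0.05, 1.0))
    def test_tm_increases_with_sodium_and_length(self, duplex, cond, dna):
        from dataclasses import replace

        richer = replace(cond, na_molar=cond.na_molar + dna)
        assert wetmur_tm(duplex, richer) > wetmur_tm(duplex, cond)
        longer = replace(duplex, length_bp=duplex.length_bp + 100)
        assert wetmur_tm(longer, cond) > wetmur_tm(duplex, cond)

    def test_invalid_parameters_are_rejected(self):
        with pytest.raises(InvalidParameterError):
            DuplexParams(gc_percent=120, length_bp=450)
        with pytest.raises(InvalidParameterError):
            DuplexParams(gc_percent=50, length_bp=0)
        with pytest.raises(InvalidParameterError):
            HybridizationConditions(na_molar=0.0)
        with pytest.raises(InvalidParameterError):
            HybridizationConditions(fa_percent=101)


class TestMaxMismatch:
    def test_linear_rearrangement(self):
        # pick conditions so that Tm(M=0) lands 20 degrees above 46 °C
        d = DuplexParams(gc_percent=50, length_bp=500)
        cond = HybridizationConditions(na_molar=1.0, fa_percent=0.0, hyb_temp_c=46.0)
        tm0 = wetmur_tm(d, cond)
        budget = max_mismatch(d, cond)
        assert budget == pytest.approx(tm0 - 46.0, abs=1e-9)

    def test_zero_at_equality_and_floored_with_warning_below(self):
        d = DuplexParams(gc_percent=50, length_bp=500)
        cond = HybridizationConditions(na_molar=1.0, fa_percent=0.0)
        tm0 = wetmur_tm(d, cond)
        at_edge = HybridizationConditions(na_molar=1.0, fa_percent=0.0, hyb_temp_c=tm0)
        assert max_mismatch(d, at_edge) == 0.0
        too_hot = HybridizationConditions(na_molar=1.0, fa_percent=0.0, hyb_temp_c=tm0 + 5)
        with pytest.warns(ProbeUnstableWarning):
            assert max_mismatch(d, too_hot) == 0.0

    def test_margin_shrinks_the_budget(self):
        d = DuplexParams(gc_percent=50, length_bp=450)
        base = HybridizationConditions(na_molar=1.0, fa_percent=10.0, hyb_temp_c=46.0)
        margined = HybridizationConditions(na_molar=1.0, fa_percent=10.0, hyb_temp_c=46.0,
                                           tm_margin_c=5.0)
        assert max_mismatch(d, margined) == pytest.approx(max_mismatch(d, base) - 5.0, abs=1e-9)


class TestRecommendFa:
    @pytest.mark.parametrize(
        "stringent, mismatch, rounding, expected",
        [
            (35.0, 14.0, "nearest-5", 15.0),   # the 86%-identity cross-taxon case
            (35.0, 0.0, "nearest-5", 35.0),
            (35.0, 0.0, "none", 35.0),
            (35.0, 6.3, "none", 25.0),          # 6.3/0.63 = 10 exactly
            (35.0, 14.0, "nearest-5-down", 10.0),
        ],
    )
    def test_worked_examples(self, stringent, mismatch, rounding, expected):
        assert recommend_fa(stringent, mismatch, rounding) == pytest.approx(expected)

    def test_uncompensatable_mismatch_warns_and_floors(self):
        with pytest.warns(StringencyWarning):
            assert recommend_fa(10.0, 20.0, "none") == 0.0

    @given(
        stringent=st.floats(0, 100),
        m=st.floats(0, 40),
    )
    def test_relaxation_roundtrip_admits_exactly_m_more_mismatch(self, stringent, m):
        """max_mismatch at the relaxed FA = max_mismatch at the stringent FA + M."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StringencyWarning)
            fa = recommend_fa(stringent, m, rounding="none")
        if fa == 0.0 and stringent - m / 0.63 < 0:
            return  # flooring breaks exactness by design
        d = DuplexParams(gc_percent=55, length_bp=450)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ProbeUnstableWarning)
            before = max_mismatch(
                d, HybridizationConditions(na_molar=1.0, fa_percent=stringent, hyb_temp_c=40)
            )
            after = max_mismatch(
                d, HybridizationConditions(na_molar=1.0, fa_percent=fa, hyb_temp_c=40)
            )
        if before > 0 and after > 0:
            assert after - before == pytest.approx(m, abs=1e-9)


class TestStringencyEnvelope:
    def test_degenerate_grid_equals_wetmur(self):
        d = DuplexParams(gc_percent=48, length_bp=450)
        cond = HybridizationConditions(na_molar=0.39, fa_percent=0.0)
        env = stringency_envelope(d, cond, [35.0], [10.0])
        from dataclasses import replace

        expected = wetmur_tm(replace(d, mismatch_percent=10.0), replace(cond, fa_percent=35.0))
        assert env.tm(35.0, 10.0) == pytest.approx(expected, abs=1e-12)

    def test_cells_match_oracle_and_linearity(self):
        d = DuplexParams(gc_percent=62, length_bp=442)
        cond = HybridizationConditions(na_molar=0.39, fa_percent=0.0, hyb_temp_c=46.0)
        fas = [0.0, 5.0, 15.0, 35.0, 50.0]
        mms = [0.0, 4.0, 10.0, 20.0]
        env = stringency_envelope(d, cond, fas, mms)
        from dataclasses import replace

        for row in env.grid.itertuples(index=False):
            oracle = wetmur_tm(
                replace(d, mismatch_percent=row.mismatch_percent),
                replace(cond, fa_percent=row.fa_percent),
            )
            assert row.tm_c == pytest.approx(oracle, abs=1e-9)
        # linearity in FA at fixed mismatch
        assert env.tm(35.0, 10.0) - env.tm(15.0, 10.0) == pytest.approx(-0.63 * 20, abs=1e-9)
        # strict monotone decrease along both axes
        for m in mms:
            col = [env.tm(fa, m) for fa in fas]
            assert all(a > b for a, b in zip(col, col[1:]))
        for fa in fas:
            row = [env.tm(fa, m) for m in mms]
            assert all(a > b for a, b in zip(row, row[1:]))

    def test_max_mismatch_curve_drops_063_per_percent_fa(self):
        d = DuplexParams(gc_percent=50, length_bp=450)
        cond = HybridizationConditions(na_molar=1.0, fa_percent=0.0, hyb_temp_c=46.0)
        fas = [float(x) for x in range(0, 21)]
        env = stringency_envelope(d, cond, fas, [0.0])
        mm = env.max_mismatch_curve.max_mismatch_percent.tolist()
        diffs = [b - a for a, b in zip(mm, mm[1:])]
        assert all(dx == pytest.approx(-0.63, abs=1e-9) for dx in diffs)

    def test_empty_grid_rejected(self):
        d = DuplexParams(gc_percent=50, length_bp=450)
        with pytest.raises(InvalidParameterError):
            stringency_envelope(d, HybridizationConditions(), [], [0.0])

    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        d = DuplexParams(gc_percent=50, length_bp=450)
        env = stringency_envelope(d, HybridizationConditions(), [15.0, 35.0], [0.0, 14.0])
        out = tmp_path / "env.tsv"
        env.to_tsv(out)
        back = pd.read_csv(out, sep="\t")
        assert list(back.columns) == ["fa_percent", "mismatch_percent", "tm_c"]
        assert len(back) == 4
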