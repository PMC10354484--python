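"""Faecal progesterone QC: CV screening, LOD substitution, unit conversion,
mass filtering, duplicate resolution, annual aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from whalepreg.hormones import (
    FaecalResult,
    aggregate_annual_fp4m,
    convert_to_ngg,
    filter_mass,
    process_assays,
    replicate_cv,
    resolve_same_day,
    substitute_lod,
)


class TestReplicateCV:
    def test_identical_replicates_pass(self):
        cv, rerun = replicate_cv([100.0, 100.0])
        assert cv == 0.0 and not rerun

    def test_divergent_replicates_flagged(self):
        cv, rerun = replicate_cv([80.0, 120.0])
        assert cv == pytest.approx(28.2843, abs=1e-3)
        assert rerun

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            replicate_cv([0.0, 0.0])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_cv([50.0])


class TestSubstituteLOD:
    @pytest.mark.parametrize(
        "raw, expected, flagged",
        [(3.0, 4.285, True), (8.57, 8.57, False), (100.0, 100.0, False)],
    )
    def test_half_lod_rule(self, raw, expected, flagged):
        value, below = substitute_lod(raw)
        assert value == pytest.approx(expected)
        assert below is flagged

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError):
            substitute_lod(-1.0)


class TestConvertToNgg:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1000.0, 1.0, 1.0, 1.0), 1.0),
            ((500.0, 2.0, 10.0, 0.5), 20.0),
            ((8.57 / 2, 1.0, 1.0, 0.02), 0.21425),
        ],
    )
    def test_conversion(self, args, expected):
        assert convert_to_ngg(*args) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            convert_to_ngg(100.0, 1.0, 0.0, 1.0)


class TestFilterMass:
    @pytest.mark.parametrize("mass, keep", [(0.019, False), (0.020, True), (1.2, True)])
    def test_strict_threshold(self, mass, keep):
        assert filter_mass(mass) is keep


def _result(mass, sample_id="a", whale="W1", date="2019-08-30"):
    return FaecalResult(
        whale_id=whale, date=date, fp4m_ngg=10.0 * mass, below_lod=False,
        cv_pct=5.0, dry_mass_g=mass, rerun_required=False, sample_id=sample_id,
    )


class TestResolveSameDay:
    def test_higher_mass_wins(self):
        kept = resolve_same_day([_result(0.05, "a"), _result(0.30, "b")])
        assert kept.sample_id == "b"

    def test_single_sample_is_itself(self):
        r = _result(0.1)
        assert resolve_same_day([r]) is r

    def test_tie_breaks_deterministically_on_sample_id(self):
        kept = resolve_same_day([_result(0.3, "a"), _result(0.3, "b")])
        assert kept.sample_id == "b"

    def test_mixed_days_rejected(self):
        with pytest.raises(ValueError):
            resolve_same_day([_result(0.1, date="2019-08-30"), _result(0.2, date="2019-08-31")])


class TestAnnualAggregation:
    def test_single_value(self):
        assert aggregate_annual_fp4m([math.e ** 4]) == pytest.approx(4.0)

    def test_odd_count_median_then_log(self):
        vals = [math.e ** 3, math.e ** 5, math.e ** 7]
        assert aggregate_annual_fp4m(vals) == pytest.approx(5.0)

    def test_even_count_midpoint_on_natural_scale(self):
        vals = [math.e ** 3, math.e ** 5]
        expected = math.log((math.e ** 3 + math.e ** 5) / 2.0)
        assert aggregate_annual_fp4m(vals) == pytest.approx(expected)
        assert aggregate_annual_fp4m(vals) == pytest.approx(4.4338, abs=1e-3)

    def test_empty_is_absent_not_zero(self):
        assert aggregate_annual_fp4m([]) is None

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_bounded(self, vals):
        out = aggregate_annual_fp4m(vals)
        assert out == aggregate_annual_fp4m(list(reversed(vals)))
        assert math.log(min(vals)) - 1e-9 <= out <= math.log(max(vals)) + 1e-9

    def test_log_preserves_rank_order(self):
        natural = [0.5, 3.0, 20.0, 100.0]
        logs = [aggregate_annual_fp4m([v]) for v in natural]
        assert logs == sorted(logs)


class TestProcessAssays:
    def test_pipeline_applies_every_rule(self):
        rows = [
            # two same-day jars: only the heavier is kept
            dict(sample_id="s1", whale_id="W1", date="2019-09-01", rep1_pgml=100.0,
                 rep2_pgml=102.0, dilution=1.0, extract_volume_ml=1.0, dry_mass_g=0.05),
            dict(sample_id="s2", whale_id="W1", date="2019-09-01", rep1_pgml=400.0,
                 rep2_pgml=404.0, dilution=1.0, extract_volume_ml=1.0, dry_mass_g=0.30),
            # a second day in the same year; below-LOD reading
            dict(sample_id="s3", whale_id="W1", date="2019-09-10", rep1_pgml=4.0,
                 rep2_pgml=4.1, dilution=1.0, extract_volume_ml=1.0, dry_mass_g=0.10),
            # excluded: too little dried material
            dict(sample_id="s4", whale_id="W1", date="2019-09-20", rep1_pgml=900.0,
                 rep2_pgml=910.0, dilution=1.0, extract_volume_ml=1.0, dry_mass_g=0.019),
        ]
        out = process_assays(pd.DataFrame(rows))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n_samples"] == 2  # day-1 resolved + day-2
        assert bool(row["any_below_lod"])
        # day 1 keeps s2: 402 pg/ml -> 402/(1000*0.3) ng/g; day 2 LOD/2 substitution
        day1 = 402.0 / (1000 * 0.30)
        day2 = (8.57 / 2) / (1000 * 0.10)
        assert row["log_fp4m"] == pytest.approx(np.log(np.median([day1, day2])))

    def test_cv_flagged_samples_can_be_dropped(self):
        rows = [
            dict(sample_id="s1", whale_id="W1", date="2019-09-01", rep1_pgml=80.0,
                 rep2_pgml=120.0, dilution=1.0, extract_volume_ml=1.0, dry_mass_g=0.1),
        ]
        assert len(process_assays(pd.DataFrame(rows), use_flagged=True)) == 1
        assert len(process_assays(pd.DataFrame(rows), use_flagged=False)) == 0
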