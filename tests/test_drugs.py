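"""Hill pore-block model: dose-response, two-point fits, drug application."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotrial import ChannelScaling, registry
from cardiotrial.drugs import (
    DrugEffect,
    DrugSpec,
    apply_drug,
    block_fraction,
    example_drug_table,
    fit_two_point_hill,
    load_drug_table,
    save_drug_table,
)

ic50s = st.floats(1e-4, 1e3)
hills = st.floats(0.2, 5.0)


class TestBlockFraction:
    def test_zero_concentration_means_no_block(self):
        e = DrugEffect("I_Kr", ic50=1.0, n_h=1.3)
        assert block_fraction(0.0, e) == 0.0

    def test_negative_concentration_rejected(self):
        e = DrugEffect("I_Kr", ic50=1.0, n_h=1.0)
        with pytest.raises(ValueError):
            block_fraction(-0.1, e)

    @settings(derandomize=True, max_examples=200)
    @given(ic50=ic50s, n_h=hills)
    def test_half_block_at_ic50(self, ic50, n_h):
        e = DrugEffect("I_Kr", ic50=ic50, n_h=n_h)
        assert block_fraction(ic50, e) == pytest.approx(0.5, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(ic50=ic50s, n_h=hills, data=st.data())
    def test_strictly_increasing_with_limits(self, ic50, n_h, data):
        e = DrugEffect("I_Kr", ic50=ic50, n_h=n_h)
        c1 = data.draw(st.floats(ic50 * 1e-3, ic50 * 1e3), label="c1")
        c2 = data.draw(st.floats(c1, ic50 * 1e4), label="c2")
        b1, b2 = block_fraction(c1, e), block_fraction(c2, e)
        assert 0.0 < b1 < 1.0
        if c2 > c1:
            assert b2 > b1
        # saturation: 5 decades above IC50 in Hill-scaled units
        assert block_fraction(ic50 * 10.0 ** (5.0 / n_h), e) > 0.99


class TestTwoPointFit:
    @settings(derandomize=True, max_examples=200)
    @given(ic50=ic50s, n_h=hills)
    def test_round_trips_parameters(self, ic50, n_h):
        e = DrugEffect("I_CaL", ic50=ic50, n_h=n_h)
        c1, c2 = 0.5 * ic50, 5.0 * ic50
        fit = fit_two_point_hill(
            c1, block_fraction(c1, e), c2, block_fraction(c2, e), "I_CaL"
        )
        assert fit.ic50 == pytest.approx(ic50, rel=1e-12)
        assert fit.n_h == pytest.approx(n_h, rel=1e-12)

    def test_anchor_identity(self):
        fit = fit_two_point_hill(1.0, 0.3, 10.0, 0.69)
        assert block_fraction(1.0, fit) == pytest.approx(0.3, abs=1e-14)
        assert block_fraction(10.0, fit) == pytest.approx(0.69, abs=1e-14)

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_two_point_hill(1.0, 0.5, 10.0, 0.5)
        with pytest.raises(ValueError):
            fit_two_point_hill(1.0, 0.7, 10.0, 0.3)
        with pytest.raises(ValueError):
            fit_two_point_hill(1.0, 0.5, 1.0, 0.6)
        with pytest.raises(ValueError):
            fit_two_point_hill(1.0, 0.0, 10.0, 0.5)

    def test_calcium_blocker_reconstruction(self):
        """Fitting through 85% at 0.1 µM and 97% at 1 µM gives the published
        dose-response shape and predicts 99% block at 10 µM."""
        fit = fit_two_point_hill(0.1, 0.85, 1.0, 0.97, "I_CaL")
        assert fit.n_h == pytest.approx(0.756, abs=1e-3)
        assert fit.ic50 == pytest.approx(0.0101, abs=1e-4)
        assert round(block_fraction(10.0, fit), 2) == 0.99


class TestApplyDrug:
    def _flecainide_like(self):
        specs = {s.name: s for s in example_drug_table()}
        return specs["flecainide"]

    def test_zero_concentration_is_identity(self):
        base = ChannelScaling({"I_Kr": 0.7})
        spec = self._flecainide_like()
        assert apply_drug(base, spec, 0.0) == base

    @pytest.mark.parametrize(
        "conc,expected",
        [
            (1.0, {"I_Na": 0.70, "I_Kr": 0.60, "I_CaL": 0.96}),
            (10.0, {"I_Na": 0.31, "I_Kr": 0.19, "I_CaL": 0.72}),
        ],
    )
    def test_mixed_blocker_factors_match_published_percentages(
        self, conc, expected
    ):
        """The shipped mixed Na/Kr/CaL blocker reproduces its published
        per-concentration block percentages after like rounding."""
        scaling = apply_drug(ChannelScaling(), self._flecainide_like(), conc)
        for channel, factor in expected.items():
            assert round(scaling.factor(channel), 2) == factor

    def test_channels_absent_from_model_are_skipped(self, caplog):
        model = registry.create("fixture")  # no I_Na
        spec = self._flecainide_like()
        with caplog.at_level("WARNING"):
            scaling = apply_drug(ChannelScaling(), spec, 1.0, model=model)
        assert "I_Na" in caplog.text
        assert scaling.factor("I_Na") == 1.0
        assert scaling.factor("I_Kr") < 1.0

    @settings(derandomize=True, max_examples=50)
    @given(conc=st.floats(0.0, 100.0), f0=st.floats(0.1, 1.0))
    def test_composes_with_base_scaling(self, conc, f0):
        spec = DrugSpec("x", "I", (DrugEffect("I_Kr", 1.0, 1.0),))
        base = ChannelScaling({"I_Kr": f0})
        out = apply_drug(base, spec, conc)
        expected = f0 * (1.0 - block_fraction(conc, spec.effects[0]))
        assert out.factor("I_Kr") == pytest.approx(expected, rel=1e-12)

    def test_independent_channels_commute(self):
        s_kr = DrugSpec("a", "I", (DrugEffect("I_Kr", 1.0, 1.0),))
        s_cal = DrugSpec("b", "I", (DrugEffect("I_CaL", 2.0, 0.8),))
        one = apply_drug(apply_drug(ChannelScaling(), s_kr, 3.0), s_cal, 5.0)
        two = apply_drug(apply_drug(ChannelScaling(), s_cal, 5.0), s_kr, 3.0)
        assert one == two


class TestSpecValidation:
    def test_duplicate_channel_rejected(self):
        with pytest.raises(ValueError):
            DrugSpec(
                "x", "I",
                (DrugEffect("I_Kr", 1.0, 1.0), DrugEffect("I_Kr", 2.0, 1.0)),
            )

    def test_channel_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            DrugEffect("I_f", 1.0, 1.0)
        with pytest.raises(ValueError):
            DrugEffect("I_Kr", -1.0, 1.0)
        with pytest.raises(ValueError):
            DrugEffect("I_Kr", 1.0, 0.0)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        specs = example_drug_table()
        for name in ("drugs.csv", "drugs.json"):
            path = tmp_path / name
            save_drug_table(specs, path)
            back = load_drug_table(path)
            assert {(s.name, s.characterization) for s in back} == {
                (s.name, s.characterization) for s in specs
            }
            by_key = {(s.name, s.characterization): s for s in back}
            for s in specs:
                b = by_key[(s.name, s.characterization)]
                for e0, e1 in zip(
                    sorted(s.effects, key=lambda e: e.channel),
                    sorted(b.effects, key=lambda e: e.channel),
                ):
                    assert e0.channel == e1.channel
                    assert math.isclose(e0.ic50, e1.ic50, rel_tol=1e-12)
                    assert math.isclose(e0.n_h, e1.n_h, rel_tol=1e-12)

    def test_example_table_is_labeled_as_reconstruction(self):
        for spec in example_drug_table():
            assert "reconstruction" in spec.provenance
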