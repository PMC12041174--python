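"""Vessel geometry, Poiseuille resistances, templates and validation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import hepanet as hp
from hepanet.network import (
    DEFAULT_VISCOSITY_PA_S,
    VesselSegment,
    segment_resistance,
)

MU = DEFAULT_VISCOSITY_PA_S


class TestPoiseuilleResistance:
    def test_hand_computed_si_conversion(self):
        """Independent SI evaluation of 8*mu*L/(pi r^4), converted by hand."""
        r_si = 8 * 0.0035 * 0.030 / (math.pi * 0.002**4)  # Pa*s/m^3
        expected = r_si / 133.322 / 1e6 / 60  # -> mmHg/(ml/min)
        got = hp.poiseuille_resistance(2.0, 30.0, 0.0035)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.089e-3, rel=1e-3)

    @given(
        r=st.floats(0.5, 5.0),
        length=st.floats(5.0, 100.0),
        mu=st.floats(0.002, 0.006),
    )
    def test_scaling_laws(self, r, length, mu):
        base = hp.poiseuille_resistance(r, length, mu)
        assert base > 0
        assert hp.poiseuille_resistance(r, 2 * length, mu) == pytest.approx(
            2 * base, rel=1e-12
        )
        assert hp.poiseuille_resistance(r / 2, length, mu) == pytest.approx(
            16 * base, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"radius": 0.0, "length": 10, "viscosity": MU}, "radius"),
            ({"radius": 1.0, "length": -1, "viscosity": MU}, "length"),
            ({"radius": 1.0, "length": 10, "viscosity": 0}, "viscosity"),
        ],
    )
    def test_nonpositive_geometry_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            hp.poiseuille_resistance(**kwargs)


class TestSegmentResistance:
    def _segment(self, **kw):
        base = dict(
            id="S", name="seg", proximal_node="a", distal_node="b",
            radius=2.0, length=30.0,
        )
        base.update(kw)
        return VesselSegment(**base)

    def test_healthy_equals_poiseuille(self):
        seg = self._segment()
        assert segment_resistance(seg, MU) == hp.poiseuille_resistance(2.0, 30.0, MU)

    def test_full_length_75pct_stenosis_is_16x(self):
        seg = self._segment(area_reduction=0.75, stenosis_length=30.0)
        healthy = hp.poiseuille_resistance(2.0, 30.0, MU)
        assert segment_resistance(seg, MU) == pytest.approx(16 * healthy, rel=1e-12)

    def test_half_length_stenosis_series_sum(self):
        seg = self._segment(area_reduction=0.75, stenosis_length=15.0)
        healthy = hp.poiseuille_resistance(2.0, 30.0, MU)
        assert segment_resistance(seg, MU) == pytest.approx(
            (1 + 16) / 2 * healthy, rel=1e-12
        )

    @given(
        sev=st.floats(0.0, 0.95),
        delta=st.floats(0.0, 0.3),
        frac=st.floats(0.1, 1.0),
    )
    def test_monotone_in_severity_and_extent(self, sev, delta, frac):
        length = 30.0
        lo = self._segment(area_reduction=sev, stenosis_length=frac * length)
        hi = self._segment(
            area_reduction=min(sev + delta, 0.97), stenosis_length=frac * length
        )
        assert segment_resistance(hi, MU) >= segment_resistance(lo, MU)
        if sev > 0:
            longer = self._segment(
                area_reduction=sev, stenosis_length=min(frac * 1.2, 1.0) * length
            )
            assert segment_resistance(longer, MU) >= segment_resistance(lo, MU) * (
                1 - 1e-12
            )

    def test_invalid_area_reduction_rejected(self):
        with pytest.raises(ValueError, match="area_reduction"):
            self._segment(area_reduction=1.0, stenosis_length=30.0)


class TestTemplates:
    def test_michels1_is_valid_with_four_outlets(self, michels1):
        assert hp.validate_network(michels1) == []
        assert len(michels1.outlets) == 4
        assert {o.node for o in michels1.outlets} == {"SPL", "LIV", "PDA", "SMAJ"}

    def test_michels8_adds_replaced_rha_and_fifth_outlet(self):
        net = hp.build_template(hp.Variant.MICHELS_VIII_REPLACED_RHA)
        assert hp.validate_network(net) == []
        assert len(net.outlets) == 5
        rha = net.segment("RHA")
        assert rha.proximal_node == "SMAJ"

    def test_stenosis_template_raises_ct_resistance(self, michels1):
        sten = hp.build_template(hp.Variant.CELIAC_STENOSIS, area_reduction=0.8)
        r_sten = segment_resistance(sten.segment("CT"), sten.viscosity)
        r_healthy = segment_resistance(michels1.segment("CT"), michels1.viscosity)
        assert r_sten > 5 * r_healthy
        assert r_sten == pytest.approx(r_healthy / (1 - 0.8) ** 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_templates_valid_under_seeded_overrides(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        for variant in hp.Variant:
            base = hp.build_template(variant)
            overrides = {
                s.id: {
                    "radius": s.radius * rng.uniform(0.9, 1.1),
                    "length": s.length * rng.uniform(0.85, 1.15),
                }
                for s in base.segments
            }
            net = hp.build_template(variant, overrides)
            assert hp.validate_network(net) == []

    def test_unknown_variant_and_override_rejected(self):
        with pytest.raises(ValueError):
            hp.build_template("MICHELS_IX")
        with pytest.raises(KeyError, match="NOPE"):
            hp.build_template(hp.Variant.MICHELS_I, {"NOPE": {"radius": 2.0}})


class TestValidateNetwork:
    def test_dangling_leaf_reported(self, michels1):
        import dataclasses

        missing = tuple(o for o in michels1.outlets if o.node != "SPL")
        net = dataclasses.replace(michels1, outlets=missing)
        assert "dangling_leaf:SPL" in hp.validate_network(net)

    def test_inlet_cannot_be_outlet(self, michels1):
        import dataclasses

        net = dataclasses.replace(
            michels1,
            outlets=michels1.outlets + (hp.WindkesselOutlet(node="AO", resistance=1.0),),
        )
        assert "inlet_is_outlet:AO" in hp.validate_network(net)

    def test_disconnected_component_reported(self, michels1):
        import dataclasses

        extra = hp.VesselSegment(
            id="X", name="floating", proximal_node="Z1", distal_node="Z2",
            radius=1.0, length=10.0,
        )
        outlet = hp.WindkesselOutlet(node="Z2", resistance=1.0)
        net = dataclasses.replace(
            michels1,
            segments=michels1.segments + (extra,),
            outlets=michels1.outlets + (outlet,),
        )
        diags = hp.validate_network(net)
        assert any(d.startswith("disconnected:") for d in diags)
        # Z1 is also a dangling leaf of the floating component
        assert "dangling_leaf:Z1" in diags

    def test_unknown_clamp_reference_reported(self, michels1):
        import dataclasses

        net = dataclasses.replace(michels1, clamped_segments=frozenset({"NOPE"}))
        assert "unknown_clamped_segment:NOPE" in hp.validate_network(net)
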