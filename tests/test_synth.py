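"""Generator contracts: cohorts, melt-curve physics, plates, MLPA tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smnscreen import synth
from smnscreen.synth import (
    VALIDATION_COHORT_COMPOSITION,
    Genotype,
    ProbeTarget,
    Role,
    SampleSpec,
    SimulationConfig,
    amplitudes,
    build_plates,
    generate_cohort,
    simulate_melt_curve,
    simulate_mlpa_profile,
)

from conftest import specimen


class TestGenotype:
    def test_rejects_double_null(self):
        with pytest.raises(ValueError):
            Genotype(0, 0)

    @pytest.mark.parametrize("bad", [(-1, 2), (7, 0), (2, 7)])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            Genotype(*bad)


class TestSampleSpec:
    def test_blank_needs_no_dna(self):
        with pytest.raises(ValueError):
            SampleSpec("b", None, 3.0, role=Role.BLANK)

    def test_sd074_ratio_enforced(self):
        with pytest.raises(ValueError):
            SampleSpec("c", Genotype(1, 4), 5.0, role=Role.SD074)
        SampleSpec("c", Genotype(1, 5), 5.0, role=Role.SD074)

    def test_sd075_lacks_smn1(self):
        with pytest.raises(ValueError):
            SampleSpec("c", Genotype(1, 2), 5.0, role=Role.SD075)

    def test_variant_shift_never_positive(self):
        with pytest.raises(ValueError):
            specimen((2, 2), shift=+1.0)


class TestGenerateCohort:
    def test_validation_composition_counts(self):
        specs = generate_cohort(VALIDATION_COHORT_COMPOSITION, seed=3)
        assert len(specs) == 422
        assert sum(s.genotype.smn1_copies == 0 for s in specs) == 47
        got = {}
        for s in specs:
            got[s.genotype] = got.get(s.genotype, 0) + 1
        assert got == VALIDATION_COHORT_COMPOSITION
        assert all(s.role is Role.SPECIMEN and s.input_dna_ng > 0 for s in specs)

    def test_empty_composition(self):
        assert generate_cohort({}, seed=0) == []

    def test_seed_controls_order_not_content(self):
        a = generate_cohort({(2, 2): 3, (0, 1): 2}, seed=1)
        b = generate_cohort({(2, 2): 3, (0, 1): 2}, seed=2)
        assert sorted(s.genotype for s in a) == sorted(s.genotype for s in b)
        assert [s.genotype for s in a] != [s.genotype for s in b]
        again = generate_cohort({(2, 2): 3, (0, 1): 2}, seed=1)
        assert [(s.genotype, s.input_dna_ng) for s in a] == \
               [(s.genotype, s.input_dna_ng) for s in again]

    def test_rejects_double_null_genotype(self):
        with pytest.raises(ValueError):
            generate_cohort({(0, 0): 1}, seed=0)


class TestMeltCurveModel:
    def test_sd075_has_no_smn1_transition(self, noiseless_config):
        spec = SampleSpec("sd075", Genotype(0, 2), 5.0, role=Role.SD075)
        curve = simulate_melt_curve(spec, noiseless_config)
        t = curve.temperatures_c
        neg = -np.gradient(curve.fluorescence, t)
        smn1 = neg[(t >= 61.5) & (t <= 64.5)]
        smn2 = neg[(t >= 53.5) & (t <= 58.5)]
        assert smn1.max() < 0.05 * smn2.max()
        apex = t[(t >= 53.5) & (t <= 58.5)][np.argmax(smn2)]
        assert apex == pytest.approx(56.0, abs=0.3)

    def test_blank_shows_only_q(self, noiseless_config):
        spec = SampleSpec("blank", None, 0.0, 0.0, role=Role.BLANK)
        a1, a2, aq = amplitudes(spec, noiseless_config)
        assert a1 == a2 == 0.0
        assert aq == noiseless_config.amplitude_total
        curve = simulate_melt_curve(spec, noiseless_config)
        t = curve.temperatures_c
        neg = -np.gradient(curve.fluorescence, t)
        assert 48.5 <= t[np.argmax(neg)] <= 49.5

    def test_equal_ratio_genotypes_are_indistinguishable(self, noiseless_config):
        a = simulate_melt_curve(specimen((1, 1)), noiseless_config)
        b = simulate_melt_curve(specimen((2, 2)), noiseless_config)
        np.testing.assert_allclose(a.fluorescence, b.fluorescence)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(c1=st.integers(0, 3), c2=st.integers(0, 3), lam=st.integers(2, 3))
    def test_ratio_only_visibility(self, c1, c2, lam, noiseless_config):
        # scaling both copy numbers leaves the (noiseless) curve unchanged
        if c1 + c2 == 0:
            return
        a = simulate_melt_curve(specimen((c1, c2)), noiseless_config)
        b = simulate_melt_curve(specimen((lam * c1, lam * c2)),
                                noiseless_config) \
            if max(lam * c1, lam * c2) <= 6 else None
        if b is not None:
            np.testing.assert_allclose(a.fluorescence, b.fluorescence)

    def test_q_amplitude_strictly_decreasing_in_dna(self, noiseless_config):
        qs = [amplitudes(specimen((2, 2), dna=d), noiseless_config)[2]
              for d in (0.5, 1, 2, 5, 10, 20)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_oversaturation_quenches_total_signal(self, noiseless_config):
        sat = simulate_melt_curve(specimen((2, 2), load=1.0), noiseless_config)
        over = simulate_melt_curve(specimen((2, 2), load=2.0), noiseless_config)
        assert over.fluorescence.sum() < sat.fluorescence.sum()
        # blood_load <= 1 does not quench
        dry = simulate_melt_curve(specimen((2, 2), load=0.5), noiseless_config)
        np.testing.assert_allclose(dry.fluorescence, sat.fluorescence)

    def test_variant_shift_never_raises_smn1_window_signal(self,
                                                           noiseless_config):
        heights = []
        for shift in (0.0, -1.0, -2.0, -3.0, -4.0, -6.0):
            curve = simulate_melt_curve(specimen((2, 2), shift=shift),
                                        noiseless_config)
            t = curve.temperatures_c
            neg = -np.gradient(curve.fluorescence, t)
            heights.append(neg[(t >= 62.0) & (t <= 64.5)].max())
        tol = 0.02 * heights[0]
        assert all(b <= a + tol for a, b in zip(heights, heights[1:]))

    def test_logistic_derivative_peak_closed_form(self):
        # independent oracle: A/(4w) at Tm, checked on a 0.01 degC grid
        amp, width, tm = 3.0, 1.2, 63.0
        t = np.arange(45, 75, 0.01)
        f = amp / (1 + np.exp(-(tm - t) / width))
        neg = -np.gradient(f, t)
        assert neg.max() == pytest.approx(amp / (4 * width), rel=1e-4)
        assert t[np.argmax(neg)] == pytest.approx(tm, abs=0.01)


class TestBuildPlates:
    def test_validation_cohort_fills_five_plates(self, config):
        specs = generate_cohort(VALIDATION_COHORT_COMPOSITION, 1, config)
        plates = build_plates(specs, seed=2, config=config)
        assert [len(p.specimens()) for p in plates] == [90, 90, 90, 90, 62]
        assert all(len(p.controls()) == 6 for p in plates)
        placed = sorted(s.sample_id for p in plates for _, s in p.specimens())
        assert placed == sorted(s.sample_id for s in specs)

    def test_single_specimen_plate(self, config):
        plates = build_plates([specimen((2, 2))], seed=0, config=config)
        assert len(plates) == 1
        assert len(plates[0].wells) == 7

    def test_full_plate_is_96_wells(self, config):
        specs = [specimen((2, 2), sample_id=f"s{i}") for i in range(90)]
        plates = build_plates(specs, seed=0, config=config)
        assert len(plates) == 1
        assert len(plates[0].wells) == 96

    def test_control_well_roles(self, config):
        plates = build_plates([specimen((2, 2))], seed=0, config=config)
        roles = sorted(s.role.value for _, s in plates[0].controls())
        assert roles == ["BLANK", "BLANK", "SD074", "SD074", "SD075", "SD075"]

    def test_empty_cohort_rejected(self, config):
        with pytest.raises(ValueError):
            build_plates([], seed=0, config=config)


class TestMlpaSimulation:
    def test_deleted_gene_yields_zero_probes(self, noiseless_mlpa_config):
        profile = simulate_mlpa_profile(specimen((0, 2)), noiseless_mlpa_config)
        for probe, ann in profile.probe_annotations.items():
            h = profile.probe_heights[probe]
            if ann.target in (ProbeTarget.SMN1_EX7, ProbeTarget.SMN1_EX8):
                assert h == 0.0
            else:
                assert h == pytest.approx(2.0)

    def test_heights_proportional_to_copies(self, noiseless_mlpa_config):
        profile = simulate_mlpa_profile(specimen((2, 4)), noiseless_mlpa_config)
        for probe, ann in profile.probe_annotations.items():
            copies = {ProbeTarget.SMN1_EX7: 2, ProbeTarget.SMN1_EX8: 2,
                      ProbeTarget.SMN2_EX7: 4, ProbeTarget.SMN2_EX8: 4,
                      ProbeTarget.REFERENCE: 2}[ann.target]
            assert profile.probe_heights[probe] == pytest.approx(copies)

    def test_panel_composition(self, config):
        profile = simulate_mlpa_profile(specimen((2, 2)), config)
        by_target = {}
        for ann in profile.probe_annotations.values():
            by_target[ann.target] = by_target.get(ann.target, 0) + 1
        assert by_target[ProbeTarget.REFERENCE] >= 8
        assert all(by_target[t] >= 2 for t in ProbeTarget
                   if t is not ProbeTarget.REFERENCE)


def test_simulation_config_requires_ordered_tms():
    with pytest.raises(ValueError):
        SimulationConfig(tm_smn1_c=55.0)
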