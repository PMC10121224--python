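import numpy as np
import pandas as pd
import pytest

from organoscreen.errors import ConfigError
from organoscreen.model import CellLine, Treatment
from organoscreen.simulate import (
    PRESETS,
    GroundTruth,
    SimConfig,
    simulate_campaign,
    truth_to_expected_calls,
)
from organoscreen.triage import TriageConfig


def noiseless_config(**kw):
    base = dict(
        n_compounds=5,
        noise_cv=0.0,
        gradient_amplitude=0.0,
        edge_amplitude=0.0,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


def dmso_mean(plates, line, channel):
    df = plates.wells
    sel = (df.cell_line == line.value) & (df.treatment == Treatment.DMSO.value)
    return df.loc[sel, channel].mean()


class TestSimulateCampaign:
    def test_reproducible_bit_identical_for_fixed_seed(self):
        cfg = SimConfig(n_compounds=40, seed=9)
        a, truth_a = simulate_campaign(cfg)
        b, truth_b = simulate_campaign(SimConfig(n_compounds=40, seed=9))
        pd.testing.assert_frame_equal(a.wells, b.wells)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_different_seed_changes_intensities(self):
        a, _ = simulate_campaign(SimConfig(n_compounds=40, seed=9))
        b, _ = simulate_campaign(SimConfig(n_compounds=40, seed=10))
        assert not a.wells["gfp"].equals(b.wells["gfp"])

    def test_null_screen_compound_wells_sit_at_rd16_baseline(self):
        cfg = noiseless_config(
            class_probabilities={"inactive": 1.0}, n_compounds=8
        )
        plates, _ = simulate_campaign(cfg)
        df = plates.wells
        disease = df[
            (df.treatment == Treatment.COMPOUND.value)
            & (df.cell_line == CellLine.RD16.value)
        ]
        assert np.allclose(disease.gfp, cfg.rd16_gfp_fraction * cfg.wt_gfp_mean)
        assert np.allclose(
            disease.dapi, cfg.rd16_viability_fraction * cfg.dapi_mean
        )

    def test_full_rescue_at_saturation_reaches_wt_gfp_level(self):
        # a purely efficacious compound at C >> AC50 with Ainf = 1 restores
        # the WT GFP level exactly in the noiseless simulator
        cfg = noiseless_config(
            class_probabilities={"efficacious": 1.0}, n_compounds=3
        )
        plates, truth = simulate_campaign(cfg)
        df = plates.wells
        wt_mean = dmso_mean(plates, CellLine.WT, "gfp")
        for t in truth.itertuples(index=False):
            top = df[
                (df.compound_id == t.compound_id)
                & (df.cell_line == CellLine.RD16.value)
                & (df.concentration_molar > 1e4 * t.ac50_e)
            ]
            if len(top) == 0:
                continue
            expected = (
                cfg.rd16_gfp_fraction * cfg.wt_gfp_mean
                + t.ainf_e * (wt_mean - cfg.rd16_gfp_fraction * cfg.wt_gfp_mean)
            )
            assert np.allclose(top.gfp, expected, rtol=1e-6)

    def test_disease_deficit_calibration_recovered_from_noisy_controls(self):
        # empirical RD16/WT DMSO ratios match the configured fractions
        cfg = SimConfig(n_compounds=100, seed=5)
        plates, _ = simulate_campaign(cfg)
        df = plates.wells
        for channel, frac in (
            ("gfp", cfg.rd16_gfp_fraction),
            ("dapi", cfg.rd16_viability_fraction),
        ):
            rd = df[
                (df.cell_line == CellLine.RD16.value)
                & (df.treatment == Treatment.DMSO.value)
            ][channel]
            wt = df[
                (df.cell_line == CellLine.WT.value)
                & (df.treatment == Treatment.DMSO.value)
            ][channel]
            ratio = rd.mean() / wt.mean()
            se = ratio * np.sqrt(
                rd.std() ** 2 / (rd.mean() ** 2 * len(rd))
                + wt.std() ** 2 / (wt.mean() ** 2 * len(wt))
            )
            assert abs(ratio - frac) < 3 * se + 1e-9

    def test_monotone_in_saturating_amplitude(self):
        # raising Ainf never lowers any noiseless disease-assay GFP well
        base = noiseless_config(class_probabilities={"efficacious": 1.0},
                                n_compounds=2)
        plates_a, truth_a = simulate_campaign(base)

        from organoscreen.simulate import _expected_intensities
        from organoscreen.model import AssayKind

        series = np.array(base.series)
        for t in truth_a.itertuples(index=False):
            lo_t = GroundTruth(
                t.compound_id, t.compound_class, True, False, False,
                a0_e=0.0, ainf_e=t.ainf_e * 0.5, ac50_e=t.ac50_e, n_e=t.n_e,
            )
            hi_t = GroundTruth(
                t.compound_id, t.compound_class, True, False, False,
                a0_e=0.0, ainf_e=t.ainf_e, ac50_e=t.ac50_e, n_e=t.n_e,
            )
            g_lo, _ = _expected_intensities(lo_t, series, base, AssayKind.DISEASE_ASSAY)
            g_hi, _ = _expected_intensities(hi_t, series, base, AssayKind.DISEASE_ASSAY)
            assert (g_hi >= g_lo - 1e-12).all()

    def test_counter_screen_sees_autofluorescence_not_rescue(self):
        cfg = noiseless_config(
            class_probabilities={"efficacious": 0.5, "autofluorescent": 0.5},
            n_compounds=10,
        )
        plates, truth = simulate_campaign(cfg)
        df = plates.wells
        par = df[
            (df.cell_line == CellLine.PARENTAL.value)
            & (df.treatment == Treatment.COMPOUND.value)
        ]
        for t in truth.itertuples(index=False):
            mine = par[par.compound_id == t.compound_id]
            if t.is_autofluorescent:
                assert mine.gfp.max() > cfg.parental_gfp_mean + 1.0
            else:
                assert np.allclose(mine.gfp, cfg.parental_gfp_mean)

    def test_control_well_counts_meet_minima(self, small_campaign):
        _, plates, _ = small_campaign
        df = plates.wells
        for pid in plates.plate_ids:
            sub = df[df.plate_id == pid]
            dmso = sub[sub.treatment == Treatment.DMSO.value]
            assert len(dmso) >= 16

    def test_probabilities_must_sum_to_one(self):
        cfg = SimConfig(class_probabilities={"inactive": 0.5, "toxic": 0.4})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(preset="weekly-3pt").validate()

    def test_presets_match_screen_designs(self):
        assert PRESETS["primary-7pt"][1:] == (3.0, 7, 1)
        assert PRESETS["confirmatory-11pt-x3"][1:] == (3.0, 11, 3)


class TestExpectedCalls:
    def _truth_frame(self, truths):
        from organoscreen.simulate import truth_table

        return truth_table(truths)

    def test_clean_efficacious_compound_is_expected_hit(self):
        cfg = noiseless_config()
        t = GroundTruth("A", "efficacious", True, False, False,
                        a0_e=0.0, ainf_e=0.8, ac50_e=1e-4, n_e=1.5)
        out = truth_to_expected_calls(
            self._truth_frame([t]), TriageConfig(), cfg
        )
        assert out.expected_verdict.tolist() == ["HIT"]

    def test_matched_autofluorescence_is_expected_nonhit(self):
        cfg = noiseless_config()
        t = GroundTruth(
            "A", "efficacious+autofluorescent", True, False, True,
            a0_e=0.0, ainf_e=0.8, ac50_e=1e-4, n_e=1.5,
            ac50_f=1.5e-4, n_f=1.5, added_intensity=500.0,
        )
        out = truth_to_expected_calls(
            self._truth_frame([t]), TriageConfig(), cfg
        )
        assert out.expected_verdict.tolist() == ["AUTOFLUORESCENT"]
        assert not out.expected_hit.iloc[0]

    def test_inactive_compound_is_expected_nonhit(self):
        cfg = noiseless_config()
        t = GroundTruth("A", "inactive", False, False, False)
        out = truth_to_expected_calls(
            self._truth_frame([t]), TriageConfig(), cfg
        )
        assert out.expected_verdict.tolist() == ["INACTIVE"]

    def test_toxicity_inside_series_suppresses_expected_hit(self):
        # nominal selectivity ratio passes the margin, but the kill inside
        # the tested range wrecks the top of the observable efficacy curve
        cfg = noiseless_config()
        t = GroundTruth(
            "A", "efficacious+toxic", True, True, False,
            a0_e=0.0, ainf_e=0.9, ac50_e=3e-5, n_e=2.0,
            ac50_t=3.6e-4, n_t=2.0, max_kill=0.7,
        )
        out = truth_to_expected_calls(
            self._truth_frame([t]), TriageConfig(), cfg
        )
        assert out.expected_verdict.tolist() == ["TOXIC"]

    def test_pure_autofluorescent_expected_caught_by_counter_screen(self):
        cfg = noiseless_config()
        t = GroundTruth(
            "A", "autofluorescent", False, False, True,
            ac50_f=1e-4, n_f=1.5, added_intensity=500.0,
        )
        out = truth_to_expected_calls(
            self._truth_frame([t]), TriageConfig(), cfg
        )
        assert out.expected_verdict.tolist() == ["AUTOFLUORESCENT"]
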