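"""Affinity scoring: unit conversions, window/promoter aggregation and
the least-squares calibration of the slide/stop/bend model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tatascan import (
    TbpAffinityModel,
    kd_nM_to_neglog,
    neglog_to_kd_nM,
    promoter_affinity,
    window_affinity,
)
from tatascan.affinity import AffinityModelConfig, pwm_best_subwindow
from tatascan.fixtures import calibrate_model, verification_panel_frame
from tatascan.records import SequenceAlphabetError, SequenceLengthError

from conftest import random_dna


class TestUnitConversions:
    @pytest.mark.parametrize(
        "kd_nM,expected",
        [(39, 17.06), (260, 15.16), (1500, 13.41), (160, 15.65)],
    )
    def test_nM_to_neglog_matches_printed_precision(self, kd_nM, expected):
        assert round(kd_nM_to_neglog(kd_nM), 2) == expected

    def test_one_molar_is_zero(self):
        assert kd_nM_to_neglog(1e9) == pytest.approx(0.0)

    def test_nonpositive_kd_rejected(self):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                kd_nM_to_neglog(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e9))
    def test_round_trip(self, kd):
        assert neglog_to_kd_nM(kd_nM_to_neglog(kd)) == pytest.approx(
            kd, rel=1e-9
        )


class TestWindowAffinity:
    def test_deterministic(self, config):
        seq = "GAGGTCGCCGCGTATAAATAGTGAGA"
        assert window_affinity(seq, config) == window_affinity(seq, config)

    def test_wrong_length(self, config):
        with pytest.raises(SequenceLengthError):
            window_affinity("ACGT" * 7, config)

    def test_unknown_base(self, config):
        with pytest.raises(SequenceAlphabetError):
            window_affinity("N" * 26, config)


class TestPromoterAffinity:
    def test_single_window_degenerate_case(self, config):
        seq = "GAGGTCGCCGCGTATAAATAGTGAGA"
        est = promoter_affinity(seq, config)
        assert est.neglog_kd == window_affinity(seq, config)
        assert est.best_window_offset == 0
        assert est.se == config.residual_sd_sigma

    def test_kd_consistent_with_neglog(self, config, rng):
        est = promoter_affinity(random_dna(rng, 70), config)
        assert est.kd_nM == pytest.approx(1e9 * math.exp(-est.neglog_kd))

    def test_too_short(self, config):
        with pytest.raises(SequenceLengthError):
            promoter_affinity("ACGT" * 6, config)

    def test_equals_brute_force_window_enumeration(self, config, rng):
        # independent oracle: explicit max over all L-25 windows
        for L in (26, 31, 70, 128, 200):
            seq = random_dna(rng, L, gc=0.4)
            scores = [
                window_affinity(seq[i:i + 26], config)
                for i in range(L - 25)
            ]
            est = promoter_affinity(seq, config)
            assert est.neglog_kd == max(scores)
            assert scores[est.best_window_offset] == max(scores)

    def test_appending_base_never_decreases_score(self, config, rng):
        seq = random_dna(rng, 60)
        base = promoter_affinity(seq, config).neglog_kd
        for extra in "ACGT":
            assert promoter_affinity(seq + extra, config).neglog_kd >= base

    def test_embedded_strong_site_scores_as_its_own_window(
            self, config, panel_fixture):
        # SHOX: a strong TATA box between GC-only flanks; the promoter
        # estimate must equal the embedded probe's window score
        promoters, _ = panel_fixture
        shox = next(p for p in promoters if p.gene_id == "SHOX")
        odn = verification_panel_frame().query(
            "gene == 'SHOX' and allele_class == 'WT'"
        ).sequence.iloc[0]
        est = promoter_affinity(shox.sequence, config)
        assert est.neglog_kd == window_affinity(odn.upper(), config)
        assert est.best_window_offset == shox.sequence.find(odn.upper())


class TestStopTermMonotonicity:
    def test_consensus_edit_never_decreases_pwm_score(self, config, rng):
        consensus = config.consensus()
        for _ in range(25):
            seq = random_dna(rng, 26)
            score, start = pwm_best_subwindow(seq, config)
            j = int(rng.integers(0, config.pwm_length))
            edited = (seq[:start + j] + consensus[j]
                      + seq[start + j + 1:])
            assert pwm_best_subwindow(edited, config)[0] >= score


class TestCalibration:
    def test_shipped_config_is_the_panel_fit(self, config):
        model = calibrate_model()
        assert model.intercept_ == pytest.approx(config.coef_intercept)
        assert model.coef_ == pytest.approx(
            [config.coef_slide, config.coef_stop, config.coef_bend]
        )

    def test_recovers_printed_ordering_and_signs(self, config, panel_odns):
        model = TbpAffinityModel.from_config(config)
        pred = {(o.gene_id, o.allele_class): model.predict([o.sequence])[0]
                for o in panel_odns}
        printed = {(o.gene_id, o.allele_class): o.predicted_neglog_kd
                   for o in panel_odns}
        keys = list(printed)
        r = np.corrcoef([pred[k] for k in keys], [printed[k] for k in keys])
        assert r[0, 1] > 0.95
        for gene in ("SHOX", "GTPBP6", "ASMT", "ZFY", "CDY2A"):
            d_model = pred[(gene, "min")] - pred[(gene, "WT")]
            d_print = printed[(gene, "min")] - printed[(gene, "WT")]
            assert math.copysign(1, d_model) == math.copysign(1, d_print)

    def test_coefficient_signs_are_physical(self, config):
        # TA-step density, PWM match and site deformability all favour
        # binding
        assert config.coef_slide > 0
        assert config.coef_stop > 0
        assert config.coef_bend > 0

    def test_estimator_follows_sklearn_conventions(self, panel_odns):
        from sklearn.base import clone

        model = TbpAffinityModel(residual_sd_sigma=0.3)
        cloned = clone(model)
        assert cloned.get_params()["residual_sd_sigma"] == 0.3
        X = [o.sequence for o in panel_odns]
        y = [o.predicted_neglog_kd for o in panel_odns]
        fitted = cloned.fit(X, y)
        assert fitted.predict(X).shape == (10,)
        assert fitted.config_.residual_sd_sigma == 0.3
        assert len(fitted.loo_residuals_) == 10


class TestConfigIO:
    def test_yaml_round_trip(self, config, tmp_path):
        path = tmp_path / "model.yaml"
        config.to_yaml(path)
        back = AffinityModelConfig.from_yaml(path)
        assert back == config

    def test_bad_sigma_rejected(self, config):
        with pytest.raises(ValueError):
            AffinityModelConfig(
                pwm_counts=config.pwm_counts,
                nn_dg=config.nn_dg,
                coef_intercept=0, coef_slide=0, coef_stop=0, coef_bend=0,
                residual_sd_sigma=0.0,
            )
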