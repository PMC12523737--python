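"""Generator determinism, calibration bands, and known-truth recovery."""

import dataclasses

import numpy as np
import pytest

from haarisk.data import Censor, CensoringPolicy, Treatment, totals_by_sample
from haarisk.doe import Factor, build_full_factorial, estimate_effects
from haarisk.errors import ConfigError, InsufficientDesignError
from haarisk.simulate import (
    DEFAULT_LODS,
    DEFAULT_LOQS,
    GeneratorConfig,
    generate_calibration,
    generate_concentrations,
    generate_doe_responses,
    generate_recovery_training,
)
from haarisk.stats import compare_commercial_homemade
from haarisk.validation import fit_calibration, matrix_effect

FACTORS3 = [Factor("A", 0, 1), Factor("B", 0, 1), Factor("C", 0, 1)]


class TestConcentrationGenerator:
    def test_same_seed_reproduces_identical_output(self):
        a = generate_concentrations(GeneratorConfig(seed=5))
        b = generate_concentrations(GeneratorConfig(seed=5))
        assert a.records == b.records

    def test_different_seeds_differ(self):
        a = generate_concentrations(GeneratorConfig(seed=5))
        b = generate_concentrations(GeneratorConfig(seed=6))
        assert a.records != b.records

    def test_noiseless_synergy_multiplies_sweet_pasteurized_only(self):
        base_cfg = GeneratorConfig(seed=0, noise_sd=0.0, synergy=1.0)
        doubled = dataclasses.replace(base_cfg, synergy=2.0)
        a = generate_concentrations(base_cfg)
        b = generate_concentrations(doubled)
        for ra, rb in zip(a.records, b.records):
            if ra.censor is not Censor.QUANTIFIED or rb.censor is not Censor.QUANTIFIED:
                continue
            factor = rb.concentration / ra.concentration
            if ra.meta.treatment in (Treatment.HSP, Treatment.CSP):
                assert factor == pytest.approx(2.0)
            else:
                assert factor == pytest.approx(1.0)

    def test_default_lod_and_loq_bands(self):
        assert all(0.01 <= v <= 0.04 for v in DEFAULT_LODS.values())
        assert all(0.02 <= v <= 0.05 for v in DEFAULT_LOQS.values())
        assert all(DEFAULT_LOQS[c] > DEFAULT_LODS[c] for c in DEFAULT_LODS)

    def test_sample_totals_within_survey_band(self):
        """Totals stay in the emulated survey range in >= 99% of draws."""
        totals = []
        for seed in range(17):  # 17 surveys × 60 samples > 1000 draws
            cset = generate_concentrations(GeneratorConfig(seed=seed))
            totals.extend(totals_by_sample(cset).to_numpy())
        totals = np.array(totals[:1000])
        in_band = np.mean((totals >= 0.05) & (totals <= 20.0))
        assert in_band >= 0.99

    def test_treatment_ordering_in_expectation_per_base(self):
        """Mean totals order HSP > HP, HSP > HS, HSP > H within every base."""
        sums: dict[tuple[str, str], float] = {}
        for seed in range(200):
            cfg = GeneratorConfig(seed=seed, n_replicates=1)
            cset = generate_concentrations(cfg)
            totals = totals_by_sample(cset, CensoringPolicy.HALF_LOD)
            for sid, value in totals.items():
                meta = cset.sample_meta(sid)
                key = (meta.base.value, meta.treatment.value)
                sums[key] = sums.get(key, 0.0) + value
        for base in ("almond", "soy", "cashew", "peanut"):
            hsp = sums[(base, "HSP")]
            assert hsp > sums[(base, "HP")]
            assert hsp > sums[(base, "HS")]
            assert hsp > sums[(base, "H")]

    def test_commercial_shift_power(self):
        """Welch test detects the commercial shift in >= 80% of 200 seeds."""
        hits = sum(
            compare_commercial_homemade(
                generate_concentrations(GeneratorConfig(seed=seed))
            ).p_value
            < 0.05
            for seed in range(200)
        )
        assert hits / 200 >= 0.80

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_replicates=0)
        with pytest.raises(ConfigError):
            GeneratorConfig(noise_sd=-1.0)
        with pytest.raises(ConfigError):
            GeneratorConfig(lods={"IQ": -0.01})
        with pytest.raises(ConfigError):
            GeneratorConfig(base_profiles={})  # type: ignore[arg-type]


class TestCalibrationGenerator:
    def test_matrix_factor_unity_no_matrix_effect(self):
        solvent, spiked = generate_calibration(matrix_factor=1.0, noise_sd=0.0)
        me = matrix_effect(
            fit_calibration(spiked).slope, fit_calibration(solvent).slope
        )
        assert me == pytest.approx(0.0, abs=1e-9)

    def test_known_matrix_factor_recovered_exactly_without_noise(self):
        solvent, spiked = generate_calibration(matrix_factor=0.95, noise_sd=0.0)
        me = matrix_effect(
            fit_calibration(spiked).slope, fit_calibration(solvent).slope
        )
        assert me == pytest.approx(5.0, abs=1e-9)

    def test_seeded_noise_preserves_linearity(self):
        # noise at 1% of the maximum response
        solvent, _ = generate_calibration(
            slope=1000.0, noise_sd=0.01 * 1000.0 * 80.0 / 100, seed=2
        )
        assert fit_calibration(solvent).r_squared > 0.99

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDesignError):
            generate_calibration(levels=(1.0, 2.0, 4.0))


class TestDoeGenerator:
    def test_zero_noise_effects_are_twice_coefficients(self):
        design = build_full_factorial(FACTORS3)
        truth = {"intercept": 50.0, "A": 4.0, "B": -2.0, "A:C": 1.5}
        design.responses["y"] = generate_doe_responses(truth, design)
        effects = {e.term: e.effect for e in estimate_effects(design, "y").entries}
        assert effects["A"] == pytest.approx(8.0)
        assert effects["B"] == pytest.approx(-4.0)
        assert effects["A:C"] == pytest.approx(3.0)
        assert effects["A:B:C"] == pytest.approx(0.0, abs=1e-12)

    def test_small_noise_median_recovery_error_bounded(self):
        """Median absolute effect-recovery error < 3 × noise over 100 seeds."""
        noise_sd = 0.5
        truth = {"intercept": 10.0, "A": 3.0, "B": 2.0, "A:B": 1.0}
        errors = []
        for seed in range(100):
            design = build_full_factorial(FACTORS3)
            design.responses["y"] = generate_doe_responses(
                truth, design, noise_sd=noise_sd, seed=seed
            )
            effects = {
                e.term: e.effect for e in estimate_effects(design, "y").entries
            }
            errors.append(
                max(
                    abs(effects["A"] - 6.0),
                    abs(effects["B"] - 4.0),
                    abs(effects["A:B"] - 2.0),
                )
            )
        assert np.median(errors) < 3 * noise_sd

    def test_null_truth_rarely_flags_significance(self):
        """Type-I: all-zero coefficients flag nothing in >= 90% of seeds."""
        clean = 0
        for seed in range(100):
            design = build_full_factorial(FACTORS3)
            design.responses["y"] = generate_doe_responses(
                {"intercept": 10.0}, design, noise_sd=1.0, seed=seed
            )
            table = estimate_effects(design, "y")
            clean += not any(e.significant for e in table.entries)
        assert clean / 100 >= 0.90

    def test_unknown_factor_in_term_rejected(self):
        design = build_full_factorial(FACTORS3)
        with pytest.raises(InsufficientDesignError, match="unknown factor"):
            generate_doe_responses({"Z": 1.0}, design)

    def test_recovery_training_shape(self):
        X, responses, factors = generate_recovery_training(seed=0)
        assert X.shape == (27, 4)
        assert responses.shape == (27, 10)
        assert len(factors) == 4
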