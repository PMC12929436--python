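"""Synthetic-data generators: determinism, noise model, convergence."""

import numpy as np
import pandas as pd
import pytest

from photothermal import io as ptio
from photothermal.synth import (
    CtEffect,
    DEFAULT_GENOTYPE_PARAMS,
    DesignSpec,
    default_ct_effects,
    default_design,
    generate_ct_table,
    generate_phenotypes,
    generate_temperature_log,
)
from photothermal.thermal import accumulate_thermal_time
from photothermal.types import (
    CANONICAL_GENOTYPES,
    ResponseParams,
    ValidationError,
)


class TestGeneratePhenotypes:
    def test_default_design_yields_350_records(self):
        recs = generate_phenotypes(default_design(seed=0))
        assert len(recs) == 350  # 7 genotypes x 5 photoperiods x 5 x 2

    def test_noise_free_records_equal_bilinear_mean(self, genotype_spec):
        params = ResponseParams(600.0, 50.0, 20.0, sigma=0.0)
        design = DesignSpec(genotypes=[(genotype_spec, params)],
                            photoperiods_h=[16.0], seed=1)
        recs = generate_phenotypes(design)
        assert all(r.thermal_time_cd == pytest.approx(800.0) for r in recs)

    def test_flat_genotype_mean_equal_across_photoperiods(self, genotype_spec):
        sigma, reps, repetitions = 12.0, 200, 2
        params = ResponseParams(550.0, 0.0, 16.0, sigma=sigma)
        design = DesignSpec(genotypes=[(genotype_spec, params)],
                            replicates=reps, repetitions=repetitions, seed=5)
        recs = generate_phenotypes(design)
        by_p = {}
        for r in recs:
            by_p.setdefault(r.photoperiod_h, []).append(r.thermal_time_cd)
        diff = np.mean(by_p[16.0]) - np.mean(by_p[24.0])
        se = sigma * np.sqrt(2.0 / (reps * repetitions))
        assert abs(diff) <= 3.0 * se

    def test_same_seed_byte_identical_files_different_seed_differs(self, tmp_path):
        a, b, c = (tmp_path / n for n in ("a.csv", "b.csv", "c.csv"))
        ptio.write_phenotypes(a, generate_phenotypes(default_design(seed=9)),
                              CANONICAL_GENOTYPES)
        ptio.write_phenotypes(b, generate_phenotypes(default_design(seed=9)),
                              CANONICAL_GENOTYPES)
        ptio.write_phenotypes(c, generate_phenotypes(default_design(seed=10)),
                              CANONICAL_GENOTYPES)
        assert a.read_bytes() == b.read_bytes()
        assert a.read_bytes() != c.read_bytes()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            ResponseParams(600.0, 50.0, 20.0, sigma=-1.0)

    def test_repetition_shift_applied_to_second_repetition_only(self,
                                                                genotype_spec):
        params = ResponseParams(600.0, 0.0, 16.0, sigma=0.0)
        design = DesignSpec(genotypes=[(genotype_spec, params)],
                            photoperiods_h=[16.0], repetition_shift=30.0,
                            seed=2)
        recs = generate_phenotypes(design)
        assert {r.thermal_time_cd for r in recs if r.repetition == 1} == {600.0}
        assert {r.thermal_time_cd for r in recs if r.repetition == 2} == {630.0}

    def test_empirical_means_converge_to_generating_curve(self, simulate_single):
        # large-replicate simulation: genotype means approach the bi-linear
        # truth within 3 standard errors at every photoperiod
        params = ResponseParams(620.0, 45.0, 19.5, sigma=12.0)
        reps = 500
        recs = simulate_single(params, seed=21, replicates=reps)
        se = params.sigma / np.sqrt(reps)
        for p in (16.0, 18.0, 20.0, 22.0, 24.0):
            sample = [r.thermal_time_cd for r in recs if r.photoperiod_h == p]
            assert np.mean(sample) == pytest.approx(params.mean(p), abs=3 * se)


class TestGenerateTemperatureLog:
    def test_constant_log_10_days(self):
        log = generate_temperature_log(days=10, sd_c=0.0)
        assert len(log) == 480
        assert (log.series == 20.0).all()
        tt = accumulate_thermal_time(log, log.start,
                                     log.start + pd.Timedelta(days=10))
        assert tt == pytest.approx(200.0)

    def test_daily_means_concentrate_around_setpoint(self):
        # sd 0.5 per reading, 48 readings/day -> SE ~0.072; 4-sigma ~0.29
        log = generate_temperature_log(days=100, sd_c=0.5, seed=8)
        daily = log.series.groupby(log.series.index.normalize()).mean()
        assert len(daily) == 100
        assert (np.abs(daily - 20.0) < 0.3).all()


class TestGenerateCtTable:
    def _effects(self, genes, genos, pps, zts, mean=25.0, p=0.0):
        return {(g, geno, pp, zt): CtEffect(mean, p)
                for g in genes for geno in genos for pp in pps for zt in zts}

    def test_record_count_is_design_product(self):
        genes, genos, pps, zts = ["A", "B"], ["g1", "g2", "g3", "g4"], \
            [16.0, 22.0], [5.0, 11.0, 17.0, 23.0]
        recs = generate_ct_table(genes, genos, pps,
                                 self._effects(genes, genos, pps, zts),
                                 zts=zts, seed=0)
        assert len(recs) == 2 * 4 * 2 * 4 * 2 * 2  # 256

    def test_undetected_probability_one_flags_everything(self):
        recs = generate_ct_table(["A"], ["g"], [16.0],
                                 self._effects(["A"], ["g"], [16.0], [5.0],
                                               p=1.0),
                                 zts=[5.0], seed=0)
        assert all(r.undetected for r in recs)

    def test_zero_variance_components_reproduce_means_exactly(self):
        recs = generate_ct_table(["A"], ["g"], [16.0],
                                 self._effects(["A"], ["g"], [16.0], [5.0],
                                               mean=24.0),
                                 zts=[5.0], bio_sd=0.0, tech_sd=0.0, seed=0)
        assert all(r.ct == 24.0 for r in recs)

    def test_dropout_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            CtEffect(25.0, undetected_p=1.5)

    def test_default_effects_cover_full_factorial(self):
        genes, genos, pps, effects = default_ct_effects()
        assert set(genes) == {"HvTubA", "PPD-H1", "FT1"}
        assert len(effects) == len(genes) * len(genos) * len(pps) * 4


class TestDefaultFixture:
    def test_ppdh1_hsp_lines_generated_flat(self):
        for gid, params in DEFAULT_GENOTYPE_PARAMS.items():
            spec = CANONICAL_GENOTYPES[gid]
            if spec.ppdh1_allele.value == "Hsp" or spec.elf3_allele.value == "elf3":
                assert params.sensitivity == 0.0
            else:
                assert params.sensitivity > 0.0
                assert params.threshold == 20.0
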