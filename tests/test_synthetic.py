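"""Synthetic cohort generator: determinism, structure, effect directions."""

import numpy as np
import pytest

from fetalhrv.errors import ConfigError
from fetalhrv.synthetic import (
    HOURS,
    IL6_FLOOR,
    PHYSIOLOGY_TRAJECTORIES,
    LPSEffects,
    RRBaseline,
    SyntheticCohortConfig,
    _rng_for,
    generate_cohort,
    generate_physiology,
    generate_rr,
    spectral_fgn,
    write_cohort,
)


def small_config(seed=0, **kw):
    kw.setdefault("n_lps", 2)
    kw.setdefault("n_control", 2)
    kw.setdefault("record_length", 1200.0)
    return SyntheticCohortConfig(seed=seed, **kw)


class TestRRGeneration:
    def test_zero_noise_gives_constant_rr(self):
        b = RRBaseline(lf_amp_ms=0, hf_amp_ms=0, fgn_sd_ms=0, white_sd_ms=0)
        s = generate_rr(400.0, 300.0, np.random.default_rng(0), baseline=b)
        np.testing.assert_allclose(s.rr_intervals, 400.0, atol=1e-6)

    def test_sdnn_near_configured_target(self):
        """Generator self-consistency: full-record interval SD within 30%
        of the configured composite SD."""
        b = RRBaseline()
        target = np.sqrt(b.total_var)
        sds = [np.std(generate_rr(340.0, 1500.0,
                                  np.random.default_rng(s)).rr_intervals,
                      ddof=1)
               for s in range(5)]
        assert np.mean(sds) == pytest.approx(target, rel=0.30)

    def test_lps_h3_raises_variability_in_most_seeds(self):
        """The H2-H4 variance surge shows in full-record SD for nearly
        every seed (stochastic dominance by construction)."""
        from fetalhrv.synthetic import _hour_rr_params

        cfg = SyntheticCohortConfig()
        wins = 0
        n = 20
        for s in range(n):
            p0 = _hour_rr_params(cfg, "LPS", 0, 0.0)
            p3 = _hour_rr_params(cfg, "LPS", 3, 0.0)
            sd0 = np.std(generate_rr(p0["mean_rr_ms"], 1200.0,
                                     np.random.default_rng(1000 + s),
                                     fgn_sd_ms=p0["fgn_sd_ms"],
                                     fgn_alpha=p0["fgn_alpha"]).rr_intervals)
            sd3 = np.std(generate_rr(p3["mean_rr_ms"], 1200.0,
                                     np.random.default_rng(2000 + s),
                                     fgn_sd_ms=p3["fgn_sd_ms"],
                                     fgn_alpha=p3["fgn_alpha"]).rr_intervals)
            wins += sd3 > sd0
        assert wins >= 0.9 * n

    def test_out_of_bound_mean_rr_rejected(self):
        with pytest.raises(ConfigError):
            generate_rr(50.0, 300.0, np.random.default_rng(0))


class TestFractionalNoise:
    def test_unit_scale_and_zero_mean(self, rng):
        x = spectral_fgn(4096, 0.9, rng)
        assert np.mean(x) == pytest.approx(0.0, abs=1e-9)
        assert np.std(x) == pytest.approx(1.0, rel=1e-9)

    def test_alpha_one_has_more_lowfreq_power_than_half(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        white = spectral_fgn(4096, 0.5, rng1)
        pink = spectral_fgn(4096, 1.0, rng2)
        def lowfreq_fraction(x):
            p = np.abs(np.fft.rfft(x))**2
            return p[1:41].sum() / p[1:].sum()
        assert lowfreq_fraction(pink) > 2 * lowfreq_fraction(white)


class TestPhysiology:
    def test_control_il6_censored_every_hour(self):
        cohort = generate_cohort(small_config(seed=5))
        for subj in cohort.subjects:
            if subj.group != "Control":
                continue
            for hour in HOURS:
                assert subj.physiology[hour]["IL6"] == IL6_FLOOR

    def test_zero_noise_reproduces_medians(self):
        traj = {
            var: {**spec, "sd_between": 0.0, "sd_within": 0.0,
                  "sigma_log": 0.0}
            for var, spec in PHYSIOLOGY_TRAJECTORIES.items()
        }
        cfg = small_config()
        effects = {var: 0.0 for var in traj}
        out = generate_physiology(cfg, "LPS", 3, effects,
                                  np.random.default_rng(0), trajectories=traj)
        assert out["pH"] == pytest.approx(7.32)
        assert out["Lactate"] == pytest.approx(4.44)

    def test_lps_ph_declines_to_h3_in_expectation(self):
        meds = PHYSIOLOGY_TRAJECTORIES["pH"]["LPS"][:4]
        assert all(b <= a for a, b in zip(meds, meds[1:]))

    def test_tachycardia_at_h6(self):
        cohort = generate_cohort(small_config(seed=2, n_lps=4, n_control=4))
        phys = cohort.physiology_frame()
        h6 = phys[phys["timepoint"] == "H6"]
        lps = h6[h6["group"] == "LPS"]["FHR"].mean()
        ctrl = h6[h6["group"] == "Control"]["FHR"].mean()
        assert lps > ctrl + 10


class TestCohort:
    def test_default_inventory(self):
        cfg = SyntheticCohortConfig()
        assert cfg.n_lps == 8 and cfg.n_control == 7
        # record count without generating the full default cohort
        cohort = generate_cohort(small_config(n_lps=3, n_control=2))
        assert sum(1 for _ in cohort.iter_records()) == 5 * 7

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = small_config(seed=11)
        write_cohort(generate_cohort(cfg), tmp_path / "a")
        write_cohort(generate_cohort(cfg), tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_different_seeds_differ_in_content_not_structure(self, tmp_path):
        c1 = generate_cohort(small_config(seed=1), out_dir=tmp_path / "s1")
        c2 = generate_cohort(small_config(seed=2), out_dir=tmp_path / "s2")
        names1 = sorted(p.name for p in (tmp_path / "s1" / "rr").iterdir())
        names2 = sorted(p.name for p in (tmp_path / "s2" / "rr").iterdir())
        assert names1 == names2
        rr1 = c1.subjects[0].rr["H0"].rr_intervals
        rr2 = c2.subjects[0].rr["H0"].rr_intervals
        assert not np.array_equal(rr1[:50], rr2[:50])

    def test_per_record_stream_is_splittable(self):
        """Per-(subject, hour) streams are independent of generation order:
        the same coordinates always yield the same stream."""
        a = _rng_for(9, 0, 2).normal(size=5)
        b = _rng_for(9, 0, 2).normal(size=5)
        c = _rng_for(9, 0, 3).normal(size=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticCohortConfig(n_lps=1)
        with pytest.raises(ConfigError):
            SyntheticCohortConfig(record_length=600.0)
        with pytest.raises(ConfigError):
            LPSEffects(sdnn_mult=(1.0, 2.0))

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=4)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticCohortConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
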