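"""Generator unit and property tests: pulse shape, closed-form truth,
noise calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from sigstr import (
    DatasetSpec,
    MoleculeSpec,
    default_panel,
    generate_dataset,
    ground_truth,
    normalize,
    pulse_value,
    str_estimates,
)
from sigstr.synthetic import (
    ConfigurationError,
    _loguniform_factors,
    write_ground_truth,
)


def triangle(amplitude=2.0, t_peak=15.0, tau=45.0, baseline=1.0):
    return MoleculeSpec("m", baseline_intensity=baseline,
                        pulse_amplitude=amplitude, t_peak=t_peak, tau_true=tau)


class TestPulseValue:
    def test_midpoint_of_decline(self):
        # A = 2, peak at 15, back to baseline at 45: halfway down at t = 30
        assert pulse_value(triangle(), 30.0) == pytest.approx(1.0)

    def test_endpoints_and_peak(self):
        m = triangle()
        assert pulse_value(m, 0.0) == 0.0
        assert pulse_value(m, 15.0) == 2.0
        assert pulse_value(m, 45.0) == 0.0
        assert pulse_value(m, 180.0) == 0.0

    def test_continuous_and_nonnegative(self):
        m = triangle(amplitude=3.7, t_peak=12.0, tau=80.0)
        ts = np.linspace(0, 120, 2401)
        vals = np.array([pulse_value(m, t) for t in ts])
        assert np.all(vals >= 0)
        assert np.abs(np.diff(vals)).max() < 3.7 / 12.0 * 0.06  # no jumps

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pulse_value(triangle(), -1.0)


class TestGroundTruth:
    def test_closed_form(self):
        # baseline 1, amplitude 2(e^0.9 - 1), tau 30 => beta = 0.9/30 = 0.03
        amp = 2.0 * (np.exp(0.9) - 1.0)
        spec = DatasetSpec(
            molecules=(MoleculeSpec("m", 1.0, amp, 15.0, 30.0),),
            time_grid=(0.0, 15.0, 30.0, 60.0),
        )
        tau, beta = ground_truth(spec)["m"]
        assert tau == 30.0
        assert beta == pytest.approx(0.03, abs=1e-12)

    def test_inactive_molecule(self):
        spec = DatasetSpec(molecules=(MoleculeSpec("m"),))
        tau, beta = ground_truth(spec)["m"]
        assert np.isnan(tau) and beta == 0.0

    def test_sidecar_roundtrip(self, tmp_path):
        import json

        spec = default_panel(stressed=True, seed=3)
        path = tmp_path / "gt.json"
        write_ground_truth(spec, path)
        payload = json.loads(path.read_text())
        assert payload["condition"] == "stressed"
        assert payload["truth"]["Src"]["beta_true"] == pytest.approx(0.08)
        assert payload["truth"]["EGFR"]["tau_true"] is None


class TestSpecValidation:
    def test_grid_must_start_at_zero(self):
        with pytest.raises(ConfigurationError):
            DatasetSpec(molecules=(MoleculeSpec("m"),), time_grid=(5.0, 10.0))

    def test_grid_must_increase(self):
        with pytest.raises(ConfigurationError):
            DatasetSpec(molecules=(MoleculeSpec("m"),), time_grid=(0.0, 10.0, 10.0))

    def test_replicate_floor(self):
        with pytest.raises(ConfigurationError):
            DatasetSpec(molecules=(MoleculeSpec("m"),), n_replicates=4)

    def test_pulse_ordering(self):
        with pytest.raises(ConfigurationError):
            MoleculeSpec("m", pulse_amplitude=1.0, t_peak=50.0, tau_true=45.0)


class TestGenerateDataset:
    def test_deterministic_for_seed(self):
        spec = default_panel(seed=11)
        a = generate_dataset(spec).records
        b = generate_dataset(spec).records
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_data(self):
        a = generate_dataset(default_panel(seed=1)).records
        b = generate_dataset(default_panel(seed=2)).records
        assert not a["intensity"].equals(b["intensity"])

    def test_shape_and_channels(self):
        spec = default_panel()
        ds = generate_dataset(spec)
        # 19 molecules x 2 channels x 7 times x 6 replicates + negctrl block
        assert len(ds.records) == 19 * 2 * 7 * 6 + 7 * 6
        assert ds.records["intensity"].gt(0).all()
        assert set(ds.records["channel"]) == {"phospho", "total",
                                              "negative_control"}

    def test_noiseless_recovery_is_exact(self):
        """With all noise off, the full duration/rate pipeline returns the
        generator's closed-form beta to machine precision."""
        spec = default_panel(stressed=True, seed=0)
        spec = DatasetSpec(
            molecules=spec.molecules, time_grid=spec.time_grid,
            n_replicates=6, noise_cv=0.0, replicate_effect_cv=0.0,
            condition=spec.condition,
        )
        truth = ground_truth(spec)
        strs = str_estimates(normalize(generate_dataset(spec)))
        for mol, grp in strs.groupby("molecule_id"):
            beta_true = truth[mol][1]
            if beta_true == 0.0:
                assert (grp["status"] == "no_signal").all()
                assert (grp["beta_per_min"] == 0.0).all()
            else:
                assert grp["beta_per_min"].to_numpy() == pytest.approx(
                    beta_true, rel=1e-12
                )

    def test_replicate_effect_scales_rates(self):
        """The per-replicate response effect acts at the rate level: in a
        spot-noise-free dataset each replicate's STR is gamma_i * beta_true,
        identical across equal-rate molecules."""
        spec = default_panel(seed=5)
        spec = DatasetSpec(molecules=spec.molecules, time_grid=spec.time_grid,
                           noise_cv=0.0, replicate_effect_cv=0.45, seed=5)
        strs = str_estimates(normalize(generate_dataset(spec)))
        srme = strs[strs["molecule_id"].isin(["Src", "Raf1", "MEK1", "ERK1"])]
        pivot = srme.pivot(index="replicate", columns="molecule_id",
                           values="beta_per_min")
        # equal true rate + shared replicate effect => identical columns
        assert np.allclose(pivot.to_numpy(),
                           pivot.iloc[:, [0]].to_numpy(), rtol=1e-10)
        # and the replicate mean stays near the nominal rate
        assert pivot.to_numpy().mean() == pytest.approx(0.08, rel=0.25)


class TestReplicateEffectDistribution:
    def test_mean_one_and_cv(self):
        gen = np.random.default_rng(0)
        x = _loguniform_factors(gen, 0.45, 400_000)
        assert x.mean() == pytest.approx(1.0, abs=2e-3)
        assert x.std() == pytest.approx(0.45, abs=0.01)

    def test_bounded_support(self):
        gen = np.random.default_rng(0)
        x = _loguniform_factors(gen, 0.45, 100_000)
        a = np.sqrt(3.0) * 0.45
        bound = np.exp(a) / (np.sinh(a) / a)
        assert x.max() < bound + 1e-9
        assert x.min() > np.exp(-a) / (np.sinh(a) / a) - 1e-9

    def test_zero_cv_degenerates(self):
        gen = np.random.default_rng(0)
        assert np.all(_loguniform_factors(gen, 0.0, 10) == 1.0)
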