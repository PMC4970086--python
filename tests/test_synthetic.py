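"""Synthetic cohort generator: kinematic consistency and error model."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from imu_qc.errors import ConfigError
from imu_qc.prep import JOINT_MODULES, MODULES, PHASES
from imu_qc.report import build_segment_table
from imu_qc.synthetic import (
    SEVERE_FLOOR_AMPLITUDE,
    CohortConfig,
    ErrorModelConfig,
    NoiseConfig,
    SyntheticDataset,
    corrupt_orientation,
    generate_cohort,
    generate_trial,
    inject_magnetic_perturbation,
)


def _noise_free_config(**kwargs):
    return CohortConfig(
        noise=NoiseConfig(gyro_sd_deg_s=0.0, accel_sd_g=0.0, mag_sd=0.0),
        error_model=ErrorModelConfig(orient_noise_deg=0.0, ref_noise_deg=0.0),
        max_sync_offset_samples=0,
        **kwargs,
    )


def _segment_table_for(trial, cfg):
    ds = SyntheticDataset(cfg, [trial], trial.annotations)
    return build_segment_table(ds)


def _phase_slice(trial, phase, module):
    ann = next(a for a in trial.annotations if a.phase == phase)
    # annotations index the 100 Hz reference grid; raw runs at 60 Hz
    ratio = trial.raw[module].t.shape[0] / trial.ref["knee"].t.shape[0]
    s, e = int(ann.start * ratio), int(ann.end * ratio)
    return trial.raw[module].slice(s, e)


class TestGenerateTrial:
    def test_sit_phase_is_quiet_on_all_modules(self, rng):
        trial = generate_trial(CohortConfig(), 0, 0, rng)
        for m in MODULES:
            seg = _phase_slice(trial, "sit", m)
            assert np.mean(np.linalg.norm(seg.gyro, axis=1)) < 5.0

    def test_fast_condition_moves_faster_than_slow(self, rng):
        cfg = CohortConfig()
        slow = generate_trial(cfg, 0, 1, np.random.default_rng(3))
        fast = generate_trial(cfg, 0, 2, np.random.default_rng(3))
        assert slow.speed == "slow" and fast.speed == "fast"
        for m in ("shank", "foot"):
            g_slow = np.mean(
                np.linalg.norm(_phase_slice(slow, "walk1", m).gyro, axis=1)
            )
            g_fast = np.mean(
                np.linalg.norm(_phase_slice(fast, "walk1", m).gyro, axis=1)
            )
            assert g_fast > g_slow

    def test_distal_modules_rotate_more(self, rng):
        trial = generate_trial(CohortConfig(), 0, 0, rng)
        means = {
            m: np.mean(np.linalg.norm(_phase_slice(trial, "walk1", m).gyro, axis=1))
            for m in MODULES
        }
        assert means["foot"] > means["thigh"] > means["pelvis"]

    def test_gyro_integration_recovers_true_orientation(self):
        """Noise-free gyro integrates back to the truth within 0.1 degree."""
        trial = generate_trial(_noise_free_config(), 0, 0, np.random.default_rng(1))
        dt = 1.0 / 60.0
        for m in ("pelvis", "foot"):
            q_true = trial.module_truth[m].q
            gyro = np.radians(trial.raw[m].gyro)
            r = Rotation.from_quat(np.roll(q_true[0], -1))
            worst = 0.0
            for k in range(1, len(q_true)):
                r = r * Rotation.from_rotvec(gyro[k - 1] * dt)
                r_true = Rotation.from_quat(np.roll(q_true[k], -1))
                worst = max(worst, np.degrees((r.inv() * r_true).magnitude()))
            assert worst < 0.1

    def test_accel_norm_is_one_g_at_rest(self, rng):
        trial = generate_trial(_noise_free_config(), 0, 0, rng)
        sit = _phase_slice(trial, "sit", "pelvis")
        np.testing.assert_allclose(
            np.linalg.norm(sit.accel, axis=1), 1.0, atol=1e-6
        )

    def test_annotations_cover_all_phases_and_joints(self, rng):
        trial = generate_trial(CohortConfig(), 0, 0, rng)
        assert len(trial.annotations) == 24
        assert {a.phase for a in trial.annotations} == set(PHASES)

    def test_offset_beyond_margin_rejected(self):
        cfg = CohortConfig(max_sync_offset_samples=200)
        with pytest.raises(ConfigError):
            generate_trial(cfg, 0, 0, np.random.default_rng(0))


class TestMagneticPerturbation:
    def test_zero_amplitude_leaves_magnetometer_unchanged(self, rng):
        cfg = CohortConfig()
        trial = generate_trial(cfg, 0, 0, rng)
        before = {m: trial.raw[m].mag.copy() for m in MODULES}
        inject_magnetic_perturbation(trial, cfg, rng, amplitude=0.0)
        for m in MODULES:
            np.testing.assert_array_equal(trial.raw[m].mag, before[m])

    def test_floor_proximal_modules_deviate_most(self, rng):
        cfg = CohortConfig()
        trial = generate_trial(cfg, 0, 0, rng)
        inject_magnetic_perturbation(trial, cfg, rng, amplitude=0.5)
        dev = {
            m: abs(np.mean(np.linalg.norm(trial.raw[m].mag, axis=1)) - 1.0)
            for m in MODULES
        }
        assert dev["foot"] > dev["shank"] > dev["thigh"] > dev["trunk_upper"]

    def test_f15_responds_only_to_injected_field_difference(self):
        """Feature-extractor cross-check of the inter-module field difference:
        ~0 without perturbation, graded by floor proximity with it."""
        cfg = _noise_free_config()

        def f15_by_joint(amplitude):
            rng = np.random.default_rng(4)
            trial = generate_trial(cfg, 0, 0, rng)
            inject_magnetic_perturbation(trial, cfg, rng=None, amplitude=amplitude)
            corrupt_orientation(trial, cfg, rng)
            table = _segment_table_for(trial, cfg)
            return table.groupby("joint")["f15"].apply(lambda s: np.abs(s).max())

        # residual at zero amplitude is only the lerp shrinkage of the
        # rotating field vector (~1e-5), far below any injected difference
        clean = f15_by_joint(0.0)
        assert clean.max() < 1e-3
        hot = f15_by_joint(0.6)
        assert hot["ankle"] > 0.05
        assert hot["ankle"] > hot["knee"] > hot["hip"] > hot["trunk"]


class TestCorruptOrientation:
    def test_no_drivers_keeps_joint_rmsd_below_one_degree(self):
        cfg = _noise_free_config()
        rng = np.random.default_rng(2)
        trial = generate_trial(cfg, 0, 1, rng)  # slow condition
        inject_magnetic_perturbation(trial, cfg, rng=None, amplitude=0.0)
        corrupt_orientation(trial, cfg, rng)
        table = _segment_table_for(trial, cfg)
        assert table["rmsd"].max() < 1.0

    def test_severe_preset_ruins_floor_proximal_segments(self):
        """Median over draws: a severe floor field pushes ankle sit RMSD
        far past the 10 degree bad threshold."""
        cfg = CohortConfig(max_sync_offset_samples=0)
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            trial = generate_trial(cfg, 0, 1, rng)
            inject_magnetic_perturbation(
                trial, cfg, rng, amplitude=SEVERE_FLOOR_AMPLITUDE
            )
            corrupt_orientation(trial, cfg, rng)
            table = _segment_table_for(trial, cfg)
            vals.append(
                table[(table.joint == "ankle") & (table.phase == "sit")].rmsd.iloc[0]
            )
        assert np.median(vals) > 10.0

    def test_error_monotone_in_perturbation_amplitude(self):
        """Same trial, same error-model draws: larger field, larger error."""
        cfg = _noise_free_config()
        rmsds = []
        for amp in (0.0, 0.2, 0.4, 0.8):
            rng = np.random.default_rng(6)
            trial = generate_trial(cfg, 0, 1, rng)
            inject_magnetic_perturbation(trial, cfg, rng=None, amplitude=amp)
            corrupt_orientation(trial, cfg, np.random.default_rng(99))
            table = _segment_table_for(trial, cfg)
            rmsds.append(
                table[(table.joint == "ankle") & (table.phase == "sit")].rmsd.iloc[0]
            )
        assert all(b > a for a, b in zip(rmsds, rmsds[1:]))


class TestGenerateCohort:
    def test_training_partition_size_matches_study_design(self):
        """10 participants x 9 trials x 6 phases x 4 joints = 2160 segments."""
        ds = generate_cohort(CohortConfig(n_participants=10, seed=0))
        assert ds.n_segments == 2160

    def test_default_cohort_doubles_it(self, midsize_cohort):
        # arithmetic scales linearly in participants
        per_participant = midsize_cohort.n_segments / 6
        assert per_participant == 216
        assert 20 * per_participant == 4320

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = CohortConfig(n_participants=1, trials_per_participant=2, seed=9)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a")
                         for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b")
                         for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b and len(files_a) > 10
        for rel in files_a:
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel,
                               shallow=False), rel


class TestCohortStatistics:
    def test_ankle_fails_far_more_often_than_trunk(self, midsize_table):
        bad_frac = (
            midsize_table.assign(bad=midsize_table.label == "bad")
            .groupby("joint")["bad"].mean()
        )
        assert bad_frac["ankle"] > bad_frac["trunk"] + 0.2
        assert bad_frac["ankle"] > bad_frac["hip"]

    def test_f15_tracks_injected_field_difference(self, midsize_cohort, midsize_table):
        """Rank correlation between the injected inter-module disturbance
        difference and the extracted f15 feature exceeds 0.9."""
        injected = {
            t.trial_id: {
                j: t.mag_amplitude[JOINT_MODULES[j][0]]
                - t.mag_amplitude[JOINT_MODULES[j][1]]
                for j in JOINT_MODULES
            }
            for t in midsize_cohort.trials
        }
        truth = [
            injected[r.trial_id][r.joint] for r in midsize_table.itertuples()
        ]
        rho = spearmanr(truth, midsize_table["f15"].to_numpy()).statistic
        assert rho > 0.9
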