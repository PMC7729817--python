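"""Simulate two walkers and project their signals onto the gravity axis.

The phone sits in an arbitrary orientation, so raw X/Y/Z axes are
meaningless across recordings; the scalar projection acc_g = acc · ĝ onto
the windowed-mean gravity estimate is not.  This script shows the
projection recovering the body-frame vertical signal and being exactly
invariant to how the device was oriented.
"""

import numpy as np

import gaitid as g

cohort = g.simulate_cohort(2, 30.0, 50.0, seed=7, separability="easy")
for profile, (acc, gyro) in zip(cohort.profiles, cohort.recordings):
    acc_g = g.vertical_acceleration_pipeline(acc, half_window_m=150,
                                             trim_samples=150)
    print(f"{profile.subject_id}: cadence {profile.step_frequency_hz:.2f} Hz, "
          f"acc_g mean {np.mean(acc_g.values):.3f} m/s^2 "
          f"(gravity), sd {np.std(acc_g.values):.3f} m/s^2 (gait oscillation)")

# same walker, two different device orientations -> identical projection
profile = cohort.profiles[0]
rng = np.random.default_rng(0)
reoriented = g.SyntheticUserProfile(
    subject_id=profile.subject_id,
    step_frequency_hz=profile.step_frequency_hz,
    harmonic_amps=profile.harmonic_amps,
    harmonic_phases=profile.harmonic_phases,
    noise_sd=profile.noise_sd, gyro_amp=profile.gyro_amp,
    device_rotation=g.random_rotation(rng), noise_seed=profile.noise_seed)
a = g.vertical_acceleration_pipeline(g.simulate_walk(profile, 30.0, 50.0)[0])
b = g.vertical_acceleration_pipeline(g.simulate_walk(reoriented, 30.0, 50.0)[0])
dev = np.abs(a.values - b.values).max()
print(f"max |acc_g difference| across device orientations: {dev:.2e} m/s^2")
print("-> the projection is orientation-invariant (differences are float rounding)")
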