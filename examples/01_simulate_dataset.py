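"""Generate a small synthetic cutting-movement dataset and inspect a trial.

Each trial is one planted-foot change-of-direction cycle: 15 joint/segment
angle channels, a two-peak vertical ground-reaction force, and 18 raw IMU
channels on a shared 200 Hz time base.
"""

from cutcoord.synthetic import GeneratorConfig, generate_dataset

config = GeneratorConfig(n_subjects=3, cycles_per_subject=4, seed=7)
trials, manifest = generate_dataset(config)

print(f"{len(trials)} trials "
      f"({config.n_subjects} subjects x {config.cycles_per_subject} cycles "
      "x 3 directions)")
print(manifest.head(6).to_string(index=False))

trial = trials[0]
print(f"\ntrial {trial.trial_id}: {len(trial.vgrf)} samples at "
      f"{trial.sample_rate:.0f} Hz")
print(f"  vGRF peak: {trial.vgrf.max():.0f} N "
      f"(~{trial.vgrf.max() / config.body_weight_n:.2f} body weights)")
print(f"  knee flexion-extension range: "
      f"{trial.angle_curves['knee_fe'].min():.1f} to "
      f"{trial.angle_curves['knee_fe'].max():.1f} deg")
print(f"  IMU block shape: {trial.imu.shape} (samples x channels)")
# The peak should sit near 1.7 body weights (first landing peak) and the
# knee curve should span a few tens of degrees - plausible cutting-gait
# magnitudes for synthetic data.
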