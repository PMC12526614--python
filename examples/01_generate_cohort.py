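"""Generate a synthetic squat-exergame cohort with known ground truth.

Each subject yields two CSV-ready streams — camera joint positions (~60 Hz,
meters) and force-plate center of pressure (50 Hz, millimeters) — plus a
ground-truth table saying which squats carry an injected knee-instability
oscillation.
"""

from squatstab import SynthConfig, generate_cohort

config = SynthConfig(n_subjects=4, squats_per_subject=30, seed=42)
sessions, truth = generate_cohort(config)

first = sessions[0]
print(f"subjects: {len(sessions)}, squats per subject: {config.squats_per_subject}")
print(f"camera stream: {first.camera.timestamps.size} samples at "
      f"{first.camera.nominal_rate:.0f} Hz, channels {list(first.camera.channels)}")
print(f"plate stream:  {first.plate.timestamps.size} samples at "
      f"{first.plate.nominal_rate:.0f} Hz, starting "
      f"{first.plate.start - first.camera.start:.2f} s after the camera")
print(f"unstable squats: {truth['true_unstable'].sum()} of {len(truth)} "
      f"({100 * truth['true_unstable'].mean():.1f}% — drawn at "
      f"{100 * config.instability_prevalence:.1f}% prevalence)")
print(truth.head(3).to_string(index=False))
print("-> each row is one squat: its oscillation amplitude/frequency decide "
      "whether the knee-shakiness label threshold will be crossed downstream.")
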