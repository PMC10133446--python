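"""Synthesize the reference distractor and a bright singleton; verify timbre.

Builds the 170 ms harmonic-complex distractor (20 harmonics, spectral slope
solved so its spectral centroid is 512 Hz) and a brighter singleton at
768 Hz, measures both centroids from the rendered audio, and writes WAVs.
"""

from pathlib import Path

import timbrecapture as tc

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

f0 = tc.nominal_f0()  # fundamental fixed by alpha=3 <-> SC=512 Hz
print(f"nominal fundamental: {f0:.1f} Hz")

for name, sc in [("distractor", 512.0), ("singleton_bright", 768.0)]:
    alpha = tc.solve_alpha_for_sc(sc, f0)
    spec = tc.ToneSpec(f0=f0, alpha=alpha, duration_ms=170.0, ramp_ms=5.0)
    buf = tc.synth_tone(spec)
    measured = tc.measured_sc(buf)
    tc.write_wav(out / f"{name}.wav", buf)
    print(
        f"{name}: alpha = {alpha:.3f}, target SC = {sc:.0f} Hz, "
        f"measured SC = {measured:.1f} Hz"
    )

# a rough singleton: the same tone amplitude-modulated at 50 Hz, depth 0.5
rough = tc.apply_am(
    tc.synth_tone(tc.ToneSpec(f0=f0, alpha=tc.solve_alpha_for_sc(512.0, f0))),
    m=0.5, fmod=50.0,
)
print(f"rough singleton: demodulated depth = {tc.measured_am_depth(rough):.3f}")
tc.write_wav(out / "singleton_rough.wav", rough)

# one full trial sequence: 5 tones at a 230 ms inter-onset interval
cfg = tc.load_experiment("exp2")
plan = tc.generate_plan(cfg, seed=0)
trial = next(t for t in plan.trials if t.singleton is not None)
seq = tc.assemble_sequence(tc.resolve_trial_tones(trial, cfg), ioi_ms=cfg.ioi_ms)
tc.write_wav(out / "sequence.wav", seq)
print(
    f"sequence: {seq.duration_s * 1000:.0f} ms, target {trial.target_kind} "
    f"at position {trial.target_pos}, singleton {trial.singleton_pos} it"
)
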