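"""Simulate a small annotated EEG cohort and write one subject to EDF+.

The generator emulates the clinical recording protocol: five alternating
eyes-open/eyes-closed resting periods, photic stimulation at five flash
frequencies, and hyperventilation, with group-dependent band power for the
MDD subjects.
"""
from pathlib import Path

import restmdd as rm

protocol = rm.make_default_protocol(total_resting_seconds=100.0)
recordings = rm.synth_cohort(n_mdd=3, n_healthy=3, protocol=protocol, seed=7)

print(f"simulated {len(recordings)} recordings "
      f"({sum(r.group == 'MDD' for r in recordings)} MDD)")
rec = recordings[0]
print(f"subject {rec.subject_id}: {rec.n_channels} channels, "
      f"{rec.duration:.0f} s at {rec.fs:.0f} Hz, "
      f"age {rec.age}, sex {rec.sex}")
print("protocol annotations:")
for ann in rec.annotations:
    print(f"  {ann.onset:7.1f}s +{ann.duration:5.1f}s  {ann.label}")

out = Path("scratch_example_output")
out.mkdir(exist_ok=True)
rm.write_edf(rec, out / f"{rec.subject_id}.edf")
print(f"wrote {out / (rec.subject_id + '.edf')}")
# Each annotation marks one protocol phase; downstream feature extraction
# uses only the five EYES_OPEN/EYES_CLOSED periods.
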