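"""Clean an artifact-contaminated recording with the full preprocessing
chain and show how well band powers are restored.

The chain is: 0.1-40 Hz zero-phase FIR bandpass -> average reference ->
ICA with rule-based component labelling -> removal of EYE/MUSCLE/LINE_NOISE
components.
"""
import numpy as np
import scipy.signal

import restmdd as rm

profile = rm.SubjectProfile("demo", "HEALTHY", 35, "F", seed=7)
clean = rm.synth_recording(profile)
dirty = rm.inject_artifacts(clean, rm.ArtifactSpec(), seed=8)

reference, _ = rm.preprocess_recording(clean, seed=3)
restored, log = rm.preprocess_recording(dirty, seed=3)
print("component labels:", log["labels"])
print("dropped components:", log["dropped"])


def band_power(x, lo, hi):
    f, P = scipy.signal.welch(x, fs=200.0, nperseg=1600, axis=-1)
    return P[..., (f >= lo) & (f <= hi)].sum(axis=-1)


fp1 = clean.channel_index("Fp1")
for name, val in [
    ("frontal delta, artifacted / clean",
     band_power(dirty.data[fp1], 0.5, 4) / band_power(clean.data[fp1], 0.5, 4)),
    ("frontal delta, restored / reference",
     band_power(restored.data[fp1], 0.5, 4) / band_power(reference.data[fp1], 0.5, 4)),
    ("50 Hz (all channels), restored / reference",
     band_power(restored.data, 49, 51).mean() / band_power(reference.data, 49, 51).mean()),
]:
    print(f"{name}: {val:.2f}")
# Blinks inflate frontal delta severalfold before cleaning; after the chain
# both ratios should sit near 1 (within ~25%), meaning the artifacts are
# removed without destroying the underlying band structure.
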