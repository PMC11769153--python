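"""Core in-memory containers for annotated multichannel EEG."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 scalp electrodes of the standard 10-20 montage used throughout.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

#: Frontal-pole channels where ocular artifacts dominate.
FRONTAL_CHANNELS = ["Fp1", "Fp2"]


@dataclass(frozen=True)
class Annotation:
    """A labelled event: onset and duration in seconds from recording start."""

    onset: float
    duration: float
    label: str


@dataclass
class EEGRecording:
    """Annotated multichannel EEG time series.

    Data are stored as a ``(n_channels, n_samples)`` float array in microvolts.
    Annotations mark protocol phases (eyes open/closed, photic stimulation,
    hyperventilation) and injected artifact events.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = "unknown"
    group: str | None = None
    age: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        dur = self.duration
        for ann in self.annotations:
            if not (0 <= ann.onset <= dur):
                raise ValueError(
                    f"annotation {ann.label!r} at {ann.onset:.3f}s lies outside "
                    f"the recording [0, {dur:.3f}]s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), annotations=list(self.annotations))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


@dataclass
class Segment:
    """A single eyes-open or eyes-closed resting period cut from a recording."""

    subject_id: str
    condition: str  # EYES_OPEN or EYES_CLOSED
    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_names: list[str]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs
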