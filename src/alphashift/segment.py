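"""In-memory container for a multichannel EEG segment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import MontageLayout, standard_1020_layout


@dataclass
class EEGSegment:
    """channels x samples EEG data (microvolts) with layout metadata.

    Invariants checked on construction: finite data, fs > 0, unique labels,
    at least one second of data, one row per label.
    """

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float  # Hz
    channel_labels: tuple[str, ...]
    layout: MontageLayout | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] < self.fs:
            raise ValueError("segment shorter than one second")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def positions(self) -> np.ndarray:
        """Per-channel 2-D positions (mm) from the attached layout."""
        lay = self.layout if self.layout is not None else standard_1020_layout()
        return np.stack([lay.position(lbl) for lbl in self.channel_labels])

    def copy_with(self, data: np.ndarray) -> "EEGSegment":
        return EEGSegment(data=np.array(data), fs=self.fs,
                          channel_labels=self.channel_labels, layout=self.layout)
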