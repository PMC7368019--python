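"""In-memory container for one multichannel electrophysiology recording.

A :class:`Recording` holds one rat-session-condition time series: a matrix of
electrode traces in microvolts, the stimulus onset times, and the condition
metadata (rat, group, wavelength, week, paradigm) that every downstream stage
keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Canonical electrode montage: left/right visual cortex, left/right superior
#: colliculus.
ELECTRODES = ("VC_L", "VC_R", "SC_L", "SC_R")

GROUPS = ("alpha_syn", "control")

WAVELENGTHS = ("red", "green", "blue", "short_blue", "white")

PARADIGMS = ("VEP", "SSVEP")


@dataclass
class Recording:
    """One multichannel recording with stimulus events and metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_electrodes, n_samples)`` in microvolts.
    sampling_rate
        Samples per second (Hz).
    electrodes
        Channel labels, one per row of ``data``.
    events
        Stimulus onset times in seconds from the start of the recording.
    meta
        Condition metadata.  Recognised keys: ``rat_id``, ``group``,
        ``wavelength``, ``week``, ``paradigm``, ``stim_freq_hz``,
        ``flash_duration_s``.
    """

    data: np.ndarray
    sampling_rate: float
    electrodes: tuple[str, ...]
    events: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        self.electrodes = tuple(self.electrodes)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be 2-D (electrodes x samples)")
        if self.data.shape[0] != len(self.electrodes):
            raise ConfigurationError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.electrodes)} electrode labels were declared"
            )
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        dur = self.duration
        if self.events.size and (
            self.events.min() < 0 or self.events.max() > dur
        ):
            raise ConfigurationError(
                "all event times must lie within [0, run_duration]"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, electrode: str) -> np.ndarray:
        """Return the trace (µV) for one electrode label."""
        try:
            idx = self.electrodes.index(electrode)
        except ValueError:
            raise ConfigurationError(
                f"electrode {electrode!r} not in recording "
                f"(has {list(self.electrodes)})"
            ) from None
        return self.data[idx]
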