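"""Frequency-domain SSVEP feature extraction.

The steady-state analysis works on 1-s bins: the first and last 5 s of each
run are discarded (onset transients / offset artefacts), every remaining
1-s segment is Fourier-transformed at 1-Hz resolution, and the amplitude
and phase at the stimulation harmonics (1f = 14 Hz, 2f = 28 Hz for a 14-Hz
drive) are kept as samples.  Each sample gets a signal-to-noise ratio:
harmonic amplitude over the root-mean-square of the amplitudes in the four
1-Hz bins on each side.  Samples with SNR < 1 are excluded; SNR = 1 is
retained.  Retained samples are pooled per feature (electrode, wavelength,
harmonic) for the bootstrap classifier — 13 contributing animals with no
exclusions give the maximal pool of 13 × 90 = 1,170 bins per feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .recording import Recording

__all__ = [
    "BinSpectrum",
    "FeaturePool",
    "trim_and_bin",
    "amplitude_spectrum",
    "side_bin_noise",
    "compute_snr",
    "extract_harmonic_samples",
    "extract_cohort_samples",
    "build_feature_pools",
]

#: Column order of the tidy harmonic-sample table.
SAMPLE_COLUMNS = [
    "rat_id",
    "group",
    "week",
    "electrode",
    "wavelength",
    "harmonic",
    "bin",
    "amplitude_uV",
    "phase_rad",
    "snr",
    "retained",
]


@dataclass
class BinSpectrum:
    """Single-sided amplitude/phase spectrum of one 1-s segment.

    ``frequencies`` is the 1-Hz grid from 0 to Nyquist inclusive; a pure
    sinusoid of peak amplitude A maps to amplitude A at its frequency.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def at(self, f: float) -> int:
        """Index of the exact bin at frequency ``f`` (error if off-grid)."""
        idx = f / self.resolution
        if abs(idx - round(idx)) > 1e-9:
            raise ConfigurationError(
                f"frequency {f} Hz is not on the {self.resolution}-Hz grid"
            )
        i = int(round(idx))
        if not 0 <= i < len(self.frequencies):
            raise ConfigurationError(
                f"frequency {f} Hz outside the spectrum (0"
                f"-{self.frequencies[-1]} Hz)"
            )
        return i


@dataclass
class FeaturePool:
    """Retained amplitude bins for one feature key, with provenance."""

    electrode: str
    wavelength: str
    harmonic: int
    amplitudes: np.ndarray
    rat_ids: np.ndarray
    bin_indices: np.ndarray

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.electrode, self.wavelength, self.harmonic)

    def __len__(self) -> int:
        return len(self.amplitudes)


def trim_and_bin(
    recording: Recording,
    bin_duration: float = 1.0,
    trim: float = 5.0,
) -> np.ndarray:
    """Cut each electrode trace into contiguous 1-s bins, trimming 5 s ends.

    Returns an array of shape ``(n_electrodes, n_bins, samples_per_bin)``
    with ``n_bins = floor((duration - 2*trim)/bin_duration)`` segments
    starting at ``t = trim``.
    """
    duration = recording.duration
    if duration < 2 * trim + bin_duration:
        raise ConfigurationError(
            f"recording of {duration:g} s is too short: need at least "
            f"{2 * trim + bin_duration:g} s (2x{trim:g} s trim + one "
            f"{bin_duration:g} s bin)"
        )
    fs = recording.sampling_rate
    per_bin = int(round(bin_duration * fs))
    n_bins = int(math.floor((duration - 2 * trim) / bin_duration + 1e-9))
    start = int(round(trim * fs))
    segments = recording.data[:, start : start + n_bins * per_bin]
    return segments.reshape(recording.data.shape[0], n_bins, per_bin)


def amplitude_spectrum(
    segment: np.ndarray,
    sampling_rate: float,
    demean: bool = False,
) -> BinSpectrum:
    """Single-sided amplitude spectrum of one segment.

    Normalised so that a pure sinusoid of peak amplitude A gives amplitude
    A at its frequency (DC and Nyquist carry 1/N instead of 2/N).  Phases
    are the arguments of the complex rFFT coefficients.  ``demean``
    subtracts the segment mean first (off by default: the source analysis
    applies no detrending or windowing).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise DataError("segment must be one-dimensional")
    if not np.all(np.isfinite(segment)):
        raise DataError("segment contains non-finite samples")
    if demean:
        segment = segment - segment.mean()
    n = len(segment)
    coeffs = np.fft.rfft(segment)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    amplitudes = np.abs(coeffs) / n
    # interior bins appear twice in the two-sided spectrum
    upper = len(amplitudes) - 1 if n % 2 == 0 else len(amplitudes)
    amplitudes[1:upper] *= 2.0
    return BinSpectrum(
        frequencies=freqs, amplitudes=amplitudes, phases=np.angle(coeffs)
    )


def side_bin_noise(
    spectrum: BinSpectrum,
    f: float,
    n_side: int = 4,
    method: str = "rms",
) -> float:
    """Local noise estimate around frequency ``f``.

    Root mean square (default) or arithmetic mean of the amplitudes in the
    ``n_side`` grid bins on each side of ``f`` (the bin at ``f`` itself is
    excluded).
    """
    if n_side < 1:
        raise ConfigurationError("n_side must be >= 1")
    res = spectrum.resolution
    if f - n_side * res < res / 2 or f + n_side * res > spectrum.frequencies[-1]:
        raise ConfigurationError(
            f"side bins of {f} Hz (±{n_side} bins at {res:g}-Hz resolution) "
            "fall outside the spectrum"
        )
    offsets = np.arange(1, n_side + 1)
    idx = [spectrum.at(f + s * k * res) for s in (-1, 1) for k in offsets]
    vals = spectrum.amplitudes[idx]
    if method == "rms":
        return float(np.sqrt(np.mean(vals**2)))
    if method == "mean":
        return float(np.mean(vals))
    raise ConfigurationError(f"unknown noise method {method!r}")


def compute_snr(amplitude: float, noise_rms: float) -> float:
    """Signal-to-noise ratio: harmonic amplitude over side-bin noise RMS.

    Returns ``inf`` for a nonzero amplitude over zero noise and ``nan``
    (undefined; sample excluded downstream) for 0/0.
    """
    if amplitude < 0 or noise_rms < 0:
        raise ConfigurationError("amplitude and noise_rms must be >= 0")
    if noise_rms == 0:
        return math.inf if amplitude > 0 else math.nan
    return amplitude / noise_rms


def extract_harmonic_samples(
    recording: Recording,
    harmonics: tuple[int, ...] = (1, 2),
    bin_duration: float = 1.0,
    trim: float = 5.0,
    n_side: int = 4,
    noise_method: str = "rms",
    demean: bool = False,
) -> pd.DataFrame:
    """Per-bin harmonic amplitude/phase/SNR table for one SSVEP recording.

    One row per (electrode, analysed bin, harmonic).  ``retained`` is True
    where SNR >= 1 ("lower than 1" is excluded, equality retained).  The
    stimulation frequency must sit exactly on the spectral grid
    (1/bin_duration Hz); off-grid frequencies are rejected rather than
    interpolated.
    """
    if recording.meta.get("paradigm") != "SSVEP":
        raise DataError(
            "extract_harmonic_samples requires an SSVEP recording "
            f"(got paradigm={recording.meta.get('paradigm')!r})"
        )
    stim_freq = recording.meta.get("stim_freq_hz")
    if stim_freq is None:
        raise DataError("recording meta lacks stim_freq_hz")
    resolution = 1.0 / bin_duration
    for k in harmonics:
        if abs(k * stim_freq / resolution - round(k * stim_freq / resolution)) > 1e-9:
            raise ConfigurationError(
                f"harmonic {k}x{stim_freq} Hz is not on the "
                f"{resolution:g}-Hz spectral grid; off-grid frequencies "
                "are not interpolated"
            )
    segments = trim_and_bin(recording, bin_duration=bin_duration, trim=trim)
    meta = recording.meta
    rows = []
    for ei, electrode in enumerate(recording.electrodes):
        for bi in range(segments.shape[1]):
            spec = amplitude_spectrum(
                segments[ei, bi], recording.sampling_rate, demean=demean
            )
            for k in harmonics:
                f = k * stim_freq
                idx = spec.at(f)
                amp = float(spec.amplitudes[idx])
                noise = side_bin_noise(spec, f, n_side=n_side, method=noise_method)
                snr = compute_snr(amp, noise)
                rows.append(
                    (
                        meta.get("rat_id", ""),
                        meta.get("group", ""),
                        meta.get("week", 0),
                        electrode,
                        meta.get("wavelength", ""),
                        k,
                        bi,
                        amp,
                        float(spec.phases[idx]),
                        snr,
                        bool(snr >= 1.0),
                    )
                )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def extract_cohort_samples(
    recordings, **kwargs
) -> pd.DataFrame:
    """Concatenate :func:`extract_harmonic_samples` over SSVEP recordings."""
    frames = [
        extract_harmonic_samples(rec, **kwargs)
        for rec in recordings
        if rec.meta.get("paradigm") == "SSVEP"
    ]
    if not frames:
        raise DataError("no SSVEP recordings supplied")
    return pd.concat(frames, ignore_index=True)


def build_feature_pools(
    samples: pd.DataFrame,
    group: str | None = None,
    electrodes: tuple[str, ...] | None = None,
    wavelengths: tuple[str, ...] | None = None,
    harmonics: tuple[int, ...] | None = None,
) -> dict[tuple[str, str, int], FeaturePool]:
    """Group retained samples into per-feature sampling pools.

    Features are keyed by (electrode, wavelength, harmonic); only retained
    (SNR >= 1) samples enter a pool.  The samples must come from a single
    week (pools are per session).  Raises if a requested feature ends up
    with an empty pool.
    """
    if samples["week"].nunique() > 1:
        raise DataError(
            "feature pools must be built from a single week "
            f"(got weeks {sorted(samples['week'].unique())})"
        )
    df = samples[samples["retained"]]
    if group is not None:
        df = df[df["group"] == group]
    want_electrodes = electrodes or tuple(sorted(samples["electrode"].unique()))
    want_wavelengths = wavelengths or tuple(sorted(samples["wavelength"].unique()))
    want_harmonics = harmonics or tuple(sorted(samples["harmonic"].unique()))
    pools: dict[tuple[str, str, int], FeaturePool] = {}
    grouped = df.groupby(["electrode", "wavelength", "harmonic"])
    for el in want_electrodes:
        for wl in want_wavelengths:
            for k in want_harmonics:
                key = (el, wl, int(k))
                try:
                    sub = grouped.get_group(key)
                except KeyError:
                    raise DataError(
                        f"empty feature pool for {key} (no retained samples)"
                    ) from None
                pools[key] = FeaturePool(
                    electrode=el,
                    wavelength=wl,
                    harmonic=int(k),
                    amplitudes=sub["amplitude_uV"].to_numpy(),
                    rat_ids=sub["rat_id"].to_numpy(),
                    bin_indices=sub["bin"].to_numpy(),
                )
    return pools
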