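"""File formats: long-table CSV, EDF, and the run configuration.

Two interchange formats are supported for raw traces:

* **long table** — the lossless internal format: one sample per row
  (``rat_id, group, week, electrode, wavelength, paradigm, time_s,
  value_uV``) with a sidecar events table (``onset_s, code``).
* **EDF** — European Data Format, the standard multichannel biosignal
  container (16-bit; round-trips are lossless up to quantisation).
  Reading goes through :mod:`mne`; writing uses a minimal writer for the
  classic EDF header + int16 data records, since no installed library
  exports EDF.  Condition metadata and stimulus events travel in JSON/CSV
  sidecars (``<file>.meta.json``, ``<file>.events.csv``).

Run configurations are YAML and round-trip losslessly through
:class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import ClassifierConfig
from .errors import ConfigurationError, DataError
from .recording import Recording
from .simulate import (
    CohortSpec,
    ElectrodeEffect,
    PeakTemplate,
    SimulationConfig,
)
from .vep import DEFAULT_BASELINE_WINDOW, DEFAULT_PEAK_WINDOWS

__all__ = [
    "write_long_table",
    "read_long_table",
    "write_edf",
    "read_edf",
    "write_recording",
    "read_recording",
    "RunConfig",
]

LONG_COLUMNS = [
    "rat_id",
    "group",
    "week",
    "electrode",
    "wavelength",
    "paradigm",
    "time_s",
    "value_uV",
]


# ---------------------------------------------------------------------------
# long table


def write_long_table(recording: Recording, path) -> None:
    """Write one recording as a tidy per-sample table + events sidecar."""
    path = Path(path)
    meta = recording.meta
    t = recording.time
    frames = []
    for i, el in enumerate(recording.electrodes):
        frames.append(
            pd.DataFrame(
                {
                    "rat_id": meta.get("rat_id", ""),
                    "group": meta.get("group", ""),
                    "week": meta.get("week", 0),
                    "electrode": el,
                    "wavelength": meta.get("wavelength", ""),
                    "paradigm": meta.get("paradigm", ""),
                    "time_s": t,
                    "value_uV": recording.data[i],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    _write_sidecars(recording, path)


def _write_sidecars(recording: Recording, path: Path) -> None:
    events = pd.DataFrame(
        {"onset_s": recording.events, "code": "stim"}
    )
    events.to_csv(path.with_suffix(path.suffix + ".events.csv"), index=False)
    meta = dict(recording.meta)
    meta["sampling_rate_hz"] = recording.sampling_rate
    meta["n_samples"] = int(recording.n_samples)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_sidecars(path: Path):
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    events_path = path.with_suffix(path.suffix + ".events.csv")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    if not events_path.exists():
        raise DataError(
            f"{path}: events sidecar {events_path.name} is missing"
        )
    events = pd.read_csv(events_path)["onset_s"].to_numpy(dtype=float)
    return meta, events


def read_long_table(path, electrodes: tuple[str, ...] | None = None) -> Recording:
    """Read a long-table recording back into a :class:`Recording`."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing_cols = set(LONG_COLUMNS) - set(df.columns)
    if missing_cols:
        raise DataError(
            f"{path}: long table lacks columns {sorted(missing_cols)}"
        )
    meta, events = _read_sidecars(path)
    found = tuple(df["electrode"].unique())
    if electrodes is not None:
        missing = [el for el in electrodes if el not in found]
        if missing:
            raise DataError(
                f"{path}: missing channel(s) {missing} "
                f"(file has {list(found)})"
            )
        use = electrodes
    else:
        use = found
    traces = []
    fs = None
    for el in use:
        sub = df[df["electrode"] == el].sort_values("time_s")
        t = sub["time_s"].to_numpy()
        steps = np.diff(t)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise DataError(f"{path}: non-uniform sampling on channel {el}")
        if len(steps):
            fs_el = 1.0 / steps[0]
            if fs is not None and not np.isclose(fs, fs_el):
                raise DataError(f"{path}: sampling rate differs across channels")
            fs = fs_el
        traces.append(sub["value_uV"].to_numpy())
    if fs is None:
        fs = float(meta.get("sampling_rate_hz", 0)) or 1.0
    row = df.iloc[0]
    full_meta = {
        "rat_id": row["rat_id"],
        "group": row["group"],
        "week": int(row["week"]),
        "wavelength": row["wavelength"],
        "paradigm": row["paradigm"],
    }
    full_meta.update(meta)
    try:
        return Recording(
            data=np.asarray(traces),
            sampling_rate=fs,
            electrodes=use,
            events=events,
            meta=full_meta,
        )
    except ConfigurationError as exc:
        raise DataError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _edf_number(value: float, width: int) -> bytes:
    """Format a physical min/max so it fits the fixed-width ASCII field."""
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.3g}", f"{value:.1e}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise DataError(f"cannot format {value} in {width} EDF characters")


def write_edf(recording: Recording, path) -> None:
    """Write a classic EDF file (16-bit) plus meta/events sidecars.

    One data record per second; each channel is scaled to the int16 range
    by its own physical min/max, so amplitude resolution is
    (max - min) / 65535 µV.  The sampling rate must be an integer.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise DataError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(recording.electrodes)
    n = recording.n_samples
    n_records = int(np.ceil(n / fs))
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, :n] = recording.data
    if n_records * fs > n:  # pad with the channel edge value
        padded[:, n:] = recording.data[:, -1:]

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # guard degenerate flat channels
    flat = phys_max - phys_min == 0
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(recording.meta.get("rat_id", "X"), 80),
            _edf_field(
                "Startdate 01-JAN-2000 "
                + str(recording.meta.get("paradigm", "")),
                80,
            ),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_sig + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(n_sig, 4),
        ]
    )
    per_signal = []
    for spec, width in (
        (list(recording.electrodes), 16),  # label
        ([""] * n_sig, 80),  # transducer
        (["uV"] * n_sig, 8),  # physical dimension
        ([_edf_number(v, 8).decode() for v in phys_min], 8),
        ([_edf_number(v, 8).decode() for v in phys_max], 8),
        ([dig_min] * n_sig, 8),
        ([dig_max] * n_sig, 8),
        (["HP:1Hz LP:200Hz"] * n_sig, 80),  # prefiltering
        ([fs] * n_sig, 8),
        ([""] * n_sig, 32),
    ):
        for v in spec:
            per_signal.append(_edf_field(v, width))
    header += b"".join(per_signal)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round(
        (padded - phys_min[:, None]) * scale[:, None] + dig_min
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(chunk.tobytes())
    _write_sidecars(recording, path)


def read_edf(path, electrodes: tuple[str, ...] | None = None) -> Recording:
    """Read an EDF recording (via mne) and its sidecars."""
    import mne

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    meta, events = _read_sidecars(path)
    found = tuple(raw.ch_names)
    if electrodes is not None:
        missing = [el for el in electrodes if el not in found]
        if missing:
            raise DataError(
                f"{path}: missing channel(s) {missing} "
                f"(file has {list(found)})"
            )
        use = electrodes
    else:
        use = found
    data_v = raw.get_data(picks=list(use))
    fs = float(raw.info["sfreq"])
    n = int(meta.get("n_samples", data_v.shape[1]))
    try:
        return Recording(
            data=data_v[:, :n] * 1e6,
            sampling_rate=fs,
            electrodes=use,
            events=events,
            meta=meta,
        )
    except ConfigurationError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_recording(recording: Recording, path, format: str = "long") -> None:
    if format in ("long", "long_table"):
        write_long_table(recording, path)
    elif format == "edf":
        write_edf(recording, path)
    else:
        raise ConfigurationError(f"unknown recording format {format!r}")


def read_recording(
    path, format: str = "long", electrodes: tuple[str, ...] | None = None
) -> Recording:
    if format in ("long", "long_table"):
        return read_long_table(path, electrodes=electrodes)
    if format == "edf":
        return read_edf(path, electrodes=electrodes)
    raise ConfigurationError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one pipeline run needs, YAML-round-trippable."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    peak_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_WINDOWS)
    )
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
    phase_pooling: str = "per_rat"  # or "raw_bins"
    kappa_threshold: float = 2.0
    output_dir: str = "veptools_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "simulation": asdict(self.simulation),
            "cohort": asdict(self.cohort),
            "classifier": asdict(self.classifier),
            "peak_windows": {
                k: [float(a), float(b)] for k, (a, b) in self.peak_windows.items()
            },
            "baseline_window": [float(v) for v in self.baseline_window],
            "phase_pooling": self.phase_pooling,
            "kappa_threshold": self.kappa_threshold,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        d["simulation"]["peak_templates"] = [
            asdict(p) if not isinstance(p, dict) else p
            for p in d["simulation"]["peak_templates"]
        ]
        d["cohort"]["group_effects"] = {
            f"{g}/{el}": asdict(e) if not isinstance(e, dict) else e
            for (g, el), e in self.cohort.group_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = dict(d.get("simulation", {}))
        if "peak_templates" in sim:
            sim["peak_templates"] = tuple(
                PeakTemplate(**p) for p in sim["peak_templates"]
            )
        if "harmonic_amplitudes" in sim:
            sim["harmonic_amplitudes"] = {
                int(k): float(v) for k, v in sim["harmonic_amplitudes"].items()
            }
        if "harmonic_phases" in sim:
            sim["harmonic_phases"] = {
                int(k): float(v) for k, v in sim["harmonic_phases"].items()
            }
        coh = dict(d.get("cohort", {}))
        if "group_effects" in coh:
            effects = {}
            for key, e in coh["group_effects"].items():
                group, el = key.split("/")
                effects[(group, el)] = ElectrodeEffect(**e)
            coh["group_effects"] = effects
        for tup_field in ("electrodes", "wavelengths", "weeks"):
            if tup_field in coh:
                coh[tup_field] = tuple(coh[tup_field])
        return cls(
            simulation=SimulationConfig(**sim),
            cohort=CohortSpec(**coh),
            classifier=ClassifierConfig(**d.get("classifier", {})),
            peak_windows={
                k: (float(a), float(b))
                for k, (a, b) in d.get(
                    "peak_windows", DEFAULT_PEAK_WINDOWS
                ).items()
            },
            baseline_window=tuple(
                d.get("baseline_window", DEFAULT_BASELINE_WINDOW)
            ),
            phase_pooling=d.get("phase_pooling", "per_rat"),
            kappa_threshold=float(d.get("kappa_threshold", 2.0)),
            output_dir=d.get("output_dir", "veptools_out"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"no such config file: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        try:
            return cls.from_dict(d)
        except (TypeError, KeyError, ValueError) as exc:
            raise ConfigurationError(f"{path}: bad config: {exc}") from exc

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs land is
        irrelevant to what they contain)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
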