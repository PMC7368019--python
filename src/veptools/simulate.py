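"""Synthetic VEP/SSVEP cohort generator.

Emulates the recording design of a unilateral AAV-α-synuclein rat study:
four chronic electrodes (bilateral visual cortex and superior colliculus),
1 kHz sampling, five stimulus wavelength conditions, weekly sessions.  Two
paradigms are simulated per condition:

* **SSVEP** — a 100-s run driven by a 14-Hz square-wave flicker (10-ms
  flashes).  The neural response is modelled directly as a harmonic sum at
  1f and 2f (only those harmonic amplitudes/phases enter the analysis) on
  top of 1/f ("pink") plus white noise.  The flash train itself is kept as
  the event list for bookkeeping.
* **Flash VEP** — 400 one-per-second flashes; each epoch is a sum of named
  Gaussian deflections (P1, N1, P2, N2, P3, P4) whose latencies are defined
  relative to stimulus *offset* (onset + flash duration), plus the same
  noise model.

Disease effects are injected per (group, electrode): a multiplicative SSVEP
amplitude factor, an additive SSVEP phase offset, and an additive VEP peak
latency shift.  The default disease effect is confined to the left superior
colliculus (ipsilateral to the simulated injection), mirroring a unilateral
lesion model; the control group is always identity.

All randomness flows through :class:`numpy.random.SeedSequence` so a single
cohort seed deterministically spawns per-recording streams without any
global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .recording import ELECTRODES, GROUPS, WAVELENGTHS, Recording

__all__ = [
    "PeakTemplate",
    "SimulationConfig",
    "ElectrodeEffect",
    "CohortSpec",
    "default_peak_templates",
    "default_group_effects",
    "pink_noise",
    "generate_ssvep_recording",
    "generate_vep_trials",
    "generate_cohort",
]


@dataclass(frozen=True)
class PeakTemplate:
    """One named VEP deflection: a signed Gaussian bump.

    ``latency_s`` is measured from stimulus offset; ``amplitude_mv`` is the
    unsigned bump height in millivolts and ``polarity`` is +1 for P-peaks,
    −1 for N-peaks.
    """

    name: str
    polarity: int
    latency_s: float
    width_s: float
    amplitude_mv: float


def default_peak_templates() -> tuple[PeakTemplate, ...]:
    """Default flash-VEP morphology (six peaks, collicular-like timing)."""
    return (
        PeakTemplate("P1", +1, 0.030, 0.006, 0.30),
        PeakTemplate("N1", -1, 0.060, 0.010, 0.25),
        PeakTemplate("P2", +1, 0.095, 0.012, 0.20),
        PeakTemplate("N2", -1, 0.140, 0.016, 0.15),
        PeakTemplate("P3", +1, 0.200, 0.020, 0.10),
        PeakTemplate("P4", +1, 0.280, 0.025, 0.08),
    )


@dataclass
class SimulationConfig:
    """Physical and stimulus parameters for one simulated recording.

    Units: seconds, Hz, µV for SSVEP harmonic amplitudes and noise scales,
    mV for VEP peak templates (the convention in which flash-VEP peaks are
    reported).
    """

    sampling_rate: float = 1000.0
    run_duration: float = 100.0
    stim_freq: float = 14.0
    flash_duration: float = 0.010
    vep_rate: float = 1.0
    n_vep_trials: int = 400
    harmonic_amplitudes: dict[int, float] = field(
        default_factory=lambda: {1: 10.0, 2: 5.0}
    )
    harmonic_phases: dict[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 0.0}
    )
    noise_pink_scale: float = 6.0
    noise_white_scale: float = 35.0
    #: acquisition band of the amplifier chain (high-pass 1 Hz, low-pass
    #: 200 Hz); the 1/f background is restricted to this band
    band_low_hz: float = 1.0
    band_high_hz: float = 200.0
    rat_effect_sd: float = 0.2
    peak_templates: tuple[PeakTemplate, ...] = field(
        default_factory=default_peak_templates
    )
    seed: int = 0

    def validate(self) -> None:
        if self.stim_freq <= 0:
            raise ConfigurationError("stim_freq must be > 0")
        if self.run_duration <= 0:
            raise ConfigurationError("run_duration must be > 0")
        if self.flash_duration <= 0:
            raise ConfigurationError("flash_duration must be > 0")
        if self.sampling_rate < 2 * (4 + 2 * self.stim_freq):
            raise ConfigurationError(
                "sampling_rate must be >= 2*(4 + 2*stim_freq) so the side "
                "bins of the second harmonic lie below Nyquist"
            )
        if self.vep_rate <= 0:
            raise ConfigurationError("vep_rate must be > 0")
        lats = [p.latency_s for p in self.peak_templates]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ConfigurationError(
                "peak_templates latencies must be strictly increasing"
            )
        for k, a in self.harmonic_amplitudes.items():
            if k < 1 or a < 0:
                raise ConfigurationError(
                    "harmonic_amplitudes keys must be >= 1 with "
                    "non-negative amplitudes"
                )
        if self.noise_pink_scale < 0 or self.noise_white_scale < 0:
            raise ConfigurationError("noise scales must be non-negative")


@dataclass(frozen=True)
class ElectrodeEffect:
    """Per-(group, electrode) condition effect.

    ``amp_factor`` multiplies every SSVEP harmonic amplitude,
    ``phase_offset`` (rad) is added to every harmonic phase, and
    ``latency_shift`` (s) is added to every VEP peak latency.
    """

    amp_factor: float = 1.0
    phase_offset: float = 0.0
    latency_shift: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (
            self.amp_factor == 1.0
            and self.phase_offset == 0.0
            and self.latency_shift == 0.0
        )


def default_group_effects() -> dict[tuple[str, str], ElectrodeEffect]:
    """Default unilateral disease effect: left SC only, in the AAV group.

    A 16% SSVEP amplitude reduction, a 0.3-rad phase offset, and a 4-ms
    VEP latency delay on SC_L of α-synuclein animals; identity everywhere
    else.  The amplitude factor is calibrated so the all-electrode
    bootstrap classifier operates in the 84–93% accuracy regime typical of
    this assay while the per-electrode amplitude difference stays too
    small for univariate detection — the classifier's sensitivity, not a
    gross lesion, is what the effect size emulates.
    """
    effects: dict[tuple[str, str], ElectrodeEffect] = {}
    for group in GROUPS:
        for el in ELECTRODES:
            effects[(group, el)] = ElectrodeEffect()
    effects[("alpha_syn", "SC_L")] = ElectrodeEffect(
        amp_factor=0.84, phase_offset=0.3, latency_shift=0.004
    )
    return effects


@dataclass
class CohortSpec:
    """Design of a simulated two-group cohort.

    ``group_effects`` maps ``(group, electrode)`` to the condition effect;
    the control group must be identity on every electrode (it received the
    empty vector).  ``wavelength_factors`` optionally scales SSVEP amplitude
    per wavelength label (wavelength is otherwise just a label).
    """

    n_per_group: int = 13
    electrodes: tuple[str, ...] = ELECTRODES
    wavelengths: tuple[str, ...] = WAVELENGTHS
    weeks: tuple[int, ...] = (3, 5, 6, 7, 8, 9, 10, 11)
    group_effects: dict[tuple[str, str], ElectrodeEffect] = field(
        default_factory=default_group_effects
    )
    wavelength_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        for labels, what in (
            (self.electrodes, "electrodes"),
            (self.wavelengths, "wavelengths"),
        ):
            if len(set(labels)) != len(labels):
                raise ConfigurationError(f"{what} labels must be unique")
        for el in self.electrodes:
            eff = self.group_effects.get(("control", el), ElectrodeEffect())
            if not eff.is_identity:
                raise ConfigurationError(
                    "control-group effect must be identity on every "
                    f"electrode (violated on {el})"
                )

    def effect(self, group: str, electrode: str) -> ElectrodeEffect:
        return self.group_effects.get((group, electrode), ElectrodeEffect())


# ---------------------------------------------------------------------------
# noise


def pink_noise(
    n: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    sampling_rate: float = 1.0,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping.

    The amplitude profile over the positive rFFT frequencies is
    ``1/f**exponent`` with independent random phases, optionally restricted
    to ``band = (f_lo, f_hi)`` Hz (emulating an acquisition band-pass); the
    result is normalised to zero mean and unit standard deviation.
    """
    if n < 2:
        raise ConfigurationError("pink noise requires n >= 2")
    n_freq = n // 2 + 1
    spectrum = rng.normal(size=n_freq) + 1j * rng.normal(size=n_freq)
    freqs = np.arange(n_freq) * sampling_rate / n
    profile = np.zeros(n_freq)
    profile[1:] = 1.0 / np.arange(1, n_freq) ** exponent
    if band is not None:
        f_lo, f_hi = band
        profile[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spectrum * profile, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        return x
    return x / sd


def _noise(config: SimulationConfig, n: int, rng: np.random.Generator):
    """Pink + white background, pink band-limited to the hardware band."""
    out = np.zeros(n)
    if config.noise_pink_scale > 0:
        out += config.noise_pink_scale * pink_noise(
            n,
            rng,
            sampling_rate=config.sampling_rate,
            band=(config.band_low_hz, config.band_high_hz),
        )
    if config.noise_white_scale > 0:
        out += rng.normal(0.0, config.noise_white_scale, size=n)
    return out


# ---------------------------------------------------------------------------
# single-recording generators


def _as_effect_map(effects, electrodes) -> dict[str, ElectrodeEffect]:
    if isinstance(effects, ElectrodeEffect):
        return {el: effects for el in electrodes}
    return {el: effects.get(el, ElectrodeEffect()) for el in electrodes}


def generate_ssvep_recording(
    config: SimulationConfig,
    effects: ElectrodeEffect | dict[str, ElectrodeEffect] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    electrodes: tuple[str, ...] = ELECTRODES,
    meta: dict | None = None,
) -> Recording:
    """Simulate one steady-state run: harmonic sum plus 1/f and white noise.

    Each electrode trace is ``sum_k A_k * factor * sin(2*pi*k*f_stim*t +
    phi_k + offset)`` with independent noise per electrode; events mark
    every flash onset (one per stimulus period).
    """
    config.validate()
    if effects is None:
        effects = ElectrodeEffect()
    eff_map = _as_effect_map(effects, electrodes)
    rng_parent = np.random.SeedSequence(
        seed if seed is not None else config.seed
    ) if not isinstance(seed, np.random.SeedSequence) else seed
    children = rng_parent.spawn(len(electrodes))

    n = int(round(config.run_duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    data = np.empty((len(electrodes), n))
    for i, el in enumerate(electrodes):
        eff = eff_map[el]
        sig = np.zeros(n)
        for k, amp in config.harmonic_amplitudes.items():
            phi = config.harmonic_phases.get(k, 0.0)
            sig += (
                amp
                * eff.amp_factor
                * np.sin(
                    2 * np.pi * k * config.stim_freq * t
                    + phi
                    + eff.phase_offset
                )
            )
        rng = np.random.default_rng(children[i])
        data[i] = sig + _noise(config, n, rng)

    events = np.arange(0.0, config.run_duration, 1.0 / config.stim_freq)
    full_meta = {
        "paradigm": "SSVEP",
        "stim_freq_hz": config.stim_freq,
        "flash_duration_s": config.flash_duration,
    }
    if meta:
        full_meta.update(meta)
    return Recording(
        data=data,
        sampling_rate=config.sampling_rate,
        electrodes=electrodes,
        events=events,
        meta=full_meta,
    )


def vep_epoch_template(
    config: SimulationConfig, latency_shift: float = 0.0
) -> np.ndarray:
    """Noise-free single-epoch waveform (µV) over one stimulus period.

    Peak latencies are defined relative to stimulus offset, so each bump is
    centred at ``flash_duration + latency + latency_shift`` within the
    epoch.  Raises if a shift pushes any peak outside the inter-stimulus
    interval.
    """
    period = 1.0 / config.vep_rate
    n = int(round(period * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    template = np.zeros(n)
    for peak in config.peak_templates:
        centre = config.flash_duration + peak.latency_s + latency_shift
        if not 0.0 < centre < period:
            raise ConfigurationError(
                f"latency shift {latency_shift} s pushes peak {peak.name} "
                f"outside the inter-stimulus interval [0, {period}) s"
            )
        amp_uv = 1000.0 * peak.amplitude_mv * peak.polarity
        template += amp_uv * np.exp(-0.5 * ((t - centre) / peak.width_s) ** 2)
    return template


def generate_vep_trials(
    config: SimulationConfig,
    latency_shift: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    electrodes: tuple[str, ...] = ELECTRODES,
    effects: ElectrodeEffect | dict[str, ElectrodeEffect] | None = None,
    meta: dict | None = None,
) -> Recording:
    """Simulate a flash-VEP run of ``n_vep_trials`` identical epochs + noise.

    ``latency_shift`` applies to every electrode; per-electrode shifts can
    be supplied through ``effects`` instead (their ``latency_shift`` adds to
    the global one).
    """
    config.validate()
    if config.n_vep_trials < 1:
        raise ConfigurationError("n_vep_trials must be >= 1")
    if effects is None:
        effects = ElectrodeEffect()
    eff_map = _as_effect_map(effects, electrodes)
    rng_parent = np.random.SeedSequence(
        seed if seed is not None else config.seed
    ) if not isinstance(seed, np.random.SeedSequence) else seed
    children = rng_parent.spawn(len(electrodes))

    period = 1.0 / config.vep_rate
    n_epoch = int(round(period * config.sampling_rate))
    n = n_epoch * config.n_vep_trials
    data = np.empty((len(electrodes), n))
    for i, el in enumerate(electrodes):
        shift = latency_shift + eff_map[el].latency_shift
        template = vep_epoch_template(config, shift)
        rng = np.random.default_rng(children[i])
        data[i] = np.tile(template, config.n_vep_trials) + _noise(
            config, n, rng
        )

    events = np.arange(config.n_vep_trials) * period
    full_meta = {
        "paradigm": "VEP",
        "flash_duration_s": config.flash_duration,
        "vep_rate_hz": config.vep_rate,
    }
    if meta:
        full_meta.update(meta)
    return Recording(
        data=data,
        sampling_rate=config.sampling_rate,
        electrodes=electrodes,
        events=events,
        meta=full_meta,
    )


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    cohort: CohortSpec,
    config: SimulationConfig,
    paradigms: tuple[str, ...] = ("SSVEP", "VEP"),
) -> list[Recording]:
    """Generate all recordings of a two-group cohort.

    One multichannel :class:`Recording` (one trace per declared electrode)
    per (rat, wavelength, week, paradigm); per-rat seeds are spawned
    deterministically from the cohort seed.  Each rat carries one
    log-normal amplitude gain (SD ``config.rat_effect_sd`` on the log
    scale) shared across its electrodes and recordings — a global-gain
    animal idiosyncrasy (reference electrode, skull/tissue conductivity) —
    so bins from different animals are not i.i.d.  The gain is common to
    all of a rat's features, hence within-animal z-scoring cancels it:
    arbitrary splits of the animals are then not classifiable, which is
    the regime a chance-level shuffled control presupposes.
    """
    cohort.validate()
    config.validate()
    root = np.random.SeedSequence(cohort.seed)
    rats = [
        (f"{group}_{i + 1:02d}", group)
        for group in GROUPS
        for i in range(cohort.n_per_group)
    ]
    rat_seqs = root.spawn(len(rats))
    recordings: list[Recording] = []
    for (rat_id, group), rat_seq in zip(rats, rat_seqs):
        rat_rng = np.random.default_rng(rat_seq)
        rat_gain = (
            float(np.exp(rat_rng.normal(0.0, config.rat_effect_sd)))
            if config.rat_effect_sd > 0
            else 1.0
        )
        n_rec = len(cohort.weeks) * len(cohort.wavelengths) * len(paradigms)
        rec_seqs = iter(rat_seq.spawn(n_rec))
        for week in cohort.weeks:
            for wavelength in cohort.wavelengths:
                wl_factor = cohort.wavelength_factors.get(wavelength, 1.0)
                eff_map = {}
                for el in cohort.electrodes:
                    base = cohort.effect(group, el)
                    eff_map[el] = replace(
                        base,
                        amp_factor=base.amp_factor * rat_gain * wl_factor,
                    )
                meta = {
                    "rat_id": rat_id,
                    "group": group,
                    "wavelength": wavelength,
                    "week": week,
                }
                for paradigm in paradigms:
                    seq = next(rec_seqs)
                    if paradigm == "SSVEP":
                        rec = generate_ssvep_recording(
                            config,
                            effects=eff_map,
                            seed=seq,
                            electrodes=cohort.electrodes,
                            meta=meta,
                        )
                    elif paradigm == "VEP":
                        rec = generate_vep_trials(
                            config,
                            seed=seq,
                            electrodes=cohort.electrodes,
                            effects=eff_map,
                            meta=meta,
                        )
                    else:
                        raise ConfigurationError(
                            f"unknown paradigm {paradigm!r}"
                        )
                    recordings.append(rec)
    return recordings
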