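"""Shared fixtures: small, fast synthetic inputs built at test time."""

import numpy as np
import pandas as pd
import pytest

from veptools.recording import Recording
from veptools.simulate import SimulationConfig
from veptools.spectral import SAMPLE_COLUMNS


@pytest.fixture
def quiet_config():
    """Noise-free simulation config with a short SSVEP run."""
    return SimulationConfig(
        run_duration=12.0,
        noise_pink_scale=0.0,
        noise_white_scale=0.0,
        rat_effect_sd=0.0,
        n_vep_trials=3,
    )


@pytest.fixture
def default_config():
    return SimulationConfig()


def make_recording(
    data,
    sampling_rate=1000.0,
    electrodes=("SC_L",),
    events=None,
    **meta,
):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if events is None:
        events = np.array([0.0])
    base = {"paradigm": "SSVEP", "stim_freq_hz": 14.0, "flash_duration_s": 0.01}
    base.update(meta)
    return Recording(
        data=data,
        sampling_rate=sampling_rate,
        electrodes=electrodes,
        events=np.asarray(events, dtype=float),
        meta=base,
    )


def make_sample_table(
    n_rats=13,
    n_bins=90,
    electrodes=("VC_L", "VC_R", "SC_L", "SC_R"),
    wavelengths=("red", "green", "blue", "short_blue", "white"),
    harmonics=(1, 2),
    group="alpha_syn",
    week=11,
    amplitude=10.0,
    rng=None,
    excluded_bins=0,
):
    """Synthetic retained-sample table with controllable exclusions."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for r in range(n_rats):
        rat = f"{group}_{r + 1:02d}"
        for el in electrodes:
            for wl in wavelengths:
                for k in harmonics:
                    for b in range(n_bins):
                        excluded = b < excluded_bins
                        rows.append(
                            (
                                rat,
                                group,
                                week,
                                el,
                                wl,
                                k,
                                b,
                                amplitude + rng.normal(0, 1),
                                float(rng.uniform(-np.pi, np.pi)),
                                0.5 if excluded else 3.0,
                                not excluded,
                            )
                        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
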