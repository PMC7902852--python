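"""Stimulus protocols and the action-potential voltage template.

The source recordings do not constrain the exact AP shape, so the template
is a skewed Gaussian depolarization (rest -70 mV, peak 0 mV, 1 ms full
width at half maximum, decay slower than rise) with every parameter exposed;
the peak is calibrated against the terminal's pump capacity (see
docs/methods.md).
The stimulus is deterministic: a protocol fully determines V(t), and only
channel gating downstream is stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

REST_VOLTAGE = -70.0  # mV
PEAK_VOLTAGE = 0.0    # mV (overshoot-free depolarization; see docs/methods.md)
HALF_WIDTH_MS = 1.0
RELEASE_WINDOW = 0.020  # s, success-counting window after each AP onset

# skew: decay sigma / rise sigma; FWHM of the two-sided Gaussian is
# sqrt(2 ln 2) * (sigma_rise + sigma_decay)
_SKEW = 1.8
_FWHM_FACTOR = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class APWaveform:
    """Membrane-voltage trajectory built from one template per AP onset."""

    onset_times: Tuple[float, ...]
    rest_voltage: float = REST_VOLTAGE
    peak_voltage: float = PEAK_VOLTAGE
    half_width_ms: float = HALF_WIDTH_MS
    shape: str = "skewed_gaussian"

    def __post_init__(self):
        if self.shape != "skewed_gaussian":
            raise ValueError("only the 'skewed_gaussian' template is available")
        if self.half_width_ms <= 0:
            raise ValueError("half_width_ms must be > 0")
        if list(self.onset_times) != sorted(self.onset_times):
            raise ValueError("onset_times must be sorted")

    @property
    def sigma_rise(self) -> float:
        """Rise-side Gaussian width, seconds."""
        total = self.half_width_ms * 1e-3 / _FWHM_FACTOR
        return total / (1.0 + _SKEW)

    @property
    def sigma_decay(self) -> float:
        return self.sigma_rise * _SKEW

    @property
    def peak_delay(self) -> float:
        """Time from AP onset to the voltage peak, seconds.

        The template's support is (peak - 8 sigma_rise, peak + 8 sigma_decay),
        so with an 8 sigma_rise delay the depolarization lies entirely after
        the declared onset.
        """
        return 8.0 * self.sigma_rise

    @property
    def amplitude(self) -> float:
        return self.peak_voltage - self.rest_voltage


def voltage_at(waveform: APWaveform, t: float) -> float:
    """Deterministic membrane voltage (mV) at time t (s).

    Equals rest before the first onset and after relaxation; overlapping
    templates superpose in time order.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    v = waveform.rest_voltage
    sr, sd = waveform.sigma_rise, waveform.sigma_decay
    for onset in waveform.onset_times:
        dt = t - (onset + waveform.peak_delay)
        if -8 * sr < dt < 8 * sd:
            s = sr if dt < 0 else sd
            v += waveform.amplitude * math.exp(-0.5 * (dt / s) ** 2)
    return v


def sample_voltage(waveform: APWaveform, times: np.ndarray) -> np.ndarray:
    return np.array([voltage_at(waveform, float(t)) for t in times])


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulus timing: kind, AP onsets and the total simulated time."""

    kind: str
    onsets: Tuple[float, ...]
    total_time: float
    isi: float = 0.0
    frequency: float = 0.0
    n_pulses: int = 0
    waveform: APWaveform = None

    def __post_init__(self):
        if self.kind not in ("single", "paired_pulse", "train", "none"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.onsets and self.total_time < self.onsets[-1] + RELEASE_WINDOW:
            raise ValueError("total_time must cover the last AP plus the "
                             "20 ms release window")
        if self.waveform is None:
            object.__setattr__(self, "waveform", APWaveform(tuple(self.onsets)))


# total times used for the three tabulated train frequencies; other trains
# get the last onset plus a 100 ms tail
_TRAIN_TOTALS = {20.0: 2.050, 50.0: 0.450}


def make_protocol(kind: str, isi: float = None, frequency: float = None,
                  n_pulses: int = None, total_time: float = None,
                  **waveform_kwargs) -> ProtocolSpec:
    """Build a stimulus protocol.

    ``single``: one AP, 50 ms simulated.  ``paired_pulse``: onsets at 0 and
    ISI, total 30 ms + ISI.  ``train``: ``n_pulses`` APs at ``frequency``
    (total time per the tabulated protocol durations where defined).
    ``none``: no APs (resting activity), requires ``total_time``.
    """
    if kind == "single":
        onsets = (0.0,)
        total = total_time if total_time is not None else 0.050
    elif kind == "paired_pulse":
        if isi is None or isi <= 0:
            raise ValueError("paired_pulse requires isi > 0 (seconds)")
        onsets = (0.0, isi)
        total = total_time if total_time is not None else 0.030 + isi
        return ProtocolSpec("paired_pulse", onsets, total, isi=isi,
                            waveform=APWaveform(onsets, **waveform_kwargs))
    elif kind == "train":
        if not frequency or frequency <= 0 or not n_pulses or n_pulses < 1:
            raise ValueError("train requires frequency > 0 and n_pulses >= 1")
        onsets = tuple(i / frequency for i in range(n_pulses))
        total = total_time if total_time is not None else \
            _TRAIN_TOTALS.get(float(frequency), onsets[-1] + 0.100)
        return ProtocolSpec("train", onsets, total, frequency=frequency,
                            n_pulses=n_pulses,
                            waveform=APWaveform(onsets, **waveform_kwargs))
    elif kind == "none":
        if total_time is None or total_time <= 0:
            raise ValueError("kind='none' requires total_time > 0")
        return ProtocolSpec("none", (), total_time,
                            waveform=APWaveform((), **waveform_kwargs))
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    return ProtocolSpec(kind, onsets, total,
                        waveform=APWaveform(onsets, **waveform_kwargs))


def isi_grid() -> Tuple[float, ...]:
    """The paired-pulse ISI grid: 20-100 ms in 10 ms steps, then 120-200 ms
    in 20 ms steps (seconds)."""
    ms = list(range(20, 101, 10)) + list(range(120, 201, 20))
    return tuple(m / 1000.0 for m in ms)


def export_voltage_csv(protocol: ProtocolSpec, path, dt: float = 1e-5) -> None:
    """Write the sampled V(t) as a two-column CSV (time s, voltage mV)."""
    t = np.arange(0.0, protocol.total_time + 0.5 * dt, dt)
    v = sample_voltage(protocol.waveform, t)
    arr = np.column_stack([t, v])
    np.savetxt(path, arr, delimiter=",", header="time_s,voltage_mV", comments="")
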