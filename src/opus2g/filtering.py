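"""Butterworth band-pass filtering of raw acoustic signals.

Three shipped presets differ only in the lower cut-off (LCO): 100, 300 and
700 kHz, all paired with an 8 MHz upper cut-off.  The band-pass is the cascade
of an 8th-order low-pass and a 2nd-order high-pass Butterworth filter.
Raising the LCO suppresses out-of-plane signal at the cost of band-limiting
artifacts; the choice is a per-visualization trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sig

__all__ = ["BandpassSpec", "bandpass", "LCO_PRESETS"]


@dataclass(frozen=True)
class BandpassSpec:
    low_cutoff: float            # Hz
    high_cutoff: float = 8e6     # Hz
    lp_order: int = 8
    hp_order: int = 2

    def __post_init__(self):
        if not (0 < self.low_cutoff < self.high_cutoff):
            raise ValueError("need 0 < low_cutoff < high_cutoff")
        if self.lp_order < 1 or self.hp_order < 1:
            raise ValueError("filter orders must be >= 1")

    def validate_for(self, sampling_rate: float) -> None:
        if self.high_cutoff >= sampling_rate / 2:
            raise ValueError(
                f"high cut-off {self.high_cutoff:g} Hz >= Nyquist "
                f"{sampling_rate / 2:g} Hz")

    def sos(self, sampling_rate: float) -> np.ndarray:
        """Cascaded second-order sections of the band-pass."""
        self.validate_for(sampling_rate)
        lp = sig.butter(self.lp_order, self.high_cutoff, "lowpass",
                        fs=sampling_rate, output="sos")
        hp = sig.butter(self.hp_order, self.low_cutoff, "highpass",
                        fs=sampling_rate, output="sos")
        return np.vstack([hp, lp])


#: The three lower-cut-off variants (pass-bands 0.1-8, 0.3-8 and 0.7-8 MHz).
LCO_PRESETS = {
    100: BandpassSpec(1e5),
    300: BandpassSpec(3e5),
    700: BandpassSpec(7e5),
}


def _impulse_response_length(sos: np.ndarray, sampling_rate: float) -> int:
    # heuristic decay length from the slowest pole
    poles = np.concatenate([np.roots(s[3:]) for s in sos])
    mags = np.abs(poles)
    mags = mags[mags < 1.0]
    if mags.size == 0:
        return 64
    slowest = np.max(mags)
    return int(np.clip(np.ceil(np.log(1e-9) / np.log(slowest)), 64, 100000))


def bandpass(signals: np.ndarray, spec: BandpassSpec, sampling_rate: float,
             zero_phase: bool = True) -> np.ndarray:
    """Band-pass filter each channel of a (n_elements, n_samples) frame.

    ``zero_phase`` applies the filter forward and backward (no arrival-time
    shift, squared magnitude response); the causal mode applies a single
    forward pass with the textbook -3 dB magnitude at each cut-off.  Traces
    are reflect-padded by three impulse-response lengths before filtering.
    """
    x = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signals must be finite")
    sos = spec.sos(sampling_rate)

    n = x.shape[-1]
    pad = min(3 * _impulse_response_length(sos, sampling_rate), n - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    if zero_phase:
        y = sig.sosfiltfilt(sos, xp, axis=-1, padtype=None)
    else:
        y = sig.sosfilt(sos, xp, axis=-1)
    return y[..., pad:pad + n]
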