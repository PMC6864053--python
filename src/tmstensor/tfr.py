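"""Single-trial time-frequency chain for TMS-induced oscillations.

Cleaned epochs (trials × channels × samples around a stimulation pulse)
are converted to one 3D tensor per subject/condition:

1. ``subtract_evoked`` — remove the trial-averaged (phase-locked) response
   so only induced, non-phase-locked power survives;
2. ``hanning_tfr`` — Hann-tapered sliding-window FFT power with a
   frequency-dependent window (fixed number of cycles per window);
3. ``znorm_trials`` — per trial/channel/frequency z-scoring over the full
   trial length;
4. ``baseline_correct`` — subtract the pre-stimulus baseline mean so
   values read as change from baseline, in z-units;
5. ``average_and_crop`` — average trials and restrict to the analysis
   window, away from stimulation and edge artifacts.

Output bins whose analysis window does not fit inside the epoch are
flagged undefined (NaN) rather than zero-padded: zero-padding would bias
the z-transform. The statistics in steps 3–4 use defined bins only.
``induced_tfr`` chains the five steps in this fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

__all__ = [
    "EpochSet",
    "TFRConfig",
    "TrialTFR",
    "TFRTensor",
    "subtract_evoked",
    "hanning_tfr",
    "znorm_trials",
    "baseline_correct",
    "average_and_crop",
    "induced_tfr",
]


@dataclass
class EpochSet:
    """Per-trial multichannel time series (microvolts) around a pulse at t=0."""

    data: np.ndarray  # (trials, channels, samples)
    sampling_rate: float
    times: np.ndarray  # seconds, strictly increasing, uniform 1/sampling_rate
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")
        n_tr, n_ch, n_s = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError(f"{n_ch} channels but {len(self.ch_names)} labels")
        if self.times.shape != (n_s,):
            raise ValueError("time axis length must match the sample count")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.allclose(steps, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("time axis step must equal 1/sampling_rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TFRConfig:
    """Parameters of the induced-power chain.

    Defaults: 3.5 cycles per window, 10 ms steps, 1 Hz bins from 4 to
    45 Hz; baseline −100..−50 ms; crop to 40 ms onward and 4–34 Hz.
    """

    cycles_per_window: float = 3.5
    time_step_ms: float = 10.0
    freq_min: float = 4.0
    freq_max: float = 45.0
    freq_step: float = 1.0
    baseline_ms: tuple[float, float] = (-100.0, -50.0)
    crop_time_ms: tuple[float, float] = (40.0, 1000.0)
    crop_freq: tuple[float, float] = (4.0, 34.0)
    use_power: bool = True  # squared magnitude (power), not amplitude
    crop_undefined: str = "error"  # error | trim | keep

    def __post_init__(self) -> None:
        if self.freq_min < 1.0:
            raise ValueError("freq_min must be >= 1 Hz")
        if self.freq_max < self.freq_min or self.freq_step <= 0:
            raise ValueError("invalid frequency grid")
        if self.baseline_ms[1] > 0 or self.baseline_ms[0] >= self.baseline_ms[1]:
            raise ValueError("baseline window must precede the pulse at t=0")
        if self.crop_undefined not in ("error", "trim", "keep"):
            raise ValueError("crop_undefined must be error|trim|keep")

    @property
    def freqs(self) -> np.ndarray:
        n = int(np.floor((self.freq_max - self.freq_min) / self.freq_step + 0.5)) + 1
        return self.freq_min + self.freq_step * np.arange(n)


@dataclass
class TrialTFR:
    """Single-trial power (trials × channels × freqs × times); NaN = undefined."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # seconds
    ch_names: list[str]
    defined: np.ndarray  # (freqs, times) bool mask

    @property
    def shape(self) -> tuple[int, ...]:
        return self.power.shape


@dataclass
class TFRTensor:
    """One subject/condition block: channels × freqs × times, z-units."""

    values: np.ndarray
    ch_names: list[str]
    freqs: np.ndarray
    times: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def subtract_evoked(epochs: EpochSet) -> EpochSet:
    """Remove the per-channel trial average (the evoked response) from each trial."""
    if epochs.n_trials < 2:
        raise ValueError(
            "evoked subtraction needs >= 2 trials (with one trial it would "
            "zero the data)"
        )
    return replace(epochs, data=epochs.data - epochs.data.mean(axis=0, keepdims=True))


def _window_length(sampling_rate: float, cycles: float, freq: float) -> int:
    n = int(round(sampling_rate * cycles / freq))
    return n + 1 if n % 2 == 0 else n  # odd, so the taper is centred on the bin


def hanning_tfr(epochs: EpochSet, cfg: TFRConfig) -> TrialTFR:
    """Hann-tapered sliding-FFT power on a fixed time-frequency grid.

    For each frequency f the window spans ``cycles_per_window / f`` seconds
    (odd sample count, centred on the output bin). The taper is amplitude-
    normalised so a unit sinusoid at f maps to unit power regardless of the
    window length. Output times are the epoch's samples at ``time_step_ms``
    spacing starting from the first sample. Bins whose window would leave
    the epoch are NaN and cleared in the ``defined`` mask.
    """
    fs = epochs.sampling_rate
    step = int(round(cfg.time_step_ms / 1000.0 * fs))
    if step < 1:
        raise ValueError("time_step_ms below one sample")
    n_samples = epochs.data.shape[2]
    centre_idx = np.arange(0, n_samples, step)
    times = epochs.times[centre_idx]
    freqs = cfg.freqs

    n_tr, n_ch = epochs.data.shape[:2]
    power = np.full((n_tr, n_ch, len(freqs), len(times)), np.nan)
    defined = np.zeros((len(freqs), len(times)), dtype=bool)

    for fi, f in enumerate(freqs):
        n_win = _window_length(fs, cfg.cycles_per_window, f)
        if n_win > n_samples:
            continue  # window never fits: whole row stays flagged
        half = n_win // 2
        valid = (centre_idx >= half) & (centre_idx + half < n_samples)
        if not np.any(valid):
            continue
        taper = hann(n_win, sym=True)
        phase = np.exp(-2j * np.pi * f * (np.arange(n_win) - half) / fs)
        # amplitude normalisation: a unit sinusoid at f yields unit power
        # whatever the (frequency-dependent) window length
        kernel = taper * phase * (2.0 / taper.sum())
        starts = centre_idx[valid] - half
        windows = sliding_window_view(epochs.data, n_win, axis=2)[:, :, starts, :]
        spec = windows @ kernel
        power[:, :, fi, valid] = np.abs(spec) ** 2 if cfg.use_power else np.abs(spec)
        defined[fi, valid] = True

    return TrialTFR(
        power=power,
        freqs=freqs,
        times=times,
        ch_names=list(epochs.ch_names),
        defined=defined,
    )


def znorm_trials(tfr: TrialTFR) -> TrialTFR:
    """Z-transform each trial/channel/frequency row over the (defined) time axis.

    Mean and SD (ddof=1) come from the full trial length, i.e. every
    defined time bin. Undefined bins stay NaN.
    """
    out = np.array(tfr.power)
    for fi in range(len(tfr.freqs)):
        cols = np.flatnonzero(tfr.defined[fi])
        if len(cols) == 0:
            continue
        if len(cols) < 2:
            raise ValueError(
                f"frequency {tfr.freqs[fi]:g} Hz has fewer than 2 defined "
                "time bins; z-transform undefined"
            )
        block = out[:, :, fi, cols]
        mean = block.mean(axis=2, keepdims=True)
        sd = block.std(axis=2, ddof=1, keepdims=True)
        if np.any(sd == 0):
            tr, ch = np.argwhere(sd[:, :, 0] == 0)[0]
            raise ValueError(
                f"zero temporal SD in trial {tr}, channel "
                f"{tfr.ch_names[ch]!r}, frequency {tfr.freqs[fi]:g} Hz"
            )
        out[:, :, fi, cols] = (block - mean) / sd
    return replace(tfr, power=out)


def baseline_correct(tfr: TrialTFR, cfg: TFRConfig) -> TrialTFR:
    """Subtract the mean over the pre-stimulus baseline window per frequency row."""
    b0, b1 = np.asarray(cfg.baseline_ms) / 1000.0
    in_window = (tfr.times >= b0 - 1e-12) & (tfr.times <= b1 + 1e-12)
    out = np.array(tfr.power)
    for fi in range(len(tfr.freqs)):
        cols = np.flatnonzero(in_window & tfr.defined[fi])
        if len(cols) == 0:
            raise ValueError(
                f"no defined baseline bins in [{cfg.baseline_ms[0]:g}, "
                f"{cfg.baseline_ms[1]:g}] ms at {tfr.freqs[fi]:g} Hz"
            )
        base = out[:, :, fi, cols].mean(axis=2, keepdims=True)
        defined_cols = np.flatnonzero(tfr.defined[fi])
        out[:, :, fi, defined_cols] -= base
    return replace(tfr, power=out)


def average_and_crop(
    tfr: TrialTFR,
    cfg: TFRConfig,
    subject: str | None = None,
    condition: str | None = None,
) -> TFRTensor:
    """Average over trials and restrict to the configured analysis window.

    ``cfg.crop_undefined`` controls what happens if flagged (NaN) bins
    survive inside the crop: ``error`` refuses (the downstream tensor
    must be fully defined), ``trim`` drops time columns containing any
    undefined value, ``keep`` leaves the NaNs in place.
    """
    t0, t1 = np.asarray(cfg.crop_time_ms) / 1000.0
    f0, f1 = cfg.crop_freq
    tsel = (tfr.times >= t0 - 1e-12) & (tfr.times <= t1 + 1e-12)
    fsel = (tfr.freqs >= f0 - 1e-12) & (tfr.freqs <= f1 + 1e-12)
    if not np.any(tsel) or not np.any(fsel):
        raise ValueError("crop window excludes all time or frequency bins")
    mean = tfr.power.mean(axis=0)  # NaN propagates by design
    values = mean[:, fsel][:, :, tsel]
    freqs = tfr.freqs[fsel]
    times = tfr.times[tsel]

    bad = np.isnan(values).any(axis=(0, 1))
    if bad.any():
        if cfg.crop_undefined == "error":
            raise ValueError(
                f"{int(bad.sum())} cropped time bins contain undefined values; "
                "narrow crop_time_ms/crop_freq or choose crop_undefined="
                "'trim'/'keep'"
            )
        if cfg.crop_undefined == "trim":
            values = values[:, :, ~bad]
            times = times[~bad]
            if values.shape[2] == 0:
                raise ValueError("trimming undefined bins left no time bins")

    provenance = {
        "subject": subject,
        "condition": condition,
        "n_trials": tfr.power.shape[0],
        "shape": tuple(values.shape),
        "n_undefined": int(np.isnan(values).sum()),
    }
    return TFRTensor(
        values=values,
        ch_names=list(tfr.ch_names),
        freqs=freqs,
        times=times,
        provenance=provenance,
    )


def induced_tfr(
    epochs: EpochSet,
    cfg: TFRConfig | None = None,
    subject: str | None = None,
    condition: str | None = None,
) -> TFRTensor:
    """Full induced-power chain in the fixed order:
    subtract_evoked → hanning_tfr → znorm_trials → baseline_correct →
    average_and_crop."""
    cfg = cfg or TFRConfig()
    trial_tfr = hanning_tfr(subtract_evoked(epochs), cfg)
    trial_tfr = baseline_correct(znorm_trials(trial_tfr), cfg)
    return average_and_crop(trial_tfr, cfg, subject=subject, condition=condition)
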