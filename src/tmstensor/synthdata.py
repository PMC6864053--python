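"""Ground-truth factor sets and synthetic TMS-EEG-like data.

The study's recordings are not public, so every downstream stage is
exercised on factor-structured surrogates with known components:

* a frontal beta component (15–30 Hz) with the classic event-related
  peak → suppression → rebound temporal profile,
* an occipital alpha component (6–13 Hz) that is absent early and rises
  from ~140 ms to a plateau,
* a theta component (4–6 Hz) centred on the stimulated electrode (C3),
  peaking ~90–240 ms and suppressed later.

Three generators are provided: ``make_ground_truth`` (the factor set),
``synth_tensor5d`` (the 5-way analysis tensor, CP structure + noise,
with a multiplicative post-drug effect on condition loadings), and
``synth_epochs`` (raw epochs whose induced-power transform approximates
a given factor structure — band-limited oscillations with random
per-trial phase under the component envelopes).

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cpd import Tensor5D, khatri_rao
from .montage import default_montage, subset_montage
from .tfr import EpochSet

__all__ = ["SimConfig", "GroundTruth", "make_ground_truth", "synth_tensor5d", "synth_epochs"]

# (name, spectral band Hz, spatial centre channel) of the three templates
_TEMPLATES = (
    ("beta", (15.0, 30.0), "Fz"),
    ("alpha", (6.0, 13.0), "Oz"),
    ("theta", (4.0, 6.0), "C3"),
)


@dataclass
class SimConfig:
    """Study-shaped simulation defaults.

    Mode sizes mirror the analysed dataset: 61 channels, 31 frequency
    bins (4–34 Hz), 98 time bins (40–1010 ms in 10 ms steps), 13
    subjects, 4 conditions, rank 3. ``noise_level`` is the SD of the
    additive Gaussian noise as a fraction of the noiseless tensor's RMS;
    ``subject_spread`` the SD of the |Normal(1, s²)| subject loadings.
    """

    n_channels: int = 61
    n_freqs: int = 31
    freq_min: float = 4.0
    freq_max: float = 34.0
    n_times: int = 98
    time_min_ms: float = 40.0
    time_step_ms: float = 10.0
    n_subjects: int = 13
    n_conditions: int = 4
    rank: int = 3
    seed: int = 0
    condition_labels: tuple[str, ...] = ("pre-LEV", "post-LEV", "pre-LTG", "post-LTG")
    effect: tuple[float, ...] = (0.9, 0.7, 0.9)
    noise_level: float = 0.05
    subject_spread: float = 0.2
    component_scales: tuple[float, ...] = (1.2, 1.0, 0.8)
    condition_jitter: float = 0.0  # |N(1, j²)| per-condition modulation of E
    spatial_sigma: float = 0.45  # Gaussian kernel width on the montage, head radii
    noise_tail: str = "gaussian"  # or "laplace" for a heavier-tailed check

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_freqs", "n_times", "n_subjects", "n_conditions", "rank"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        sizes = (self.n_channels, self.n_freqs, self.n_times, self.n_subjects, self.n_conditions)
        if self.rank > min(sizes):
            raise ValueError(f"rank {self.rank} exceeds smallest mode size {min(sizes)}")
        if len(self.condition_labels) != self.n_conditions:
            raise ValueError("condition_labels length must equal n_conditions")
        if self.noise_level < 0 or self.subject_spread < 0:
            raise ValueError("noise_level and subject_spread must be >= 0")
        if self.noise_tail not in ("gaussian", "laplace"):
            raise ValueError("noise_tail must be 'gaussian' or 'laplace'")

    @property
    def freqs(self) -> np.ndarray:
        return np.linspace(self.freq_min, self.freq_max, self.n_freqs)

    @property
    def times_ms(self) -> np.ndarray:
        return self.time_min_ms + self.time_step_ms * np.arange(self.n_times)


@dataclass
class GroundTruth:
    """Generating factors of a synthetic 5-way dataset.

    The first four factor matrices have unit-norm non-negative columns;
    ``condition_loadings`` carries each component's scale and already
    includes the post-drug multiplicative effect (``effect`` keeps the
    per-component factors for reference). ``noise_sigma`` is the additive
    noise SD as a fraction of the noiseless tensor RMS; the absolute SD
    is fixed at synthesis time.
    """

    space_factors: np.ndarray
    freq_factors: np.ndarray
    time_factors: np.ndarray
    subject_loadings: np.ndarray
    condition_loadings: np.ndarray
    condition_labels: tuple[str, ...]
    effect: np.ndarray
    noise_sigma: float
    channels: list[str] = field(default_factory=list)
    freqs: np.ndarray | None = None
    times_ms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return self.space_factors.shape[1]

    def factor_list(self) -> list[np.ndarray]:
        return [
            self.space_factors,
            self.freq_factors,
            self.time_factors,
            self.subject_loadings,
            self.condition_loadings,
        ]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate all-zero profile")
    return v / n


def _band_bump(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth non-negative bump supported on [lo, hi]."""
    centre = 0.5 * (lo + hi)
    width = 0.5 * (hi - lo)
    x = (freqs - centre) / max(width, 1e-9)
    bump = np.where(np.abs(x) <= 1.0, np.cos(0.5 * np.pi * x) ** 2, 0.0)
    if not bump.any():  # band falls between grid points: use nearest bin
        bump = np.exp(-0.5 * ((freqs - centre) / max(width, freqs.ptp() / len(freqs))) ** 2)
    return bump


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _temporal_templates(t_ms: np.ndarray) -> dict[str, np.ndarray]:
    """The three temporal shapes on an arbitrary post-stimulus grid (ms)."""
    peak = np.exp(-0.5 * ((t_ms - 110.0) / 45.0) ** 2)
    rebound = _sigmoid((t_ms - 470.0) / 60.0)
    beta = peak + 0.65 * rebound  # peak 40–200, suppression 200–400, rebound after
    alpha = _sigmoid((t_ms - 240.0) / 55.0)  # absent to ~140 ms, plateau from ~340
    theta = np.exp(-0.5 * ((t_ms - 165.0) / 80.0) ** 2) * (
        1.0 - _sigmoid((t_ms - 420.0) / 50.0)
    )  # early peak (~90–240 ms) then suppression
    return {"beta": beta, "alpha": alpha, "theta": theta}


def _smooth_random_profile(n: int, rng: np.random.Generator) -> np.ndarray:
    raw = rng.standard_normal(n + 8)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")[4 : n + 4]
    return np.abs(smooth) + 0.05


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Build the generating factor set for ``config``.

    The first three components follow the beta/alpha/theta templates;
    ranks above 3 add random smooth non-negative profiles, flagged in
    ``meta['extra_components']``.
    """
    rng = np.random.default_rng([max(config.seed, 0), 101])
    montage = subset_montage(default_montage(), config.n_channels)
    coords = montage[["x", "y"]].to_numpy()
    freqs = config.freqs
    t_ms = config.times_ms
    temporal = _temporal_templates(t_ms)

    space_cols, freq_cols, time_cols = [], [], []
    extra = []
    for r in range(config.rank):
        if r < len(_TEMPLATES):
            name, (lo, hi), centre_label = _TEMPLATES[r]
            if centre_label in montage["label"].values:
                centre = coords[montage["label"].tolist().index(centre_label)]
            else:  # thinned montage: nearest retained site
                full = default_montage()
                target = full.loc[full["label"] == centre_label, ["x", "y"]].to_numpy()[0]
                centre = coords[np.argmin(((coords - target) ** 2).sum(axis=1))]
            d2 = ((coords - centre) ** 2).sum(axis=1)
            space_cols.append(np.exp(-0.5 * d2 / config.spatial_sigma**2))
            freq_cols.append(_band_bump(freqs, lo, hi))
            time_cols.append(temporal[name])
        else:
            extra.append(r)
            space_cols.append(_smooth_random_profile(config.n_channels, rng))
            freq_cols.append(_smooth_random_profile(config.n_freqs, rng))
            time_cols.append(_smooth_random_profile(config.n_times, rng))

    A = np.column_stack([_unit(c) for c in space_cols])
    B = np.column_stack([_unit(c) for c in freq_cols])
    C = np.column_stack([_unit(c) for c in time_cols])

    D = np.abs(rng.normal(1.0, config.subject_spread, (config.n_subjects, config.rank)))
    D = D / np.linalg.norm(D, axis=0)

    scales = np.asarray(config.component_scales, float)
    if len(scales) < config.rank:
        scales = np.concatenate([scales, np.ones(config.rank - len(scales))])
    scales = scales[: config.rank]
    effect = np.asarray(config.effect, float)
    if len(effect) < config.rank:
        effect = np.concatenate([effect, np.ones(config.rank - len(effect))])
    effect = effect[: config.rank]

    E = np.tile(scales, (config.n_conditions, 1))
    if config.condition_jitter > 0:
        # distinct rows keep the condition factor matrix full column rank
        E = E * np.abs(
            rng.normal(1.0, config.condition_jitter, E.shape)
        )
    post = np.array([lbl.startswith("post") for lbl in config.condition_labels])
    E[post] = E[post] * effect

    return GroundTruth(
        space_factors=A,
        freq_factors=B,
        time_factors=C,
        subject_loadings=D,
        condition_loadings=E,
        condition_labels=tuple(config.condition_labels),
        effect=effect,
        noise_sigma=config.noise_level,
        channels=montage["label"].tolist(),
        freqs=freqs,
        times_ms=t_ms,
        meta={"extra_components": extra, "seed": config.seed},
    )


def synth_tensor5d(gt: GroundTruth, config: SimConfig) -> Tensor5D:
    """Factor-structured 5-way tensor with additive noise.

    W[i,j,k,s,c] = Σ_r A[i,r]·B[j,r]·C[k,r]·D[s,r]·E[c,r] + ε, with ε
    i.i.d. of SD ``noise_level × RMS(signal)`` (Gaussian by default).
    """
    factors = gt.factor_list()
    sizes = (config.n_channels, config.n_freqs, config.n_times, config.n_subjects, config.n_conditions)
    for mode, (f, n) in enumerate(zip(factors, sizes)):
        if f.shape[0] != n:
            raise ValueError(
                f"mode {mode}: ground-truth factor has {f.shape[0]} rows but "
                f"config expects {n}"
            )
    signal = (khatri_rao(factors) @ np.ones(gt.rank)).reshape(sizes)
    rms = float(np.sqrt(np.mean(signal**2)))
    sigma = gt.noise_sigma * rms
    rng = np.random.default_rng([max(config.seed, 0), 202])
    if sigma > 0:
        if config.noise_tail == "laplace":
            noise = rng.laplace(0.0, sigma / np.sqrt(2.0), sizes)
        else:
            noise = rng.normal(0.0, sigma, sizes)
        values = signal + noise
    else:
        values = signal
    return Tensor5D(
        values=values,
        channels=list(gt.channels),
        freqs=np.asarray(gt.freqs),
        times=np.asarray(gt.times_ms) / 1000.0,
        subjects=[f"S{i + 1:02d}" for i in range(config.n_subjects)],
        condition_labels=list(gt.condition_labels),
        meta={"noise_sigma_abs": sigma, "signal_rms": rms, "seed": config.seed},
    )


def synth_epochs(
    gt: GroundTruth,
    n_trials: int,
    seed: int,
    sampling_rate: float = 1000.0,
    t_start: float = -1.0,
    t_stop: float = 1.0,
    amplitude: float = 10.0,
    noise_level: float = 0.3,
) -> EpochSet:
    """Raw epochs whose induced-power transform approximates ``gt``.

    Each trial is, per channel, a sum over components of a band-limited
    oscillation: carrier at the component's spectral peak, envelope the
    component's temporal profile (zero before its window), amplitude set
    by the spatial profile, and a uniformly random phase per trial and
    component — so the power is induced, not evoked, and the trial
    average tends to zero. Broadband Gaussian noise is added with SD
    ``noise_level × amplitude``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng([max(seed, 0), 303])
    n_samples = int(round((t_stop - t_start) * sampling_rate)) + 1
    times = t_start + np.arange(n_samples) / sampling_rate
    t_ms = times * 1000.0

    carriers = np.asarray(gt.freqs)[np.argmax(gt.freq_factors, axis=0)]
    envelopes = np.stack(
        [
            np.interp(t_ms, gt.times_ms, gt.time_factors[:, r], left=0.0, right=0.0)
            for r in range(gt.rank)
        ]
    )  # (R, samples)
    # component amplitude: condition scale of the first condition row
    amps = amplitude * gt.condition_loadings[0]

    n_ch = gt.space_factors.shape[0]
    data = np.empty((n_trials, n_ch, n_samples))
    for trial in range(n_trials):
        phases = rng.uniform(0.0, 2.0 * np.pi, gt.rank)
        waves = np.cos(2.0 * np.pi * carriers[:, None] * times[None, :] + phases[:, None])
        comp = amps[:, None] * envelopes * waves  # (R, samples)
        data[trial] = gt.space_factors @ comp
    data += rng.normal(0.0, noise_level * amplitude, data.shape)

    return EpochSet(
        data=data,
        sampling_rate=sampling_rate,
        times=times,
        ch_names=list(gt.channels),
    )
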