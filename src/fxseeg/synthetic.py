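"""Synthetic EEG with known ground truth.

Two tiers of simulation back the test pyramid:

* **Feature level** — participants are drawn from class-conditional
  distributions whose mean and SD are moment-matched to published group
  statistics (see :mod:`fxseeg.presets`).  Features are drawn independently
  per participant, mirroring the independence assumption of the downstream
  naive Bayes classifier.
* **Signal level** — multichannel resting EEG (1/f background + band-limited
  oscillators + white noise, cut into 2 s epochs) and epoched auditory chirp
  trials (onset/offset transients, a frequency-sweeping response with
  controllable per-trial phase jitter, a desynchronizing alpha background,
  and noise).  Every extracted feature moves monotonically with its
  controlling generator parameter, which is what the round-trip tests check.

Bounded variables (relative power, ITPC in [0, 1]; absolute amplitude >= 0;
PAF in [6, 14] Hz) are sampled from moment-matched bounded families — a gamma
law anchored at the near bound, or a moment-matched truncated normal when
both bounds bind — so that sample means and SDs reproduce the target
statistics without truncation bias.  When both bounds are at least 4 SD away
a plain Gaussian is used (residual clipping is negligible there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .containers import GROUP_CON, GROUP_FXS, META_COLUMNS, EpochedRecording
from .montages import FRONTOCENTRAL_CLUSTER, HYDROCEL128, hydrocel128_labels
from .presets import (
    GroupStats,
    POP_CON_F,
    POP_CON_M,
    POP_FXS_F,
    POP_FXS_M,
    POP_FXS_NM,
)
from .utils import rng_from

_GAUSSIAN_SAFE_SD = 4.0  # bounds farther than this many SDs: plain Gaussian


# ---------------------------------------------------------------------------
# feature-level simulation
# ---------------------------------------------------------------------------

def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Find (mu, sigma) such that a normal truncated to [lo, hi] has the
    requested mean and SD."""

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m = sps.truncnorm.mean(a, b, loc=mu, scale=sigma)
        s = sps.truncnorm.std(a, b, loc=mu, scale=sigma)
        return [m - mean, s - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - only hit for infeasible targets
        raise ValueError(
            f"cannot moment-match a truncated normal to mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    return sol.x[0], math.exp(sol.x[1])


def sample_matched(rng, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Draw ``size`` values with the given mean/SD respecting [lo, hi].

    Distribution family is chosen by how close the target sits to its bounds;
    see the module docstring.  ``sd == 0`` returns the (bound-respecting)
    constant.
    """
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    d_lo = (mean - lo) / sd if np.isfinite(lo) else np.inf
    d_hi = (hi - mean) / sd if np.isfinite(hi) else np.inf
    if d_lo <= 0 or d_hi <= 0:
        raise ValueError(f"target mean {mean} outside bounds [{lo}, {hi}]")
    if d_lo >= _GAUSSIAN_SAFE_SD and d_hi >= _GAUSSIAN_SAFE_SD:
        return np.clip(rng.normal(mean, sd, size), lo, hi)
    if d_hi >= _GAUSSIAN_SAFE_SD:
        # near lower bound only: gamma supports any coefficient of variation
        shape = ((mean - lo) / sd) ** 2
        scale = sd**2 / (mean - lo)
        return np.clip(lo + rng.gamma(shape, scale, size), lo, hi)
    if d_lo >= _GAUSSIAN_SAFE_SD:
        shape = ((hi - mean) / sd) ** 2
        scale = sd**2 / (hi - mean)
        return np.clip(hi - rng.gamma(shape, scale, size), lo, hi)
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def default_composition(task: str) -> list[dict]:
    """Cohort composition mirroring the study samples.

    Resting: 70 FXS (26 non-mosaic males, 12 mosaic males, 32 females) vs
    71 CON (41 males, 30 females).  Chirp: 57 FXS (28 non-mosaic males,
    9 mosaic males, 20 females) vs 57 CON (34 males, 23 females).
    """
    if task == "rest":
        return [
            dict(group=GROUP_FXS, sex="M", mosaic=False, n=26, population=POP_FXS_NM),
            dict(group=GROUP_FXS, sex="M", mosaic=True, n=12, population=POP_FXS_M),
            dict(group=GROUP_FXS, sex="F", mosaic=False, n=32, population=POP_FXS_F),
            dict(group=GROUP_CON, sex="M", mosaic=False, n=41, population=POP_CON_M),
            dict(group=GROUP_CON, sex="F", mosaic=False, n=30, population=POP_CON_F),
        ]
    if task == "chirp":
        return [
            dict(group=GROUP_FXS, sex="M", mosaic=False, n=28, population=POP_FXS_NM),
            dict(group=GROUP_FXS, sex="M", mosaic=True, n=9, population=POP_FXS_M),
            dict(group=GROUP_FXS, sex="F", mosaic=False, n=20, population=POP_FXS_F),
            dict(group=GROUP_CON, sex="M", mosaic=False, n=34, population=POP_CON_M),
            dict(group=GROUP_CON, sex="F", mosaic=False, n=23, population=POP_CON_F),
        ]
    raise ValueError(f"unknown task {task!r}")


def simulate_feature_table(
    stats: GroupStats,
    n_per_group: dict[str, int] | None = None,
    composition: list[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a labeled feature table from class-conditional statistics.

    Exactly one of ``n_per_group`` (draw each group from its own population
    statistics, no sex/mosaic structure) or ``composition`` (a list of strata
    dicts with keys group/sex/mosaic/n and optional population) must be given.
    Deterministic under ``seed``.
    """
    if (n_per_group is None) == (composition is None):
        raise ValueError("provide exactly one of n_per_group or composition")
    if n_per_group is not None:
        composition = [
            dict(group=g, sex=None, mosaic=False, n=n, population=g)
            for g, n in n_per_group.items()
        ]
    for stratum in composition:
        if stratum["n"] < 0:
            raise ValueError(f"negative stratum size: {stratum}")

    rng = rng_from(seed, "feature-table")
    variables = stats.variables
    rows: list[dict] = []
    draws: list[np.ndarray] = []
    for stratum in composition:
        pop = stratum.get("population", stratum["group"])
        n = int(stratum["n"])
        if n == 0:
            continue
        block = np.empty((n, len(variables)))
        for j, var in enumerate(variables):
            mean, sd = stats.get(var, pop)  # raises KeyError naming the pair
            lo, hi = stats.bound(var)
            block[:, j] = sample_matched(rng, mean, sd, lo, hi, n)
        draws.append(block)
        for _ in range(n):
            rows.append(
                dict(group=stratum["group"], sex=stratum.get("sex"), mosaic=bool(stratum.get("mosaic", False)))
            )
    meta = pd.DataFrame(rows)
    meta.insert(0, "participant_id", [f"S{i+1:04d}" for i in range(len(meta))])
    feats = pd.DataFrame(np.vstack(draws) if draws else np.empty((0, len(variables))), columns=variables)
    return pd.concat([meta, feats], axis=1)[META_COLUMNS + variables]


# ---------------------------------------------------------------------------
# signal-level simulation: resting EEG
# ---------------------------------------------------------------------------

@dataclass
class RestingSimParams:
    """Parameters of the resting-state EEG generator.

    The signal per channel is 1/f-shaped background + band-limited sinusoidal
    oscillators (one of which is the alpha oscillator at ``alpha_peak`` Hz)
    + white sensor noise, segmented into non-overlapping 2 s epochs.
    """

    n_channels: int = 129
    sfreq: float = 1000.0
    duration: float = 300.0  # 5 min of resting data
    one_over_f_exponent: float = 1.5  # power-spectrum slope chi: P(f) ~ f^-chi
    pink_amplitude: float = 5.0  # µV RMS of the 1/f background
    #: oscillator name -> (center frequency Hz, amplitude µV); the alpha
    #: oscillator frequency is taken from ``alpha_peak`` instead.
    oscillators: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"theta": (6.0, 1.0), "beta": (20.0, 0.5), "gamma": (40.0, 0.3)}
    )
    alpha_peak: float = 8.5
    alpha_amplitude: float = 3.0
    noise_amplitude: float = 1.0  # white noise µV RMS
    montage: str = HYDROCEL128
    ch_names: list[str] | None = None
    seed: int = 0

    def validate(self):
        if not (6.0 <= self.alpha_peak <= 14.0):
            raise ValueError(f"alpha peak {self.alpha_peak} Hz outside [6, 14]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        top = max([f for f, _ in self.oscillators.values()] + [self.alpha_peak])
        if self.sfreq < 2 * top:
            raise ValueError(f"sampling rate {self.sfreq} below Nyquist for {top} Hz oscillator")
        amps = [a for _, a in self.oscillators.values()] + [
            self.alpha_amplitude, self.noise_amplitude, self.pink_amplitude]
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")


def _one_over_f_noise(rng, n: int, sfreq: float, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f^-exponent."""
    freqs = np.fft.rfftfreq(n, 1 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_resting_eeg(params: RestingSimParams) -> EpochedRecording:
    """Generate resting EEG and segment it into non-overlapping 2 s epochs."""
    params.validate()
    rng = rng_from(params.seed, "resting-eeg")
    n_total = int(round(params.duration * params.sfreq))
    epoch_len = int(round(2.0 * params.sfreq))
    n_epochs = n_total // epoch_len
    if n_epochs == 0:
        raise ValueError("duration shorter than one 2 s epoch")
    t = np.arange(n_epochs * epoch_len) / params.sfreq

    if params.ch_names is not None:
        ch_names = list(params.ch_names)
    elif params.montage == HYDROCEL128 and params.n_channels == 129:
        ch_names = hydrocel128_labels()
    else:
        ch_names = [f"E{i+1}" for i in range(params.n_channels)]

    oscs = [(f, a) for f, a in params.oscillators.values()]
    oscs.append((params.alpha_peak, params.alpha_amplitude))

    data = np.empty((len(ch_names), len(t)))
    for ci in range(len(ch_names)):
        x = _one_over_f_noise(rng, len(t), params.sfreq, params.one_over_f_exponent, params.pink_amplitude)
        for f, a in oscs:
            if a > 0:
                x += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if params.noise_amplitude > 0:
            x += rng.normal(0, params.noise_amplitude, len(t))
        data[ci] = x

    epoched = data.reshape(len(ch_names), n_epochs, epoch_len)
    return EpochedRecording(epoched, params.sfreq, ch_names, params.montage, task="rest")


# ---------------------------------------------------------------------------
# signal-level simulation: auditory chirp trials
# ---------------------------------------------------------------------------

@dataclass
class ChirpSimParams:
    """Parameters of the auditory chirp trial generator.

    Each trial carries (i) phase-locked damped onset/offset transients in the
    theta/alpha range, (ii) a chirp-following oscillation whose instantaneous
    frequency sweeps ``sweep_rate * t`` Hz (0→100 Hz over the 2 s stimulus at
    the default 50 Hz/s) with a per-trial phase offset drawn from a wrapped
    normal of SD ``phase_jitter_sd`` (or uniform on [-pi, pi) when
    ``uniform_jitter``), (iii) a non-phase-locked background alpha oscillator
    attenuated by ``alpha_desync`` after stimulus onset, and (iv) white noise.
    The inter-trial gap of the original paradigm (1.5–2.0 s jittered) is
    irrelevant to epoched analysis and kept only as metadata.
    """

    n_trials: int = 200
    n_channels: int = 23
    sfreq: float = 1000.0
    pre_stimulus: float = 0.5
    stimulus_duration: float = 2.0
    post_stimulus: float = 0.5
    sweep_rate: float = 50.0  # Hz per second
    phase_jitter_sd: float = 1.0  # radians (wrapped normal)
    uniform_jitter: bool = False
    response_amplitude: float = 1.0  # µV of the chirp-following oscillation
    onset_amplitude: float = 2.0
    offset_amplitude: float = 2.0
    onset_frequency: float = 6.0  # Hz of the damped transient
    transient_decay: float = 0.15  # s, exponential decay constant
    alpha_amplitude: float = 1.5
    alpha_frequency: float = 10.0
    alpha_desync: float = 0.7  # post-onset multiplier (<1 -> negative evoked alpha)
    noise_amplitude: float = 1.0
    inter_trial_gap: tuple[float, float] = (1.5, 2.0)
    ch_names: list[str] | None = None
    seed: int = 0

    def validate(self):
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase jitter SD must be non-negative")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.pre_stimulus < 0 or self.post_stimulus < 0:
            raise ValueError("trial window shorter than the stimulus (negative pre/post padding)")
        if self.sfreq < 2 * self.sweep_rate * self.stimulus_duration:
            raise ValueError("sampling rate below Nyquist for the chirp sweep")


def simulate_chirp_trials(params: ChirpSimParams) -> EpochedRecording:
    """Generate epoched chirp trials; time 0 is stimulus onset."""
    params.validate()
    rng = rng_from(params.seed, "chirp-trials")
    sf = params.sfreq
    n_pre = int(round(params.pre_stimulus * sf))
    n_stim = int(round(params.stimulus_duration * sf))
    n_post = int(round(params.post_stimulus * sf))
    n_samp = n_pre + n_stim + n_post
    t = (np.arange(n_samp) - n_pre) / sf  # seconds relative to onset

    if params.ch_names is not None:
        ch_names = list(params.ch_names)
    elif params.n_channels == 23:
        ch_names = list(FRONTOCENTRAL_CLUSTER)
    else:
        ch_names = [f"E{i+1}" for i in range(params.n_channels)]

    stim = (t >= 0) & (t < params.stimulus_duration)
    post_onset = t >= 0
    offset_t = t - params.stimulus_duration

    onset_tr = np.where(
        post_onset,
        np.exp(-np.maximum(t, 0) / params.transient_decay)
        * np.sin(2 * np.pi * params.onset_frequency * np.maximum(t, 0)),
        0.0,
    )
    offset_tr = np.where(
        offset_t >= 0,
        np.exp(-np.maximum(offset_t, 0) / params.transient_decay)
        * np.sin(2 * np.pi * params.onset_frequency * np.maximum(offset_t, 0)),
        0.0,
    )
    # instantaneous frequency f(t) = sweep_rate * t  ->  phase = pi*sweep*t^2
    chirp_phase = np.pi * params.sweep_rate * np.maximum(t, 0) ** 2
    alpha_gain = np.where(post_onset, params.alpha_desync, 1.0)

    if params.uniform_jitter:
        phis = rng.uniform(-np.pi, np.pi, params.n_trials)
    else:
        phis = np.mod(rng.normal(0, params.phase_jitter_sd, params.n_trials) + np.pi, 2 * np.pi) - np.pi

    data = np.empty((len(ch_names), params.n_trials, n_samp))
    for k in range(params.n_trials):
        sig = params.onset_amplitude * onset_tr + params.offset_amplitude * offset_tr
        sig = sig + params.response_amplitude * np.cos(chirp_phase + phis[k]) * stim
        psi = rng.uniform(0, 2 * np.pi)
        sig = sig + params.alpha_amplitude * alpha_gain * np.cos(
            2 * np.pi * params.alpha_frequency * t + psi
        )
        if params.noise_amplitude > 0:
            data[:, k, :] = sig + rng.normal(0, params.noise_amplitude, (len(ch_names), n_samp))
        else:
            data[:, k, :] = sig

    return EpochedRecording(
        data,
        sf,
        ch_names,
        montage=HYDROCEL128 if ch_names[0].startswith("E") else "unknown",
        task="chirp",
        tmin=-params.pre_stimulus,
        meta={"stimulus_duration": params.stimulus_duration, "inter_trial_gap": params.inter_trial_gap},
    )


def jitter_for_itpc(target_itpc: float) -> float:
    """Wrapped-normal jitter SD whose expected resultant length is ``target``.

    For phases ~ wrapped normal(0, sigma), E|mean(e^{i phi})| -> exp(-sigma^2/2)
    as the trial count grows.
    """
    if not 0 < target_itpc <= 1:
        raise ValueError("target ITPC must be in (0, 1]")
    return math.sqrt(-2.0 * math.log(target_itpc))
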