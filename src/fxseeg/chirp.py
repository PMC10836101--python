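"""Auditory chirp time-frequency features.

Seven variables per recording, measured on the trial-average of a small
fronto-central sensor cluster after a Morlet wavelet transform (1 Hz steps,
cycle count increasing linearly from 1 at the lowest analyzed frequency to 30
at the highest):

* inter-trial phase coherence (ITPC) — the resultant length of unit phase
  vectors across trials — to the stimulus onset (theta/alpha), along the
  chirp's frequency sweep centered on 40 Hz (low gamma) and 80 Hz (high
  gamma), and to the stimulus offset (theta/alpha);
* single-trial power (STP) — trial-averaged squared wavelet magnitude,
  10·log10 µV² — for theta and gamma over the whole trial, and
  baseline-corrected ("evoked") alpha power, negative when alpha
  desynchronizes after stimulus onset.

ITPC is blind to amplitude; STP is blind to phase — the two measures
dissociate phase-locked synchrony from oscillatory power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .containers import EpochedRecording
from .montages import FRONTOCENTRAL_CLUSTER

logger = logging.getLogger(__name__)

DEFAULT_FMIN = 2.0
DEFAULT_FMAX = 100.0
CYCLES_RANGE = (1.0, 30.0)


def cluster_average(rec: EpochedRecording, cluster: list[str] | None = None) -> np.ndarray:
    """Per-trial mean over the cluster's channels -> (n_trials, n_samples)."""
    if cluster is None:
        cluster = [c for c in FRONTOCENTRAL_CLUSTER if c in rec.ch_names] or rec.ch_names
    cluster = list(cluster)
    if not cluster:
        raise ValueError("cluster is empty")
    sub = rec.pick(cluster)
    return sub.data.mean(axis=0)


def n_cycles_for(freqs: np.ndarray, fmin: float | None = None, fmax: float | None = None) -> np.ndarray:
    """Cycle counts increasing linearly from 1 to 30 across the analyzed grid."""
    freqs = np.asarray(freqs, dtype=float)
    fmin = freqs.min() if fmin is None else fmin
    fmax = freqs.max() if fmax is None else fmax
    lo, hi = CYCLES_RANGE
    if fmax == fmin:
        return np.full(freqs.shape, lo)
    return lo + (hi - lo) * (freqs - fmin) / (fmax - fmin)


@dataclass
class TimeFrequencyCube:
    """Complex Morlet coefficients, (n_trials, n_freqs, n_times).

    ``valid`` marks time-frequency points whose wavelet support stays inside
    the trial; edge points are excluded from ITPC/STP aggregation.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: np.ndarray
    valid: np.ndarray  # bool (n_freqs, n_times)
    sfreq: float

    def __post_init__(self):
        if self.coeffs.ndim != 3:
            raise ValueError("coefficients must be (trials, freqs, times)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite wavelet coefficients")
        d = np.diff(self.n_cycles)
        if len(d) and np.any(d <= 0):
            raise ValueError("cycle counts must increase strictly with frequency")

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]


def _morlet_kernel(f: float, n_cyc: float, sfreq: float, n_sigmas: float = 4.0) -> np.ndarray:
    """Complex Morlet wavelet normalized so a grid-registered amplitude-A
    sinusoid returns coefficients of magnitude ~A."""
    sigma_t = n_cyc / (2.0 * np.pi * f)
    half = int(np.ceil(n_sigmas * sigma_t * sfreq))
    tau = np.arange(-half, half + 1) / sfreq
    env = np.exp(-(tau**2) / (2.0 * sigma_t**2))
    kernel = env * np.exp(2j * np.pi * f * tau)
    return kernel * (2.0 / env.sum())


def morlet_transform(
    signal: np.ndarray,
    sfreq: float,
    tmin: float = 0.0,
    freqs: np.ndarray | None = None,
    decim: int = 1,
) -> TimeFrequencyCube:
    """Morlet wavelet transform of trial signals (n_trials, n_times).

    ``decim`` keeps every ``decim``-th time sample of the output (the
    convolution itself runs at full rate).  Raises if a trial is shorter than
    the longest wavelet, naming the offending frequency.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_trials, n_times = signal.shape
    if freqs is None:
        freqs = np.arange(DEFAULT_FMIN, DEFAULT_FMAX + 1.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if sfreq < 2 * freqs.max():
        raise ValueError(f"sampling rate {sfreq} Hz below Nyquist for {freqs.max()} Hz")
    cycles = n_cycles_for(freqs)

    times_full = tmin + np.arange(n_times) / sfreq
    keep = np.arange(0, n_times, decim)
    coeffs = np.empty((n_trials, len(freqs), len(keep)), dtype=complex)
    valid = np.zeros((len(freqs), len(keep)), dtype=bool)
    for j, (f, nc) in enumerate(zip(freqs, cycles)):
        kernel = _morlet_kernel(f, nc, sfreq)
        if len(kernel) > n_times:
            raise ValueError(
                f"trial of {n_times} samples shorter than the {f:g} Hz wavelet ({len(kernel)} samples)"
            )
        conv = fftconvolve(signal, kernel[None, :], mode="same", axes=1)
        coeffs[:, j, :] = conv[:, keep]
        half = (len(kernel) - 1) // 2
        ok = (np.arange(n_times) >= half) & (np.arange(n_times) < n_times - half)
        valid[j] = ok[keep]
    return TimeFrequencyCube(coeffs, freqs, times_full[keep], cycles, valid, sfreq / decim)


def itpc(cube: TimeFrequencyCube) -> np.ndarray:
    """Inter-trial phase coherence map (n_freqs, n_times) in [0, 1].

    Resultant length of unit phase vectors across trials; invalid edge points
    are NaN.  Zero-magnitude coefficients cannot contribute a phase and are
    excluded (count logged).
    """
    if cube.n_trials < 2:
        raise ValueError("ITPC needs at least 2 trials")
    mag = np.abs(cube.coeffs)
    zero = mag == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.info("excluding %d zero-magnitude coefficients from ITPC", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(zero, 0.0, cube.coeffs / np.where(zero, 1.0, mag))
    counts = (~zero).sum(axis=0)
    resultant = np.abs(phasors.sum(axis=0))
    out = np.where(counts > 0, resultant / np.maximum(counts, 1), np.nan)
    out = np.where(cube.valid, out, np.nan)
    return out


def single_trial_power(cube: TimeFrequencyCube, baseline: tuple[float, float] | None = None) -> np.ndarray:
    """Trial-mean log power map, 10·log10(µV²); NaN at invalid edge points.

    With ``baseline=(t0, t1)`` (a pre-onset window, t1 <= 0) the mean log
    baseline power is subtracted per frequency, so post-onset
    desynchronization yields negative values.
    """
    power = (np.abs(cube.coeffs) ** 2).mean(axis=0)
    with np.errstate(divide="ignore"):
        logp = 10.0 * np.log10(power)
    logp = np.where(cube.valid, logp, np.nan)
    if baseline is not None:
        t0, t1 = baseline
        if t1 > 0:
            raise ValueError("baseline window overlaps the stimulus (must end at or before onset)")
        sel = (cube.times >= t0) & (cube.times <= t1)
        if not sel.any():
            raise ValueError("baseline window contains no time samples")
        base = np.nanmean(np.where(sel[None, :], logp, np.nan), axis=1)
        if np.isnan(base).any():
            raise ValueError("baseline window has no valid (edge-free) samples at some frequency")
        logp = logp - base[:, None]
    return logp


@dataclass(frozen=True)
class TFROI:
    """Time-frequency region of interest.

    ``kind="rect"`` selects the full rectangle [fmin, fmax] x [tmin, tmax];
    ``kind="diagonal"`` additionally requires |f - sweep_rate*t| <= half_bw,
    tracking the chirp's instantaneous frequency.  ``measure`` picks the map
    the ROI mean is taken over: "itpc", "stp", or "stp_evoked" (baseline-
    corrected STP; ``baseline`` then gives the pre-onset window).
    """

    name: str
    fmin: float
    fmax: float
    tmin: float
    tmax: float
    measure: str = "itpc"
    kind: str = "rect"
    half_bw: float = 10.0
    sweep_rate: float = 50.0
    baseline: tuple[float, float] | None = None

    def mask(self, freqs: np.ndarray, times: np.ndarray) -> np.ndarray:
        f = freqs[:, None]
        t = times[None, :]
        m = (f >= self.fmin) & (f <= self.fmax) & (t >= self.tmin) & (t <= self.tmax)
        if self.kind == "diagonal":
            m &= np.abs(f - self.sweep_rate * t) <= self.half_bw
        elif self.kind != "rect":
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        return m


def default_rois(
    stimulus_duration: float = 2.0,
    sweep_rate: float = 50.0,
    baseline: tuple[float, float] = (-0.5, 0.0),
) -> tuple[TFROI, ...]:
    """The seven a-priori ROIs (order matches the chirp report rows)."""
    T = stimulus_duration
    return (
        TFROI("Gamma Power", 30, 90, -np.inf, np.inf, measure="stp"),
        TFROI("Theta Power", 4, 8, -np.inf, np.inf, measure="stp"),
        TFROI("Alpha Power", 8, 13, 0.0, T, measure="stp_evoked", baseline=baseline),
        TFROI("Low Gamma ITPC", 30, 50, 30 / sweep_rate, 50 / sweep_rate,
              measure="itpc", kind="diagonal", sweep_rate=sweep_rate),
        TFROI("High Gamma ITPC", 70, 90, 70 / sweep_rate, 90 / sweep_rate,
              measure="itpc", kind="diagonal", sweep_rate=sweep_rate),
        TFROI("Stimulus Onset ITPC", 4, 13, 0.0, 0.5, measure="itpc"),
        TFROI("Stimulus Offset ITPC", 4, 13, T, T + 0.5, measure="itpc"),
    )


CHIRP_FEATURE_NAMES = [r.name for r in default_rois()]


def extract_chirp_variables(cube: TimeFrequencyCube, rois: tuple[TFROI, ...] | None = None) -> pd.Series:
    """Mean of the relevant map over each ROI's valid points (7 named values)."""
    if rois is None:
        rois = default_rois()
    itpc_map = None
    stp_map = None
    out: dict[str, float] = {}
    for roi in rois:
        if roi.measure == "itpc":
            if itpc_map is None:
                itpc_map = itpc(cube)
            src = itpc_map
        elif roi.measure == "stp":
            if stp_map is None:
                stp_map = single_trial_power(cube)
            src = stp_map
        elif roi.measure == "stp_evoked":
            src = single_trial_power(cube, baseline=roi.baseline)
        else:
            raise ValueError(f"unknown ROI measure {roi.measure!r}")
        m = roi.mask(cube.freqs, cube.times)
        vals = src[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {roi.name!r} contains no valid time-frequency points")
        out[roi.name] = float(vals.mean())
    if len(out) != len(rois):
        raise ValueError("duplicate ROI names")
    return pd.Series(out, name="chirp")


def chirp_feature_vector(
    rec: EpochedRecording,
    cluster: list[str] | None = None,
    rois: tuple[TFROI, ...] | None = None,
    decim: int = 10,
) -> pd.Series:
    """Cluster-average -> Morlet transform -> ROI means, for one recording."""
    sig = cluster_average(rec, cluster)
    if rois is None:
        rois = default_rois(stimulus_duration=float(rec.meta.get("stimulus_duration", 2.0)))
    cube = morlet_transform(sig, rec.sfreq, tmin=rec.tmin, decim=decim)
    return extract_chirp_variables(cube, rois)
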