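"""Resting-state spectral features.

45 variables per recording: absolute and relative amplitude in seven bands
(delta, theta, low/high alpha, beta, low/high gamma) over three scalp regions
(frontal, posterior, whole head), plus peak alpha frequency (PAF) per region.

Spectra are magnitude FFTs of Hann-windowed, non-overlapping 2 s epochs, which
fixes the frequency grid at 0.5 Hz.  Absolute band values are sums of bin
amplitudes reported on a picovolt scale; relative values divide by the total
over all analyzed bins.  A 55–65 Hz line-noise notch is excluded from the
analyzed set, so the seven bands partition the analyzed bins and relative
values sum to one per region.  PAF is the argmax of log spectral power within
6–14 Hz, ties broken toward the lower frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochedRecording
from .montages import REGION_LABELS, REGIONS, default_region_map

logger = logging.getLogger(__name__)

PV_PER_UV = 1e6  # picovolts per microvolt: absolute power scale factor
FREQ_STEP = 0.5  # Hz


class EdgePeakWarning(UserWarning):
    """Peak alpha frequency landed on the search-window edge (no local peak)."""


@dataclass(frozen=True)
class Band:
    name: str
    label: str
    low: float  # Hz, inclusive
    high: float  # Hz, exclusive


#: conventional band edges; 55–65 Hz is excluded as a line-noise notch
DEFAULT_BANDS = (
    Band("delta", "Delta", 1.0, 4.0),
    Band("theta", "Theta", 4.0, 8.0),
    Band("alpha1", "Alpha 1", 8.0, 10.0),
    Band("alpha2", "Alpha 2", 10.0, 13.0),
    Band("beta", "Beta", 13.0, 30.0),
    Band("gamma1", "Gamma 1", 30.0, 55.0),
    Band("gamma2", "Gamma 2", 65.0, 90.0),
)


def validate_bands(bands) -> tuple[Band, ...]:
    bands = tuple(bands)
    for b in bands:
        if b.low >= b.high:
            raise ValueError(f"band {b.name} has non-positive width")
    for a, b in zip(bands, bands[1:]):
        if b.low < a.high:
            raise ValueError(f"bands {a.name} and {b.name} overlap or are out of order")
    return bands


@dataclass
class AmplitudeSpectrum:
    """Region-averaged amplitude spectrum on the 0.5 Hz grid (µV per bin)."""

    freqs: np.ndarray
    amplitude: dict[str, np.ndarray]  # region -> amplitude per frequency bin
    n_epochs: int = 0

    def __post_init__(self):
        steps = np.diff(self.freqs)
        if len(steps) and not np.allclose(steps, FREQ_STEP):
            raise ValueError("frequency grid must be uniform with 0.5 Hz steps")
        for region, amp in self.amplitude.items():
            if len(amp) != len(self.freqs):
                raise ValueError(f"amplitude length mismatch for region {region!r}")
            if np.any(np.asarray(amp) < 0):
                raise ValueError(f"negative amplitudes in region {region!r}")

    @property
    def regions(self) -> list[str]:
        return list(self.amplitude)


def amplitude_spectrum(rec: EpochedRecording, regions: dict[str, list[str]] | None = None) -> AmplitudeSpectrum:
    """Epoch- and region-averaged one-sided magnitude spectrum.

    Each 2 s epoch is Hann-windowed and Fourier transformed; magnitudes are
    normalized so a unit-amplitude grid-aligned sinusoid yields 1 µV in its
    bin.  Epochs containing non-finite samples are dropped (count logged).
    """
    if regions is None:
        regions = default_region_map(rec.montage, rec.ch_names)
    n = rec.n_samples
    if abs(rec.epoch_duration - 2.0) > 1e-9:
        raise ValueError(
            f"epoch length {rec.epoch_duration:.3f} s does not give the 0.5 Hz grid (need 2 s epochs)"
        )

    finite = np.isfinite(rec.data).all(axis=(0, 2))
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("dropping %d epochs with non-finite samples", n_bad)
    data = rec.data[:, finite, :]
    if data.shape[1] == 0:
        raise ValueError("no finite epochs to analyze")

    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))  # periodic Hann
    scale = 2.0 / window.sum()  # one-sided amplitude normalization
    spec = np.abs(np.fft.rfft(data * window, axis=2)) * scale
    per_channel = spec.mean(axis=1)  # average over epochs
    freqs = np.fft.rfftfreq(n, 1.0 / rec.sfreq)

    amp = {}
    for region, labels in regions.items():
        if not labels:
            raise ValueError(f"region {region!r} is empty")
        missing = [lb for lb in labels if lb not in rec.ch_names]
        if missing:
            raise KeyError(f"region {region!r} channels not in recording: {missing}")
        idx = [rec.ch_names.index(lb) for lb in labels]
        amp[region] = per_channel[idx].mean(axis=0)
    return AmplitudeSpectrum(freqs, amp, n_epochs=data.shape[1])


def band_bins(freqs: np.ndarray, band: Band) -> np.ndarray:
    return (freqs >= band.low) & (freqs < band.high)


def band_power(spec: AmplitudeSpectrum, bands=DEFAULT_BANDS, mode: str = "absolute") -> pd.DataFrame:
    """Band values per region.

    ``absolute``: sum of bin amplitudes over the band, reported in picovolts.
    ``relative``: band sum divided by the total over all analyzed bins (the
    union of the bands), a proportion in [0, 1].
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    bands = validate_bands(bands)
    masks = {b.label: band_bins(spec.freqs, b) for b in bands}
    analyzed = np.logical_or.reduce(list(masks.values()))
    out = {}
    for region, amp in spec.amplitude.items():
        total = amp[analyzed].sum()
        if mode == "relative" and total <= 0:
            raise ValueError(f"zero total power in region {region!r}; relative power undefined")
        vals = {}
        for label, mask in masks.items():
            s = amp[mask].sum()
            vals[label] = s / total if mode == "relative" else s * PV_PER_UV
        out[region] = vals
    return pd.DataFrame(out).T  # regions x bands


def peak_alpha_frequency(
    spec: AmplitudeSpectrum,
    region: str,
    fmin: float = 6.0,
    fmax: float = 14.0,
    detrend: bool = False,
) -> float:
    """Frequency of maximal log spectral power within [fmin, fmax].

    Ties break toward the lower frequency.  With ``detrend`` a straight line
    in log-log coordinates (the 1/f background) is removed before the argmax.
    An ``EdgePeakWarning`` is emitted when the maximum sits on the window
    edge, i.e. there is no interior alpha peak.
    """
    if region not in spec.amplitude:
        raise KeyError(f"unknown region {region!r}")
    mask = (spec.freqs >= fmin) & (spec.freqs <= fmax)
    if not mask.any():
        raise ValueError("frequency grid does not cover the alpha search window")
    freqs = spec.freqs[mask]
    amp = np.asarray(spec.amplitude[region])[mask]
    if np.all(amp == 0):
        raise ValueError(f"spectrum is all zero in [{fmin}, {fmax}] Hz for region {region!r}")
    with np.errstate(divide="ignore"):
        logp = np.log10(np.maximum(amp, 1e-300) ** 2)
    if detrend:
        x = np.log10(freqs)
        coef = np.polyfit(x, logp, 1)
        logp = logp - np.polyval(coef, x)
    i = int(np.argmax(logp))  # first maximum -> lower-frequency tie break
    if i in (0, len(freqs) - 1):
        warnings.warn(
            f"peak alpha frequency at window edge ({freqs[i]:g} Hz) in region {region!r}",
            EdgePeakWarning,
            stacklevel=2,
        )
    return float(freqs[i])


def resting_feature_names(bands=DEFAULT_BANDS) -> list[str]:
    """The 45 resting variable names, namespaced ``Family|Region Band``."""
    names = []
    region_labels = [REGION_LABELS[r] for r in REGIONS]
    for fam in ("Absolute", "Relative"):
        for rl in region_labels:
            for b in validate_bands(bands):
                names.append(f"{fam}|{rl} {b.label}")
    names += [f"PAF|{rl}" for rl in region_labels]
    return names


def resting_feature_vector(
    rec: EpochedRecording,
    regions: dict[str, list[str]] | None = None,
    bands=DEFAULT_BANDS,
    detrend_paf: bool = False,
) -> pd.Series:
    """All 45 resting variables for one recording.

    7 bands x {absolute, relative} x {frontal, posterior, whole head} = 42
    power values plus PAF for the three regions.
    """
    if regions is None:
        regions = default_region_map(rec.montage, rec.ch_names)
    spec = amplitude_spectrum(rec, regions)
    out: dict[str, float] = {}
    for fam, mode in (("Absolute", "absolute"), ("Relative", "relative")):
        bp = band_power(spec, bands, mode)
        for region in REGIONS:
            rl = REGION_LABELS[region]
            for b in validate_bands(bands):
                out[f"{fam}|{rl} {b.label}"] = float(bp.loc[region, b.label])
    for region in REGIONS:
        out[f"PAF|{REGION_LABELS[region]}"] = peak_alpha_frequency(spec, region, detrend=detrend_paf)
    return pd.Series(out, name="resting")
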