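"""File exchange: EDF, delimited feature tables, YAML configuration.

Continuous (resting) EEG is written as plain 16-bit EDF so that recordings
round-trip through standard clinical tooling; reading goes through MNE's EDF
reader.  Epoched chirp trials are exchanged as ``.npz`` arrays (or in-memory
``EpochedRecording`` objects) since trial data is discontinuous.  Feature
tables are CSV with a metadata header (participant_id, group, sex, mosaic)
followed by the named EEG variables.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd
import yaml

from .containers import META_COLUMNS, EpochedRecording, validate_feature_table
from .montages import make_region_map
from .spectral import Band, validate_bands
from .chirp import TFROI

# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num(value, width: int) -> bytes:
    s = f"{value:.{width - 2}g}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EpochedRecording, path, patient: str = "X", recording: str = "fxseeg simulation") -> None:
    """Write an epoched (contiguous-epoch) recording as continuous 16-bit EDF.

    Epochs are concatenated back to the continuous signal; the record
    duration is 1 s, so the sampling rate must be an integer.
    """
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    sfreq = int(round(sfreq))
    data = rec.data.reshape(rec.n_channels, -1)  # µV, concatenate epochs
    n_total = data.shape[1]
    if n_total % sfreq != 0:
        raise ValueError("total duration must be an integer number of seconds")
    n_records = n_total // sfreq
    n_sig = rec.n_channels

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max - phys_min <= 0, 1.0, phys_max - phys_min)
    phys_max = phys_min + span
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / span
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient, 80),
            _ascii(recording, 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + n_sig), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(n_sig, 4),
        ]
    )
    fields = [
        (16, [ch for ch in rec.ch_names]),
        (80, ["simulated EEG"] * n_sig),
        (8, ["uV"] * n_sig),
    ]
    sig_header = b"".join(b"".join(_ascii(v, w) for v in vals) for w, vals in fields)
    sig_header += b"".join(_num(v, 8) for v in phys_min)
    sig_header += b"".join(_num(v, 8) for v in phys_max)
    sig_header += b"".join(_ascii(_EDF_DIG_MIN, 8) for _ in range(n_sig))
    sig_header += b"".join(_ascii(_EDF_DIG_MAX, 8) for _ in range(n_sig))
    sig_header += b"".join(_ascii("", 80) for _ in range(n_sig))
    sig_header += b"".join(_ascii(sfreq, 8) for _ in range(n_sig))
    sig_header += b"".join(_ascii("", 32) for _ in range(n_sig))

    # But physical min/max written with %g can lose precision; rescale digital
    # to the values actually written so the round trip is exact to 16 bits.
    pm = np.array([float(_num(v, 8).decode()) for v in phys_min])
    px = np.array([float(_num(v, 8).decode()) for v in phys_max])
    span_w = np.where(px - pm <= 0, 1.0, px - pm)
    scale_w = (_EDF_DIG_MAX - _EDF_DIG_MIN) / span_w
    digital = np.round((data - pm[:, None]) * scale_w[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        rec_view = digital.reshape(n_sig, n_records, sfreq)
        for r in range(n_records):
            fh.write(rec_view[:, r, :].tobytes())


def read_resting_edf(path, montage: str = "unknown") -> EpochedRecording:
    """Read a continuous EDF and segment it into non-overlapping 2 s epochs."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE stores EEG in volts
    sfreq = float(raw.info["sfreq"])
    epoch_len = int(round(2.0 * sfreq))
    n_epochs = data.shape[1] // epoch_len
    if n_epochs == 0:
        raise ValueError("recording shorter than one 2 s epoch")
    epoched = data[:, : n_epochs * epoch_len].reshape(data.shape[0], n_epochs, epoch_len)
    return EpochedRecording(epoched, sfreq, list(raw.ch_names), montage, task="rest")


# ---------------------------------------------------------------------------
# chirp trials as npz
# ---------------------------------------------------------------------------

def write_chirp_npz(rec: EpochedRecording, path) -> None:
    np.savez_compressed(
        path,
        data=rec.data,
        sfreq=rec.sfreq,
        ch_names=np.array(rec.ch_names),
        tmin=rec.tmin,
        montage=rec.montage,
        stimulus_duration=float(rec.meta.get("stimulus_duration", 2.0)),
    )


def read_chirp_npz(path) -> EpochedRecording:
    z = np.load(path, allow_pickle=False)
    return EpochedRecording(
        z["data"],
        float(z["sfreq"]),
        [str(c) for c in z["ch_names"]],
        str(z["montage"]),
        task="chirp",
        tmin=float(z["tmin"]),
        meta={"stimulus_duration": float(z["stimulus_duration"])},
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path) -> None:
    validate_feature_table(table)
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table)
    return table


def write_family_csv(table: pd.DataFrame, family_prefix: str, path) -> None:
    """Write one task family's columns with the bare published variable names.

    ``family_prefix`` is e.g. ``"Relative|"``; the prefix is stripped so the
    column header matches the published row labels bit-exactly
    (e.g. "Frontal Theta").
    """
    meta = [c for c in META_COLUMNS if c in table.columns]
    cols = [c for c in table.columns if c.startswith(family_prefix)]
    if not cols and family_prefix:
        raise KeyError(f"no columns with prefix {family_prefix!r}")
    out = table[meta + cols].rename(columns={c: c[len(family_prefix):] for c in cols})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def load_bands(path) -> tuple[Band, ...]:
    """Bands config: list of {name, label, low, high}."""
    raw = load_yaml(path)
    return validate_bands(Band(b["name"], b.get("label", b["name"].title()), float(b["low"]), float(b["high"])) for b in raw["bands"])


def load_regions(path) -> dict[str, list[str]]:
    raw = load_yaml(path)
    return make_region_map(raw["frontal"], raw["posterior"], raw["whole-head"])


def load_cluster(path) -> list[str]:
    return list(load_yaml(path)["cluster"])


def load_rois(path) -> tuple[TFROI, ...]:
    raw = load_yaml(path)
    rois = []
    for r in raw["rois"]:
        rois.append(
            TFROI(
                r["name"], float(r["fmin"]), float(r["fmax"]),
                float(r.get("tmin", -np.inf)), float(r.get("tmax", np.inf)),
                measure=r.get("measure", "itpc"), kind=r.get("kind", "rect"),
                half_bw=float(r.get("half_bw", 10.0)), sweep_rate=float(r.get("sweep_rate", 50.0)),
                baseline=tuple(r["baseline"]) if r.get("baseline") else None,
            )
        )
    return tuple(rois)
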