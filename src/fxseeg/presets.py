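"""Published group statistics used as generative parameters.

Each entry gives the sample mean and standard deviation of an EEG variable in
a diagnostic (sub)population: all FXS, all typically developing controls
(CON), FXS males, FXS females, non-mosaic (fully methylated) FXS males, CON
males and CON females.  Absolute resting power is on the study's picovolt
scale, relative power is a proportion of total analyzed power, peak alpha
frequency (PAF) is in Hz, chirp power variables are log-scaled µV² and ITPC
is a resultant length in [0, 1].

These statistics drive the feature-level simulator (`fxseeg.synthetic`): the
class-conditional distributions are moment-matched so the simulated cohorts
reproduce the printed means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POP_FXS = "FXS"
POP_CON = "CON"
POP_FXS_M = "FXS male"
POP_FXS_F = "FXS female"
POP_FXS_NM = "FXS non-mosaic male"
POP_CON_M = "CON male"
POP_CON_F = "CON female"

POPULATIONS = [POP_FXS, POP_CON, POP_FXS_M, POP_FXS_F, POP_FXS_NM, POP_CON_M, POP_CON_F]

#: per-population sample sizes of the resting cohort
RESTING_N = dict(zip(POPULATIONS, [70, 71, 38, 32, 27, 41, 30]))
#: per-population sample sizes of the chirp cohort
CHIRP_N = dict(zip(POPULATIONS, [57, 57, 37, 20, 26, 34, 23]))


@dataclass
class GroupStats:
    """Per (variable, population) Gaussian summary plus native-range bounds.

    ``table`` is indexed by (variable, population) with columns ``mean``,
    ``sd`` and ``n``; ``bounds`` maps a variable to its native (lo, hi) range
    (``-inf``/``inf`` when unbounded).
    """

    table: pd.DataFrame
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if (self.table["sd"] < 0).any():
            raise ValueError("standard deviations must be non-negative")
        if (self.table["n"] <= 0).any():
            raise ValueError("sample sizes must be positive")

    @property
    def variables(self) -> list[str]:
        return list(dict.fromkeys(self.table.index.get_level_values(0)))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table.index.get_level_values(1)))

    def get(self, variable: str, population: str) -> tuple[float, float]:
        try:
            row = self.table.loc[(variable, population)]
        except KeyError:
            raise KeyError(
                f"no statistics for variable {variable!r} in population {population!r}"
            ) from None
        return float(row["mean"]), float(row["sd"])

    def bound(self, variable: str) -> tuple[float, float]:
        return self.bounds.get(variable, (-np.inf, np.inf))

    def subset(self, variables) -> "GroupStats":
        variables = list(variables)
        tab = self.table.loc[self.table.index.get_level_values(0).isin(variables)]
        return GroupStats(tab.copy(), {v: self.bounds[v] for v in variables if v in self.bounds})

    @classmethod
    def from_dict(cls, stats: dict, n: dict, bounds=None) -> "GroupStats":
        """Build from {variable: {population: (mean, sd)}} plus {population: n}."""
        rows = []
        for var, pops in stats.items():
            for pop, (m, s) in pops.items():
                rows.append((var, pop, float(m), float(s), int(n[pop])))
        tab = pd.DataFrame(rows, columns=["variable", "population", "mean", "sd", "n"])
        tab = tab.set_index(["variable", "population"])
        return cls(tab, dict(bounds or {}))


def _cols(*pairs):
    return dict(zip(POPULATIONS, pairs))


# --- resting absolute power (picovolt scale) --------------------------------
ABSOLUTE_POWER_STATS = {
    "Frontal Delta": _cols((3.45, 2.96), (2.15, 1.74), (4.13, 3.44), (2.65, 2.04), (4.30, 3.56), (2.48, 1.95), (1.70, 1.32)),
    "Frontal Theta": _cols((2.63, 2.12), (1.44, 1.24), (3.11, 2.37), (2.05, 1.65), (3.42, 2.59), (1.58, 1.28), (1.27, 1.18)),
    "Frontal Alpha 1": _cols((1.54, 1.18), (1.39, 1.34), (1.73, 1.39), (1.31, 0.84), (1.79, 1.39), (1.47, 1.19), (1.29, 1.53)),
    "Frontal Alpha 2": _cols((1.24, 0.97), (1.07, 0.77), (1.38, 1.10), (1.07, 0.77), (1.45, 1.14), (1.19, 0.75), (0.90, 0.77)),
    "Frontal Beta": _cols((0.94, 0.85), (0.57, 0.40), (1.09, 0.91), (0.74, 0.74), (1.16, 0.91), (0.64, 0.42), (0.48, 0.36)),
    "Frontal Gamma 1": _cols((0.83, 0.84), (0.44, 0.31), (0.99, 0.89), (0.64, 0.73), (1.04, 0.89), (0.48, 0.30), (0.38, 0.31)),
    "Frontal Gamma 2": _cols((0.79, 0.81), (0.42, 0.29), (0.94, 0.86), (0.61, 0.72), (0.99, 0.86), (0.45, 0.29), (0.36, 0.31)),
    "Posterior Delta": _cols((3.86, 3.84), (2.11, 2.23), (4.85, 4.52), (2.69, 2.41), (5.02, 4.66), (2.57, 2.69), (1.49, 1.17)),
    "Posterior Theta": _cols((2.91, 2.83), (1.47, 1.57), (3.80, 3.41), (1.85, 1.38), (4.09, 3.69), (1.75, 1.88), (1.07, 0.91)),
    "Posterior Alpha 1": _cols((1.82, 1.38), (1.57, 1.71), (2.19, 1.63), (1.39, 0.85), (2.22, 1.51), (1.94, 2.07), (1.06, 0.82)),
    "Posterior Alpha 2": _cols((1.51, 1.18), (1.23, 0.98), (1.79, 1.39), (1.16, 0.73), (1.82, 1.29), (1.52, 1.13), (0.84, 0.53)),
    "Posterior Beta": _cols((1.00, 1.00), (0.56, 0.51), (1.26, 1.19), (0.71, 0.60), (1.24, 1.02), (0.68, 0.61), (0.40, 0.24)),
    "Posterior Gamma 1": _cols((0.90, 0.97), (0.45, 0.44), (1.14, 1.16), (0.62, 0.60), (1.12, 0.97), (0.54, 0.54), (0.32, 0.20)),
    "Posterior Gamma 2": _cols((0.86, 0.93), (0.43, 0.44), (1.09, 1.10), (0.59, 0.59), (1.06, 0.92), (0.52, 0.53), (0.31, 0.19)),
    "Whole Head Delta": _cols((3.95, 4.24), (2.07, 1.82), (4.49, 4.22), (3.29, 4.24), (4.48, 3.84), (2.47, 2.13), (1.53, 1.13)),
    "Whole Head Theta": _cols((2.58, 2.40), (1.24, 1.21), (3.12, 2.67), (1.94, 1.89), (3.35, 2.76), (1.42, 1.35), (0.99, 0.96)),
    "Whole Head Alpha 1": _cols((1.13, 0.81), (1.23, 1.38), (1.24, 0.94), (1.01, 0.62), (1.23, 0.76), (1.41, 1.52), (0.99, 1.15)),
    "Whole Head Alpha 2": _cols((0.76, 0.49), (0.87, 0.67), (0.81, 0.55), (0.71, 0.40), (0.81, 0.47), (1.02, 0.72), (0.66, 0.54)),
    "Whole Head Beta": _cols((0.30, 0.23), (0.21, 0.14), (0.36, 0.27), (0.23, 0.15), (0.35, 0.19), (0.25, 0.16), (0.16, 0.08)),
    "Whole Head Gamma 1": _cols((0.18, 0.19), (0.08, 0.04), (0.23, 0.22), (0.12, 0.12), (0.21, 0.13), (0.09, 0.05), (0.07, 0.03)),
    "Whole Head Gamma 2": _cols((0.13, 0.13), (0.06, 0.04), (0.16, 0.16), (0.08, 0.09), (0.15, 0.08), (0.06, 0.04), (0.05, 0.03)),
}

# --- resting relative power (proportion of total analyzed power) ------------
RELATIVE_POWER_STATS = {
    "Frontal Delta": _cols((0.40, 0.11), (0.36, 0.09), (0.41, 0.09), (0.39, 0.12), (0.40, 0.09), (0.36, 0.09), (0.35, 0.11)),
    "Frontal Theta": _cols((0.30, 0.06), (0.24, 0.05), (0.32, 0.05), (0.29, 0.07), (0.33, 0.06), (0.24, 0.05), (0.24, 0.05)),
    "Frontal Alpha 1": _cols((0.19, 0.04), (0.22, 0.06), (0.18, 0.03), (0.19, 0.05), (0.17, 0.03), (0.22, 0.05), (0.22, 0.07)),
    "Frontal Alpha 2": _cols((0.15, 0.03), (0.19, 0.04), (0.14, 0.02), (0.16, 0.03), (0.14, 0.02), (0.19, 0.04), (0.18, 0.04)),
    "Frontal Beta": _cols((0.10, 0.02), (0.09, 0.02), (0.10, 0.02), (0.09, 0.02), (0.11, 0.02), (0.09, 0.02), (0.09, 0.02)),
    "Frontal Gamma 1": _cols((0.08, 0.02), (0.08, 0.02), (0.09, 0.02), (0.08, 0.02), (0.09, 0.02), (0.07, 0.02), (0.08, 0.02)),
    "Frontal Gamma 2": _cols((0.08, 0.02), (0.07, 0.02), (0.08, 0.02), (0.07, 0.02), (0.08, 0.02), (0.07, 0.02), (0.07, 0.02)),
    "Posterior Delta": _cols((0.39, 0.11), (0.33, 0.11), (0.39, 0.09), (0.39, 0.13), (0.39, 0.09), (0.32, 0.11), (0.34, 0.11)),
    "Posterior Theta": _cols((0.29, 0.06), (0.23, 0.06), (0.31, 0.05), (0.27, 0.06), (0.32, 0.05), (0.23, 0.06), (0.24, 0.05)),
    "Posterior Alpha 1": _cols((0.20, 0.04), (0.25, 0.06), (0.19, 0.03), (0.22, 0.05), (0.19, 0.03), (0.25, 0.06), (0.24, 0.05)),
    "Posterior Alpha 2": _cols((0.17, 0.03), (0.21, 0.05), (0.16, 0.02), (0.18, 0.04), (0.15, 0.02), (0.21, 0.05), (0.20, 0.05)),
    "Posterior Beta": _cols((0.10, 0.02), (0.09, 0.02), (0.10, 0.02), (0.10, 0.02), (0.10, 0.02), (0.09, 0.02), (0.09, 0.02)),
    "Posterior Gamma 1": _cols((0.09, 0.02), (0.07, 0.02), (0.09, 0.02), (0.08, 0.03), (0.09, 0.02), (0.07, 0.02), (0.08, 0.05)),
    "Posterior Gamma 2": _cols((0.08, 0.02), (0.07, 0.02), (0.08, 0.02), (0.08, 0.03), (0.08, 0.02), (0.07, 0.02), (0.07, 0.02)),
    "Whole Head Delta": _cols((0.39, 0.11), (0.35, 0.09), (0.39, 0.09), (0.38, 0.13), (0.39, 0.09), (0.35, 0.09), (0.35, 0.11)),
    "Whole Head Theta": _cols((0.28, 0.09), (0.21, 0.05), (0.29, 0.07), (0.26, 0.09), (0.31, 0.08), (0.20, 0.06), (0.21, 0.05)),
    "Whole Head Alpha 1": _cols((0.15, 0.06), (0.21, 0.09), (0.14, 0.04), (0.17, 0.08), (0.13, 0.04), (0.21, 0.08), (0.20, 0.09)),
    "Whole Head Alpha 2": _cols((0.11, 0.04), (0.16, 0.07), (0.09, 0.03), (0.12, 0.05), (0.09, 0.03), (0.17, 0.06), (0.16, 0.07)),
    "Whole Head Beta": _cols((0.04, 0.02), (0.04, 0.02), (0.04, 0.02), (0.04, 0.01), (0.04, 0.03), (0.04, 0.02), (0.05, 0.02)),
    "Whole Head Gamma 1": _cols((0.02, 0.01), (0.02, 0.01), (0.02, 0.01), (0.02, 0.01), (0.02, 0.01), (0.02, 0.01), (0.02, 0.01)),
    "Whole Head Gamma 2": _cols((0.02, 0.01), (0.01, 0.01), (0.02, 0.01), (0.01, 0.01), (0.02, 0.01), (0.01, 0.01), (0.02, 0.01)),
}

# --- resting peak alpha frequency (Hz) ---------------------------------------
ALPHA_PEAK_STATS = {
    "Frontal": _cols((8.55, 0.39), (8.46, 0.33), (8.56, 0.41), (8.54, 0.39), (8.56, 0.45), (8.49, 0.34), (8.42, 0.31)),
    "Posterior": _cols((8.17, 0.52), (8.57, 0.29), (8.18, 0.53), (8.16, 0.51), (8.21, 0.57), (8.59, 0.28), (8.53, 0.31)),
    "Whole Head": _cols((8.35, 0.27), (8.53, 0.18), (8.31, 0.22), (8.31, 0.31), (8.32, 0.22), (8.53, 0.19), (8.54, 0.17)),
}

# --- chirp variables (log-power in 10*log10 µV²; ITPC resultant length) -----
CHIRP_STATS = {
    "Gamma Power": _cols((7.07, 1.80), (5.45, 1.88), (7.65, 1.79), (6.01, 1.27), (8.09, 1.78), (5.64, 1.36), (5.21, 2.47)),
    "Theta Power": _cols((24.25, 2.94), (22.19, 2.25), (24.14, 2.85), (24.45, 3.17), (24.39, 2.87), (22.48, 2.07), (21.76, 2.47)),
    "Alpha Power": _cols((-0.21, 0.33), (-0.06, 0.32), (-0.21, 0.36), (-0.21, 0.28), (-0.22, 0.37), (-0.04, 0.33), (-0.08, 0.31)),
    "Low Gamma ITPC": _cols((0.10, 0.06), (0.14, 0.08), (0.09, 0.06), (0.13, 0.06), (0.08, 0.06), (0.15, 0.08), (0.13, 0.07)),
    "High Gamma ITPC": _cols((0.04, 0.03), (0.03, 0.02), (0.03, 0.03), (0.04, 0.03), (0.04, 0.04), (0.04, 0.03), (0.03, 0.02)),
    "Stimulus Onset ITPC": _cols((0.14, 0.08), (0.08, 0.06), (0.14, 0.08), (0.12, 0.07), (0.14, 0.08), (0.08, 0.06), (0.08, 0.06)),
    "Stimulus Offset ITPC": _cols((0.05, 0.04), (0.04, 0.04), (0.06, 0.04), (0.05, 0.04), (0.06, 0.04), (0.05, 0.04), (0.04, 0.05)),
}

POSITIVE = (0.0, np.inf)
UNIT = (0.0, 1.0)
PAF_RANGE = (6.0, 14.0)


def absolute_power_stats() -> GroupStats:
    bounds = {v: POSITIVE for v in ABSOLUTE_POWER_STATS}
    return GroupStats.from_dict(ABSOLUTE_POWER_STATS, RESTING_N, bounds)


def relative_power_stats() -> GroupStats:
    bounds = {v: UNIT for v in RELATIVE_POWER_STATS}
    return GroupStats.from_dict(RELATIVE_POWER_STATS, RESTING_N, bounds)


def alpha_peak_stats() -> GroupStats:
    bounds = {v: PAF_RANGE for v in ALPHA_PEAK_STATS}
    return GroupStats.from_dict(ALPHA_PEAK_STATS, RESTING_N, bounds)


def chirp_stats() -> GroupStats:
    bounds = {v: UNIT for v in CHIRP_STATS if v.endswith("ITPC")}
    return GroupStats.from_dict(CHIRP_STATS, CHIRP_N, bounds)


def resting_stats() -> GroupStats:
    """All 45 resting variables, namespaced by family (Absolute/Relative/PAF)."""
    stats, bounds = {}, {}
    for fam, src, bnd in (
        ("Absolute", ABSOLUTE_POWER_STATS, POSITIVE),
        ("Relative", RELATIVE_POWER_STATS, UNIT),
        ("PAF", ALPHA_PEAK_STATS, PAF_RANGE),
    ):
        for var, pops in src.items():
            name = f"{fam}|{var}"
            stats[name] = pops
            bounds[name] = bnd
    return GroupStats.from_dict(stats, RESTING_N, bounds)
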