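"""Montage definitions: channel labels, scalp regions, cluster and montage maps.

The frontal/posterior quadrant membership and the fronto-central cluster for
the dense 128-channel geodesic net are editable conventions, not measured
geometry: any analysis can pass its own ``RegionMap``/cluster.  The 20-channel
target montage follows the standard 10–20 layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGION_FRONTAL = "frontal"
REGION_POSTERIOR = "posterior"
REGION_WHOLE_HEAD = "whole-head"
REGIONS = (REGION_FRONTAL, REGION_POSTERIOR, REGION_WHOLE_HEAD)

#: human-readable region labels used in variable names
REGION_LABELS = {
    REGION_FRONTAL: "Frontal",
    REGION_POSTERIOR: "Posterior",
    REGION_WHOLE_HEAD: "Whole Head",
}

HYDROCEL128 = "hydrocel128"
STANDARD1020 = "standard1020-20"


def hydrocel128_labels() -> list[str]:
    """129 recorded channels of the 128-channel geodesic net (vertex ref Cz)."""
    return [f"E{i}" for i in range(1, 129)] + ["Cz"]


TEN20_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]

# Approximate 10-20 equivalents on the 128-channel geodesic net.
HYDROCEL_TO_1020 = {
    "Fp1": "E22", "Fp2": "E9", "F7": "E33", "F3": "E24", "Fz": "E11",
    "F4": "E124", "F8": "E122", "T7": "E45", "C3": "E36", "Cz": "Cz",
    "C4": "E104", "T8": "E108", "P7": "E58", "P3": "E52", "Pz": "E62",
    "P4": "E92", "P8": "E96", "O1": "E70", "Oz": "E75", "O2": "E83",
}

# Editable frontal / posterior quadrant membership for the dense net.
_HYDROCEL_FRONTAL = [
    "E1", "E2", "E3", "E4", "E5", "E8", "E9", "E10", "E11", "E12", "E14",
    "E15", "E16", "E18", "E19", "E20", "E21", "E22", "E23", "E24", "E25",
    "E26", "E27", "E32", "E33", "E121", "E122", "E123", "E124", "E125",
    "E126", "E127", "E128",
]
_HYDROCEL_POSTERIOR = [
    "E58", "E59", "E60", "E61", "E62", "E63", "E64", "E65", "E66", "E67",
    "E68", "E69", "E70", "E71", "E72", "E73", "E74", "E75", "E76", "E77",
    "E78", "E81", "E82", "E83", "E84", "E85", "E86", "E88", "E89", "E90",
    "E91", "E92", "E94", "E95", "E96", "E97", "E99", "E100",
]

#: default fronto-central sensor cluster used for the chirp task (23 channels)
FRONTOCENTRAL_CLUSTER = [
    "E3", "E4", "E5", "E6", "E7", "E12", "E13", "E20", "E28", "E29", "E30",
    "E35", "E36", "E37", "E41", "E42", "E54", "E55", "E79", "E80", "E87",
    "E104", "E105",
]

_1020_FRONTAL = ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"]
_1020_POSTERIOR = ["P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2"]


def make_region_map(frontal, posterior, whole_head) -> dict[str, list[str]]:
    """Build and validate a region map (whole-head must cover both quadrants)."""
    fr, po, wh = list(frontal), list(posterior), list(whole_head)
    missing = (set(fr) | set(po)) - set(wh)
    if missing:
        raise ValueError(f"whole-head region must contain frontal+posterior; missing {sorted(missing)}")
    return {REGION_FRONTAL: fr, REGION_POSTERIOR: po, REGION_WHOLE_HEAD: wh}


def default_region_map(montage: str, ch_names=None) -> dict[str, list[str]]:
    """Default frontal / posterior / whole-head channel sets for a montage.

    If ``ch_names`` is given, the whole-head region is the recording's own
    channel set and quadrants are intersected with it.
    """
    if montage == HYDROCEL128:
        fr, po = _HYDROCEL_FRONTAL, _HYDROCEL_POSTERIOR
        wh = hydrocel128_labels()
    elif montage == STANDARD1020:
        fr, po = _1020_FRONTAL, _1020_POSTERIOR
        wh = list(TEN20_LABELS)
    else:
        raise KeyError(f"no default region map for montage {montage!r}")
    if ch_names is not None:
        avail = set(ch_names)
        fr = [c for c in fr if c in avail]
        po = [c for c in po if c in avail]
        wh = [c for c in wh if c in avail]
    return make_region_map(fr, po, wh)


@dataclass
class MontageMap:
    """Down-sampling map from a dense montage to a 20-channel clinical montage.

    ``mapping`` is total on the target side: every one of the 20 target labels
    names the source channel whose signal it takes (nearest-sensor selection,
    no interpolation).
    """

    source_montage: str
    target_montage: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.mapping) != 20:
            raise ValueError(f"montage map must have exactly 20 target channels, got {len(self.mapping)}")

    @classmethod
    def default_hydrocel_to_1020(cls) -> "MontageMap":
        return cls(HYDROCEL128, STANDARD1020, dict(HYDROCEL_TO_1020))

    @classmethod
    def identity_1020(cls) -> "MontageMap":
        return cls(STANDARD1020, STANDARD1020, {c: c for c in TEN20_LABELS})
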