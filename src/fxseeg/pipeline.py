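"""Study orchestration: variable sets, subgroups, montage reduction, reports.

Stage 1 evaluates every a-priori variable set on the full cohort, per task
family (resting absolute power, resting relative power, resting alpha peak,
chirp).  Stage 2 flags the two best sets per family by full-dataset AUC
(cross-validation error, then name, break ties).  Stage 3 re-runs those sets
on genetically mediated subgroups (males, females, non-mosaic FXS males vs
male controls).  Stage 4 re-checks the best resting family/subgroup after
down-sampling to a 20-channel clinical montage.  Every row records the seed
that produced it, so reports are bit-reproducible from config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .containers import GROUP_CON, GROUP_FXS, EpochedRecording
from .evaluation import EvalReport, evaluate_variable_set
from .montages import MontageMap
from .presets import chirp_stats, resting_stats
from .synthetic import default_composition, simulate_feature_table
from .utils import derive_seed

BAND_LABELS = ["Delta", "Theta", "Alpha 1", "Alpha 2", "Beta", "Gamma 1", "Gamma 2"]
REGION_ORDER = ["Frontal", "Posterior", "Whole Head"]

FAMILY_REST_ABS = "rest-absolute"
FAMILY_REST_REL = "rest-relative"
FAMILY_REST_PAF = "rest-alphapeak"
FAMILY_CHIRP = "chirp"
FAMILIES = (FAMILY_REST_ABS, FAMILY_REST_REL, FAMILY_REST_PAF, FAMILY_CHIRP)

_FAMILY_PREFIX = {FAMILY_REST_ABS: "Absolute|", FAMILY_REST_REL: "Relative|", FAMILY_REST_PAF: "PAF|", FAMILY_CHIRP: ""}

#: exact report column heads
COL_VARIABLE = "Variable"
COL_AUC_HOLDOUT = "AUC – 30% holdout test set"
COL_AUC_FULL = "AUC – entire dataset"
COL_CV_ERROR = "Cross Validation Classification Error"
REPORT_COLUMNS = [COL_VARIABLE, COL_AUC_HOLDOUT, COL_AUC_FULL, COL_CV_ERROR, "Subgroup", "Top 2", "Seed"]

SUBGROUP_ALL = "ALL SUBJECTS"
SUBGROUP_MALES = "MALES ONLY"
SUBGROUP_FEMALES = "FEMALES ONLY"
SUBGROUP_NONMOSAIC = "NON-MOSAIC MALES ONLY"
SUBGROUPS = (SUBGROUP_MALES, SUBGROUP_FEMALES, SUBGROUP_NONMOSAIC)


@dataclass(frozen=True)
class VariableSet:
    name: str
    members: tuple[str, ...]
    task: str

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"variable set {self.name!r} has no members")


def build_variable_sets(task: str) -> list[VariableSet]:
    """Enumerate the study's a-priori variable sets for a task family.

    Resting absolute/relative power: per region an "All <Region> Variables"
    composite plus the seven band singletons, then "All Variables" (25 sets).
    Alpha peak: the three regions plus "All Variables" (4).  Chirp: the seven
    singletons, "All ITPC Variables", "All Power Variables", the a-priori
    "Gamma Power/Low Gamma ITPC" pair, and "All Variables" (11).
    """
    pre = _FAMILY_PREFIX.get(task)
    if pre is None:
        raise ValueError(f"unknown task {task!r}")
    sets: list[VariableSet] = []
    if task in (FAMILY_REST_ABS, FAMILY_REST_REL):
        for region in REGION_ORDER:
            members = tuple(f"{pre}{region} {b}" for b in BAND_LABELS)
            sets.append(VariableSet(f"All {region} Variables", members, task))
            for b in BAND_LABELS:
                sets.append(VariableSet(f"{region} {b}", (f"{pre}{region} {b}",), task))
        all_members = tuple(f"{pre}{r} {b}" for r in REGION_ORDER for b in BAND_LABELS)
        sets.append(VariableSet("All Variables", all_members, task))
    elif task == FAMILY_REST_PAF:
        for region in REGION_ORDER:
            sets.append(VariableSet(region, (f"{pre}{region}",), task))
        sets.append(VariableSet("All Variables", tuple(f"{pre}{r}" for r in REGION_ORDER), task))
    else:  # chirp
        singles = ["Gamma Power", "Theta Power", "Alpha Power", "Low Gamma ITPC",
                   "High Gamma ITPC", "Stimulus Onset ITPC", "Stimulus Offset ITPC"]
        for s in singles:
            sets.append(VariableSet(s, (s,), task))
        itpc_vars = tuple(s for s in singles if s.endswith("ITPC"))
        power_vars = tuple(s for s in singles if s.endswith("Power"))
        sets.append(VariableSet("All ITPC Variables", itpc_vars, task))
        sets.append(VariableSet("All Power Variables", power_vars, task))
        sets.append(VariableSet("Gamma Power/Low Gamma ITPC", ("Gamma Power", "Low Gamma ITPC"), task))
        sets.append(VariableSet("All Variables", tuple(singles), task))
    return sets


@dataclass(frozen=True)
class SubgroupSpec:
    """Filter describing a case/control subgroup comparison.

    The same sex restriction applies to both groups — subgroup analyses never
    compare across sexes.  ``fxs_nonmosaic_only`` additionally drops mosaic
    FXS participants.
    """

    name: str
    sex: str | None = None  # None = both sexes
    fxs_nonmosaic_only: bool = False


SUBGROUP_SPECS = {
    SUBGROUP_ALL: SubgroupSpec(SUBGROUP_ALL),
    SUBGROUP_MALES: SubgroupSpec(SUBGROUP_MALES, sex="M"),
    SUBGROUP_FEMALES: SubgroupSpec(SUBGROUP_FEMALES, sex="F"),
    SUBGROUP_NONMOSAIC: SubgroupSpec(SUBGROUP_NONMOSAIC, sex="M", fxs_nonmosaic_only=True),
}


def apply_subgroup(table: pd.DataFrame, spec: SubgroupSpec) -> pd.DataFrame:
    """Filter a feature table to the subgroup's case and control rows."""
    out = table
    if spec.sex is not None:
        out = out[out["sex"] == spec.sex]
    if spec.fxs_nonmosaic_only:
        out = out[(out["group"] != GROUP_FXS) | (~out["mosaic"].astype(bool))]
    for c in (GROUP_FXS, GROUP_CON):
        if (out["group"] == c).sum() == 0:
            raise ValueError(f"subgroup {spec.name!r} leaves class {c!r} empty")
    return out.reset_index(drop=True)


def reduce_montage(rec: EpochedRecording, mmap: MontageMap) -> EpochedRecording:
    """Down-sample a dense recording to the 20-channel clinical montage.

    Each target channel takes the signal of its mapped source channel
    (nearest-sensor selection, no interpolation).
    """
    targets = list(mmap.mapping)
    missing = [s for s in mmap.mapping.values() if s not in rec.ch_names]
    if missing:
        raise KeyError(f"montage map source channels missing from recording: {sorted(set(missing))}")
    idx = [rec.ch_names.index(mmap.mapping[t]) for t in targets]
    return EpochedRecording(
        rec.data[idx].copy(), rec.sfreq, targets, mmap.target_montage, rec.task, rec.tmin, dict(rec.meta)
    )


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Inputs of ``run_full_study``.

    When ``rest_table``/``chirp_table`` are None, cohorts are simulated from
    the published group statistics with the study's subgroup composition
    (seeded from ``seed``); the montage stage then re-draws the selected
    subgroup as an independent 20-channel re-measurement.
    """

    seed: int = 0
    rest_table: pd.DataFrame | None = None
    chirp_table: pd.DataFrame | None = None
    include_absolute_subgroups: bool = False
    montage_stage: bool = True
    confusion_on: str = "full"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tables = {}
        for key in ("rest_table", "chirp_table"):
            p = raw.pop(key, None)
            tables[key] = pd.read_csv(p) if p else None
        return cls(**raw, **tables)


@dataclass
class StudyReport:
    """Consolidated per-family report tables plus a reproducibility manifest."""

    frames: dict[str, pd.DataFrame]
    manifest: dict = field(default_factory=dict)
    details: dict[str, list[EvalReport]] = field(default_factory=dict)

    def rows(self, family: str, subgroup: str | None = None) -> pd.DataFrame:
        df = self.frames[family]
        return df if subgroup is None else df[df["Subgroup"] == subgroup]

    def to_csv(self, outdir) -> list[str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        written = []
        for family, df in self.frames.items():
            path = os.path.join(outdir, f"report_{family.replace('-', '_')}.csv")
            df.to_csv(path, index=False)
            written.append(path)
        manifest_path = os.path.join(outdir, "run_manifest.yaml")
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        written.append(manifest_path)
        return written


def _row(report: EvalReport, name: str, subgroup: str, top2: bool) -> dict:
    return {
        COL_VARIABLE: name,
        COL_AUC_HOLDOUT: report.auc_holdout,
        COL_AUC_FULL: report.auc_full,
        COL_CV_ERROR: report.cv_error,
        "Subgroup": subgroup,
        "Top 2": bool(top2),
        "Seed": report.seed,
    }


def _simulate_tables(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    rest = simulate_feature_table(
        resting_stats(), composition=default_composition("rest"), seed=derive_seed(seed, "rest-cohort")
    )
    chirp = simulate_feature_table(
        chirp_stats(), composition=default_composition("chirp"), seed=derive_seed(seed, "chirp-cohort")
    )
    return rest, chirp


def run_full_study(config: StudyConfig | str) -> StudyReport:
    """Run the complete classification study and return the consolidated report."""
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    seed = int(config.seed)

    simulated = config.rest_table is None and config.chirp_table is None
    if simulated:
        rest_table, chirp_table = _simulate_tables(seed)
    else:
        rest_table, chirp_table = config.rest_table, config.chirp_table
    tables = {
        FAMILY_REST_ABS: rest_table,
        FAMILY_REST_REL: rest_table,
        FAMILY_REST_PAF: rest_table,
        FAMILY_CHIRP: chirp_table,
    }

    frames: dict[str, pd.DataFrame] = {}
    details: dict[str, list[EvalReport]] = {}
    top2_by_family: dict[str, list[VariableSet]] = {}
    subgroup_rows: dict[str, list[tuple[VariableSet, str, EvalReport]]] = {}

    for family in FAMILIES:
        table = tables[family]
        if table is None:
            continue
        sets = build_variable_sets(family)
        rows, reps = [], []
        results = []
        for vs in sets:
            rep = evaluate_variable_set(
                table, list(vs.members), seed=derive_seed(seed, family, vs.name, SUBGROUP_ALL),
                name=vs.name, subgroup=SUBGROUP_ALL, confusion_on=config.confusion_on,
            )
            results.append((vs, rep))
            reps.append(rep)
        ranked = sorted(results, key=lambda t: (-t[1].auc_full, t[1].cv_error, t[0].name))
        top2 = [vs for vs, _ in ranked[:2]]
        top2_by_family[family] = top2
        top_names = {vs.name for vs in top2}
        for vs, rep in results:
            rows.append(_row(rep, vs.name, SUBGROUP_ALL, vs.name in top_names))

        run_subgroups = family != FAMILY_REST_ABS or config.include_absolute_subgroups
        subgroup_rows[family] = []
        if run_subgroups:
            for sg in SUBGROUPS:
                sub = apply_subgroup(table, SUBGROUP_SPECS[sg])
                for vs in top2:
                    rep = evaluate_variable_set(
                        sub, list(vs.members), seed=derive_seed(seed, family, vs.name, sg),
                        name=vs.name, subgroup=sg, confusion_on=config.confusion_on,
                    )
                    rows.append(_row(rep, vs.name, sg, False))
                    reps.append(rep)
                    subgroup_rows[family].append((vs, sg, rep))
        frames[family] = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        details[family] = reps

    # stage 4: 20-channel montage re-run for the best resting family rows
    if config.montage_stage:
        for family in (FAMILY_REST_REL, FAMILY_REST_PAF):
            if family not in frames:
                continue
            candidates: list[tuple[VariableSet, str, EvalReport]] = []
            for vs in top2_by_family[family]:
                rep = next(r for r in details[family] if r.name == vs.name and r.subgroup == SUBGROUP_ALL)
                candidates.append((vs, SUBGROUP_ALL, rep))
            candidates.extend(subgroup_rows[family])
            vs, sg, _ = sorted(candidates, key=lambda t: (-t[2].auc_full, t[2].cv_error, t[0].name))[0]
            mseed = derive_seed(seed, family, vs.name, sg, "montage20")
            if simulated:
                redraw = simulate_feature_table(
                    resting_stats(), composition=default_composition("rest"), seed=mseed
                )
            else:
                redraw = tables[family]
            sub = apply_subgroup(redraw, SUBGROUP_SPECS[sg])
            rep = evaluate_variable_set(
                sub, list(vs.members), seed=mseed, name=vs.name,
                subgroup=f"{sg}: 20 CHANNEL MONTAGE", confusion_on=config.confusion_on,
            )
            frames[family] = pd.concat(
                [frames[family], pd.DataFrame([_row(rep, vs.name, rep.subgroup, False)], columns=REPORT_COLUMNS)],
                ignore_index=True,
            )
            details[family].append(rep)

    manifest = {
        "seed": seed,
        "simulated_cohort": simulated,
        "n_rest": 0 if rest_table is None else int(len(rest_table)),
        "n_chirp": 0 if chirp_table is None else int(len(chirp_table)),
        "include_absolute_subgroups": config.include_absolute_subgroups,
        "montage_stage": config.montage_stage,
        "confusion_on": config.confusion_on,
        "families": list(frames),
    }
    return StudyReport(frames, manifest, details)
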