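"""Synthetic dual-phase SUVr cohorts with the study's statistical structure.

The generator emulates a dual-phase tau-PET study of 4-repeat tauopathies:
a training site with 4RT patients, mixed other neurodegenerative diseases
(AD-like, FTLD-like, alpha-synucleinopathy-like, unspecified) and a small
healthy-control group, plus an independent external site, all quantified as
cerebellar-reference SUVr over the 246 Brainnetome regions in an early
(perfusion) and a late (tau) window.

Generative model, for subject j (group g, disease pattern pi), phase p,
region r::

    suvr_jpr = mu_pr * (1 + delta_{pi,p,r} * (1 + gamma_p * a_jp))
               + b_pr * u_j + s_g * sigma_pr * eps_jpr

with two latent standard-normal factors per disease subject (both 0 for
healthy controls): a clinical severity factor ``u_j`` that scales the
early-phase (perfusion) deficit and drives the clinical scores, and an
independent tau-burden factor ``v_j`` that scales the late-phase pattern
(``a_jp`` is ``u_j`` for the early phase and ``v_j`` for the late phase).
The amplitude terms have mean zero, so group-mean percent differences equal
``delta`` exactly while subjects express the pattern to varying degree --
the source of the between-patient overlap that keeps multivariate
discrimination below ceiling.  ``b_pr`` adds an optional direct severity
loading, ``eps`` is i.i.d. standard normal, and values are floored at 0.05
so SUVr stays positive.  Clinical scores are affine in ``u_j`` plus noise,
truncated to their valid ranges; the pre-truncation values are kept in the
truth record.  The 4RT early-phase effects ``delta`` default to the 21
published target-region percent differences; the distractor-disease patterns
are synthetic design choices, not published quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from tauperf.atlas import RegionAtlas, load_atlas
from tauperf.core import CohortTable, Phase, SuvrMatrix, SCORE_RANGES

SCENARIOS = ("paper_like", "null", "separable", "complementary")

TRAINING_SITE = "training"
EXTERNAL_SITE = "external"


@dataclass(frozen=True)
class SubgroupSpec:
    """Size and demographics of one simulated diagnostic subgroup."""

    group: str
    subgroup: str
    n: int
    pattern: str            # key into SimulationConfig.effect_table ("none" = no effect)
    site: str = TRAINING_SITE
    age_mean: float = 68.0
    age_sd: float = 8.0
    frac_female: float = 0.5
    duration_mean: float | None = 36.0   # months; None -> missing (healthy controls)
    duration_sd: float = 25.0


@dataclass(frozen=True)
class ClinicalCoupling:
    """Affine link from the latent severity factor to one clinical score."""

    slope: float
    noise_sd: float


@dataclass(frozen=True)
class SimulationConfig:
    subgroups: tuple[SubgroupSpec, ...]
    seed: int
    baseline_early: float | Mapping[str, float] = 1.0
    baseline_late: float | Mapping[str, float] = 1.0
    noise_sd: float | Mapping[str, float] = 0.06
    #: per-group multiplier on the residual scale (normative-band width)
    noise_scale_by_group: Mapping[str, float] = field(default_factory=dict)
    #: pattern -> phase value -> {region label: signed fractional effect}
    effect_table: Mapping[str, Mapping[str, Mapping[str, float]]] = field(default_factory=dict)
    #: phase value -> {region label: loading of the severity factor, SUVr units}
    latent_loadings: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: phase value -> gamma: per-subject pattern-amplitude heterogeneity
    #: (early phase scales with severity u, late phase with tau burden v)
    amplitude_gamma: Mapping[str, float] = field(default_factory=dict)
    #: score name -> coupling to the severity factor
    clinical_coupling: Mapping[str, ClinicalCoupling] = field(default_factory=dict)
    #: group -> score name -> population mean (absent score -> missing)
    group_score_means: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    suvr_floor: float = 0.05
    #: if True, each 4RT subject expresses its disease effect in only one
    #: phase (alternating), planting complementary perfusion/tau information
    split_phase_informative: bool = False

    def validate(self, atlas: RegionAtlas) -> None:
        labels = set(atlas.labels)
        if not self.subgroups:
            raise ValueError("config has no subgroups")
        for sg in self.subgroups:
            if sg.n < 2:
                raise ValueError(f"subgroup {sg.subgroup!r} has n={sg.n} < 2")
        if isinstance(self.noise_sd, Mapping):
            if any(v <= 0 for v in self.noise_sd.values()):
                raise ValueError("noise_sd must be positive")
        elif self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for pattern, phases in self.effect_table.items():
            for phase, effects in phases.items():
                unknown = set(effects) - labels
                if unknown:
                    raise ValueError(
                        f"effect_table[{pattern}][{phase}] has unknown labels: {sorted(unknown)[:5]}"
                    )
                if any(d <= -1 for d in effects.values()):
                    raise ValueError("effects must be > -1 to keep SUVr positive")
        for phase, loadings in self.latent_loadings.items():
            unknown = set(loadings) - labels
            if unknown:
                raise ValueError(f"latent_loadings[{phase}] unknown labels: {sorted(unknown)[:5]}")


@dataclass(frozen=True)
class SimulatedStudy:
    """A generated cohort with its ground truth."""

    cohort: CohortTable
    early: SuvrMatrix
    late: SuvrMatrix
    truth: dict

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=1, sort_keys=True)


def _as_region_vector(value: float | Mapping[str, float], labels: list[str]) -> np.ndarray:
    if isinstance(value, Mapping):
        return np.array([value.get(lab, 1.0) for lab in labels], dtype=float)
    return np.full(len(labels), float(value))


def _noise_vector(value: float | Mapping[str, float], labels: list[str]) -> np.ndarray:
    if isinstance(value, Mapping):
        return np.array([value[lab] for lab in labels], dtype=float)
    return np.full(len(labels), float(value))


def generate_study(config: SimulationConfig, atlas: RegionAtlas | None = None) -> SimulatedStudy:
    """Draw one synthetic study; deterministic given ``config.seed``."""
    atlas = atlas or load_atlas()
    config.validate(atlas)
    labels = atlas.labels
    rng = np.random.default_rng(config.seed)

    rows = []
    u_values = []
    v_values = []
    informative = []
    fourrt_counter = 0
    sid = 0
    for sg in config.subgroups:
        # fixed sex composition (rounded to the configured fraction), shuffled:
        # matches tabulated counts and avoids single-sex draws in small groups
        n_female = int(round(sg.frac_female * sg.n))
        sexes = np.array(["F"] * n_female + ["M"] * (sg.n - n_female))
        rng.shuffle(sexes)
        for i_sub in range(sg.n):
            sid += 1
            subject = f"S{sid:04d}"
            age = float(np.clip(rng.normal(sg.age_mean, sg.age_sd), 40.0, 95.0))
            sex = str(sexes[i_sub])
            if sg.duration_mean is None:
                duration = np.nan
            else:
                duration = float(np.clip(rng.normal(sg.duration_mean, sg.duration_sd), 1.0, None))
            if sg.group != "HC":
                u = float(rng.normal())
                v = float(rng.normal())
            else:
                u = v = 0.0
            if config.split_phase_informative and sg.group == "FOURRT":
                phase_info = Phase.EARLY.value if fourrt_counter % 2 == 0 else Phase.LATE.value
                fourrt_counter += 1
            else:
                phase_info = "BOTH"
            rows.append({
                "subject_id": subject, "group": sg.group, "subgroup": sg.subgroup,
                "age": round(age, 1), "sex": sex,
                "disease_duration_months": round(duration, 1) if np.isfinite(duration) else np.nan,
                "site": sg.site, "_pattern": sg.pattern,
            })
            u_values.append(u)
            v_values.append(v)
            informative.append(phase_info)

    cohort_df = pd.DataFrame(rows)
    u_arr = np.array(u_values)
    v_arr = np.array(v_values)

    # clinical scores: group mean + slope*u + noise, truncated to valid range
    pre_trunc: dict[str, list[float]] = {}
    for score in ("pspr", "moca", "seadl"):
        coupling = config.clinical_coupling.get(score, ClinicalCoupling(0.0, 1.0))
        noise = rng.normal(0.0, coupling.noise_sd, size=len(cohort_df))
        vals = np.full(len(cohort_df), np.nan)
        for i, grp in enumerate(cohort_df["group"]):
            mean = config.group_score_means.get(grp, {}).get(score)
            if mean is not None:
                vals[i] = mean + coupling.slope * u_arr[i] + noise[i]
        pre_trunc[score] = [round(v, 2) if np.isfinite(v) else None for v in vals]
        lo, hi = SCORE_RANGES[score]
        cohort_df[score] = np.round(np.clip(vals, lo, hi), 2)

    cohort_df = cohort_df[
        ["subject_id", "group", "subgroup", "age", "sex",
         "disease_duration_months", "pspr", "moca", "seadl", "site", "_pattern"]
    ]

    matrices: dict[str, pd.DataFrame] = {}
    for phase, baseline in ((Phase.EARLY, config.baseline_early), (Phase.LATE, config.baseline_late)):
        mu = _as_region_vector(baseline, labels)
        sigma = _noise_vector(config.noise_sd, labels)
        b = np.array(
            [config.latent_loadings.get(phase.value, {}).get(lab, 0.0) for lab in labels]
        )
        n = len(cohort_df)
        label_pos = {lab: i for i, lab in enumerate(labels)}
        pattern_rows: dict[str, np.ndarray] = {}
        for pattern, phases in config.effect_table.items():
            row = np.zeros(len(labels))
            for lab, d in phases.get(phase.value, {}).items():
                row[label_pos[lab]] = d
            pattern_rows[pattern] = row
        delta = np.zeros((n, len(labels)))
        for i, (pattern, info) in enumerate(zip(cohort_df["_pattern"], informative)):
            if pattern not in pattern_rows:
                continue
            if info != "BOTH" and info != phase.value:
                continue
            delta[i] = pattern_rows[pattern]
        scale = np.array(
            [config.noise_scale_by_group.get(g, 1.0) for g in cohort_df["group"]]
        )
        gamma = config.amplitude_gamma.get(phase.value, 0.0)
        amp_factor = u_arr if phase is Phase.EARLY else v_arr
        amplitude = 1.0 + gamma * amp_factor
        eps = rng.standard_normal((n, len(labels)))
        values = mu * (1.0 + delta * amplitude[:, None]) \
            + np.outer(u_arr, b) + (scale[:, None] * sigma) * eps
        values = np.maximum(values, config.suvr_floor)
        matrices[phase.value] = pd.DataFrame(
            values, index=pd.Index(cohort_df["subject_id"], name="subject_id"), columns=labels
        )

    truth = {
        "seed": config.seed,
        "u": dict(zip(cohort_df["subject_id"], u_arr)),
        "v": dict(zip(cohort_df["subject_id"], v_arr)),
        "informative_phase": dict(zip(cohort_df["subject_id"], informative)),
        "pattern": dict(zip(cohort_df["subject_id"], cohort_df["_pattern"])),
        "pre_truncation_scores": {
            s: dict(zip(cohort_df["subject_id"], pre_trunc[s])) for s in pre_trunc
        },
        "effect_table": {p: {ph: dict(v) for ph, v in phases.items()}
                         for p, phases in config.effect_table.items()},
        "latent_loadings": {ph: dict(v) for ph, v in config.latent_loadings.items()},
        "amplitude_gamma": dict(config.amplitude_gamma),
        "clinical_coupling": {s: asdict(c) for s, c in config.clinical_coupling.items()},
        "baseline_early": config.baseline_early if not isinstance(config.baseline_early, Mapping)
        else dict(config.baseline_early),
        "baseline_late": config.baseline_late if not isinstance(config.baseline_late, Mapping)
        else dict(config.baseline_late),
        "noise_sd": config.noise_sd if not isinstance(config.noise_sd, Mapping)
        else dict(config.noise_sd),
    }

    cohort = CohortTable(cohort_df.drop(columns="_pattern"))
    return SimulatedStudy(
        cohort=cohort,
        early=SuvrMatrix(phase=Phase.EARLY, values=matrices[Phase.EARLY.value]),
        late=SuvrMatrix(phase=Phase.LATE, values=matrices[Phase.LATE.value]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# default scenarios
# ---------------------------------------------------------------------------

def _fourrt_early_effects(atlas: RegionAtlas) -> dict[str, float]:
    """Published target-region percent differences as planted fractions."""
    return {lab: atlas.targets.percent_diff[lab] / 100.0 for lab in atlas.targets.labels}


def _labels_by(atlas: RegionAtlas, compartment: str) -> list[str]:
    return [e.label for e in atlas.entries if e.compartment == compartment]


def _labels_with_prefix(atlas: RegionAtlas, prefixes: tuple[str, ...]) -> list[str]:
    return [lab for lab in atlas.labels if lab.split("_")[0] in prefixes]


# Frontal-gyrus subregion stems used for the FTLD-like frontal pattern.
_FRONTAL_STEMS = (
    "A8m", "A8dl", "A9l", "A6dl", "A6m", "A9m", "A10m",
    "A9/46d", "IFJ", "A46", "A9/46v", "A8vl", "A6vl", "A10l",
    "A44d", "IFS", "A45c", "A45r", "A44op", "A44v",
)
# Temporoparietal stems for the AD-like pattern.
_TEMPOROPARIETAL_STEMS = (
    "A39c", "A39rd", "A40rd", "A40c", "A39rv", "A40rv",
    "A7m", "A5m", "dmPOS", "A31",
    "A21c", "A21r", "A22c", "A22r",
)


def _paper_like_subgroups() -> tuple[SubgroupSpec, ...]:
    return (
        # training-site 4RT cohort, n = 78
        SubgroupSpec("FOURRT", "PSP-RS", 30, "fourrt", TRAINING_SITE, 71.2, 7.1, 0.50, 38.0, 28.6),
        SubgroupSpec("FOURRT", "PSP-CBS", 23, "fourrt", TRAINING_SITE, 71.2, 7.1, 0.50, 38.0, 28.6),
        SubgroupSpec("FOURRT", "CBS", 15, "fourrt", TRAINING_SITE, 71.2, 7.1, 0.50, 38.0, 28.6),
        SubgroupSpec("FOURRT", "other", 10, "fourrt", TRAINING_SITE, 71.2, 7.1, 0.50, 38.0, 28.6),
        # training-site other neurodegenerative diseases, n = 79
        SubgroupSpec("OTHER_ND", "AD", 47, "ad", TRAINING_SITE, 66.6, 11.6, 0.44, 32.0, 26.0),
        SubgroupSpec("OTHER_ND", "FTLD", 10, "ftld", TRAINING_SITE, 66.6, 11.6, 0.44, 32.0, 26.0),
        SubgroupSpec("OTHER_ND", "aSyn", 12, "asyn", TRAINING_SITE, 66.6, 11.6, 0.44, 32.0, 26.0),
        SubgroupSpec("OTHER_ND", "other", 10, "none", TRAINING_SITE, 66.6, 11.6, 0.44, 32.0, 26.0),
        # healthy controls, n = 12
        SubgroupSpec("HC", "HC", 12, "none", TRAINING_SITE, 68.5, 7.5, 0.67, None),
        # external validation site, n = 21 + 16
        SubgroupSpec("FOURRT", "PSP-RS", 17, "fourrt", EXTERNAL_SITE, 70.7, 5.8, 0.38, 49.4, 29.3),
        SubgroupSpec("FOURRT", "other", 4, "fourrt", EXTERNAL_SITE, 70.7, 5.8, 0.38, 49.4, 29.3),
        SubgroupSpec("OTHER_ND", "AD", 9, "ad", EXTERNAL_SITE, 67.7, 10.1, 0.44, 36.9, 22.0),
        SubgroupSpec("OTHER_ND", "FTLD", 5, "ftld", EXTERNAL_SITE, 67.7, 10.1, 0.44, 36.9, 22.0),
        SubgroupSpec("OTHER_ND", "other", 2, "none", EXTERNAL_SITE, 67.7, 10.1, 0.44, 36.9, 22.0),
    )


def _paper_like_effects(atlas: RegionAtlas) -> dict:
    subcortical = _labels_by(atlas, "Basal ganglia") + _labels_by(atlas, "Thalamus")
    return {
        "fourrt": {
            Phase.EARLY.value: _fourrt_early_effects(atlas),
            # late-phase tau accumulation concentrated subcortically (synthetic choice)
            Phase.LATE.value: {lab: 0.12 if atlas.compartment_of(lab) == "Basal ganglia" else 0.10
                               for lab in subcortical},
        },
        # distractor patterns are synthetic design choices, not published values
        "ad": {
            Phase.EARLY.value: {lab: -0.10 for lab in _labels_with_prefix(atlas, _TEMPOROPARIETAL_STEMS)},
            Phase.LATE.value: {lab: 0.25 for lab in _labels_with_prefix(atlas, _TEMPOROPARIETAL_STEMS)},
        },
        "ftld": {
            Phase.EARLY.value: {lab: -0.12 for lab in _labels_with_prefix(atlas, _FRONTAL_STEMS)},
            Phase.LATE.value: {lab: 0.05 for lab in _labels_with_prefix(atlas, _FRONTAL_STEMS)},
        },
        "asyn": {
            Phase.EARLY.value: {lab: -0.04 for lab in atlas.labels},
            Phase.LATE.value: {},
        },
    }


def _paper_like_clinical() -> tuple[dict, dict]:
    coupling = {
        "pspr": ClinicalCoupling(slope=6.0, noise_sd=12.0),
        "seadl": ClinicalCoupling(slope=-9.0, noise_sd=18.0),
        "moca": ClinicalCoupling(slope=0.0, noise_sd=5.5),
    }
    means = {
        "FOURRT": {"pspr": 30.0, "moca": 21.9, "seadl": 60.5},
        "OTHER_ND": {"pspr": 22.9, "moca": 20.3, "seadl": 68.7},
        "HC": {"moca": 28.9},
    }
    return coupling, means


def default_config(scenario: str, seed: int = 0, atlas: RegionAtlas | None = None) -> SimulationConfig:
    """Build the configuration for one of the named study scenarios.

    ``paper_like``
        Cohort sizes, demographics and 4RT early-phase effect sizes match the
        published study (78/79/12 training, 21/16 external); distractor and
        late-phase patterns are synthetic defaults.
    ``null``
        Same cohort layout with every effect, loading and coupling zeroed.
    ``separable``
        Large disjoint group effects on a wide normative band, so threshold
        classification is error-free.
    ``complementary``
        Each 4RT subject carries the disease effect in only one phase, so the
        combined perfusion+tau score must beat either single score.
    """
    atlas = atlas or load_atlas()
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")

    subgroups = _paper_like_subgroups()

    if scenario == "paper_like":
        coupling, means = _paper_like_clinical()
        return SimulationConfig(
            subgroups=subgroups,
            seed=seed,
            noise_sd=0.05,
            effect_table=_paper_like_effects(atlas),
            # per-subject pattern-amplitude heterogeneity: the perfusion
            # deficit deepens with clinical severity u, the tau pattern
            # scales with an independent burden factor v
            amplitude_gamma={Phase.EARLY.value: 0.5, Phase.LATE.value: 0.8},
            clinical_coupling=coupling,
            group_score_means=means,
        )

    if scenario == "null":
        _, means = _paper_like_clinical()
        return SimulationConfig(
            subgroups=subgroups, seed=seed, noise_sd=0.06,
            effect_table={}, latent_loadings={},
            clinical_coupling={}, group_score_means=means,
        )

    if scenario == "separable":
        from dataclasses import replace

        subcortical = _labels_by(atlas, "Basal ganglia") + _labels_by(atlas, "Thalamus")
        # every non-4RT disease expresses one shared pattern shifted AWAY from
        # the hypoperfusion direction on the target regions, so groups are
        # disjoint both region-wise and direction-wise
        sep_subgroups = tuple(
            replace(sg, pattern={"FOURRT": "fourrt", "OTHER_ND": "nd", "HC": "none"}[sg.group])
            for sg in subgroups
        )
        return SimulationConfig(
            subgroups=sep_subgroups, seed=seed, noise_sd=0.02,
            effect_table={
                "fourrt": {
                    Phase.EARLY.value: {lab: -0.5 for lab in atlas.targets.labels},
                    Phase.LATE.value: {lab: 0.5 for lab in subcortical},
                },
                "nd": {
                    Phase.EARLY.value: {lab: 0.3 for lab in atlas.targets.labels},
                    Phase.LATE.value: {lab: -0.3 for lab in subcortical},
                },
            },
            latent_loadings={}, clinical_coupling={},
            group_score_means=_paper_like_clinical()[1],
        )

    # complementary
    subcortical = _labels_by(atlas, "Basal ganglia") + _labels_by(atlas, "Thalamus")
    return SimulationConfig(
        subgroups=subgroups, seed=seed, noise_sd=0.06,
        effect_table={
            "fourrt": {
                Phase.EARLY.value: {lab: -0.25 for lab in atlas.targets.labels},
                Phase.LATE.value: {lab: 0.25 for lab in subcortical},
            },
            "ad": {Phase.EARLY.value: {}, Phase.LATE.value: {}},
            "ftld": {Phase.EARLY.value: {}, Phase.LATE.value: {}},
            "asyn": {Phase.EARLY.value: {}, Phase.LATE.value: {}},
        },
        latent_loadings={}, clinical_coupling={},
        group_score_means=_paper_like_clinical()[1],
        split_phase_informative=True,
    )
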