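"""End-to-end pipeline: simulate -> contrast -> classify -> pattern -> evaluate.

Every stage writes plain-text artifacts (CSV/JSON) into the run directory so
each step is independently inspectable, and a manifest records the config,
seed, library versions and per-stage row counts.  Identical config and seed
give identical CSV artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tauperf
from tauperf.atlas import load_atlas
from tauperf.core import (
    CohortTable, Phase, SuvrMatrix, read_cohort, read_suvr_matrix,
    write_cohort, write_suvr_matrix,
)
from tauperf.simulate import default_config, generate_study, SimulationConfig
from tauperf.contrast import build_contrast_table
from tauperf.classifier import evaluate_grid, DEFAULT_K_GRID, DEFAULT_M_GRID
from tauperf.pattern import (
    correlation_filter, fit_pattern_model, score_subjects, combine_scores,
)
from tauperf.evaluation import clinical_association_report, delong_paired_test, roc_auc


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (cohort/early/late CSV files) or
    ``scenario`` (synthetic-study name) must be given.
    """

    seed: int = 0
    output_dir: str = "tauperf_run"
    scenario: str | None = None
    input_paths: dict | None = None      # {"cohort": ..., "early": ..., "late": ...}
    q: float = 0.01
    k_grid: tuple = DEFAULT_K_GRID
    m_grid: tuple = DEFAULT_M_GRID
    targets: str = "discovered"          # "discovered" | "bundled"
    filter_rule: str = "max_abs"
    filter_threshold: float = 0.3
    regression: str = "logistic"
    include_hc_in_training: bool = False

    def validate(self) -> None:
        if (self.scenario is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of scenario or input_paths")
        if self.targets not in ("discovered", "bundled"):
            raise ValueError(f"unknown targets mode {self.targets!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.k_grid, list):
            cfg.k_grid = tuple(cfg.k_grid)
        if isinstance(cfg.m_grid, list):
            cfg.m_grid = tuple(cfg.m_grid)
        return cfg


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_all(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error aborts with the failing stage named in the exception;
    artifacts of completed stages are preserved.
    """
    config.validate()
    atlas = load_atlas()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "versions": {
            "tauperf": tauperf.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "notes": [],
    }

    def _stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {"wall_s": round(time.perf_counter() - t0, 3), **counts}
        return done

    # ---- stage: data ------------------------------------------------------
    done = _stage("data")
    try:
        if config.scenario is not None:
            sim = default_config(config.scenario, seed=config.seed, atlas=atlas)
            study = generate_study(sim, atlas)
            cohort, early, late = study.cohort, study.early, study.late
            write_cohort(cohort, outdir / "cohort.csv")
            write_suvr_matrix(early, outdir / "suvr_early.csv")
            write_suvr_matrix(late, outdir / "suvr_late.csv")
            (outdir / "truth.json").write_text(study.truth_json())
        else:
            paths = config.input_paths
            cohort = read_cohort(paths["cohort"])
            early = read_suvr_matrix(paths["early"], atlas, Phase.EARLY)
            late = read_suvr_matrix(paths["late"], atlas, Phase.LATE)
        done(n_subjects=len(cohort.table))
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    training = cohort.select(site="training") if "site" in cohort.table else cohort
    train_ids = set(training.subject_ids)

    # ---- stage: contrast --------------------------------------------------
    done = _stage("contrast")
    try:
        ct = build_contrast_table(early, training, q=config.q, atlas=atlas)
        ct.table.to_csv(outdir / "contrast_table.csv", index=False)
        _write_json(outdir / "contrast_summary.json", {
            "n_significant": ct.n_significant,
            "hemisphere_tally": ct.hemisphere_tally,
            "q": config.q,
        })
        done(n_regions=len(ct.table), n_significant=ct.n_significant)
    except Exception as exc:
        raise RuntimeError(f"stage 'contrast' failed: {exc}") from exc

    # ---- stage: classify --------------------------------------------------
    done = _stage("classify")
    try:
        if config.targets == "bundled":
            target_labels = list(atlas.targets.labels)
        else:
            sig = ct.table[(ct.table["significant"]) & (ct.table["percent_diff"] < 0)]
            target_labels = list(sig["label"])
        if target_labels:
            hc_ids = [sid for sid in training.select(group="HC").subject_ids
                      if sid in set(early.subject_ids)]
            hc_matrix = early.subset(hc_ids)
            grid = evaluate_grid(early, training, hc_matrix, target_labels,
                                 k_grid=config.k_grid, m_grid=config.m_grid)
            grid.to_csv(outdir / "grid_metrics.csv", index=False)
            from tauperf.classifier import classify_matrix, fit_thresholds
            model = fit_thresholds(hc_matrix, target_labels, k=config.k_grid[0])
            calls = classify_matrix(early, model, m=config.m_grid[0])
            calls.to_csv(outdir / "subject_calls.csv")
            done(n_targets=len(target_labels), n_grid_cells=len(grid))
        else:
            manifest["notes"].append("classify: no hypoperfusion target regions discovered")
            done(n_targets=0, n_grid_cells=0)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    # ---- stage: pattern ---------------------------------------------------
    done = _stage("pattern")
    try:
        pat_groups = ("FOURRT", "OTHER_ND", "HC") if config.include_hc_in_training \
            else ("FOURRT", "OTHER_ND")
        fit_cohort = training.select(group=pat_groups)
        fit_ids = [sid for sid in early.subject_ids if sid in set(fit_cohort.subject_ids)]
        y = (fit_cohort.subset(fit_ids).table["group"] == "FOURRT").to_numpy(dtype=float)
        all_patients = cohort.select(group=("FOURRT", "OTHER_ND"))
        score_ids = [sid for sid in early.subject_ids if sid in set(all_patients.subject_ids)]

        scores = pd.DataFrame(index=pd.Index(score_ids, name="subject_id"))
        models = {}
        for phase_name, matrix in (("perfusion", early), ("tau", late)):
            X_fit = matrix.values.loc[fit_ids]
            retained = correlation_filter(X_fit, threshold=config.filter_threshold,
                                          rule=config.filter_rule)
            if len(retained) < 2:
                manifest["notes"].append(
                    f"pattern ({phase_name}): fewer than 2 regions pass the "
                    "correlation filter; score unavailable")
                continue
            model = fit_pattern_model(X_fit[retained], y, phase=matrix.phase.value,
                                      regression=config.regression)
            models[phase_name] = model
            model.to_json(outdir / f"pattern_{phase_name}.json")
            scores[f"score_{phase_name}"] = score_subjects(
                matrix.values.loc[score_ids], model)
        if {"score_perfusion", "score_tau"} <= set(scores.columns):
            scores["score_combined"] = combine_scores(
                scores["score_perfusion"], scores["score_tau"])
        scores.to_csv(outdir / "scores.csv")
        done(n_scored=len(scores), n_models=len(models),
             n_components={k: m.n_components for k, m in models.items()})
    except Exception as exc:
        raise RuntimeError(f"stage 'pattern' failed: {exc}") from exc

    # ---- stage: evaluate --------------------------------------------------
    done = _stage("evaluate")
    try:
        roc_payload: dict = {}
        patients = all_patients.table.set_index("subject_id")
        for site_name in ("training", "external"):
            ids = [sid for sid in scores.index
                   if patients.loc[sid, "site"] == site_name]
            if not ids:
                continue
            ylab = (patients.loc[ids, "group"] == "FOURRT").to_numpy(dtype=int)
            if len(set(ylab)) < 2:
                continue
            site_block: dict = {}
            for col in scores.columns:
                res = roc_auc(scores.loc[ids, col], ylab)
                site_block[col] = {
                    "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "n_pos": res.n_pos, "n_neg": res.n_neg,
                }
            pairs = [("score_combined", "score_perfusion"),
                     ("score_combined", "score_tau"),
                     ("score_perfusion", "score_tau")]
            comparisons = {}
            for a, b in pairs:
                if a in scores.columns and b in scores.columns:
                    comparisons[f"{a}_vs_{b}"] = delong_paired_test(
                        scores.loc[ids, a], scores.loc[ids, b], ylab)
            site_block["comparisons"] = comparisons
            roc_payload[site_name] = site_block
        _write_json(outdir / "roc_results.json", roc_payload)

        if len(scores.columns):
            assoc = clinical_association_report(
                scores.loc[[sid for sid in scores.index
                            if sid in train_ids]], training)
            assoc.to_csv(outdir / "clinical_associations.csv", index=False)
            done(n_roc_sites=len(roc_payload), n_assoc_cells=len(assoc))
        else:
            manifest["notes"].append("evaluate: no scores available")
            done(n_roc_sites=len(roc_payload), n_assoc_cells=0)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    _write_json(outdir / "manifest.json", manifest)
    return outdir
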