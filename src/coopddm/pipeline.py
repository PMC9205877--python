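"""End-to-end orchestration: generation -> cleaning -> ANOVAs -> mixed model
-> DDM decomposition -> report, with a run manifest for reproducibility.

Every stage writes plain CSV into the output directory; the manifest records
the config hash, root seed, stage timings and file checksums.  Given the same
config and seed, every output byte is reproducible except the timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import stats as gs
from .cohort import generate_study
from .config import StudyConfig
from .ddm import (
    DriftDiffusionModel,
    FitConfig,
    cohort_nested_comparison,
    group_parameter_tests,
    nested_comparison,
)

__all__ = ["RunManifest", "StageError", "run_all", "fit_cohort_ddm", "cohort_model_comparison"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True), encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_config(cfg: StudyConfig, jitter_seed: int = 0) -> FitConfig:
    f = cfg.fit
    return FitConfig(restarts=f.restarts, rt_floor=f.rt_floor, min_trials=f.min_trials,
                     objective=f.objective, jitter_seed=jitter_seed)


def fit_cohort_ddm(valid: pd.DataFrame, cfg: StudyConfig):
    """Per-subject tied and bias-free fits across stimulation conditions.

    Returns (per-subject parameter table from the bias-free model, the list
    of (fixed, free) result pairs for the cohort chi-square).
    """
    rows = []
    pairs = []
    for k, (sid, sub) in enumerate(valid.groupby("subject_id")):
        model = DriftDiffusionModel.from_dataframe(
            sub, group_col=cfg.fit.grouping, fit_config=_fit_config(cfg, jitter_seed=k))
        fixed = model.fit()
        free = model.fit(free="b", warm_start=fixed)
        pairs.append((fixed, free))
        for lev, p in free.params_by_level.items():
            rows.append({"subject_id": sid, "condition": lev, "a": p.a, "b": p.b,
                         "v": p.v, "t0": p.t0, "deviance": free.deviance,
                         "converged": free.converged})
    return pd.DataFrame(rows), pairs


def cohort_model_comparison(valid: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Seven-model nested scan at the cohort level.

    Each parameter is freed in turn across the grouping factor's levels; the
    cohort statistic sums the per-subject deviance differences, with summed
    degrees of freedom.
    """
    rows = []
    subjects = list(valid.groupby("subject_id"))
    models = [
        DriftDiffusionModel.from_dataframe(
            sub, group_col=cfg.fit.grouping, fit_config=_fit_config(cfg, jitter_seed=k))
        for k, (_, sub) in enumerate(subjects)
    ]
    base_fixed = [m.fit() for m in models]
    for name in cfg.fit.free_params:
        pairs = []
        for m, f0 in zip(models, base_fixed):
            if name in ("eta", "sz", "st"):
                from .ddm import ModelSpec, BASE_PARAMS

                fixed = m.fit(ModelSpec(include=BASE_PARAMS + (name,), free=None), warm_start=f0)
            else:
                fixed = f0
            free = m.fit(free=name, warm_start=fixed if fixed.spec.free is None else None)
            pairs.append((fixed, free))
        c = cohort_nested_comparison(pairs)
        rows.append({"free_parameter": name, "chi2": c.statistic, "df": c.df, "p": c.p,
                     "n_subjects": len(models)})
    return pd.DataFrame(rows)


def run_all(cfg: StudyConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Run the full pipeline and write all result tables plus a report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg.canonical_yaml().encode()).hexdigest(),
        seed=seed,
    )
    report: list[str] = ["# Study pipeline report", ""]

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t = time.perf_counter()

            def __exit__(self, et, ev, tb):
                if ev is not None:
                    manifest.stage_seconds[name] = round(time.perf_counter() - self.t, 3)
                    manifest.write(out / "manifest.json")
                    raise StageError(name, ev) from ev
                manifest.stage_seconds[name] = round(time.perf_counter() - self.t, 3)

        return _Ctx()

    with stage("simulate"):
        ds = generate_study(
            n_subjects=cfg.cohort.n_subjects,
            effect=cfg.cohort.effect.to_effect(),
            seed=seed,
            trait_config=cfg.cohort.traits.to_traits(),
            payoff=cfg.task.payoff.to_matrix(),
            p_cooperative=cfg.task.p_cooperative,
            p_deceitful=cfg.task.p_deceitful,
            p_random=cfg.task.p_random,
            tft_first_move=cfg.task.tft_first_move,
            time_limit_s=cfg.task.time_limit_s,
        )
        cio.write_trials(ds.trials, out / "trials.csv")
        cio.write_table(ds.profiles, out / "profiles.csv")
        cio.write_table(ds.likability, out / "likability.csv")
        (out / "generation_manifest.json").write_text(
            json.dumps(ds.manifest, indent=2, sort_keys=True, default=str), encoding="utf-8")
        report += [f"Simulated cohort: {cfg.cohort.n_subjects} subjects, "
                   f"{len(ds.trials)} trials, seed {seed}.", ""]

    with stage("clean"):
        trials = cio.read_trials(out / "trials.csv")
        valid, exclusions = gs.clean_trials(trials)
        cio.write_table(exclusions, out / "exclusions.csv")
        report += [f"Trial cleaning: {int(exclusions.n_excluded.sum())} invalid trials discarded "
                   f"of {len(trials)}.", ""]

    with stage("anova"):
        coop, rt = gs.cooperation_table(valid)
        profiles = cio.read_profiles(out / "profiles.csv")
        likability = cio.read_likability(out / "likability.csv")
        anovas = []
        for name, table, dv in (
            ("cooperation", coop, "percent_cooperation"),
            ("reaction_time", rt, "mean_rt_s"),
            ("likability", _likability_cells(likability, profiles), "sam_likability"),
            ("total_points", gs.cell_table(valid, valid["points_subject"], "points", "sum"), "points"),
        ):
            a = gs.rm_anova_2x2(table, dv).assign(dependent=name)
            anovas.append(a)
        anova = pd.concat(anovas, ignore_index=True)
        cio.write_table(anova, out / "anova.csv")
        coop_summary = coop.groupby("stim_condition")["percent_cooperation"].agg(["mean", "sem"])
        report += ["## Repeated-measures ANOVAs", "",
                   "Cooperation (%) by condition (mean +/- SEM):",
                   coop_summary.round(2).to_string(), "",
                   anova.round(4).to_string(index=False), ""]

    with stage("mixed_model"):
        mm = gs.mixed_logit_cooperation(valid, profiles, likability,
                                        r2_threshold=cfg.stats.r2_threshold, agq=cfg.stats.agq)
        coef = mm.coef.reset_index(names="term")
        cio.write_table(coef, out / "mixed_model.csv")
        report += ["## Mixed-effects logistic regression (random intercept: subject)", "",
                   f"random-intercept SD: {mm.result.sigma:.4f}; "
                   f"residual df: {mm.result.df_resid}",
                   coef.round(4).to_string(index=False), ""]
        if len(mm.screen_report):
            report += ["Dropped by collinearity screen:",
                       mm.screen_report.to_string(index=False), ""]

    with stage("correlations"):
        eff = gs.stimulation_effect_per_subject(coop)
        prof_i = profiles.set_index("subject_id").loc[eff.index]
        rows = []
        if len(eff) >= 3:  # correlations are undefined for smoke-sized cohorts
            for trait in ("neuroticism", "extraversion"):
                c = gs.correlate(prof_i[f"neo_{trait}"], eff, "spearman")
                rows.append({"covariate": trait, "method": "spearman",
                             "R": c.coefficient, "p": c.p})
            clin = gs.clinical_correlations(profiles, eff).assign(method="pearson")
        else:
            clin = pd.DataFrame(columns=["covariate", "R", "p", "method"])
        corr = pd.concat([pd.DataFrame(rows, columns=["covariate", "method", "R", "p"]), clin],
                         ignore_index=True)
        cio.write_table(corr, out / "correlations.csv")
        affect = gs.affect_ttests(profiles)
        cio.write_table(affect, out / "affect_ttests.csv")
        report += ["## Post-hoc correlations of the stimulation effect",
                   corr.round(4).to_string(index=False), "",
                   "## Affect (PANAS) paired t-tests",
                   affect.round(4).to_string(index=False), ""]

    with stage("power"):
        sd = eff.std(ddof=1)
        n_req = gs.sample_size_cooperation(eff.mean(), sd, cfg.stats.alpha, cfg.stats.power_target)
        txt = (f"paired-t sample size: effect {eff.mean():.3f} pp, SD {sd:.3f} pp, "
               f"alpha {cfg.stats.alpha}, power {cfg.stats.power_target} -> minimum n = {n_req}\n")
        (out / "power.txt").write_text(txt, encoding="utf-8")
        report += ["## Sample-size computation (from this cohort as pilot)", txt]

    with stage("ddm"):
        params_df, pairs = fit_cohort_ddm(valid, cfg)
        cio.write_table(params_df, out / "ddm_params.csv")
        cohort_bias = cohort_nested_comparison(pairs)
        scan = cohort_model_comparison(valid, cfg)
        cio.write_table(scan, out / "model_comparison.csv")
        if params_df.subject_id.nunique() >= 3:
            tests = group_parameter_tests(params_df, bonferroni_m=cfg.stats.bonferroni_m)
        else:  # group inference needs >= 3 subjects; smoke runs skip it
            tests = pd.DataFrame(columns=["test", "condition", "parameter", "mean",
                                          "t", "p_raw", "cohens_d", "n", "p_bonferroni"])
        cio.write_table(tests, out / "ddm_group_tests.csv")
        report += ["## Drift-diffusion decomposition", "",
                   f"cohort chi-square (starting bias free): chi2 = {cohort_bias.statistic:.2f}, "
                   f"df = {cohort_bias.df}, p = {cohort_bias.p:.4g}", "",
                   scan.round(4).to_string(index=False), "",
                   tests.round(4).to_string(index=False), ""]

    with stage("report"):
        (out / "report.md").write_text("\n".join(report) + "\n", encoding="utf-8")
        for f in sorted(out.glob("*")):
            if f.name != "manifest.json" and f.is_file():
                manifest.files[f.name] = _sha256(f)
        manifest.write(out / "manifest.json")
    return manifest


def _likability_cells(likability: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Likability per (subject, condition, opponent class), mapping sessions
    to conditions through each subject's counterbalanced order."""
    df = likability.merge(profiles[["subject_id", "condition_order"]], on="subject_id")
    tvns_s1 = df["condition_order"] == "tvns_first"
    s1 = df["session_index"] == 1
    df["stim_condition"] = np.where(tvns_s1 == s1, "tvns", "sham")
    return (
        df.groupby(["subject_id", "stim_condition", "opponent_class"], as_index=False)
        .agg(sam_likability=("sam_likability", "mean"))
    )
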