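"""Group-level statistical analysis chain for the cooperation study.

Implements the full pipeline applied to a trial log: cleaning of invalid
trials, the per-cell cooperation (and reaction-time) tables, the 2x2
within-subject ANOVA with paired effect sizes, the collinearity-screened
mixed-effects logistic regression of trial-level choice with stimulation
interactions, post-hoc correlations, the affect t-tests and the pilot-based
paired-t sample-size computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import BinomialRandomIntercept, BinomialRandomInterceptResults

__all__ = [
    "CleaningError",
    "clean_trials",
    "cooperation_table",
    "cell_table",
    "rm_anova_2x2",
    "cohens_d_paired",
    "select_features",
    "build_design",
    "mixed_logit_cooperation",
    "stimulation_effect_per_subject",
    "correlate",
    "CorrelationResult",
    "clinical_correlations",
    "sample_size_cooperation",
    "affect_ttests",
]


class CleaningError(ValueError):
    pass


def clean_trials(trials: pd.DataFrame):
    """Drop invalid trials (undefined key or over the time limit).

    Returns the valid subset and a per-(subject, condition) exclusion report.
    Raises if any subject x condition cell would be left empty.
    """
    report = (
        trials.assign(excluded=~trials["valid"].astype(bool))
        .groupby(["subject_id", "stim_condition"], as_index=False)
        .agg(n_trials=("excluded", "size"), n_excluded=("excluded", "sum"))
    )
    report["n_valid"] = report["n_trials"] - report["n_excluded"]
    empty = report[report["n_valid"] == 0]
    if len(empty):
        cells = [f"{r.subject_id}/{r.stim_condition}" for r in empty.itertuples()]
        raise CleaningError(f"no valid trials left in cell(s): {cells}")
    valid = trials[trials["valid"].astype(bool)].copy()
    return valid, report


def cell_table(valid: pd.DataFrame, value: pd.Series, dv_name: str, how: str = "mean") -> pd.DataFrame:
    """Aggregate a per-trial value into the (subject, condition, opponent
    class) cells used by every repeated-measures analysis."""
    df = valid.assign(_dv=np.asarray(value, dtype=float))
    out = (
        df.groupby(["subject_id", "stim_condition", "opponent_class"], as_index=False)
        .agg(**{dv_name: ("_dv", how), "n_valid": ("_dv", "size")})
    )
    return out


def cooperation_table(valid: pd.DataFrame):
    """Percentage of cooperation, and mean RT, per (subject, stimulation,
    opponent class) cell of the cleaned trial log."""
    coop = cell_table(valid, (valid["subject_choice"] == "cooperate") * 100.0, "percent_cooperation")
    rt = cell_table(valid, valid["subject_rt_s"], "mean_rt_s")
    return coop, rt


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d (d_z): mean of differences over SD of differences.

    Equal vectors give 0; a constant nonzero difference gives signed
    infinity, the degenerate-case flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if np.isclose(d.mean(), 0.0) else float(np.copysign(np.inf, d.mean()))
    return float(d.mean() / sd)


def rm_anova_2x2(table: pd.DataFrame, dv: str,
                 factors: Sequence[str] = ("stim_condition", "opponent_class")) -> pd.DataFrame:
    """2x2 within-subject ANOVA (statsmodels AnovaRM) with paired Cohen's d.

    ``table`` holds one row per subject x cell.  Returns one row per effect
    (each factor and their interaction) with F, df pair, p and d.
    """
    f1, f2 = factors
    need = {"subject_id", f1, f2, dv}
    if not need.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    wide = table.pivot_table(index="subject_id", columns=[f1, f2], values=dv)
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("incomplete design: every subject needs all 4 cells")
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 subjects")

    from statsmodels.stats.anova import AnovaRM

    fit = AnovaRM(table, depvar=dv, subject="subject_id", within=list(factors)).fit()
    at = fit.anova_table

    l1 = sorted(table[f1].unique())
    l2 = sorted(table[f2].unique())
    m1 = [wide.xs(lev, axis=1, level=0).mean(axis=1) for lev in l1]
    m2 = [wide.xs(lev, axis=1, level=1).mean(axis=1) for lev in l2]
    inter = (wide[(l1[1], l2[1])] - wide[(l1[1], l2[0])]) - (wide[(l1[0], l2[1])] - wide[(l1[0], l2[0])])
    contrasts = {
        f1: (m1[1] - m1[0]).to_numpy(),
        f2: (m2[1] - m2[0]).to_numpy(),
        f"{f1}:{f2}": inter.to_numpy(),
    }
    ds = {
        f1: cohens_d_paired(m1[1], m1[0]),
        f2: cohens_d_paired(m2[1], m2[0]),
        f"{f1}:{f2}": cohens_d_paired(inter, np.zeros(len(inter))),
    }
    rows = []
    for effect in (f1, f2, f"{f1}:{f2}"):
        key = effect.replace(":", ":")
        F = float(at.loc[key, "F Value"])
        p = float(at.loc[key, "Pr > F"])
        # In a 2x2 within design F equals the squared paired t of the
        # per-subject contrast; a degenerate (constant) contrast makes the
        # OLS ratio 0/0, which we resolve explicitly.
        c = contrasts[effect]
        if c.std(ddof=1) < 1e-10 * max(1.0, float(np.abs(wide.to_numpy()).max())):
            F, p = (0.0, 1.0) if abs(c.mean()) < 1e-10 else (np.inf, 0.0)
        elif not np.isfinite(F):
            F, p = 0.0, 1.0
        rows.append({
            "effect": effect, "F": F,
            "df1": int(at.loc[key, "Num DF"]), "df2": int(at.loc[key, "Den DF"]),
            "p": p, "cohens_d": ds[effect],
        })
    return pd.DataFrame(rows)


def select_features(design: pd.DataFrame, r2_threshold: float = 0.7):
    """Collinearity screen: while any pair of predictors has squared Pearson
    correlation strictly above the threshold, drop one member of the worst
    pair — the one with the larger mean absolute correlation to all other
    predictors (ties broken by column order, later column dropped).

    Returns (retained DataFrame, report DataFrame of dropped columns).
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate predictors")
    dropped = []
    while True:
        X = design[cols]
        corr = X.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        r2 = corr**2
        i, j = np.unravel_index(np.nanargmax(r2), r2.shape)
        if not (r2[i, j] > r2_threshold):
            break
        mean_abs = np.nanmean(np.abs(corr), axis=1)
        if mean_abs[i] > mean_abs[j]:
            drop = i
        elif mean_abs[j] > mean_abs[i]:
            drop = j
        else:
            drop = max(i, j)
        dropped.append({"dropped": cols[drop], "partner": cols[i if drop == j else j],
                        "r2": float(r2[i, j])})
        cols.pop(drop)
    return design[cols], pd.DataFrame(dropped, columns=["dropped", "partner", "r2"])


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def build_design(valid: pd.DataFrame, profiles: pd.DataFrame, likability: pd.DataFrame,
                 r2_threshold: float = 0.7):
    """Trial-level design matrix for the mixed-effects logistic regression.

    Main effects: stimulation, opponent characteristics (likability, strategy
    dummies with the cooperative style as reference, last decision of the
    opponent), subject characteristics (sex, age, the five NEO traits,
    believed-live) and time (trial index, standardised).  Binary predictors
    are coded +/-0.5 and continuous ones z-scored, then the collinearity
    screen runs on the main effects, and stimulation interactions are added
    for every retained non-stimulation predictor.

    Returns (y, X DataFrame with intercept, groups, screen report).
    """
    df = valid.merge(
        likability[["subject_id", "session_index", "opponent_id", "sam_likability"]],
        on=["subject_id", "session_index", "opponent_id"], how="left", validate="m:1",
    ).merge(profiles, on="subject_id", how="left", validate="m:1")
    df = df.sort_values(["subject_id", "session_index", "trial_index"]).reset_index(drop=True)

    # last decision of this opponent toward this subject in this session
    prev = (
        df.groupby(["subject_id", "session_index", "opponent_id"], sort=False)["opponent_choice"]
        .shift(1)
    )
    last_opp = prev.map({"cooperate": 0.5, "deceive": -0.5}).fillna(0.0)

    main = pd.DataFrame({
        "stimulation": np.where(df["stim_condition"] == "tvns", 0.5, -0.5),
        "likability": _zscore(df["sam_likability"].astype(float)),
        "strategy_deceitful": (df["opponent_policy"] == "deceitful") * 1.0,
        "strategy_titfortat": (df["opponent_policy"] == "titfortat") * 1.0,
        "strategy_random": (df["opponent_policy"] == "random") * 1.0,
        "last_opponent_cooperated": last_opp,
        "sex_female": np.where(df["sex"] == "female", 0.5, -0.5),
        "age": _zscore(df["age"].astype(float)),
        "neuroticism": _zscore(df["neo_neuroticism"].astype(float)),
        "extraversion": _zscore(df["neo_extraversion"].astype(float)),
        "openness": _zscore(df["neo_openness"].astype(float)),
        "agreeableness": _zscore(df["neo_agreeableness"].astype(float)),
        "conscientiousness": _zscore(df["neo_conscientiousness"].astype(float)),
        "believed_live": np.where(df["believed_live"].astype(bool), 0.5, -0.5),
        "time": _zscore(df["trial_index"].astype(float)),
    })
    retained, report = select_features(main, r2_threshold)
    X = retained.copy()
    for col in retained.columns:
        if col != "stimulation" and "stimulation" in retained.columns:
            X[f"stimulation:{col}"] = retained["stimulation"] * retained[col]
    X.insert(0, "intercept", 1.0)
    y = (df["subject_choice"] == "cooperate").to_numpy(dtype=float)
    return y, X, df["subject_id"].to_numpy(), report


@dataclass
class MixedModelResult:
    result: BinomialRandomInterceptResults
    coef: pd.DataFrame
    screen_report: pd.DataFrame

    def summary(self) -> str:
        s = self.result.summary()
        if len(self.screen_report):
            s += "\n\ndropped by collinearity screen:\n" + self.screen_report.to_string(index=False)
        return s


def mixed_logit_cooperation(valid: pd.DataFrame, profiles: pd.DataFrame,
                            likability: pd.DataFrame, r2_threshold: float = 0.7,
                            agq: int = 7, penalty: float = 0.0) -> MixedModelResult:
    """Mixed-effects logistic regression of trial-level cooperation with a
    subject random intercept and stimulation-by-predictor interactions."""
    y, X, groups, report = build_design(valid, profiles, likability, r2_threshold)
    model = BinomialRandomIntercept(y, X.to_numpy(), groups, exog_names=list(X.columns),
                                    agq=agq, penalty=penalty)
    res = model.fit()
    return MixedModelResult(result=res, coef=res.coef_table(), screen_report=report)


def stimulation_effect_per_subject(coop_table: pd.DataFrame,
                                   dv: str = "percent_cooperation") -> pd.Series:
    """Per-subject stimulation effect: tVNS minus sham cooperation percentage
    (cells averaged over opponent class)."""
    means = coop_table.groupby(["subject_id", "stim_condition"])[dv].mean().unstack()
    return (means["tvns"] - means["sham"]).rename("stim_effect")


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p: float


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p; Spearman uses
    average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, coefficient=float(r), p=float(p))


def clinical_correlations(profiles: pd.DataFrame, effect: pd.Series) -> pd.DataFrame:
    """Pearson / point-biserial correlations of the per-subject stimulation
    effect with clinical covariates."""
    prof = profiles.set_index("subject_id").loc[effect.index]
    covs = {
        "disease_duration": prof["disease_duration"].astype(float),
        "time_since_last_seizure": prof["time_since_last_seizure"].astype(float),
        "affected_hemisphere": (prof["affected_hemisphere"] == "left").astype(float),
        "medicated": prof["medicated"].astype(bool).astype(float),
    }
    rows = []
    for name, x in covs.items():
        try:
            c = correlate(x.to_numpy(), effect.to_numpy(), "pearson")
            rows.append({"covariate": name, "R": c.coefficient, "p": c.p})
        except ValueError:
            rows.append({"covariate": name, "R": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def _paired_t_power(n: int, effect_size: float, alpha: float) -> float:
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    ncp = effect_size * np.sqrt(n)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_cooperation(pilot_mean_diff: float, pilot_sd: float,
                            alpha: float = 0.05, power: float = 0.95,
                            n_max: int = 100000) -> int:
    """Smallest n for which a two-sided paired t-test at level ``alpha``
    reaches the requested power for effect size pilot_mean_diff / pilot_sd
    (noncentral-t power curve)."""
    if pilot_sd <= 0:
        raise ValueError("pilot_sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    es = abs(pilot_mean_diff) / pilot_sd
    if es == 0:
        raise ValueError("effect size 0: required sample size is unbounded")
    for n in range(2, n_max + 1):
        if _paired_t_power(n, es, alpha) >= power:
            return n
    raise ValueError(f"required n exceeds {n_max}")


def affect_ttests(profiles: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of tVNS vs sham PANAS positive and negative affect.

    Session scores are mapped to conditions via each subject's
    counterbalanced condition order.
    """
    need = {"condition_order", "panas_positive_session1", "panas_negative_session1",
            "panas_positive_session2", "panas_negative_session2"}
    if not need.issubset(profiles.columns):
        raise ValueError(f"profiles must include {sorted(need)}")
    tvns_is_s1 = profiles["condition_order"] == "tvns_first"
    rows = []
    for scale in ("positive", "negative"):
        s1 = profiles[f"panas_{scale}_session1"].astype(float)
        s2 = profiles[f"panas_{scale}_session2"].astype(float)
        tvns = np.where(tvns_is_s1, s1, s2)
        sham = np.where(tvns_is_s1, s2, s1)
        diff = tvns - sham
        if diff.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if np.isclose(diff.mean(), 0) else (np.copysign(np.inf, diff.mean()), 0.0)
        else:
            t, p = sps.ttest_rel(tvns, sham)
        rows.append({"scale": scale, "mean_tvns": tvns.mean(), "mean_sham": sham.mean(),
                     "t": float(t), "p": float(p), "n": len(profiles)})
    return pd.DataFrame(rows)
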