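"""Synthetic study generator.

Builds a complete crossover study — subject profiles, two counterbalanced
sessions (tVNS / sham) of 120 prisoner's-dilemma trials each — with choices
and response times generated by a drift-diffusion process whose starting bias
and drift shift under tVNS.  The stimulation effect on the starting bias is
modulated by the subject's (standardised) neuroticism and extraversion, which
plants the trait-by-stimulation interaction the downstream mixed model is
meant to recover.

Default effect sizes are calibrated so that cohort-mean cooperation sits near
43.4% under tVNS and 37.2% under sham, the sham starting bias is exactly 0.5,
and the sham drift is negative (toward deception).  Trait distributions are
generator plumbing: they emulate the shape of a small clinical cohort (n=19,
mostly female, mean age 45 +/- 12) but are not estimates of any real sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import task
from .task import Choice, PayoffMatrix, DEFAULT_PAYOFF
from .wfpt import DDMParams, simulate

__all__ = [
    "TraitConfig",
    "EffectConfig",
    "StudyDataset",
    "generate_profiles",
    "agent_params",
    "simulate_choice_rt",
    "generate_study",
]


@dataclass(frozen=True)
class TraitConfig:
    """Distributions for subject covariates (generator plumbing)."""

    age_mean: float = 45.0
    age_sd: float = 12.0
    age_range: tuple = (18.0, 90.0)
    p_female: float = 13 / 19
    neo_mean: float = 50.0  # T-score-like scale for all five NEO domains
    neo_sd: float = 10.0
    neo_range: tuple = (0.0, 100.0)
    p_believed_live: float = 12 / 19
    panas_positive_mean: float = 17.6
    panas_positive_sd: float = 4.5
    panas_negative_mean: float = 18.4
    panas_negative_sd: float = 3.9
    disease_duration_mean: float = 20.0
    disease_duration_sd: float = 10.0
    seizure_free_mean: float = 5.0
    seizure_free_sd: float = 4.0
    p_medicated: float = 0.9

    def validate(self) -> None:
        for name in ("age_sd", "neo_sd", "panas_positive_sd", "panas_negative_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_female", "p_believed_live", "p_medicated"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1] or self.neo_range[0] >= self.neo_range[1]:
            raise ValueError("ranges must be increasing (low, high)")


@dataclass(frozen=True)
class EffectConfig:
    """Generative diffusion parameters and planted stimulation effects.

    The starting bias under tVNS for a subject with standardised traits
    (z_neuroticism, z_extraversion) is

        0.5 + bias_shift_tvns * (1 + neuroticism_modulation * z_n
                                   + extraversion_modulation * z_e)

    clipped to ``bias_clip``; under sham it is exactly 0.5.  Drift under tVNS
    is shifted by ``drift_shift_tvns`` (toward zero, from a negative sham
    baseline).  ``subject_drift_sd`` is the between-subject SD of baseline
    drift.  Calibration constants live here, not in code.
    """

    boundary: float = 1.6
    nondecision: float = 0.35
    drift_sham: float = -0.3463
    bias_shift_tvns: float = 0.075
    drift_shift_tvns: float = 0.011
    neuroticism_modulation: float = -0.9
    extraversion_modulation: float = 0.2
    subject_drift_sd: float = 0.32
    bias_clip: tuple = (0.05, 0.95)
    invalid_rate: float = 0.0035  # undefined-key trials, ~16 per 4560
    reciprocity: float = 0.0  # drift decrement on trials after being deceived
    dt: float = 1e-3
    bridge: bool = False
    likability_human_mean: float = 6.2
    likability_computer_mean: float = 4.2
    likability_sd: float = 1.3

    def validate(self) -> None:
        if self.boundary <= 0 or self.nondecision < 0:
            raise ValueError("boundary must be > 0 and nondecision >= 0")
        if self.subject_drift_sd < 0 or self.likability_sd < 0:
            raise ValueError("variances must be nonnegative")
        if not 0 <= self.invalid_rate < 1:
            raise ValueError("invalid_rate must be in [0, 1)")
        lo, hi = self.bias_clip
        if not (0 < lo < 0.5 < hi < 1):
            raise ValueError("bias_clip must straddle 0.5 inside (0, 1)")


@dataclass
class StudyDataset:
    profiles: pd.DataFrame
    trials: pd.DataFrame
    likability: pd.DataFrame
    manifest: dict


def generate_profiles(n_subjects: int, trait_config: TraitConfig = TraitConfig(),
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw subject profiles (traits, beliefs, affect, clinical covariates)."""
    if n_subjects < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subjects}")
    trait_config.validate()
    rng = rng if rng is not None else np.random.default_rng()
    tc = trait_config

    def trunc_normal(mean, sd, lo, hi, size):
        x = rng.normal(mean, sd, size)
        bad = (x < lo) | (x > hi)
        while bad.any():  # redraw out-of-range values
            x[bad] = rng.normal(mean, sd, bad.sum())
            bad = (x < lo) | (x > hi)
        return x

    n = n_subjects
    rows = {
        "subject_id": [f"s{i + 1:02d}" for i in range(n)],
        "age": np.round(trunc_normal(tc.age_mean, tc.age_sd, *tc.age_range, size=n), 1),
        "sex": np.where(rng.random(n) < tc.p_female, "female", "male"),
    }
    for dom in ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness"):
        rows[f"neo_{dom}"] = np.round(trunc_normal(tc.neo_mean, tc.neo_sd, *tc.neo_range, size=n), 1)
    rows["believed_live"] = rng.random(n) < tc.p_believed_live
    for s in (1, 2):
        rows[f"panas_positive_session{s}"] = np.round(
            np.clip(rng.normal(tc.panas_positive_mean, tc.panas_positive_sd, n), 10, 50), 0)
        rows[f"panas_negative_session{s}"] = np.round(
            np.clip(rng.normal(tc.panas_negative_mean, tc.panas_negative_sd, n), 10, 50), 0)
    rows["disease_duration"] = np.round(
        trunc_normal(tc.disease_duration_mean, tc.disease_duration_sd, 1.0, 60.0, n), 1)
    rows["time_since_last_seizure"] = np.round(
        trunc_normal(tc.seizure_free_mean, tc.seizure_free_sd, 1.0, 40.0, n), 1)
    rows["affected_hemisphere"] = np.where(rng.random(n) < 0.5, "left", "right")
    rows["medicated"] = rng.random(n) < tc.p_medicated
    # latent baseline-drift deviation: generator-internal subject random effect
    rows["latent_drift_re"] = rng.standard_normal(n)
    return pd.DataFrame(rows)


def _z(profile_row, trait: str, tc: TraitConfig) -> float:
    return (float(profile_row[f"neo_{trait}"]) - tc.neo_mean) / tc.neo_sd


def agent_params(profile_row, stim_condition: str, effect: EffectConfig = EffectConfig(),
                 trait_config: TraitConfig = TraitConfig()) -> DDMParams:
    """Diffusion parameters for one subject in one stimulation condition.

    Deterministic given the profile: the subject's latent baseline-drift
    deviation is part of the profile, so any session can be regenerated in
    isolation.
    """
    effect.validate()
    if stim_condition not in ("tvns", "sham"):
        raise ValueError(f"unknown stimulation condition {stim_condition!r}")
    v = effect.drift_sham + effect.subject_drift_sd * float(profile_row["latent_drift_re"])
    if stim_condition == "tvns":
        zn = _z(profile_row, "neuroticism", trait_config)
        ze = _z(profile_row, "extraversion", trait_config)
        shift = effect.bias_shift_tvns * (
            1.0 + effect.neuroticism_modulation * zn + effect.extraversion_modulation * ze
        )
        b = float(np.clip(0.5 + shift, *effect.bias_clip))
        v = v + effect.drift_shift_tvns
    else:
        b = 0.5
    a = effect.boundary
    return DDMParams(a=a, z=b * a, v=v, t0=effect.nondecision)


def simulate_choice_rt(params: DDMParams, rng: np.random.Generator, n: int = 1,
                       dt: float = 1e-3, bridge: bool = False):
    """Draw (choice, rt) pairs from the diffusion; upper boundary = COOPERATE."""
    upper, rt = simulate(params, n, rng, dt=dt, bridge=bridge)
    choices = np.where(upper, Choice.COOPERATE, Choice.DECEIVE)
    if n == 1:
        return choices[0], float(rt[0])
    return choices, rt


class _DiffusionAgent:
    """Session agent: plays pre-simulated diffusion decisions in order, with
    optional reciprocity (drift reduced on trials following a deception by
    the current opponent) and injected invalid responses."""

    def __init__(self, params: DDMParams, rng: np.random.Generator, n_trials: int,
                 effect: EffectConfig):
        self.params = params
        self.rng = rng
        self.effect = effect
        if effect.reciprocity == 0.0:
            upper, rt = simulate(params, n_trials, rng, dt=effect.dt, bridge=effect.bridge)
            self._pre = list(zip(upper.tolist(), rt.tolist()))
        else:
            self._pre = None
        self._invalid = rng.random(n_trials) < effect.invalid_rate
        self._i = 0

    def __call__(self, spec, history):
        i = self._i
        self._i += 1
        if self._pre is not None:
            up, rt = self._pre[i]
        else:
            p = self.params
            if history and history[-1][1] is Choice.DECEIVE:
                p = p.replace(v=p.v - self.effect.reciprocity)
            up, rt = simulate(p, 1, self.rng, dt=self.effect.dt, bridge=self.effect.bridge)
            up, rt = bool(up[0]), float(rt[0])
        if self._invalid[i]:
            return None, rt  # undefined key press
        return (Choice.COOPERATE if up else Choice.DECEIVE), rt


def generate_study(
    n_subjects: int = 19,
    effect: EffectConfig = EffectConfig(),
    seed: int = 0,
    trait_config: TraitConfig = TraitConfig(),
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
    p_cooperative: float = 0.7,
    p_deceitful: float = 0.3,
    p_random: float = 0.5,
    tft_first_move: str = "mirror",
    time_limit_s: float = 10.0,
) -> StudyDataset:
    """Generate the full crossover study.

    Condition order is counterbalanced (the two order groups differ by at
    most one subject) and every randomness source derives from ``seed`` via
    spawned per-subject/per-session streams, so any session is reproducible
    in isolation.
    """
    effect.validate()
    root = np.random.SeedSequence(seed)
    ss_profiles, ss_order, ss_sessions, ss_lik = root.spawn(4)
    profiles = generate_profiles(n_subjects, trait_config, np.random.default_rng(ss_profiles))

    order_rng = np.random.default_rng(ss_order)
    tvns_first = np.zeros(n_subjects, dtype=bool)
    tvns_first[order_rng.permutation(n_subjects)[: n_subjects // 2]] = True
    profiles = profiles.assign(condition_order=np.where(tvns_first, "tvns_first", "sham_first"))

    opponents = task.build_opponents(p_cooperative, p_deceitful, p_random, tft_first_move)
    session_seeds = ss_sessions.spawn(n_subjects * 2)
    all_trials: list[task.Trial] = []
    for i, row in profiles.iterrows():
        for session_index in (1, 2):
            cond = ("tvns" if session_index == 1 else "sham") if tvns_first[i] else (
                "sham" if session_index == 1 else "tvns")
            rng = np.random.default_rng(session_seeds[2 * i + (session_index - 1)])
            schedule = task.schedule_session(opponents, rng)
            params = agent_params(row, cond, effect, trait_config)
            agent = _DiffusionAgent(params, rng, len(schedule), effect)
            all_trials.extend(
                task.play_session(
                    agent, opponents, schedule, payoff, rng,
                    subject_id=row["subject_id"], session_index=session_index,
                    stim_condition=cond, time_limit_s=time_limit_s,
                )
            )

    lik_rng = np.random.default_rng(ss_lik)
    lik_rows = []
    for _, row in profiles.iterrows():
        for session_index in (1, 2):
            for spec in opponents:
                mean = (effect.likability_human_mean if spec.opponent_class == "human"
                        else effect.likability_computer_mean)
                sam = int(np.clip(np.round(lik_rng.normal(mean, effect.likability_sd)), 1, 9))
                lik_rows.append({
                    "subject_id": row["subject_id"], "session_index": session_index,
                    "opponent_id": spec.id, "opponent_class": spec.opponent_class,
                    "sam_likability": sam,
                })

    from .io import trials_to_frame

    return StudyDataset(
        profiles=profiles,
        trials=trials_to_frame(all_trials),
        likability=pd.DataFrame(lik_rows),
        manifest={"seed": seed, "n_subjects": n_subjects,
                  "effect_config": asdict(effect), "trait_config": asdict(trait_config),
                  "payoff": asdict(payoff), "time_limit_s": time_limit_s},
    )
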