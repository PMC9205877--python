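"""Iterated prisoner's dilemma task engine.

One session pits the player against 8 opponents (4 labelled as humans, 4 as
computers) over 120 trials, 15 per opponent, in seeded random order.  Each
opponent follows one of four decision policies: cooperative (cooperates with
probability 0.7), deceitful (cooperates with probability 0.3), tit-for-tat
(repeats the player's previous choice against it) and random (0.5).  Points
are awarded from a 2x2 payoff matrix in which deception strictly dominates
cooperation cell-wise, while mutual cooperation outscores mutual deception.

The tit-for-tat first move is configurable.  The default, ``"mirror"``,
matches the player's own choice on the first encounter; it is the unique
convention under which the closed-form session expectations for the
always-deceive and always-cooperate player policies reproduce the task's
documented totals of 1725 and 1500 points simultaneously.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Choice",
    "ConfigError",
    "DataError",
    "UnsupportedPolicyError",
    "PayoffMatrix",
    "OpponentSpec",
    "Trial",
    "build_opponents",
    "schedule_session",
    "opponent_decide",
    "play_session",
    "expected_session_points",
    "max_expected_session_points",
]

N_TRIALS_PER_OPPONENT = 15
POLICIES = ("cooperative", "deceitful", "titfortat", "random")
OPPONENT_CLASSES = ("human", "computer")


class ConfigError(ValueError):
    """Invalid task configuration."""


class DataError(ValueError):
    """Invalid data produced by an agent or found in a trial log."""


class UnsupportedPolicyError(ValueError):
    """Player policy that cannot be reduced to a closed-form expectation."""


class Choice(str, enum.Enum):
    COOPERATE = "cooperate"
    DECEIVE = "deceive"

    @property
    def other(self) -> "Choice":
        return Choice.DECEIVE if self is Choice.COOPERATE else Choice.COOPERATE


@dataclass(frozen=True)
class PayoffMatrix:
    """Points to the *player* for each (player choice, opponent choice) pair.

    The opponent's payoff is the mirror image (the game is symmetric), so the
    four cells fully specify the game.
    """

    cc: int  # both cooperate
    cd: int  # player cooperates, opponent deceives
    dc: int  # player deceives, opponent cooperates
    dd: int  # both deceive

    def points(self, player: Choice, opponent: Choice) -> int:
        if player is Choice.COOPERATE:
            return self.cc if opponent is Choice.COOPERATE else self.cd
        return self.dc if opponent is Choice.COOPERATE else self.dd

    def points_to_opponent(self, player: Choice, opponent: Choice) -> int:
        return self.points(opponent, player)

    def check_deception_dominant(self) -> None:
        """Raise unless deceiving strictly beats cooperating against either
        opponent choice (the task's design constraint)."""
        if not (self.dc > self.cc and self.dd > self.cd):
            raise ConfigError(
                "payoff matrix violates deception dominance: requires dc > cc and dd > cd, "
                f"got cc={self.cc}, cd={self.cd}, dc={self.dc}, dd={self.dd}"
            )


#: Payoff cells consistent with the task's documented session totals
#: (maximum 2175, always-deceive 1725, always-cooperate 1500).
DEFAULT_PAYOFF = PayoffMatrix(cc=20, cd=0, dc=30, dd=5)


@dataclass(frozen=True)
class OpponentSpec:
    id: str
    opponent_class: str  # "human" | "computer"
    policy: str  # one of POLICIES
    p_cooperate: Optional[float] = None  # for cooperative/deceitful/random
    tft_first_move: str = "mirror"  # "mirror" | "cooperate" | "deceive"

    def __post_init__(self) -> None:
        if self.opponent_class not in OPPONENT_CLASSES:
            raise ConfigError(f"unknown opponent class {self.opponent_class!r}")
        if self.policy not in POLICIES:
            raise ConfigError(f"unknown policy {self.policy!r}")
        if self.policy != "titfortat":
            p = self.p_cooperate
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigError(
                    f"cooperation probability for policy {self.policy!r} must be in [0, 1], got {p}"
                )
        if self.tft_first_move not in ("mirror", "cooperate", "deceive"):
            raise ConfigError(f"unknown tft_first_move {self.tft_first_move!r}")


@dataclass
class Trial:
    subject_id: str
    session_index: int
    stim_condition: str  # "tvns" | "sham"
    trial_index: int  # 1..120
    opponent_id: str
    opponent_class: str
    opponent_policy: str
    decision_order: str  # "subject_first" | "opponent_first"
    subject_choice: Optional[Choice]
    opponent_choice: Choice
    subject_rt: Optional[float]
    opponent_rt: float
    points_subject: int
    cumulative_points: int
    valid: bool


def build_opponents(
    p_cooperative: float = 0.7,
    p_deceitful: float = 0.3,
    p_random: float = 0.5,
    tft_first_move: str = "mirror",
) -> list[OpponentSpec]:
    """The 8 default opponents: each of the four policies once per class."""
    specs = []
    probs = {
        "cooperative": p_cooperative,
        "deceitful": p_deceitful,
        "random": p_random,
        "titfortat": None,
    }
    for klass in OPPONENT_CLASSES:
        for policy in POLICIES:
            specs.append(
                OpponentSpec(
                    id=f"{klass}_{policy}",
                    opponent_class=klass,
                    policy=policy,
                    p_cooperate=probs[policy],
                    tft_first_move=tft_first_move,
                )
            )
    return specs


def schedule_session(
    opponents: Sequence[OpponentSpec],
    rng: np.random.Generator,
    n_per_opponent: int = N_TRIALS_PER_OPPONENT,
) -> list[tuple[int, str, str]]:
    """Seeded random trial order: each opponent ``n_per_opponent`` times, with
    a pseudo-random per-trial decision order.  Returns (trial_index,
    opponent_id, decision_order) tuples, trial_index starting at 1."""
    ids = [spec.id for spec in opponents for _ in range(n_per_opponent)]
    order = rng.permutation(len(ids))
    first = rng.random(len(ids)) < 0.5
    return [
        (i + 1, ids[j], "subject_first" if f else "opponent_first")
        for i, (j, f) in enumerate(zip(order, first))
    ]


_UNSET = object()


def opponent_decide(
    spec: OpponentSpec,
    history: Sequence[tuple[Optional[Choice], Choice]],
    rng: np.random.Generator,
    subject_current=_UNSET,
) -> Choice:
    """Opponent's choice given the prior (subject, opponent) pairs against it.

    Tit-for-tat repeats the subject's most recent valid choice; on the first
    encounter it plays its configured first move, where ``"mirror"`` requires
    the subject's same-trial choice (``subject_current``).  Passing
    ``subject_current=None`` marks an invalid subject response, in which case
    a mirroring first move falls back to cooperation.
    """
    if spec.policy in ("cooperative", "deceitful", "random"):
        return Choice.COOPERATE if rng.random() < spec.p_cooperate else Choice.DECEIVE
    # tit-for-tat: last valid subject choice, skipping invalid (missing) ones
    for subj, _ in reversed(history):
        if subj is not None:
            return subj
    if spec.tft_first_move == "cooperate":
        return Choice.COOPERATE
    if spec.tft_first_move == "deceive":
        return Choice.DECEIVE
    if subject_current is _UNSET:
        raise DataError(
            "tit-for-tat first move is 'mirror' but the subject's current choice was not supplied"
        )
    if subject_current is None:  # invalid subject response on the first encounter
        return Choice.COOPERATE
    return subject_current


Agent = Callable[[OpponentSpec, Sequence[tuple[Optional[Choice], Choice]]], tuple[Optional[Choice], Optional[float]]]


def play_session(
    agent: Agent,
    opponents: Sequence[OpponentSpec],
    schedule: Sequence[tuple[int, str, str]],
    payoff: PayoffMatrix,
    rng: np.random.Generator,
    *,
    subject_id: str = "s01",
    session_index: int = 1,
    stim_condition: str = "sham",
    time_limit_s: float = 10.0,
    opponent_rt_bounds: tuple[float, float] = (1.0, 3.0),
) -> list[Trial]:
    """Play one full session.

    ``agent`` is called with the opponent spec and the history against that
    opponent and must return ``(choice, rt_seconds)``; ``choice=None`` marks
    an invalid response (undefined key).  A trial is invalid when the choice
    is missing or the response time exceeds ``time_limit_s``; invalid trials
    score no points.
    """
    by_id = {spec.id: spec for spec in opponents}
    histories: dict[str, list[tuple[Optional[Choice], Choice]]] = {o: [] for o in by_id}
    lo, hi = opponent_rt_bounds
    trials: list[Trial] = []
    cumulative = 0
    for trial_index, opp_id, decision_order in schedule:
        spec = by_id[opp_id]
        history = histories[opp_id]
        subj_choice, subj_rt = agent(spec, history)
        if subj_rt is not None and subj_rt <= 0:
            raise DataError(f"agent returned non-positive RT {subj_rt} on trial {trial_index}")
        opp_choice = opponent_decide(spec, history, rng, subject_current=subj_choice)
        opp_rt = float(rng.uniform(lo, hi))
        valid = subj_choice is not None and subj_rt is not None and subj_rt <= time_limit_s
        points = payoff.points(subj_choice, opp_choice) if valid else 0
        cumulative += points
        trials.append(
            Trial(
                subject_id=subject_id,
                session_index=session_index,
                stim_condition=stim_condition,
                trial_index=trial_index,
                opponent_id=opp_id,
                opponent_class=spec.opponent_class,
                opponent_policy=spec.policy,
                decision_order=decision_order,
                subject_choice=subj_choice,
                opponent_choice=opp_choice,
                subject_rt=subj_rt,
                opponent_rt=opp_rt,
                points_subject=points,
                cumulative_points=cumulative,
                valid=valid,
            )
        )
        histories[opp_id].append((subj_choice if valid else None, opp_choice))
    return trials


def _as_constant_choice(policy) -> Choice:
    if isinstance(policy, Choice):
        return policy
    if isinstance(policy, str):
        alias = {
            "always_cooperate": Choice.COOPERATE,
            "always_deceive": Choice.DECEIVE,
            "cooperate": Choice.COOPERATE,
            "deceive": Choice.DECEIVE,
        }
        if policy in alias:
            return alias[policy]
    raise UnsupportedPolicyError(
        f"expected a constant player policy (Choice or 'always_cooperate'/'always_deceive'), got {policy!r}"
    )


def expected_session_points(
    policy,
    opponents: Sequence[OpponentSpec],
    payoff: PayoffMatrix,
    n_per_opponent: int = N_TRIALS_PER_OPPONENT,
) -> float:
    """Exact expected total points for a player who always plays ``policy``.

    Stochastic opponents contribute their Bernoulli expectation per trial;
    tit-for-tat responses are fully determined by the player's constant choice
    and the first-move convention.
    """
    c = _as_constant_choice(policy)
    total = 0.0
    for spec in opponents:
        if spec.policy == "titfortat":
            if spec.tft_first_move == "mirror":
                first = c
            else:
                first = Choice.COOPERATE if spec.tft_first_move == "cooperate" else Choice.DECEIVE
            total += payoff.points(c, first) + (n_per_opponent - 1) * payoff.points(c, c)
        else:
            p = spec.p_cooperate
            per_trial = p * payoff.points(c, Choice.COOPERATE) + (1 - p) * payoff.points(c, Choice.DECEIVE)
            total += n_per_opponent * per_trial
    return total


def max_expected_session_points(
    opponents: Sequence[OpponentSpec],
    payoff: PayoffMatrix,
    n_per_opponent: int = N_TRIALS_PER_OPPONENT,
    mode: str = "myopic",
) -> float:
    """Best attainable expected total.

    ``mode="myopic"`` plays the per-trial best response, treating tit-for-tat
    as echoing the player's current choice (so each trial against it yields
    ``max(cc, dd)``); this is the task's documented "maximal possible" total.
    ``mode="lookahead"`` solves tit-for-tat by backward induction instead,
    which additionally exploits a final-trial defection.
    """
    if mode not in ("myopic", "lookahead"):
        raise ConfigError(f"unknown mode {mode!r}")
    total = 0.0
    for spec in opponents:
        if spec.policy == "titfortat":
            if mode == "myopic":
                total += n_per_opponent * max(
                    payoff.points(Choice.COOPERATE, Choice.COOPERATE),
                    payoff.points(Choice.DECEIVE, Choice.DECEIVE),
                )
            else:
                total += _tft_optimal_points(spec, payoff, n_per_opponent)
        else:
            p = spec.p_cooperate
            per_trial = max(
                p * payoff.points(ch, Choice.COOPERATE) + (1 - p) * payoff.points(ch, Choice.DECEIVE)
                for ch in Choice
            )
            total += n_per_opponent * per_trial
    return total


def _tft_optimal_points(spec: OpponentSpec, payoff: PayoffMatrix, n: int) -> float:
    # value[t][opp_next] with backward induction; "mirror" means the first
    # opponent move copies the player's own first move.
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(t: int, opp: Choice) -> float:
        if t == n:
            return 0.0
        return max(payoff.points(m, opp) + best(t + 1, m) for m in Choice)

    if spec.tft_first_move == "mirror":
        return max(payoff.points(m, m) + best(1, m) for m in Choice)
    first = Choice.COOPERATE if spec.tft_first_move == "cooperate" else Choice.DECEIVE
    return best(0, first)
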