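"""PVL-Delta, PVL-DecayRI and VPP models of Iowa Gambling Task choice.

All three models share the same skeleton: a prospect-theory utility maps
each trial's scaled net outcome to a subjective value, a learning rule
updates per-deck expectancies, and a softmax with trial-independent
sensitivity ``theta = 3**c - 1`` turns deck values into choice
probabilities. The two PVL variants differ only in the learning rule
(delta / Rescorla-Wagner vs. decay-reinforcement); VPP augments PVL-Delta
with a win-stay/lose-switch-like perseverance strength and mixes the two
value signals with an RL weight ``w``.

Parameters (native scale):

=========  ==========  =========================================
name       support     meaning
=========  ==========  =========================================
A          (0, 1)      learning rate (delta) / recency (decay)
alpha      (0, 2)      utility curvature (outcome sensitivity)
c          (0, 5)      choice consistency; theta = 3**c - 1
lam        (0, 10)     loss aversion
eps_p      real        perseverance impact of a gain   (VPP)
eps_n      real        perseverance impact of a loss   (VPP)
k          (0, 1)      perseverance decay              (VPP)
w          (0, 1)      RL weight in the value mix      (VPP)
=========  ==========  =========================================

Initial expectancies and perseverance strengths are zero, so the first
trial's choice is uniform. An outcome of exactly zero takes the gain
branch in both the utility and the perseverance update.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax

from . import _kernels
from .schedule import PayoffSchedule, DECKS, CARDS_PER_DECK


class ModelKind(enum.Enum):
    """The three candidate choice models."""

    PVL_DELTA = "pvl-delta"
    PVL_DECAY = "pvl-decay"
    VPP = "vpp"

    @property
    def code(self) -> int:
        return {"pvl-delta": _kernels.PVL_DELTA,
                "pvl-decay": _kernels.PVL_DECAY,
                "vpp": _kernels.VPP}[self.value]

    @property
    def param_names(self) -> tuple[str, ...]:
        if self is ModelKind.VPP:
            return ("A", "alpha", "c", "lam", "eps_p", "eps_n", "k", "w")
        return ("A", "alpha", "c", "lam")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @classmethod
    def parse(cls, name: "ModelKind | str") -> "ModelKind":
        if isinstance(name, cls):
            return name
        key = str(name).lower().replace("_", "-")
        aliases = {"pvl-delta": cls.PVL_DELTA, "pvldelta": cls.PVL_DELTA,
                   "pvl-decay": cls.PVL_DECAY, "pvl-decayri": cls.PVL_DECAY,
                   "pvldecay": cls.PVL_DECAY, "vpp": cls.VPP}
        if key not in aliases:
            raise ValueError(f"unknown model {name!r}")
        return aliases[key]


#: native-scale bounds of the bounded parameters
PARAM_BOUNDS = {"A": (0.0, 1.0), "alpha": (0.0, 2.0), "c": (0.0, 5.0),
                "lam": (0.0, 10.0), "k": (0.0, 1.0), "w": (0.0, 1.0)}


@dataclass
class SubjectParameters:
    """Native-scale parameters of one subject (VPP fields default to inert)."""

    A: float
    alpha: float
    c: float
    lam: float
    eps_p: float = 0.0
    eps_n: float = 0.0
    k: float = 0.0
    w: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.alpha, self.c, self.lam,
                         self.eps_p, self.eps_n, self.k, self.w])

    def validate(self, model: ModelKind | None = None) -> "SubjectParameters":
        for name in ("A", "alpha", "c", "lam", "k", "w"):
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"parameter {name}={v} outside [{lo}, {hi}]")
        return self

    @classmethod
    def from_array(cls, arr, model: ModelKind) -> "SubjectParameters":
        return cls(**dict(zip(model.param_names, np.asarray(arr, float))))


@dataclass
class ChoiceSequence:
    """One subject's trial sequence: 1-based deck choices and scaled nets."""

    choices: np.ndarray          # int, deck 1..4 per trial
    net_outcomes: np.ndarray     # scaled net outcome per trial
    card_indices: np.ndarray | None = None  # 1-based card position served

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.net_outcomes = np.asarray(self.net_outcomes, dtype=float)
        if self.choices.shape != self.net_outcomes.shape:
            raise ValueError("choices and net_outcomes must have equal length")
        if self.T == 0:
            raise ValueError("empty choice sequence")
        if self.choices.min() < 1 or self.choices.max() > 4:
            raise ValueError("deck indices must lie in 1..4")

    @property
    def T(self) -> int:
        return len(self.choices)


def prospect_utility(x, alpha: float, lam: float):
    """Prospect-theory utility of a (scaled) net outcome.

    u = x**alpha for x >= 0, and -lam * |x|**alpha for x < 0. ``alpha``
    bends the curve (diminishing sensitivity); ``lam`` scales losses
    relative to gains (lam > 1 means losses loom larger).
    """
    _check_bound("alpha", alpha)
    _check_bound("lam", lam)
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, np.abs(x) ** alpha, -lam * np.abs(x) ** alpha)
    return out.item() if out.ndim == 0 else out


def _check_bound(name: str, v: float) -> None:
    lo, hi = PARAM_BOUNDS[name]
    if not (lo <= v <= hi):
        raise ValueError(f"parameter {name}={v} outside [{lo}, {hi}]")


def delta_update(E, chosen_deck: int, u: float, A: float) -> np.ndarray:
    """Rescorla-Wagner update: only the chosen deck moves toward u."""
    _check_bound("A", A)
    E = np.asarray(E, dtype=float).copy()
    j = _deck_to_index(chosen_deck)
    E[j] += A * (u - E[j])
    return E


def decay_update(E, chosen_deck: int, u: float, A: float) -> np.ndarray:
    """Decay-reinforcement update: all decks decay, the chosen one gains u."""
    _check_bound("A", A)
    E = A * np.asarray(E, dtype=float)
    E[_deck_to_index(chosen_deck)] += u
    return E


def perseverance_update(P, chosen_deck: int, outcome_sign: float, k: float,
                        eps_p: float, eps_n: float) -> np.ndarray:
    """Decay all perseverance strengths; bump the chosen deck by eps_p/eps_n."""
    _check_bound("k", k)
    P = k * np.asarray(P, dtype=float)
    P[_deck_to_index(chosen_deck)] += eps_p if outcome_sign >= 0 else eps_n
    return P


def combine_value(E, P, w: float) -> np.ndarray:
    """VPP value signal: w * expectancy + (1 - w) * perseverance."""
    _check_bound("w", w)
    return w * np.asarray(E, dtype=float) + (1.0 - w) * np.asarray(P, dtype=float)


def sensitivity_from_consistency(c: float) -> float:
    """Softmax sensitivity theta = 3**c - 1; 0 (random) to 242 (deterministic)."""
    _check_bound("c", c)
    return 3.0 ** c - 1.0


def choice_probabilities(values, theta: float) -> np.ndarray:
    """Softmax over deck values, computed via overflow-safe log-sum-exp."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("deck values must be finite")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return np.exp(log_softmax(theta * values))


def _deck_to_index(deck) -> int:
    """Accept 1..4 integers or A..D letters; return a 0-based index."""
    if isinstance(deck, str):
        if deck not in DECKS:
            raise ValueError(f"unknown deck {deck!r}")
        return DECKS.index(deck)
    deck = int(deck)
    if not 1 <= deck <= 4:
        raise ValueError(f"deck index {deck} outside 1..4")
    return deck - 1


def subject_log_likelihood(model: ModelKind | str, params: SubjectParameters,
                           data: ChoiceSequence) -> tuple[float, np.ndarray]:
    """Total log-likelihood of a sequence plus the per-trial log densities.

    Trial t's choice probability uses the state accumulated through trial
    t - 1 (all-zero expectancies before the first trial).
    """
    model = ModelKind.parse(model)
    params.validate(model)
    per_trial = np.empty(data.T)
    total = _kernels.loglik_trials(model.code, params.as_array(),
                                   data.choices - 1, data.net_outcomes, per_trial)
    return total, per_trial


def net_table(schedule: PayoffSchedule) -> np.ndarray:
    """(4, 60) array of per-deck net outcomes on the schedule's scale."""
    return np.stack([schedule.net(d) for d in DECKS])


def simulate_subject(model: ModelKind | str, params: SubjectParameters,
                     schedule: PayoffSchedule, T: int = 100,
                     rng_seed: int = 0) -> ChoiceSequence:
    """Play one agent against the schedule for T trials.

    Outcomes are served per deck in card order, recycling the final block
    once a deck's 60 cards are exhausted. Deterministic given ``rng_seed``.
    """
    model = ModelKind.parse(model)
    params.validate(model)
    if T < 1:
        raise ValueError("T must be >= 1")
    choices, outcomes, cards = _kernels.simulate_choices(
        model.code, params.as_array(), net_table(schedule), T, rng_seed % 2**31)
    return ChoiceSequence(choices=choices + 1, net_outcomes=outcomes,
                          card_indices=cards)
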