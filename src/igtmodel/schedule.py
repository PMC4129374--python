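"""Payoff schedule of the modified Iowa Gambling Task.

The task presents four decks of cards. Decks A and B are disadvantageous
(long-run losing) and decks C and D are advantageous (long-run winning).
Each deck holds 60 cards organised in six blocks of ten. Within every
block, decks A and C carry five loss cards (50% punishment frequency)
while decks B and D carry one (10%). Block-level net outcomes escalate:
decks A/B lose $250 in block 1, growing by $150 per block up to $1000 in
block 6; decks C/D gain $250 in block 1, growing by $25 up to $375.

Per-card gains are the classic constant amounts: $100 per card for A/B
and $50 for C/D. Per-block loss totals are back-computed from the block
net identity ``net = gains - losses`` and split equally over the loss
cards of the block (the escalation is carried entirely by the losses).
With those amounts the single largest block-1 net gain is +100 and the
single largest block-1 net loss is -1150, so dividing by 100 reproduces
the +1 / -11.5 calibration used for cognitive modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DECKS = ("A", "B", "C", "D")
DISADVANTAGEOUS = ("A", "B")
ADVANTAGEOUS = ("C", "D")

#: fraction of loss-bearing cards per 10-card block
LOSS_FREQUENCY = {"A": 0.5, "B": 0.1, "C": 0.5, "D": 0.1}

#: constant per-card gain for each deck (task currency)
CARD_GAIN = {"A": 100.0, "B": 100.0, "C": 50.0, "D": 50.0}

#: divisor that maps the highest block-1 net gain to 1 (and the largest
#: block-1 net loss to -11.5)
DEFAULT_DIVISOR = 100.0

N_BLOCKS = 6
BLOCK_SIZE = 10
CARDS_PER_DECK = N_BLOCKS * BLOCK_SIZE

# canonical within-block positions (1-based) of the loss cards
_CANONICAL_LOSS_POSITIONS = {5: (3, 5, 7, 9, 10), 1: (9,)}


def block_net(deck: str, block: int) -> float:
    """Prescribed total net outcome of one 10-card block (block in 1..6)."""
    if deck in DISADVANTAGEOUS:
        return -(250.0 + 150.0 * (block - 1))
    return 250.0 + 25.0 * (block - 1)


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-deck card sequences of gains and losses.

    Attributes
    ----------
    gains, losses : dict mapping deck label to a length-60 float array.
        Losses are stored as non-positive numbers; ``net = gain + loss``.
    divisor : scale already applied to the net outcomes (1.0 = raw currency).
    """

    gains: dict[str, np.ndarray]
    losses: dict[str, np.ndarray]
    divisor: float = 1.0

    def net(self, deck: str) -> np.ndarray:
        return (self.gains[deck] + self.losses[deck]) / self.divisor

    def draw_card(self, deck: str, draw_index: int) -> float:
        """Net outcome of the card at 1-based position ``draw_index``.

        Positions beyond card 60 recycle the block-6 contingencies, since
        the task runs up to 100 trials while each deck holds 60 cards.
        """
        if deck not in DECKS:
            raise ValueError(f"unknown deck label {deck!r}; expected one of {DECKS}")
        if draw_index < 1:
            raise ValueError("draw_index must be >= 1")
        idx = draw_index - 1
        if idx >= CARDS_PER_DECK:
            idx = CARDS_PER_DECK - BLOCK_SIZE + (idx - CARDS_PER_DECK) % BLOCK_SIZE
        return self.net(deck)[idx]

    def card(self, deck: str, draw_index: int) -> tuple[float, float]:
        """(gain, loss) of the card served at ``draw_index`` (raw scale times 1/divisor)."""
        if deck not in DECKS:
            raise ValueError(f"unknown deck label {deck!r}; expected one of {DECKS}")
        idx = draw_index - 1
        if idx >= CARDS_PER_DECK:
            idx = CARDS_PER_DECK - BLOCK_SIZE + (idx - CARDS_PER_DECK) % BLOCK_SIZE
        return (self.gains[deck][idx] / self.divisor, self.losses[deck][idx] / self.divisor)

    def block_index(self, draw_index: int) -> int:
        """1-based block number of a 1-based card position (no recycling)."""
        if draw_index < 1:
            raise ValueError("draw_index must be >= 1")
        return (draw_index - 1) // BLOCK_SIZE + 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns deck, card_index, block, gain, loss, net."""
        rows = []
        for deck in DECKS:
            g = self.gains[deck] / self.divisor
            l = self.losses[deck] / self.divisor
            for i in range(CARDS_PER_DECK):
                rows.append((deck, i + 1, i // BLOCK_SIZE + 1, g[i], l[i], g[i] + l[i]))
        return pd.DataFrame(rows, columns=["deck", "card_index", "block", "gain", "loss", "net"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PayoffSchedule":
        df = pd.read_csv(path)
        required = {"deck", "card_index", "gain", "loss"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"schedule file missing columns: {sorted(missing)}")
        gains, losses = {}, {}
        for deck in DECKS:
            sub = df[df["deck"] == deck].sort_values("card_index")
            if len(sub) != CARDS_PER_DECK:
                raise ValueError(f"deck {deck}: expected {CARDS_PER_DECK} cards, got {len(sub)}")
            gains[deck] = sub["gain"].to_numpy(float)
            losses[deck] = sub["loss"].to_numpy(float)
        return cls(gains=gains, losses=losses, divisor=1.0)


def build_schedule(loss_placement: str = "canonical", seed: int | None = None) -> PayoffSchedule:
    """Construct the modified-IGT payoff schedule (raw task currency).

    Parameters
    ----------
    loss_placement : "canonical" or "seeded-shuffle".
        Canonical placement puts loss cards at fixed within-block positions
        and is identical across calls; seeded-shuffle permutes the loss
        positions uniformly within each block (block totals are unchanged).
    seed : required for seeded-shuffle.
    """
    if loss_placement not in ("canonical", "seeded-shuffle"):
        raise ValueError("loss_placement must be 'canonical' or 'seeded-shuffle'")
    if loss_placement == "seeded-shuffle" and seed is None:
        raise ValueError("seed is required for seeded-shuffle loss placement")
    rng = np.random.default_rng(seed) if loss_placement == "seeded-shuffle" else None

    gains, losses = {}, {}
    for deck in DECKS:
        gain = CARD_GAIN[deck]
        n_loss = round(LOSS_FREQUENCY[deck] * BLOCK_SIZE)
        g = np.full(CARDS_PER_DECK, gain)
        l = np.zeros(CARDS_PER_DECK)
        for b in range(1, N_BLOCKS + 1):
            # block loss total from net = gains - losses
            loss_total = BLOCK_SIZE * gain - block_net(deck, b)
            per_card = -loss_total / n_loss
            if rng is not None:
                pos = rng.choice(BLOCK_SIZE, size=n_loss, replace=False) + 1
            else:
                pos = _CANONICAL_LOSS_POSITIONS[n_loss]
            for p in pos:
                l[(b - 1) * BLOCK_SIZE + (p - 1)] = per_card
        gains[deck] = g
        losses[deck] = l
    return PayoffSchedule(gains=gains, losses=losses, divisor=1.0)


def scale_net_outcomes(schedule: PayoffSchedule, divisor: float = DEFAULT_DIVISOR) -> PayoffSchedule:
    """Return a copy of ``schedule`` with all outcomes divided by ``divisor``.

    The default divisor of 100 calibrates block 1 so that the highest
    single-card net gain becomes 1 and the largest net loss becomes -11.5.
    """
    if not divisor > 0:
        raise ValueError(f"divisor must be > 0, got {divisor}")
    return PayoffSchedule(gains=schedule.gains, losses=schedule.losses,
                          divisor=schedule.divisor * divisor)
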