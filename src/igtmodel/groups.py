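"""Behavioral net scores and Bayesian group contrasts.

The behavioral IGT measure is the net score per block of 20 trials:
(# advantageous C/D selections) - (# disadvantageous A/B selections).
Group differences on model parameters are summarised by the posterior
of the group-mean difference: its mean, 95% highest density interval
(HDI) and the fraction of posterior mass above zero. A difference is
called credible when the 95% HDI excludes zero; a region of practical
equivalence (ROPE) can optionally be supplied instead of the point null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def block_net_scores(choices, block_size: int = 20) -> np.ndarray:
    """Net score per block for one subject's 1..4 deck choices."""
    choices = np.asarray(choices, dtype=np.int64)
    if choices.size == 0:
        raise ValueError("empty choice sequence")
    if np.any((choices < 1) | (choices > 4)):
        raise ValueError("deck codes must lie in 1..4")
    if len(choices) % block_size:
        raise ValueError(f"block_size {block_size} does not divide T={len(choices)}")
    good = (choices >= 3).astype(int).reshape(-1, block_size).sum(axis=1)
    bad = (choices <= 2).astype(int).reshape(-1, block_size).sum(axis=1)
    return (good - bad).astype(float)


@dataclass(frozen=True)
class HdiInterval:
    """Narrowest interval holding ``mass`` of the posterior samples."""

    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def to_dict(self) -> dict:
        return {"lower": self.lower, "upper": self.upper, "mass": self.mass}


def hdi(samples, mass: float = 0.95) -> HdiInterval:
    """Highest density interval of a sample, by the shortest sorted window."""
    samples = np.sort(np.asarray(samples, float).ravel())
    n = samples.size
    if n < 2:
        raise ValueError("hdi needs at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(np.ceil(mass * n))
    widths = samples[m - 1:] - samples[:n - m + 1]
    j = int(np.argmin(widths))
    return HdiInterval(lower=float(samples[j]), upper=float(samples[j + m - 1]),
                       mass=mass)


@dataclass
class GroupContrast:
    """Posterior of the difference (group A - group B) in one group mean."""

    parameter: str
    samples: np.ndarray
    hdi: HdiInterval
    mean: float
    frac_positive: float
    rope: tuple[float, float] | None = None
    credible: bool = field(init=False)

    def __post_init__(self):
        lo, hi = self.rope if self.rope is not None else (0.0, 0.0)
        self.credible = bool(self.hdi.upper < lo or self.hdi.lower > hi)

    def to_dict(self) -> dict:
        return {"parameter": self.parameter, "mean": self.mean,
                "hdi": self.hdi.to_dict(), "frac_positive": self.frac_positive,
                "credible": self.credible}


def _group_mean_draws(draws, parameter: str) -> np.ndarray:
    if hasattr(draws, "flat_group_mean_native"):
        if parameter not in draws.param_names:
            raise KeyError(f"parameter {parameter!r} not in {draws.param_names}")
        return draws.flat_group_mean_native()[:, draws.param_names.index(parameter)]
    return np.asarray(draws, float).ravel()


def group_contrast(draws_a, draws_b, parameter: str, seed: int = 0,
                   mass: float = 0.95,
                   rope: tuple[float, float] | None = None) -> GroupContrast:
    """Contrast of native-scale group means between two independent fits.

    The two fits carry no joint draw structure, so draws are paired
    after a seeded shuffle of each margin; the longer sample is
    down-sampled (seeded) to match the shorter.
    """
    a = _group_mean_draws(draws_a, parameter)
    b = _group_mean_draws(draws_b, parameter)
    rng = np.random.default_rng(seed)
    a = rng.permutation(a)
    b = rng.permutation(b)
    m = min(len(a), len(b))
    diff = a[:m] - b[:m]
    iv = hdi(diff, mass)
    return GroupContrast(parameter=parameter, samples=diff, hdi=iv,
                         mean=float(diff.mean()),
                         frac_positive=float(np.mean(diff > 0)), rope=rope)


def contrast_density(contrast: GroupContrast, bins: int = 60):
    """Binned posterior mass of a contrast, for density-plot exports."""
    import pandas as pd

    hist, edges = np.histogram(contrast.samples, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"parameter": contrast.parameter, "value": centers,
                         "density": hist})
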