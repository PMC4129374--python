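"""Synthetic cohorts with the statistical structure the analysis assumes.

Presets carry the published group-mean parameter estimates of the three
study populations (healthy controls, amphetamine users, heroin users)
under each model, together with the posterior SDs of those group means.
Those SDs quantify uncertainty about the mean, not spread between
subjects — the true between-subject variance is unpublished — so
synthetic heterogeneity defaults to ``heterogeneity_scale`` (3x) times
them, applied on the raw (probit) scale via a delta-method conversion.

A generated cohort bundles the trial-level table (raw currency, file
convention) with a hidden truth table of the generating parameters, so
recovery and contrast pipelines can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .inference import transforms_for
from .io import ChoiceDataset, TRIAL_COLUMNS
from .models import ModelKind, SubjectParameters, simulate_subject
from .schedule import DECKS, DEFAULT_DIVISOR, PayoffSchedule, build_schedule, scale_net_outcomes

GROUPS = ("HC", "amphetamine", "heroin")
GROUP_SIZES = {"HC": 48, "amphetamine": 38, "heroin": 43}


@dataclass(frozen=True)
class CohortPreset:
    """Group-level parameter profile of one population under one model."""

    group: str
    model: ModelKind
    means: dict[str, float]
    sds: dict[str, float]
    size: int

    def __post_init__(self):
        assert set(self.means) == set(self.model.param_names)


def _preset(model: ModelKind, group: str, means: dict, sds: dict) -> CohortPreset:
    return CohortPreset(group=group, model=model, means=means, sds=sds,
                        size=GROUP_SIZES[group])


_VPP = ModelKind.VPP
_DECAY = ModelKind.PVL_DECAY
_DELTA = ModelKind.PVL_DELTA

# Published group-mean estimates (posterior SD of the group mean in sds).
PRESETS: dict[tuple[ModelKind, str], CohortPreset] = {}
for _m, _g, _mean, _sd in [
    (_VPP, "HC",
     dict(A=0.010, alpha=0.518, c=2.017, lam=0.717, eps_p=-0.001, eps_n=-0.726,
          k=0.481, w=0.825),
     dict(A=0.008, alpha=0.149, c=0.419, lam=0.273, eps_p=0.154, eps_n=0.296,
          k=0.062, w=0.110)),
    (_VPP, "amphetamine",
     dict(A=0.019, alpha=0.374, c=1.894, lam=0.593, eps_p=-0.181, eps_n=-0.500,
          k=0.404, w=0.714),
     dict(A=0.011, alpha=0.137, c=0.329, lam=0.275, eps_p=0.179, eps_n=0.297,
          k=0.067, w=0.183)),
    (_VPP, "heroin",
     dict(A=0.070, alpha=0.481, c=1.368, lam=0.023, eps_p=0.050, eps_n=-0.249,
          k=0.337, w=0.677),
     dict(A=0.044, alpha=0.159, c=0.125, lam=0.033, eps_p=0.204, eps_n=0.192,
          k=0.073, w=0.078)),
    (_DECAY, "HC",
     dict(A=0.736, alpha=0.053, c=0.216, lam=1.262),
     dict(A=0.068, alpha=0.043, c=0.038, lam=0.543)),
    (_DECAY, "amphetamine",
     dict(A=0.809, alpha=0.310, c=0.186, lam=0.910),
     dict(A=0.072, alpha=0.129, c=0.040, lam=0.494)),
    (_DECAY, "heroin",
     dict(A=0.730, alpha=0.122, c=0.210, lam=0.110),
     dict(A=0.087, alpha=0.074, c=0.050, lam=0.108)),
    (_DELTA, "HC",
     dict(A=0.037, alpha=0.382, c=1.285, lam=0.650),
     dict(A=0.019, alpha=0.126, c=0.204, lam=0.240)),
    (_DELTA, "amphetamine",
     dict(A=0.035, alpha=0.283, c=1.292, lam=0.376),
     dict(A=0.018, alpha=0.116, c=0.181, lam=0.220)),
    (_DELTA, "heroin",
     dict(A=0.172, alpha=0.475, c=0.947, lam=0.060),
     dict(A=0.080, alpha=0.123, c=0.147, lam=0.055)),
]:
    PRESETS[(_m, _g)] = _preset(_m, _g, _mean, _sd)


def builtin_presets() -> list[CohortPreset]:
    """All nine presets (3 groups x 3 models)."""
    return list(PRESETS.values())


def get_preset(model: ModelKind | str, group: str) -> CohortPreset:
    model = ModelKind.parse(model)
    for (m, g), preset in PRESETS.items():
        if m is model and g.lower() == group.lower():
            return preset
    raise KeyError(f"no preset for model={model.value}, group={group!r}")


def sample_subject_parameters(preset: CohortPreset, n: int,
                              heterogeneity_scale: float = 3.0,
                              seed: int = 0) -> list[SubjectParameters]:
    """Draw n subjects' native parameters around the preset's group means.

    Raw-scale normal draws centred at the raw image of the preset mean,
    with SD = heterogeneity_scale x (preset SD mapped to the raw scale by
    the delta method); the probit transform then guarantees bounds.
    """
    if not heterogeneity_scale >= 0:
        raise ValueError("heterogeneity_scale must be >= 0")
    model = preset.model
    rng = np.random.default_rng(seed)
    trs = transforms_for(model)
    out = np.empty((n, model.n_params))
    for p, (name, tr) in enumerate(zip(model.param_names, trs)):
        raw_mean = tr.to_raw(preset.means[name])
        if tr.kind == "unbounded":
            raw_sd = heterogeneity_scale * preset.sds[name]
        else:
            slope = tr.upper * norm.pdf(raw_mean)  # d native / d raw
            raw_sd = heterogeneity_scale * preset.sds[name] / slope
        out[:, p] = tr.to_native(rng.normal(raw_mean, raw_sd, size=n))
    return [SubjectParameters.from_array(row, model) for row in out]


@dataclass
class SyntheticCohort:
    """Generated trial data plus the hidden generating-parameter truth."""

    dataset: ChoiceDataset
    truth: pd.DataFrame  # index subject_id, columns = native parameters
    preset: CohortPreset
    seed: int

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.table.to_csv(out / "trials.csv", index=False)
        sidecar = {"group": self.preset.group, "model": self.preset.model.value,
                   "seed": self.seed,
                   "parameters": self.truth.to_dict(orient="index")}
        (out / "truth.json").write_text(json.dumps(sidecar, indent=1))


def generate_cohort(preset: CohortPreset, schedule: PayoffSchedule | None = None,
                    T: int = 100, seed: int = 0,
                    heterogeneity_scale: float = 3.0,
                    divisor: float = DEFAULT_DIVISOR) -> SyntheticCohort:
    """Simulate a full cohort playing the task under the preset's model.

    Choices are generated by model agents on the scaled schedule; the
    emitted table stores the raw-currency gain/loss of each served card.
    Byte-identical across runs with the same arguments.
    """
    if schedule is None:
        schedule = build_schedule()
    scaled = scale_net_outcomes(schedule, divisor) if schedule.divisor == 1.0 else schedule
    params = sample_subject_parameters(preset, preset.size, heterogeneity_scale, seed)
    sub_seeds = [int(s) % 2 ** 31 for s in
                 np.random.SeedSequence([seed, 101]).generate_state(preset.size)]
    rows = []
    truth_rows = {}
    for i, (p, s) in enumerate(zip(params, sub_seeds)):
        sid = f"{preset.group}_{i + 1:03d}"
        seq = simulate_subject(preset.model, p, scaled, T=T, rng_seed=s)
        for t in range(T):
            deck = DECKS[seq.choices[t] - 1]
            gain, loss = schedule.card(deck, int(seq.card_indices[t]))
            rows.append((sid, preset.group, t + 1, int(seq.choices[t]),
                         gain, loss, gain + loss))
        truth_rows[sid] = {name: getattr(p, name) for name in preset.model.param_names}
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    return SyntheticCohort(dataset=ChoiceDataset(table, divisor), truth=truth,
                           preset=preset, seed=seed)
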