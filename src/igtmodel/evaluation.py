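"""Model evaluation: WAIC, posterior-predictive simulation, recovery.

WAIC is computed per subject from that subject's own posterior draws
(not the group-level distribution): an S x T matrix of per-draw,
per-trial log predictive densities yields

    lppd    = sum_t log( mean_s p(y_t | theta_s) )
    p_waic2 = sum_t var_s( log p(y_t | theta_s) )
    WAIC    = -2 * (lppd - p_waic2)

summed over a group's members for model comparison (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from .groups import block_net_scores, hdi
from .inference import (McmcConfig, PosteriorDraws, fit_group, posterior_means,
                        transforms_for)
from .models import ChoiceSequence, ModelKind, SubjectParameters, net_table, simulate_subject
from .schedule import DECKS, PayoffSchedule


def _params8_matrix(model: ModelKind, native: np.ndarray) -> np.ndarray:
    """Expand (S, n_params) native draws to canonical (S, 8) vectors."""
    S = native.shape[0]
    out = np.zeros((S, 8))
    out[:, 7] = 1.0
    out[:, :native.shape[1]] = native
    return out


def pointwise_matrix(model: ModelKind | str, draws: PosteriorDraws, subject,
                     data: ChoiceSequence, S: int = 1000,
                     seed: int = 0) -> np.ndarray:
    """S x T matrix of log p(y_t | theta_s) for one subject.

    The S draws are subsampled uniformly without replacement from the
    subject's pooled chains, seeded.
    """
    model = ModelKind.parse(model)
    if isinstance(subject, str):
        subject = draws.subject_ids.index(subject)
    native = draws.flat_subject_native()[:, subject, :]
    total = native.shape[0]
    if S > total:
        raise ValueError(f"S={S} exceeds the {total} available draws")
    idx = np.random.default_rng(seed).choice(total, size=S, replace=False)
    params = _params8_matrix(model, native[idx])
    out = np.empty((S, data.T))
    _kernels.pointwise_matrix_kernel(model.code, params, data.choices - 1,
                                     data.net_outcomes, out)
    return out


def lppd(matrix: np.ndarray) -> float:
    """Log pointwise predictive density, via a stable log-sum-exp."""
    matrix = np.asarray(matrix, float)
    S = matrix.shape[0]
    return float(np.sum(logsumexp(matrix, axis=0) - np.log(S)))


def p_waic2(matrix: np.ndarray) -> float:
    """Effective-parameter penalty: summed per-trial variance of log densities."""
    matrix = np.asarray(matrix, float)
    if matrix.shape[0] < 2:
        raise ValueError("p_waic2 needs at least 2 posterior draws")
    return float(np.sum(np.var(matrix, axis=0, ddof=1)))


@dataclass
class WaicReport:
    """Per-subject WAIC decomposition plus per-group sums."""

    table: pd.DataFrame  # index subject_id; columns lppd, p_waic2, waic, group

    def group_summary(self) -> dict[str, float]:
        return self.table.groupby("group")["waic"].sum().to_dict()

    @property
    def total(self) -> float:
        return float(self.table["waic"].sum())

    def to_json(self) -> dict:
        return {"subjects": self.table.to_dict(orient="index"),
                "group_waic": self.group_summary(), "total": self.total}


def waic(matrices: dict[str, np.ndarray],
         group_labels: dict[str, str] | None = None) -> WaicReport:
    """Assemble a WaicReport from per-subject pointwise matrices."""
    rows = {}
    for sid, m in matrices.items():
        l, p = lppd(m), p_waic2(m)
        rows[sid] = {"lppd": l, "p_waic2": p, "waic": -2.0 * (l - p),
                     "group": (group_labels or {}).get(sid, "")}
    return WaicReport(table=pd.DataFrame.from_dict(rows, orient="index"))


def compute_waic(model: ModelKind | str, draws: PosteriorDraws, dataset,
                 S: int = 1000, seed: int = 0) -> WaicReport:
    """WAIC for every subject of a fitted group."""
    model = ModelKind.parse(model)
    sequences = dataset.sequences()
    ids = dataset.subjects()
    if ids != draws.subject_ids:
        raise ValueError("dataset subjects do not match the fitted draws")
    S = min(S, draws.n_chains * draws.n_draws)
    mats = {sid: pointwise_matrix(model, draws, i, seq, S=S, seed=seed + i)
            for i, (sid, seq) in enumerate(zip(ids, sequences))}
    groups = {sid: draws.group for sid in ids}
    return waic(mats, groups)


def random_choice_waic(n_subjects: int, T: int = 100) -> float:
    """Group WAIC of the zero-sensitivity (uniform random) baseline."""
    return 2.0 * n_subjects * T * np.log(4.0)


def simulate_posterior_predictive(model: ModelKind | str,
                                  subject_params: pd.DataFrame,
                                  schedule: PayoffSchedule, n_reps: int = 100,
                                  seed: int = 0, T: int = 100) -> dict:
    """Forward-simulate each subject at their posterior-mean parameters.

    Per-trial deck proportions are averaged within subject over the
    ``n_reps`` repetitions first, then across subjects; block net scores
    use 20-trial blocks. Returns tidy DataFrames.
    """
    model = ModelKind.parse(model)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(subject_params)
    counts = np.zeros((n, T, 4))
    blocks = T // 20
    net = np.zeros((n, blocks))
    seeds = np.random.SeedSequence(seed).generate_state(n * n_reps).reshape(n, n_reps)
    for i, (_, row) in enumerate(subject_params.iterrows()):
        params = SubjectParameters.from_array(
            row[list(model.param_names)].to_numpy(float), model)
        for r in range(n_reps):
            seq = simulate_subject(model, params, schedule, T=T,
                                   rng_seed=int(seeds[i, r]) % 2 ** 31)
            counts[i, np.arange(T), seq.choices - 1] += 1.0
            net[i] += block_net_scores(seq.choices, 20)
    per_subject = counts / n_reps
    props = per_subject.mean(axis=0)  # (T, 4)
    rows = [(t + 1, deck, props[t, j]) for t in range(T)
            for j, deck in enumerate(DECKS)]
    traj = pd.DataFrame(rows, columns=["trial", "deck", "proportion"])
    block_df = pd.DataFrame(net / n_reps, index=subject_params.index,
                            columns=[f"block{b + 1}" for b in range(blocks)])
    return {"trial_proportions": traj, "block_net": block_df}


@dataclass
class RecoverySummary:
    """True-vs-recovered comparison after a simulate-then-refit experiment."""

    model: ModelKind
    truths: pd.DataFrame            # generating native parameters
    recovered: pd.DataFrame         # posterior-mean native parameters
    correlations: dict[str, float]  # per parameter, across subjects
    bias: dict[str, float]          # mean(recovered - truth)
    hdi_coverage: dict[str, float]  # fraction of truths inside 95% HDIs
    group_mean_in_hdi: dict[str, bool] | None
    max_rhat: float
    converged: bool

    def to_dict(self) -> dict:
        return {"model": self.model.value, "correlations": self.correlations,
                "bias": self.bias, "hdi_coverage": self.hdi_coverage,
                "group_mean_in_hdi": self.group_mean_in_hdi,
                "max_rhat": self.max_rhat, "converged": self.converged}


def parameter_recovery_experiment(model: ModelKind | str,
                                  generating_params: list[SubjectParameters],
                                  schedule: PayoffSchedule,
                                  config: McmcConfig | None = None,
                                  seed: int = 0, T: int = 100,
                                  true_group_means: dict[str, float] | None = None,
                                  ) -> RecoverySummary:
    """Simulate a cohort from known parameters, refit, compare.

    ``schedule`` must be on the model (scaled) scale. When
    ``true_group_means`` is given, also checks whether each generating
    group mean falls inside the 95% HDI of the fitted native group mean.
    """
    model = ModelKind.parse(model)
    config = config or McmcConfig.desk(seed=seed)
    seeds = np.random.SeedSequence([seed, 7]).generate_state(len(generating_params))
    sequences = [simulate_subject(model, p, schedule, T=T,
                                  rng_seed=int(s) % 2 ** 31)
                 for p, s in zip(generating_params, seeds)]
    draws, report = fit_group(model, sequences, config)
    means = posterior_means(draws)
    recovered = means["subject"]
    truths = pd.DataFrame([{n: getattr(p, n) for n in model.param_names}
                           for p in generating_params],
                          index=recovered.index)
    correlations, bias, coverage = {}, {}, {}
    nat = draws.flat_subject_native()
    for p, name in enumerate(model.param_names):
        t = truths[name].to_numpy()
        r = recovered[name].to_numpy()
        correlations[name] = float(np.corrcoef(t, r)[0, 1])
        bias[name] = float(np.mean(r - t))
        inside = 0
        for i in range(len(t)):
            iv = hdi(nat[:, i, p], 0.95)
            inside += int(iv.lower <= t[i] <= iv.upper)
        coverage[name] = inside / len(t)
    group_in = None
    if true_group_means is not None:
        group_in = {}
        gm = draws.flat_group_mean_native()
        for p, name in enumerate(model.param_names):
            iv = hdi(gm[:, p], 0.95)
            group_in[name] = bool(iv.lower <= true_group_means[name] <= iv.upper)
    return RecoverySummary(model=model, truths=truths, recovered=recovered,
                           correlations=correlations, bias=bias,
                           hdi_coverage=coverage, group_mean_in_hdi=group_in,
                           max_rhat=report.max_rhat, converged=report.converged)
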