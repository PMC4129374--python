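"""Hierarchical Bayesian estimation of model parameters for one group.

Each group (e.g. healthy controls) is fitted separately. Subject-level
parameters live on an unconstrained raw scale and are tied together by
group-level normal distributions:

    mu_raw ~ Normal(0, 1)          (probit-transformed parameters)
    mu_raw ~ Normal(0, 5)          (unbounded parameters: eps_p, eps_n)
    sigma_raw ~ Uniform(0, 1.5)
    raw_i ~ Normal(mu_raw, sigma_raw)
    native_i = U * Phi(raw_i)      (bounded parameters; U = upper bound)
    native_i = raw_i               (unbounded parameters)

Phi is the standard normal CDF, so a flat-ish prior is induced over each
parameter's full native range. Sampling uses an adaptive
Metropolis-within-Gibbs scheme (see ``_kernels.run_chain``): single-site
random walks on subject parameters, conjugate draws for the group means
and a log-scale walk for the group SDs. The centered parameterization is
used because the group means then admit exact conjugate updates, which
mix well under conditional sampling. Three chains of 1000 warmup + 2000
retained draws are the reference setting; ``McmcConfig.desk()`` gives a
lighter 500 + 500 preset for quick runs.

Convergence is summarised by split R-hat and bulk effective sample size
(via arviz); any parameter with R-hat > 1.1 flags the fit as
non-converged (flagged, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _kernels
from .models import ModelKind, ChoiceSequence

SIGMA_UPPER = 1.5
RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class ParameterTransform:
    """Monotone map from the unconstrained raw scale to the native scale."""

    kind: str  # "unit-interval" | "bounded-upper" | "unbounded"
    upper: float = 1.0

    def __post_init__(self):
        if self.kind not in ("unit-interval", "bounded-upper", "unbounded"):
            raise ValueError(f"unknown transform kind {self.kind!r}")

    def to_native(self, raw):
        raw = np.asarray(raw, dtype=float)
        if self.kind == "unit-interval":
            out = norm.cdf(raw)
        elif self.kind == "bounded-upper":
            out = self.upper * norm.cdf(raw)
        else:
            out = raw
        return out.item() if np.ndim(out) == 0 else out

    def to_raw(self, native):
        native = np.asarray(native, dtype=float)
        if self.kind == "unit-interval":
            out = norm.ppf(native)
        elif self.kind == "bounded-upper":
            out = norm.ppf(native / self.upper)
        else:
            out = native
        return out.item() if np.ndim(out) == 0 else out

    @property
    def mu_prior_sd(self) -> float:
        return 5.0 if self.kind == "unbounded" else 1.0


_TRANSFORMS = {
    "A": ParameterTransform("unit-interval"),
    "alpha": ParameterTransform("bounded-upper", 2.0),
    "c": ParameterTransform("bounded-upper", 5.0),
    "lam": ParameterTransform("bounded-upper", 10.0),
    "eps_p": ParameterTransform("unbounded"),
    "eps_n": ParameterTransform("unbounded"),
    "k": ParameterTransform("unit-interval"),
    "w": ParameterTransform("unit-interval"),
}


def transforms_for(model: ModelKind | str) -> list[ParameterTransform]:
    model = ModelKind.parse(model)
    return [_TRANSFORMS[name] for name in model.param_names]


def to_native(raw, transform: ParameterTransform):
    """Map a raw-scale value through its transform (module-level alias)."""
    return transform.to_native(raw)


def _kernel_codes(model: ModelKind):
    trs = transforms_for(model)
    kinds = np.array([1 if t.kind == "unbounded" else 0 for t in trs], dtype=np.int64)
    ubounds = np.array([t.upper for t in trs], dtype=float)
    mu_sd = np.array([t.mu_prior_sd for t in trs], dtype=float)
    return kinds, ubounds, mu_sd


@dataclass
class McmcConfig:
    """Sampler settings: 3 chains x (1000 warmup + 2000 retained) by default."""

    chains: int = 3
    warmup: int = 1000
    samples: int = 2000
    thin: int = 4
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcConfig":
        """Light preset (3 x 500/500) for quick interactive runs."""
        return cls(chains=3, warmup=500, samples=500, thin=4, seed=seed)


@dataclass
class ConvergenceReport:
    """Split R-hat and bulk ESS per monitored parameter."""

    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool = field(init=False)

    def __post_init__(self):
        self.converged = bool(all(r <= RHAT_THRESHOLD for r in self.rhat.values()))

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_dict(self) -> dict:
        return {"rhat": self.rhat, "ess": self.ess, "converged": self.converged,
                "max_rhat": self.max_rhat}


@dataclass
class PosteriorDraws:
    """MCMC draws for one group fit, raw scale, indexed (chain, iteration).

    ``subject_raw`` has shape (chains, draws, n_subjects, n_params);
    ``mu_raw`` and ``sigma_raw`` have shape (chains, draws, n_params).
    """

    model: ModelKind
    param_names: list[str]
    subject_ids: list[str]
    subject_raw: np.ndarray
    mu_raw: np.ndarray
    sigma_raw: np.ndarray
    group: str = ""

    @property
    def n_chains(self) -> int:
        return self.subject_raw.shape[0]

    @property
    def n_draws(self) -> int:
        return self.subject_raw.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.subject_raw.shape[2]

    def _transform_axis(self, raw: np.ndarray) -> np.ndarray:
        out = np.empty_like(raw)
        for p, tr in enumerate(transforms_for(self.model)):
            out[..., p] = tr.to_native(raw[..., p])
        return out

    def subject_native(self) -> np.ndarray:
        """(chains, draws, n_subjects, n_params) on the native scale."""
        return self._transform_axis(self.subject_raw)

    def group_mean_native(self) -> np.ndarray:
        """Native-scale group mean per draw: U * Phi(mu_raw) (or mu_raw)."""
        return self._transform_axis(self.mu_raw)

    def flat_subject_native(self) -> np.ndarray:
        """(chains*draws, n_subjects, n_params), chains concatenated."""
        nat = self.subject_native()
        return nat.reshape(-1, self.n_subjects, len(self.param_names))

    def flat_group_mean_native(self) -> np.ndarray:
        return self.group_mean_native().reshape(-1, len(self.param_names))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: chain, iteration, parameter, value (raw scale)."""
        rows = []
        C, S, n, P = self.subject_raw.shape
        for c in range(C):
            for s in range(S):
                for p, name in enumerate(self.param_names):
                    rows.append((c, s, f"mu_{name}", self.mu_raw[c, s, p]))
                    rows.append((c, s, f"sigma_{name}", self.sigma_raw[c, s, p]))
                    for i, sid in enumerate(self.subject_ids):
                        rows.append((c, s, f"{name}[{sid}]", self.subject_raw[c, s, i, p]))
        return pd.DataFrame(rows, columns=["chain", "iteration", "parameter", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def posterior_means(draws: PosteriorDraws) -> dict:
    """Posterior means on the native scale (canonical) and the raw scale.

    The native mean is the mean of transformed draws; because the
    transform is nonlinear it differs from transforming the raw mean
    (Jensen gap), so both are reported and the native mean is canonical.
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    nat = draws.subject_native().mean(axis=(0, 1))        # (n, P)
    raw = draws.subject_raw.mean(axis=(0, 1))
    group_nat = draws.group_mean_native().mean(axis=(0, 1))
    subject = pd.DataFrame(nat, index=draws.subject_ids, columns=draws.param_names)
    subject_raw = pd.DataFrame(raw, index=draws.subject_ids, columns=draws.param_names)
    group = pd.Series(group_nat, index=draws.param_names)
    return {"subject": subject, "subject_raw": subject_raw, "group_mean": group}


def log_joint(model: ModelKind | str, sequences: list[ChoiceSequence],
              subject_raw: np.ndarray, mu_raw: np.ndarray,
              sigma_raw: np.ndarray) -> float:
    """Unnormalised log posterior of the hierarchical model (reference form).

    Used as the ground truth the sampler must target; the sampler kernel
    evaluates the same terms incrementally.
    """
    model = ModelKind.parse(model)
    kinds, ubounds, mu_sd = _kernel_codes(model)
    P = len(kinds)
    subject_raw = np.atleast_2d(np.asarray(subject_raw, float))
    mu_raw = np.asarray(mu_raw, float)
    sigma_raw = np.asarray(sigma_raw, float)
    if subject_raw.shape != (len(sequences), P) or mu_raw.shape != (P,) \
            or sigma_raw.shape != (P,):
        raise ValueError("shape mismatch between parameters, model and cohort")
    if np.any(sigma_raw <= 0) or np.any(sigma_raw > SIGMA_UPPER):
        return -np.inf
    lp = float(np.sum(norm.logpdf(mu_raw, 0.0, mu_sd)))
    lp += float(np.sum(norm.logpdf(subject_raw, mu_raw, sigma_raw)))
    nat = np.empty(8)
    for i, seq in enumerate(sequences):
        _kernels.to_native8(subject_raw[i], kinds, ubounds, nat)
        lp += _kernels.loglik_total(model.code, nat, seq.choices - 1,
                                    seq.net_outcomes)
    return lp


def compute_rhat(chains: np.ndarray) -> float:
    """Split R-hat of draws shaped (chains, iterations)."""
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("compute_rhat needs draws shaped (>=2 chains, iterations)")
    import arviz as az
    return float(az.rhat(az.convert_to_dataset(chains))["x"].values)

def compute_ess(chains: np.ndarray) -> float:
    """Bulk effective sample size of draws shaped (chains, iterations)."""
    chains = np.atleast_2d(np.asarray(chains, float))
    import arviz as az
    return float(az.ess(az.convert_to_dataset(chains))["x"].values)


def _convergence(draws: PosteriorDraws) -> ConvergenceReport:
    rhat, ess = {}, {}
    for p, name in enumerate(draws.param_names):
        for label, arr in ((f"mu_{name}", draws.mu_raw[..., p]),
                           (f"sigma_{name}", draws.sigma_raw[..., p])):
            rhat[label] = compute_rhat(arr)
            ess[label] = compute_ess(arr)
        # subject-level parameters, summarised by the worst subject
        sub_rhat = [compute_rhat(draws.subject_raw[:, :, i, p])
                    for i in range(draws.n_subjects)]
        sub_ess = [compute_ess(draws.subject_raw[:, :, i, p])
                   for i in range(draws.n_subjects)]
        rhat[f"{name}[worst_subject]"] = float(np.max(sub_rhat))
        ess[f"{name}[worst_subject]"] = float(np.min(sub_ess))
    return ConvergenceReport(rhat=rhat, ess=ess)


def fit_group(model: ModelKind | str, dataset, config: McmcConfig | None = None,
              prior_only: bool = False) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Fit the hierarchical model to one group's trial data.

    ``dataset`` is a ChoiceDataset (one group) or a list of
    ChoiceSequence. Deterministic given ``config.seed``.
    """
    model = ModelKind.parse(model)
    config = config or McmcConfig()
    sequences, subject_ids, group = _as_sequences(dataset)
    if len({s.T for s in sequences}) != 1:
        raise ValueError("all subjects must have the same number of trials")
    choices = np.stack([s.choices - 1 for s in sequences])
    outcomes = np.stack([s.net_outcomes for s in sequences])
    kinds, ubounds, mu_sd = _kernel_codes(model)
    subj, mus, sigmas = [], [], []
    for c in range(config.chains):
        chain_seed = int((config.seed * 1000003 + 7919 * c + 1) % (2 ** 31))
        s, m, sg = _kernels.run_chain(model.code, choices, outcomes, kinds,
                                      ubounds, mu_sd, SIGMA_UPPER,
                                      config.warmup, config.samples,
                                      config.thin, chain_seed, prior_only)
        subj.append(s)
        mus.append(m)
        sigmas.append(sg)
    draws = PosteriorDraws(model=model, param_names=list(model.param_names),
                           subject_ids=subject_ids,
                           subject_raw=np.stack(subj), mu_raw=np.stack(mus),
                           sigma_raw=np.stack(sigmas), group=group)
    return draws, _convergence(draws)


def _as_sequences(dataset) -> tuple[list[ChoiceSequence], list[str], str]:
    if hasattr(dataset, "sequences"):  # ChoiceDataset
        groups = dataset.groups()
        if len(groups) != 1:
            raise ValueError(f"fit_group expects a single group, got {groups}")
        return dataset.sequences(), list(dataset.subjects()), groups[0]
    sequences = list(dataset)
    ids = [f"s{i + 1:03d}" for i in range(len(sequences))]
    return sequences, ids, ""
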