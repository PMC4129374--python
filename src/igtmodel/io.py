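"""Trial-table file format, run configuration and the pipeline verbs.

The on-disk trial table mirrors the public deposits of IGT choice data:
one row per trial with columns ``subject_id, group, trial, deck, gain,
loss, net`` where decks are coded 1-4 for A-D, trials are 1-based and
contiguous, and amounts are raw task currency (``net = gain + loss``).
Scaling for cognitive modeling (division by 100 by default) happens in
memory, never in the files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import ChoiceSequence, ModelKind
from .schedule import DEFAULT_DIVISOR

TRIAL_COLUMNS = ["subject_id", "group", "trial", "deck", "gain", "loss", "net"]


@dataclass
class ChoiceDataset:
    """Trial-level choices and outcomes for a cohort, possibly multi-group.

    ``divisor`` is the scale applied when handing net outcomes to the
    models; stored amounts stay in raw currency.
    """

    table: pd.DataFrame
    divisor: float = DEFAULT_DIVISOR

    def __post_init__(self):
        self.table = validate_trials(self.table)

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def select_group(self, group: str) -> "ChoiceDataset":
        mask = self.table["group"].str.lower() == group.lower()
        if not mask.any():
            raise ValueError(f"group {group!r} not present; have {self.groups()}")
        return ChoiceDataset(self.table[mask].reset_index(drop=True), self.divisor)

    def sequences(self) -> list[ChoiceSequence]:
        """Per-subject ChoiceSequence with net outcomes on the model scale."""
        out = []
        for sid in self.subjects():
            sub = self.table[self.table["subject_id"] == sid].sort_values("trial")
            out.append(ChoiceSequence(choices=sub["deck"].to_numpy(np.int64),
                                      net_outcomes=sub["net"].to_numpy(float)
                                      / self.divisor))
        return out

    def __len__(self) -> int:
        return len(self.table)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract, naming offending rows on failure."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    bad_deck = df.index[~df["deck"].isin([1, 2, 3, 4])]
    if len(bad_deck):
        raise ValueError(f"deck outside 1..4 at rows {list(bad_deck[:5])}")
    mismatch = df.index[np.abs(df["gain"] + df["loss"] - df["net"]) > 1e-6]
    if len(mismatch):
        raise ValueError(f"net != gain + loss at rows {list(mismatch[:5])}")
    for sid, sub in df.groupby("subject_id", sort=False):
        trials = sub["trial"].to_numpy()
        if not np.array_equal(np.sort(trials), np.arange(1, len(trials) + 1)):
            raise ValueError(f"subject {sid!r}: trials not contiguous 1..T")
    return df


def read_trials(path, divisor: float = DEFAULT_DIVISOR,
                column_map: dict[str, str] | None = None) -> ChoiceDataset:
    """Read a trial CSV; ``column_map`` renames foreign headers to ours."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return ChoiceDataset(df, divisor=divisor)


def write_trials(dataset: ChoiceDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Settings for one pipeline run; defaults follow the reference setup."""

    model: str = "pvl-delta"
    divisor: float = DEFAULT_DIVISOR
    loss_placement: str = "canonical"
    schedule_seed: int | None = None
    chains: int = 3
    warmup: int = 1000
    samples: int = 2000
    waic_s: int = 1000
    n_reps: int = 100
    trials: int = 100
    heterogeneity_scale: float = 3.0
    groups: tuple[str, ...] = ("HC", "amphetamine", "heroin")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _meta(config: RunConfig, seed: int) -> dict:
    from . import __version__
    return {"config_hash": config.hash(), "seed": seed, "version": __version__,
            "config": config.to_dict()}


def run_pipeline(config: RunConfig, verb: str, out_dir, seed: int = 0,
                 log=print) -> dict:
    """Execute one pipeline stage; artifacts land under ``out_dir``.

    Verbs: generate, fit, waic, simulate, recover, compare-groups.
    Later verbs read the artifacts of earlier ones from the same
    directory and fail with an actionable message when missing.
    """
    from . import cohort as cohort_mod
    from . import evaluation, groups as groups_mod
    from .inference import McmcConfig, PosteriorDraws, fit_group, posterior_means
    from .schedule import build_schedule, scale_net_outcomes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = ModelKind.parse(config.model)
    schedule = build_schedule(config.loss_placement, config.schedule_seed)
    mcmc = McmcConfig(chains=config.chains, warmup=config.warmup,
                      samples=config.samples, seed=seed)
    meta = _meta(config, seed)
    result: dict = {"verb": verb, "meta": meta}

    def _require(path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"{path.name} not found in {out}; run the '{producer}' verb first")
        return path

    if verb == "generate":
        frames, truths = [], {}
        for g, grp_seed in zip(config.groups, _spawn(seed, len(config.groups))):
            preset = cohort_mod.get_preset(model, g)
            syn = cohort_mod.generate_cohort(
                preset, schedule, T=config.trials, seed=grp_seed,
                heterogeneity_scale=config.heterogeneity_scale,
                divisor=config.divisor)
            frames.append(syn.dataset.table)
            truths[g] = syn.truth.to_dict(orient="index")
        table = pd.concat(frames, ignore_index=True)
        write_trials(ChoiceDataset(table, config.divisor), out / "trials.csv")
        (out / "truth.json").write_text(json.dumps({"meta": meta, "truth": truths},
                                                   indent=1))
        log(f"generate: wrote {len(table)} trials for {len(config.groups)} groups")
        result["trials"] = str(out / "trials.csv")

    elif verb == "fit":
        data = read_trials(_require(out / "trials.csv", "generate"), config.divisor)
        conv_all = {}
        for g in data.groups():
            draws, report = fit_group(model, data.select_group(g), mcmc)
            draws.to_csv(out / f"draws_{g}.csv")
            conv_all[g] = report.to_dict()
            log(f"fit[{g}]: max R-hat {report.max_rhat:.3f}, "
                f"min ESS {min(report.ess.values()):.0f}")
        (out / "convergence.json").write_text(json.dumps(
            {"meta": meta, "groups": conv_all}, indent=1))
        result["convergence"] = conv_all

    elif verb == "waic":
        data = read_trials(_require(out / "trials.csv", "generate"), config.divisor)
        reports = {}
        for g in data.groups():
            draws = load_draws(_require(out / f"draws_{g}.csv", "fit"), model, g)
            rep = evaluation.compute_waic(model, draws, data.select_group(g),
                                          S=config.waic_s, seed=seed)
            reports[g] = rep.total
            rep.table.to_csv(out / f"waic_{g}.csv")
        (out / "waic.json").write_text(json.dumps({"meta": meta, "groups": reports},
                                                  indent=1))
        log(f"waic: {reports}")
        result["waic"] = reports

    elif verb == "simulate":
        data = read_trials(_require(out / "trials.csv", "generate"), config.divisor)
        scaled = scale_net_outcomes(schedule, config.divisor)
        frames = []
        for g in data.groups():
            draws = load_draws(_require(out / f"draws_{g}.csv", "fit"), model, g)
            means = posterior_means(draws)["subject"]
            sim = evaluation.simulate_posterior_predictive(
                model, means, scaled, n_reps=config.n_reps, seed=seed,
                T=config.trials)
            traj = sim["trial_proportions"].assign(group=g)
            frames.append(traj)
        pd.concat(frames, ignore_index=True).to_csv(out / "trajectories.csv",
                                                    index=False)
        log("simulate: wrote trajectories.csv")
        result["trajectories"] = str(out / "trajectories.csv")

    elif verb == "recover":
        preset = cohort_mod.get_preset(model, config.groups[0])
        params = cohort_mod.sample_subject_parameters(
            preset, preset.size, config.heterogeneity_scale, seed)
        scaled = scale_net_outcomes(schedule, config.divisor)
        summary = evaluation.parameter_recovery_experiment(
            model, params, scaled, mcmc, seed=seed,
            true_group_means=preset.means)
        (out / "recovery.json").write_text(json.dumps(
            {"meta": meta, "recovery": summary.to_dict()}, indent=1))
        log(f"recover: correlations {summary.correlations}")
        result["recovery"] = summary.to_dict()

    elif verb == "compare-groups":
        data = read_trials(_require(out / "trials.csv", "generate"), config.divisor)
        grp = data.groups()
        contrasts = {}
        for a in range(len(grp)):
            for b in range(a + 1, len(grp)):
                da = load_draws(_require(out / f"draws_{grp[a]}.csv", "fit"),
                                model, grp[a])
                db = load_draws(_require(out / f"draws_{grp[b]}.csv", "fit"),
                                model, grp[b])
                for name in model.param_names:
                    con = groups_mod.group_contrast(da, db, name, seed=seed)
                    contrasts[f"{grp[a]}-{grp[b]}:{name}"] = con.to_dict()
        (out / "contrasts.json").write_text(json.dumps(
            {"meta": meta, "contrasts": contrasts}, indent=1))
        log(f"compare-groups: wrote {len(contrasts)} contrasts")
        result["contrasts"] = contrasts

    else:
        raise ValueError(f"unknown verb {verb!r}")
    return result


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s) % 2 ** 31 for s in
            np.random.SeedSequence(seed).generate_state(n)]


def load_draws(path, model: ModelKind | str, group: str = ""):
    """Rebuild PosteriorDraws from the tidy CSV written by ``to_csv``."""
    from .inference import PosteriorDraws

    model = ModelKind.parse(model)
    df = pd.read_csv(path)
    chains = int(df["chain"].max()) + 1
    iters = int(df["iteration"].max()) + 1
    names = list(model.param_names)
    sids = sorted({p[p.index("[") + 1:-1] for p in df["parameter"]
                   if "[" in p})
    P, n = len(names), len(sids)
    mu = np.empty((chains, iters, P))
    sigma = np.empty((chains, iters, P))
    subject = np.empty((chains, iters, n, P))
    piv = df.pivot_table(index=["chain", "iteration"], columns="parameter",
                         values="value")
    for p, name in enumerate(names):
        mu[..., p] = piv[f"mu_{name}"].to_numpy().reshape(chains, iters)
        sigma[..., p] = piv[f"sigma_{name}"].to_numpy().reshape(chains, iters)
        for i, sid in enumerate(sids):
            subject[:, :, i, p] = piv[f"{name}[{sid}]"].to_numpy().reshape(chains, iters)
    return PosteriorDraws(model=model, param_names=names, subject_ids=sids,
                          subject_raw=subject, mu_raw=mu, sigma_raw=sigma,
                          group=group)
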