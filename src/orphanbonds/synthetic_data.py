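"""Synthetic registries, follows, and interactions with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
population of multi-generation core groups (a matriarch, her adult daughters,
their focal-aged daughters, maternal sisters, young calves and cousins) plus
dispersed bulls; focal follows of the young females with per-follow
aggregation membership; and per-dyad affiliative counts drawn from the
negative-binomial regression in its generative direction,

    y_ij ~ NegBinom(mean = gamma_ij * exp(alpha_j + beta' x_ij), r),
    alpha_j ~ Normal(mu_alpha, 1 / tau_alpha),

so that every pipeline stage (validation, dyad assembly, descriptives, model
fitting) can be exercised against known parameters without any field data.

Focal individuals carry "-F" in their synthetic ids; sisters can fall in the
focal age range but are never sampled as focals themselves.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes_nb import McmcConfig, ModelSpec, fit, prepare_data
from .focal_data_io import (
    ACTIVITIES,
    AFFILIATIVE_TYPES,
    FocalFollow,
    InteractionEvent,
    build_dyad_table,
    write_follows,
    write_interactions,
)
from .population_model import ElephantRecord, Registry

_AFFILIATIVE = tuple(sorted(AFFILIATIVE_TYPES))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one synthetic study.

    Defaults mirror the scale of the field study: about four dozen focal
    females in a dozen core groups, a bit over half of them orphaned, with
    many short feeding follows and few resting follows per focal, and
    coefficient magnitudes below 1.3 as reported for the fitted models.
    """

    n_core_groups: int = 12
    focals_per_group: int = 4
    orphan_fraction: float = 0.6
    aunts_per_group: int = 2
    sister_prob: float = 0.6
    n_bulls: int = 10
    window: tuple[_dt.date, _dt.date] = (_dt.date(2012, 5, 1), _dt.date(2015, 4, 30))
    true_beta: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "orphan_feeding": {
            "age": -0.446, "age_orphaned": 0.154, "age_mate": 0.390,
            "aunt": -0.521, "bull": 0.702, "calf": 0.900,
            "matriarch": -0.451, "sister": -0.404,
        },
        "non_orphan_feeding": {
            "age": 0.068, "age_mate": 0.761, "aunt": -0.730, "bull": 0.963,
            "calf": 1.298, "matriarch": -0.036, "mother": 0.631, "sister": 0.345,
        },
        "orphan_resting": {
            "age": -0.054, "age_orphaned": -0.238, "age_mate": 0.533,
            "aunt": -0.014, "bull": 1.210, "calf": 0.089,
            "matriarch": -0.299, "sister": 1.023,
        },
        "non_orphan_resting": {
            "age": 0.028, "age_mate": 0.376, "aunt": 0.935, "bull": 0.435,
            "calf": 0.326, "matriarch": 0.252, "mother": 0.477, "sister": -0.423,
        },
    })
    mu_alpha: dict[str, float] = field(default_factory=lambda: {
        "feeding": -3.9,   # exp(-3.9) ~ 0.02 interactions per exposure minute
        "resting": -1.9,   # resting rates are an order of magnitude higher
    })
    tau_alpha: float = 4.0       # random-intercept precision (sd 0.5)
    r: float = 1.5               # dispersion: Var = lam (1 + lam/r)
    follows_per_focal: dict[str, float] = field(default_factory=lambda: {
        "feeding": 18.0, "resting": 4.0,
    })
    duration_range: tuple[float, float] = (8.0, 30.0)
    presence_probability: dict[str, float] = field(default_factory=lambda: {
        "same_group": 0.65, "bull": 0.12, "other_group": 0.03,
    })
    other_event_rate: float = 0.05  # mean non-affiliative events per dyad
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.orphan_fraction <= 1.0):
            raise ValueError("orphan_fraction must be in [0, 1]")
        for p in self.presence_probability.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("presence probabilities must be in [0, 1]")
        if not (0.001 < self.tau_alpha < 100.0):
            raise ValueError("tau_alpha outside its prior support")
        if not (0.0 < self.r < 100.0):
            raise ValueError("r outside its prior support")

    def beta_for(self, stratum: str, activity: str, order: Sequence[str]) -> np.ndarray:
        table = self.true_beta[f"{stratum}_{activity}"]
        return np.array([table[name] for name in order], dtype=float)

    def replace(self, **kwargs) -> "SyntheticTruth":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def recovery_default(cls) -> "SyntheticTruth":
        """Conditions of the parameter-recovery simulation: 30 orphan focals
        with on the order of forty candidate partners each, feeding only."""
        return cls(
            n_core_groups=6, focals_per_group=5, orphan_fraction=1.0,
            n_bulls=8, follows_per_focal={"feeding": 20.0, "resting": 0.0},
            presence_probability={"same_group": 0.65, "bull": 0.12,
                                  "other_group": 0.015},
        )


def _year_fraction(date: _dt.date) -> float:
    start = _dt.date(date.year, 1, 1)
    length = 366.0 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365.0
    return date.year + (date - start).days / length


def synthetic_focal_ids(registry: Registry) -> list[str]:
    return sorted(r.id for r in registry if "-F" in r.id)


def generate_registry(truth: SyntheticTruth) -> Registry:
    """Build a multi-generation registry matching the study's design.

    Each core group holds one matriarch (the grandmother generation), one
    mother per focal, the focal females themselves (ages 8-16 at the study
    midpoint), optional maternal sisters, adult aunts (the matriarch's other
    daughters) with young calves and cousins; dispersed bulls are distributed
    round-robin across groups. ``orphan_fraction`` of the focals lose their
    mother (mostly before, occasionally during, the observation window); the
    age at orphaning is drawn directly so it stays decorrelated from age.
    """
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(truth.seed).spawn(2)[0]
    ))
    start = _year_fraction(truth.window[0])
    end = _year_fraction(truth.window[1])
    mid = 0.5 * (start + end)

    n_focals_total = truth.n_core_groups * truth.focals_per_group
    n_orphans = int(round(truth.orphan_fraction * n_focals_total))
    orphan_idx = set(rng.choice(n_focals_total, size=n_orphans, replace=False).tolist())

    records: list[ElephantRecord] = []
    focal_counter = 0
    for g in range(truth.n_core_groups):
        gid = f"G{g:02d}"
        gm_id = f"{gid}-GM"
        gm_birth = mid - rng.uniform(42.0, 55.0)
        records.append(ElephantRecord(gm_id, "F", gm_birth, None, gid))

        for k in range(truth.focals_per_group):
            mother_id = f"{gid}-M{k}"
            focal_id = f"{gid}-F{k}"
            focal_birth = mid - rng.uniform(8.0, 16.0)
            mother_birth = max(focal_birth - rng.uniform(14.0, 22.0), gm_birth + 13.0)

            # age at orphaning is drawn directly (not via a death window tied
            # to focal age), which keeps it decorrelated from focal age; the
            # death may fall shortly before or during the observation window
            mother_death = None
            if focal_counter in orphan_idx:
                age_orphaned = rng.uniform(1.0, 12.0)
                mother_death = min(focal_birth + age_orphaned, end - 0.2)
                mother_death = max(mother_death, focal_birth + 1.0)
            focal_counter += 1

            children = [(focal_id, focal_birth)]
            if rng.uniform() < truth.sister_prob:
                offset = rng.uniform(2.5, 7.0) * rng.choice([-1.0, 1.0])
                sister_birth = min(focal_birth + offset, start - 1.0)  # born pre-study
                if mother_death is not None:
                    sister_birth = min(sister_birth, mother_death - 0.3)
                if sister_birth >= mother_birth + 12.0:
                    children.append((f"{gid}-S{k}", sister_birth))
            records.append(ElephantRecord(mother_id, "F", mother_birth, gm_id, gid,
                                          death_year=mother_death))
            for cid, cbirth in children:
                records.append(ElephantRecord(cid, "F", cbirth, mother_id, gid))

        for k in range(truth.aunts_per_group):
            aunt_id = f"{gid}-A{k}"
            aunt_birth = min(gm_birth + rng.uniform(16.0, 26.0), mid - 18.5)
            records.append(ElephantRecord(aunt_id, "F", aunt_birth, gm_id, gid))
            calf_birth = rng.uniform(start - 0.3, end - 0.1)
            records.append(ElephantRecord(
                f"{gid}-C{k}", rng.choice(["F", "M"]), calf_birth, aunt_id, gid))
            cousin_birth = mid - rng.uniform(2.0, 10.0)
            records.append(ElephantRecord(
                f"{gid}-X{k}", rng.choice(["F", "M"]), cousin_birth, aunt_id, gid))

    for k in range(truth.n_bulls):
        gid = f"G{k % truth.n_core_groups:02d}"
        records.append(ElephantRecord(
            f"B{k:02d}", "M", mid - rng.uniform(16.0, 30.0), None, gid,
            dispersed_from_natal=True))

    return Registry(records)


@dataclass
class SyntheticDataset:
    """A generated study: inputs plus the ground truth that produced them."""

    truth: SyntheticTruth
    registry: Registry
    follows: list[FocalFollow]
    interactions: list[InteractionEvent]
    alphas: dict[str, dict[str, float]]  # activity -> focal_id -> alpha_j

    def manifest(self) -> dict:
        return {
            "seed": self.truth.seed,
            "truth": dataclasses.asdict(self.truth) | {
                "window": [d.isoformat() for d in self.truth.window],
            },
            "alphas": self.alphas,
        }


def generate_observations(
    registry: Registry, truth: SyntheticTruth
) -> tuple[list[FocalFollow], list[InteractionEvent], dict[str, dict[str, float]]]:
    """Draw follows, aggregation membership, and interaction events.

    Counts are generated at the dyad level from the negative-binomial
    regression and then scattered multinomially (weights proportional to
    follow duration) across the follows in which the partner was present;
    the analysis consumes dyad totals, so within-follow placement is free.
    A small number of non-affiliative ("other") events is added to exercise
    the affiliative filter. Deterministic given ``truth.seed``.
    """
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(truth.seed).spawn(2)[1]
    ))
    start_date, end_date = truth.window
    n_days = (end_date - start_date).days
    focals = synthetic_focal_ids(registry)
    everyone = sorted(r.id for r in registry)
    p_present = truth.presence_probability

    follows: list[FocalFollow] = []
    for activity in ACTIVITIES:
        mean_follows = truth.follows_per_focal.get(activity, 0.0)
        if mean_follows <= 0:
            continue
        for focal_id in focals:
            focal_rec = registry[focal_id]
            n_fol = max(1, int(rng.poisson(mean_follows)))
            n_fol = min(n_fol, n_days)
            day_offsets = np.sort(rng.choice(n_days, size=n_fol, replace=False))
            for i, day in enumerate(day_offsets):
                date = start_date + _dt.timedelta(days=int(day))
                year = _year_fraction(date)
                duration = float(rng.uniform(*truth.duration_range))
                present = []
                for other_id in everyone:
                    if other_id == focal_id:
                        continue
                    other = registry[other_id]
                    if not other.alive_at(year):
                        continue
                    if other.sex == "M" and other.dispersed_from_natal:
                        p = p_present["bull"]
                    elif other.core_group_id == focal_rec.core_group_id:
                        p = p_present["same_group"]
                    else:
                        p = p_present["other_group"]
                    if rng.uniform() < p:
                        present.append(other_id)
                follows.append(FocalFollow(
                    follow_id=f"{focal_id}:{activity}:{i:03d}",
                    focal_id=focal_id,
                    date=date,
                    activity=activity,
                    duration_minutes=duration,
                    present_ids=frozenset(present),
                ))

    interactions: list[InteractionEvent] = []
    alphas: dict[str, dict[str, float]] = {}
    for activity in ACTIVITIES:
        act_follows = [f for f in follows if f.activity == activity]
        if not act_follows:
            continue
        alphas[activity] = {}
        for stratum in ("orphan", "non_orphan"):
            dyads = build_dyad_table(follows, [], registry, activity, stratum)
            if not dyads:
                continue
            spec = ModelSpec(stratum, activity)
            data = prepare_data(dyads, spec)
            beta = truth.beta_for(stratum, activity, spec.covariates)
            alpha = rng.normal(truth.mu_alpha[activity],
                               1.0 / math.sqrt(truth.tau_alpha),
                               size=data.n_focals)
            for fid, a in zip(data.focal_ids, alpha):
                alphas[activity][fid] = float(a)
            mean = data.gamma * np.exp(alpha[data.focal_index] + data.X @ beta)
            p = truth.r / (truth.r + mean)
            counts = rng.negative_binomial(truth.r, p)

            # scatter dyad totals over the follows where the partner was present
            by_focal: dict[str, list[FocalFollow]] = {}
            for f in act_follows:
                by_focal.setdefault(f.focal_id, []).append(f)
            for dyad, y in zip(dyads, counts):
                fols = [f for f in by_focal[dyad.focal_id]
                        if dyad.partner_id in f.present_ids]
                n_extra = int(rng.poisson(truth.other_event_rate))
                if y == 0 and n_extra == 0:
                    continue
                w = np.array([f.duration_minutes for f in fols])
                w = w / w.sum()
                placed = rng.multinomial(int(y), w)
                for f, m in zip(fols, placed):
                    for _ in range(int(m)):
                        interactions.append(InteractionEvent(
                            f.follow_id, dyad.partner_id,
                            str(rng.choice(_AFFILIATIVE))))
                for _ in range(n_extra):
                    f = fols[int(rng.integers(len(fols)))]
                    interactions.append(InteractionEvent(
                        f.follow_id, dyad.partner_id, "other"))
    return follows, interactions, alphas


def generate_dataset(truth: SyntheticTruth) -> SyntheticDataset:
    registry = generate_registry(truth)
    follows, interactions, alphas = generate_observations(registry, truth)
    return SyntheticDataset(truth, registry, follows, interactions, alphas)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write registry/follows/interactions CSVs plus a truth manifest."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.registry.to_csv(outdir / "registry.csv")
    write_follows(dataset.follows, outdir / "follows.csv")
    write_interactions(dataset.interactions, outdir / "interactions.csv")
    with open(outdir / "truth_manifest.json", "w") as fh:
        json.dump(dataset.manifest(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Per-coefficient recovery metrics across simulated replicates."""

    table: pd.DataFrame  # index: coefficient; columns: true, bias, rmse, coverage
    n_replicates: int
    n_converged: int
    n_excluded: int

    @property
    def max_abs_bias(self) -> float:
        return float(self.table["bias"].abs().max())

    @property
    def max_rmse(self) -> float:
        return float(self.table["rmse"].max())

    @property
    def min_coverage(self) -> float:
        return float(self.table["coverage"].min())


def recovery_experiment(
    truth: SyntheticTruth,
    mcmc_config: McmcConfig,
    n_replicates: int,
    stratum: str = "orphan",
    activity: str = "feeding",
    seed: Optional[int] = None,
) -> RecoveryResult:
    """Repeat generate -> fit -> summarize and score coefficient recovery.

    Each replicate simulates a fresh study from ``truth`` (with a replicate-
    specific seed), fits the chosen model, and records the posterior medians
    and 95% credible intervals of the regression coefficients. Replicates
    with any R-hat >= 1.1 are excluded from the metrics and counted.
    Deterministic given ``seed`` (default: ``truth.seed``).
    """
    base = seed if seed is not None else truth.seed
    master = np.random.Generator(np.random.PCG64(np.random.SeedSequence(base)))
    spec = ModelSpec(stratum, activity)
    order = spec.covariates
    true_beta = truth.beta_for(stratum, activity, order)

    medians: list[np.ndarray] = []
    covered: list[np.ndarray] = []
    n_excluded = 0
    for _ in range(n_replicates):
        rep_seed = int(master.integers(2 ** 31))
        fit_seed = int(master.integers(2 ** 31))
        rep_truth = truth.replace(seed=rep_seed)
        registry = generate_registry(rep_truth)
        follows, interactions, _ = generate_observations(registry, rep_truth)
        dyads = build_dyad_table(follows, interactions, registry, activity, stratum)
        result = fit(dyads, spec, dataclasses.replace(mcmc_config, seed=fit_seed))
        if not result.converged:
            n_excluded += 1
            continue
        summ = result.summary()
        rows = summ.loc[[f"beta[{n}]" for n in order]]
        medians.append(rows["median"].to_numpy())
        covered.append((rows["ci_2.5"].to_numpy() <= true_beta)
                       & (true_beta <= rows["ci_97.5"].to_numpy()))

    n_converged = len(medians)
    if n_converged == 0:
        raise RuntimeError("no replicate converged; cannot score recovery")
    med = np.stack(medians)
    cov = np.stack(covered)
    table = pd.DataFrame({
        "true": true_beta,
        "bias": med.mean(axis=0) - true_beta,
        "rmse": np.sqrt(np.mean((med - true_beta) ** 2, axis=0)),
        "coverage": cov.mean(axis=0),
    }, index=pd.Index(order, name="coefficient"))
    return RecoveryResult(table, n_replicates, n_converged, n_excluded)
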