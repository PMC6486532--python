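"""Synthetic diary generation from the IRT-mCTMM.

Generates complete daily-diary studies that emulate the structure of a
year-long COPD e-diary: 14 ordinal items (9 on 0-4, 5 on 0-3), whole-day
missingness (a questionnaire is either fully completed or absent), occasional
multi-day gaps and early dropout.  The same machinery doubles as the fixture
generator for every test and for VPC replicate simulation.

Two simulation paths exist and agree in law (Chapman-Kolmogorov):

* :func:`simulate_subject` steps chain-by-chain over the *observed* days,
  with missing days simply lengthening the elapsed time of one kernel;
* :func:`simulate_dataset` steps all subjects and items on the full daily
  grid at once and then deletes the missing days (much faster for ensembles).

Both evaluate the latent severity and MET at the left endpoint of each
inter-observation interval (piecewise-constant approximation; daily sampling
makes within-interval drift negligible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _spectral
from .model import (
    ItemSpec,
    PopulationParams,
    SubjectEffects,
    PROB_FLOOR,
    DAYS_PER_YEAR,
)

__all__ = [
    "DiaryDataset",
    "MissingnessProfile",
    "default_items",
    "default_population",
    "sample_subject_effects",
    "simulate_subject",
    "simulate_dataset",
    "generate_fixture",
]


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class DiaryDataset:
    """Long-format daily diary observations plus the item catalogue.

    ``records`` has columns ``subject_id, day, item_id, score`` with one row
    per (subject, day, item); a subject-day is either fully present (all
    items) or fully absent.  ``covariates`` optionally carries one row per
    subject (``subject_id, age, sex``).
    """

    records: pd.DataFrame
    items: tuple[ItemSpec, ...]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        df = self.records.copy()
        df["subject_id"] = df["subject_id"].astype(np.int64)
        df["day"] = df["day"].astype(np.int64)
        df["item_id"] = df["item_id"].astype(np.int64)
        df["score"] = df["score"].astype(np.int64)
        df = df.sort_values(["subject_id", "day", "item_id"], kind="stable")
        df = df.reset_index(drop=True)
        self.records = df
        self.validate()

    def validate(self) -> None:
        df = self.records
        if df.empty:
            raise ValueError("empty dataset")
        if (df["day"] < 1).any():
            raise ValueError("study days are 1-based")
        if df.duplicated(["subject_id", "day", "item_id"]).any():
            dup = df[df.duplicated(["subject_id", "day", "item_id"], keep=False)]
            raise ValueError(
                "duplicate (subject, day, item) records, e.g. "
                f"{dup.iloc[0][['subject_id', 'day', 'item_id']].tolist()}"
            )
        catalogue = {it.item_id: it for it in self.items}
        unknown = set(df["item_id"].unique()) - set(catalogue)
        if unknown:
            raise ValueError(f"records reference unknown items {sorted(unknown)}")
        # all-or-none day completeness
        counts = df.groupby(["subject_id", "day"], sort=False).size()
        if (counts != len(self.items)).any():
            bad = counts[counts != len(self.items)].index[0]
            raise ValueError(
                f"subject {bad[0]} day {bad[1]}: partial questionnaire "
                f"({counts.loc[bad]} of {len(self.items)} items); days must be "
                "fully completed or fully missing"
            )
        max_score = df["item_id"].map({i: it.max_score for i, it in catalogue.items()})
        if (df["score"] < 0).any() or (df["score"] > max_score).any():
            bad = df[(df["score"] < 0) | (df["score"] > max_score)].iloc[0]
            raise ValueError(
                f"score {bad['score']} out of range for item {bad['item_id']}"
            )

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observed_days(self, subject_id: int) -> np.ndarray:
        df = self.records
        return np.sort(df.loc[df["subject_id"] == subject_id, "day"].unique())

    def day_table(self) -> pd.DataFrame:
        """One row per observed (subject, day)."""
        return self.records[["subject_id", "day"]].drop_duplicates().reset_index(drop=True)

    def item(self, item_id: int) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


# ---------------------------------------------------------------------------
# default catalogue and population
# ---------------------------------------------------------------------------

# Synthetic but realistic item parameters for the 14-item daily COPD diary
# (9 items scored 0-4, 5 items scored 0-3).  The published instrument's
# estimated parameters are not publicly deposited; these values span the
# typical published IRT ranges (a in [1, 2.5], b spread over [-2, 3]).
_DEFAULT_ITEM_TABLE: dict[int, tuple[int, float, tuple[float, ...]]] = {
    1: (5, 2.2, (-1.4, -0.2, 1.0, 2.4)),
    2: (5, 1.8, (-1.6, -0.4, 0.8, 2.2)),
    3: (4, 1.6, (-1.2, 0.3, 1.8)),
    4: (5, 1.1, (-1.0, 0.1, 1.3, 2.6)),
    5: (5, 2.4, (-1.5, -0.3, 0.9, 2.3)),
    6: (5, 2.3, (-1.3, -0.1, 1.1, 2.5)),
    7: (5, 2.0, (-1.8, -0.6, 0.6, 2.0)),
    8: (4, 1.9, (-0.9, 0.5, 2.1)),
    9: (5, 2.5, (-1.1, 0.0, 1.2, 2.7)),
    10: (4, 2.4, (-0.8, 0.7, 2.3)),
    11: (4, 2.1, (-1.7, -0.5, 1.5)),
    12: (5, 1.5, (-1.9, -0.7, 0.5, 1.9)),
    13: (5, 1.4, (-1.6, -0.2, 1.0, 2.1)),
    14: (4, 1.0, (-0.6, 0.9, 2.8)),
}


def default_items() -> tuple[ItemSpec, ...]:
    """The standard 14-item catalogue (items 3, 8, 10, 11, 14 on 0-3)."""
    return tuple(
        ItemSpec(item_id=i, n_categories=K, a=a, b=b)
        for i, (K, a, b) in sorted(_DEFAULT_ITEM_TABLE.items())
    )


def default_population() -> PopulationParams:
    """Study-like population: slow progression, MET rising 1.2 -> 5.1 days.

    slope_mean 0.007 latent units/year with ~122 %CV between subjects; the
    population MET increases linearly from 1.2 days at day 0 to 5.1 days at
    day 365, with a log-normal interindividual deviation (sd 0.3).
    """
    return PopulationParams(
        items=default_items(),
        slope_mean=0.007,
        slope_sd=0.00854,
        met0=1.2,
        met_tslope=(5.1 - 1.2) / DAYS_PER_YEAR,
        met_iiv_sd=0.3,
        met_mode="shared",
        met_time_mode="linear",
    )


def example_population() -> PopulationParams:
    """A compact 5-item population used for examples and method validation.

    Discriminations span [1, 2.5], cut-points spread over [-2, 2.2] (so every
    category is reachable in a standard-normal population), category counts
    mix the two questionnaire scales, and the Markov structure is a constant
    MET of 2 days with a log-scale IIV of 0.3; progression is 0.2 latent
    units/year with an IIV of 0.1/year.
    """
    items = (
        ItemSpec(1, 5, 1.0, (-2.0, -0.7, 0.6, 2.0)),
        ItemSpec(2, 4, 1.4, (-1.5, 0.0, 1.5)),
        ItemSpec(3, 5, 1.8, (-1.2, -0.1, 1.0, 2.2)),
        ItemSpec(4, 4, 2.1, (-0.8, 0.4, 1.8)),
        ItemSpec(5, 5, 2.5, (-1.8, -0.4, 0.8, 1.6)),
    )
    return PopulationParams(
        items=items,
        slope_mean=0.2,
        slope_sd=0.1,
        met0=2.0,
        met_iiv_sd=0.3,
        met_mode="shared",
        met_time_mode="constant",
    )


# ---------------------------------------------------------------------------
# random effects
# ---------------------------------------------------------------------------


def sample_subject_effects(
    pop: PopulationParams,
    n: int,
    seed=None,
    met_iiv_literal_exponential: bool = False,
) -> list[SubjectEffects]:
    """Draw subject random effects: d0 ~ N(0,1), slope ~ N(mean, sd^2),
    eta_met ~ N(0, omega^2) (log-normal MET model).

    ``met_iiv_literal_exponential`` replaces the log-normal MET model by a
    literal MET_i ~ Exponential(mean MET_pop) draw (alternative reading of an
    "exponential distribution" of the MET variability); not the default.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    d0 = rng.normal(0.0, pop.d0_sd, n)
    slope = rng.normal(pop.slope_mean, pop.slope_sd, n)
    if met_iiv_literal_exponential:
        eta = np.log(rng.exponential(1.0, n))
    else:
        eta = rng.normal(0.0, pop.met_iiv_sd, n)
    return [SubjectEffects(float(a), float(b), float(c)) for a, b, c in zip(d0, slope, eta)]


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------


def _item_arrays(items: Sequence[ItemSpec]):
    Kmax = max(it.n_categories for it in items)
    a = np.array([it.a for it in items])
    b = np.full((len(items), Kmax - 1), np.inf)
    for i, it in enumerate(items):
        b[i, : it.n_categories - 1] = it.b
    K = np.array([it.n_categories for it in items])
    return a, b, K, Kmax


def _pss_matrix(a: np.ndarray, b: np.ndarray, K: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Steady-state probabilities for stacked (lane,) items at severities D.

    ``a, b, K`` are aligned with ``D`` (one entry per lane); returns
    (n, Kmax) with zero probability in categories beyond each lane's K.
    """
    z = a[:, None] * (D[:, None] - b)
    c = np.zeros_like(z)
    np.negative(z, out=c)
    np.clip(c, -700, 700, out=c)
    c = 1.0 / (1.0 + np.exp(c))  # expit, b = inf -> c = 0
    Kmax = b.shape[1] + 1
    p = np.zeros((len(D), Kmax))
    p[:, 0] = 1.0 - c[:, 0]
    p[:, 1:-1] = c[:, :-1] - c[:, 1:]
    p[:, -1] = c[:, -1]
    np.clip(p, 0.0, None, out=p)
    return p


def _floored(p: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Apply the rate-equation probability floor within each lane's K states."""
    valid = np.arange(p.shape[1])[None, :] < K[:, None]
    return np.where(valid, np.maximum(p, PROB_FLOOR), 0.0)


def _met_pop_lanes(pop: PopulationParams, t: float, met0_lanes: np.ndarray) -> np.ndarray:
    """Population MET at time ``t`` for lanes with baseline METs ``met0_lanes``."""
    if pop.met_time_mode == "constant":
        return met0_lanes.astype(float)
    if pop.met_time_mode == "linear":
        return met0_lanes + pop.met_tslope * t
    return met0_lanes * (1.0 + t) ** pop.met_tslope


def _sample_categorical(rng, p: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from probability matrix p (n, K)."""
    cum = np.cumsum(p, axis=1)
    cum /= cum[:, -1][:, None]
    u = rng.random(len(p))
    return (cum < u[:, None]).sum(axis=1)


def simulate_subject(
    pop: PopulationParams,
    effects: SubjectEffects,
    observed_days: Sequence[int],
    seed=None,
    subject_id: int = 1,
) -> pd.DataFrame:
    """Simulate one subject's diary on the given observed days.

    The first score of every item is drawn from the steady-state law at the
    first observed day; each later score from the transition-kernel row of
    the previous score, with the elapsed time equal to the day gap (missing
    days lengthen the interval of a single kernel).
    """
    days = np.asarray(list(observed_days), dtype=int)
    if len(days) == 0 or np.any(np.diff(days) <= 0) or days[0] < 1:
        raise ValueError("observed_days must be non-empty, strictly increasing, 1-based")
    rng = np.random.default_rng(seed)
    items = pop.items
    n_items = len(items)
    a, b, K, Kmax = _item_arrays(items)

    D = effects.d0 + effects.slope * days / DAYS_PER_YEAR
    scores = np.empty((len(days), n_items), dtype=int)
    p0 = _pss_matrix(a, b, K, np.full(n_items, D[0]))
    scores[0] = _sample_categorical(rng, p0)
    if len(days) > 1:
        met0 = np.array([pop.met0_for(i) for i in range(n_items)])
        for step in range(1, len(days)):
            t_left = days[step - 1]
            dt = float(days[step] - days[step - 1])
            pss = _pss_matrix(a, b, K, np.full(n_items, D[step - 1]))
            met = _met_pop_lanes(pop, float(t_left), met0) * np.exp(effects.eta_met)
            kern = np.zeros((n_items, Kmax, Kmax))
            for Kv in np.unique(K):
                g = K == Kv
                kern[np.ix_(g, range(Kv), range(Kv))] = _spectral.full_kernels(
                    _floored(pss[g], K[g])[:, :Kv], met[g], np.full(g.sum(), dt)
                )
            rows = kern[np.arange(n_items), scores[step - 1], :]
            scores[step] = _sample_categorical(rng, rows)

    out = pd.DataFrame(
        {
            "subject_id": subject_id,
            "day": np.repeat(days, n_items),
            "item_id": np.tile([it.item_id for it in items], len(days)),
            "score": scores.ravel(),
        }
    )
    return out


def simulate_dataset(
    pop: PopulationParams,
    effects: Sequence[SubjectEffects],
    observed: pd.DataFrame,
    seed=None,
    covariates: pd.DataFrame | None = None,
) -> DiaryDataset:
    """Simulate a whole study on an observed (subject, day) design.

    ``observed`` has columns ``subject_id, day`` listing the completed days
    of each subject (e.g. ``DiaryDataset.day_table()`` to replicate a real
    design).  Internally every chain is advanced on the full daily grid from
    its subject's first observed day and the unobserved days are dropped,
    which is equivalent in law to gap-lengthened kernels and vectorises
    across subjects, items and days.
    """
    rec = _simulate_records(pop, effects, observed, seed)
    return DiaryDataset(records=rec, items=pop.items, covariates=covariates)


def _simulate_records(
    pop: PopulationParams,
    effects: Sequence[SubjectEffects],
    observed: pd.DataFrame,
    seed=None,
) -> pd.DataFrame:
    """Records-only simulation core (skips container validation); see
    :func:`simulate_dataset`."""
    rng = np.random.default_rng(seed)
    items = pop.items
    n_items = len(items)
    a_it, b_it, K_it, Kmax = _item_arrays(items)

    obs = observed[["subject_id", "day"]].drop_duplicates().sort_values(["subject_id", "day"])
    sids = obs["subject_id"].unique()
    if len(effects) != len(sids):
        raise ValueError("need one SubjectEffects per subject in the design")
    first_day = obs.groupby("subject_id")["day"].min().reindex(sids).to_numpy()
    last_day = obs.groupby("subject_id")["day"].max().reindex(sids).to_numpy()
    n_subj = len(sids)
    d0 = np.array([e.d0 for e in effects])
    slope = np.array([e.slope for e in effects])
    eta = np.array([e.eta_met for e in effects])

    # lanes: subject-major, item-minor
    lane_subj = np.repeat(np.arange(n_subj), n_items)
    lane_item = np.tile(np.arange(n_items), n_subj)
    a = a_it[lane_item]
    b = b_it[lane_item]
    K = K_it[lane_item]
    met0 = np.array([pop.met0_for(i) for i in range(n_items)])[lane_item]

    t_min, t_max = int(first_day.min()), int(last_day.max())
    days = np.arange(t_min, t_max + 1)
    state = np.full(n_subj * n_items, -1, dtype=int)
    chunks = []
    for d in days:
        t = float(d)
        D = d0[lane_subj] + slope[lane_subj] * t / DAYS_PER_YEAR
        starting = first_day[lane_subj] == d
        if starting.any():
            pss = _pss_matrix(a[starting], b[starting], K[starting], D[starting])
            state[starting] = _sample_categorical(rng, pss)
        if d > t_min:
            active = (first_day[lane_subj] < d) & (last_day[lane_subj] >= d)
            if active.any():
                t_left = t - 1.0
                D_left = d0[lane_subj[active]] + slope[lane_subj[active]] * t_left / DAYS_PER_YEAR
                pss = _pss_matrix(a[active], b[active], K[active], D_left)
                met = _met_pop_lanes(pop, t_left, met0[active]) * np.exp(eta[lane_subj[active]])
                Ka = K[active]
                kern_rows = np.zeros((active.sum(), Kmax))
                pf = _floored(pss, Ka)
                sa = state[active]
                for Kv in np.unique(Ka):
                    g = Ka == Kv
                    P = _spectral.full_kernels(pf[g][:, :Kv], met[g], np.ones(g.sum()))
                    kern_rows[np.ix_(g, range(Kv))] = P[np.arange(g.sum()), sa[g], :]
                state[active] = _sample_categorical(rng, kern_rows)
        chunks.append(state.copy())

    grid = np.stack(chunks, axis=0)  # (n_days, n_lanes)
    # assemble only observed (subject, day) rows
    sid_to_idx = {s: i for i, s in enumerate(sids)}
    obs_s = obs["subject_id"].map(sid_to_idx).to_numpy()
    obs_d = obs["day"].to_numpy() - t_min
    item_ids = np.array([it.item_id for it in items])
    return pd.DataFrame(
        {
            "subject_id": np.repeat(obs["subject_id"].to_numpy(), n_items),
            "day": np.repeat(obs["day"].to_numpy(), n_items),
            "item_id": np.tile(item_ids, len(obs)),
            "score": grid[obs_d[:, None], (obs_s * n_items)[:, None] + np.arange(n_items)[None, :]].ravel(),
        }
    )


# ---------------------------------------------------------------------------
# study-design fixture generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingnessProfile:
    """Non-informative whole-day missingness emulating the study's diary.

    Defaults reproduce the reported structure at year scale: 28% of subjects
    stop filling in the diary before the end, and the remainder accumulate a
    median of ~13 missing days in episodes with a median length of ~3 days
    (episode count Poisson, episode length geometric).  Rates scale with the
    study length.
    """

    dropout_fraction: float = 0.28
    gap_episodes_per_year: float = 4.33
    mean_gap_length: float = 3.0
    min_dropout_day: int = 14

    @classmethod
    def none(cls) -> "MissingnessProfile":
        return cls(dropout_fraction=0.0, gap_episodes_per_year=0.0)


def generate_fixture(
    n_subjects: int,
    n_days: int,
    pop: PopulationParams | str = "default",
    missingness: MissingnessProfile | None = None,
    seed=None,
) -> DiaryDataset:
    """Generate a complete synthetic study (design + trajectories).

    Returns a :class:`DiaryDataset` with age/sex covariates; the realized
    subject effects are attached as ``dataset.true_effects`` for recovery
    and diagnostic tests.
    """
    if n_subjects < 1 or n_days < 2:
        raise ValueError("need n_subjects >= 1 and n_days >= 2")
    if isinstance(pop, str):
        if pop != "default":
            raise ValueError(f"unknown population preset {pop!r}")
        pop = default_population()
    if missingness is None:
        missingness = MissingnessProfile()
    rng = np.random.default_rng(seed)

    # per-subject observation masks
    rows = []
    for s in range(1, n_subjects + 1):
        mask = np.ones(n_days, dtype=bool)
        if rng.random() < missingness.dropout_fraction:
            lo = min(missingness.min_dropout_day, n_days - 1)
            drop = int(rng.integers(lo, n_days))
            mask[drop:] = False
        n_epi = rng.poisson(missingness.gap_episodes_per_year * n_days / DAYS_PER_YEAR)
        for _ in range(n_epi):
            start = int(rng.integers(1, n_days))
            length = int(rng.geometric(1.0 / missingness.mean_gap_length))
            mask[start : start + length] = False
        mask[0] = True  # the diary starts on day 1
        days = np.nonzero(mask)[0] + 1
        rows.append(pd.DataFrame({"subject_id": s, "day": days}))
    design = pd.concat(rows, ignore_index=True)

    effects = sample_subject_effects(pop, n_subjects, seed=rng)
    age = np.clip(np.round(rng.normal(67, 8, n_subjects)), 42, 85).astype(int)
    sex = np.where(rng.random(n_subjects) < 0.54, "M", "F")
    cov = pd.DataFrame(
        {"subject_id": np.arange(1, n_subjects + 1), "age": age, "sex": sex}
    )
    ds = simulate_dataset(pop, effects, design, seed=rng, covariates=cov)
    ds.true_effects = list(effects)  # type: ignore[attr-defined]
    return ds
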