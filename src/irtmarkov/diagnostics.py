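"""Model-evaluation toolkit: VPCs, residuals, item correlations, Fisher
information.

Visual predictive checks simulate many replicate studies on the observed
(subject, day) design — missingness preserved, fresh random effects per
replicate — and compare observed summary statistics per time bin with the
2.5-97.5 percentile band across replicates:

* ``item_scores``: proportion of observations at each score level;
* ``transitions``: proportion of each (previous score -> current score)
  transition, normalised within the previous-score stratum;
* ``total_score``: 2.5th/50th/97.5th percentiles of the 0-100 scaled total.

Residual diagnostics follow the probability-weighted prediction: IPRED is
the expected score given the previous observation and elapsed time (the
steady state for a chain's first observation), RES = observed - IPRED.  The
item correlation map shows Pearson correlations of residuals between items
off the diagonal and, on the diagonal, the difference between observed and
simulated lag-1 residual autocorrelation (consecutive calendar days only).

Fisher information per item is the expected information of the steady-state
categorical likelihood with respect to the latent severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _spectral
from .inference import _core_loglik, _item_tables, _met_pop_obs, _pack
from .model import (
    DAYS_PER_YEAR,
    PROB_FLOOR,
    ItemSpec,
    PopulationParams,
    SubjectEffects,
    prob_at_or_above,
    steady_state_probs,
)
from .simulate import DiaryDataset, _simulate_records, sample_subject_effects

__all__ = [
    "VpcResult",
    "ipred_and_residuals",
    "item_correlation_map",
    "fisher_information",
    "information_by_percentile",
    "simulate_replicates",
    "vpc",
]

DEFAULT_BIN_DAYS = 28


# ---------------------------------------------------------------------------
# IPRED / residuals
# ---------------------------------------------------------------------------


def _effects_array(dataset: DiaryDataset, effects) -> np.ndarray:
    if isinstance(effects, pd.DataFrame):
        eff = effects.set_index("subject_id").loc[
            dataset.records["subject_id"].unique(), ["d0", "slope", "eta_met"]
        ]
        return eff.to_numpy(dtype=float)
    return np.array([[e.d0, e.slope, e.eta_met] for e in effects], dtype=float)


def ipred_and_residuals(
    dataset: DiaryDataset,
    pop: PopulationParams,
    effects,
) -> pd.DataFrame:
    """Probability-weighted expected scores and residuals per observation.

    ``effects`` is a list of :class:`SubjectEffects` (subject-id order) or a
    frame with columns ``subject_id, d0, slope, eta_met`` (e.g. the
    empirical Bayes estimates of a fit).  IPRED of a chain's first
    observation uses the steady-state law; later observations use the
    transition-kernel row of the previously observed score.
    """
    packed = _pack(dataset)
    eff = _effects_array(dataset, effects)
    a_it, b_it, K_it, Kmax = _item_tables(pop.items)
    item = packed.item
    t = packed.t_eval
    D = eff[packed.subj, 0] + eff[packed.subj, 1] * t / DAYS_PER_YEAR
    b = b_it[item]
    with np.errstate(invalid="ignore"):
        z = a_it[item][:, None] * (D[:, None] - b)
    z = np.where(np.isinf(b), -np.inf, z)
    c = 1.0 / (1.0 + np.exp(-z))
    probs = np.zeros((packed.n_obs, Kmax))
    probs[:, 0] = 1.0 - c[:, 0]
    probs[:, 1:-1] = c[:, :-1] - c[:, 1:]
    probs[:, -1] = c[:, -1]
    np.clip(probs, 0.0, None, out=probs)

    K = K_it[item]
    trans = ~packed.is_first
    met = _met_pop_obs(pop, t, item) * np.exp(eff[packed.subj, 2])
    valid = np.arange(Kmax)[None, :] < K[:, None]
    pi = np.where(valid, np.maximum(probs, PROB_FLOOR), 0.0)
    for Kv in np.unique(K[trans]):
        g = np.nonzero(trans & (K == Kv))[0]
        P = _spectral.full_kernels(pi[g][:, :Kv], met[g], packed.dt[g])
        probs[g, :Kv] = P[np.arange(len(g)), packed.prev[g], :]
        probs[g, Kv:] = 0.0

    ipred = probs @ np.arange(Kmax)
    out = pd.DataFrame(
        {
            "subject_id": packed.subject_ids[packed.subj],
            "day": packed.day.astype(int),
            "item_id": np.array([it.item_id for it in pop.items])[item],
            "score": packed.score,
            "ipred": ipred,
            "res": packed.score - ipred,
        }
    )
    return out.sort_values(["subject_id", "day", "item_id"]).reset_index(drop=True)


def item_correlation_map(
    observed_res: pd.DataFrame,
    simulated_res: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Item-by-item residual correlation matrix.

    Off-diagonal ``[i, j]``: Pearson correlation of the observed residuals of
    items i and j paired on (subject, day).  Diagonal ``[i, i]``: lag-1
    autocorrelation of the observed residuals minus that of the simulated
    residuals, computed over consecutive calendar days only.  Entries with
    fewer than ``min_pairs`` pairs are NaN.
    """
    wide_o = observed_res.pivot_table(index=["subject_id", "day"], columns="item_id", values="res")
    items = list(wide_o.columns)
    n = len(items)
    out = np.full((n, n), np.nan)
    arr = wide_o.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
            if ok.sum() >= min_pairs:
                out[i, j] = out[j, i] = stats.pearsonr(arr[ok, i], arr[ok, j])[0]
    for i, it in enumerate(items):
        ac_o = _lag1_autocorr(observed_res, it, min_pairs)
        ac_s = _lag1_autocorr(simulated_res, it, min_pairs)
        out[i, i] = ac_o - ac_s
    return pd.DataFrame(out, index=items, columns=items)


def _lag1_autocorr(res: pd.DataFrame, item_id: int, min_pairs: int) -> float:
    df = res[res["item_id"] == item_id].sort_values(["subject_id", "day"])
    r = df["res"].to_numpy()
    same = df["subject_id"].to_numpy()
    day = df["day"].to_numpy()
    ok = (same[1:] == same[:-1]) & (day[1:] - day[:-1] == 1)
    if ok.sum() < min_pairs:
        return np.nan
    return float(stats.pearsonr(r[:-1][ok], r[1:][ok])[0])


# ---------------------------------------------------------------------------
# Fisher information
# ---------------------------------------------------------------------------


def fisher_information(item: ItemSpec, D):
    """Expected Fisher information of one item about the latent severity.

    ``I(D) = sum_k p_k(D) (d log p_k / dD)^2`` under the steady-state
    categorical likelihood; for a dichotomous item this reduces to the
    classical ``a^2 P (1 - P)``.  Vectorised over ``D``.
    """
    D = np.asarray(D, dtype=float)
    scalar = D.ndim == 0
    D = np.atleast_1d(D)
    b = np.asarray(item.b)
    c = 1.0 / (1.0 + np.exp(-item.a * (D[:, None] - b[None, :])))
    cd = item.a * c * (1.0 - c)                       # d c_k / dD
    K = item.n_categories
    p = np.zeros((len(D), K))
    dp = np.zeros((len(D), K))
    p[:, 0] = 1.0 - c[:, 0]
    dp[:, 0] = -cd[:, 0]
    p[:, 1:-1] = c[:, :-1] - c[:, 1:]
    dp[:, 1:-1] = cd[:, :-1] - cd[:, 1:]
    p[:, -1] = c[:, -1]
    dp[:, -1] = cd[:, -1]
    info = np.where(p > 1e-300, dp**2 / np.maximum(p, 1e-300), 0.0).sum(axis=1)
    return float(info[0]) if scalar else info


def information_by_percentile(
    pop: PopulationParams,
    percentiles=(5, 50, 95),
    t: float = 0.0,
) -> pd.DataFrame:
    """Per-item information at population severity percentiles.

    The severity at percentile ``q`` and time ``t`` is the standard-normal
    quantile plus the population mean trajectory (baseline by default, where
    the severity is exactly N(0,1)).
    """
    percentiles = list(percentiles)
    for q in percentiles:
        if not 0 < q < 100:
            raise ValueError("percentiles must lie in (0, 100)")
    rows = []
    for q in percentiles:
        D = stats.norm.ppf(q / 100.0) + pop.slope_mean * t / DAYS_PER_YEAR
        for it in pop.items:
            rows.append((it.item_id, q, float(D), fisher_information(it, D)))
    return pd.DataFrame(rows, columns=["item_id", "percentile", "D", "information"])


# ---------------------------------------------------------------------------
# visual predictive checks
# ---------------------------------------------------------------------------


@dataclass
class VpcResult:
    """Observed statistics per bin with simulation percentile bands.

    ``table`` has one row per bin/statistic with columns
    ``observed, lo, hi, median`` (plus the binning identifiers); bands are
    the 2.5-97.5 percentiles across simulation replicates.
    """

    kind: str
    table: pd.DataFrame
    n_sim: int
    stratify_by: str | None = None

    def coverage(self, exclude_degenerate: bool = True) -> float:
        """Fraction of bins whose observed statistic lies inside the band.

        Degenerate cells — a zero-width band coinciding with the observed
        value (statistics essentially never realized, e.g. far-off-diagonal
        transitions) — carry no information and are excluded by default.
        """
        t = self.table.dropna(subset=["observed", "lo", "hi"])
        if exclude_degenerate:
            degen = (t["hi"] == t["lo"]) & (t["observed"] == t["lo"])
            t = t[~degen]
        inside = (t["observed"] >= t["lo"]) & (t["observed"] <= t["hi"])
        return float(inside.mean())


def simulate_replicates(
    dataset: DiaryDataset,
    pop: PopulationParams,
    n_sim: int,
    seed=None,
) -> list[pd.DataFrame]:
    """Simulate ``n_sim`` record frames on the dataset's (subject, day)
    design with fresh random effects per replicate."""
    rng = np.random.default_rng(seed)
    design = dataset.day_table()
    n_subj = dataset.n_subjects
    reps = []
    for _ in range(n_sim):
        eff = sample_subject_effects(pop, n_subj, seed=rng)
        reps.append(_simulate_records(pop, eff, design, seed=rng))
    return reps


def _attach_bins(df: pd.DataFrame, bin_days: int) -> pd.Series:
    return ((df["day"] - 1) // bin_days + 1).rename("bin")


def _item_score_stats(rec: pd.DataFrame, bin_days: int, by_item: bool, grid) -> pd.Series:
    """Proportion of observations at each score level per bin (x item).

    ``grid`` is the complete statistic index; combinations absent from a
    replicate are zero-proportion (the binning design is shared, so the
    denominators are identical across replicates).
    """
    df = rec.copy()
    df["bin"] = _attach_bins(df, bin_days)
    keys = (["item_id"] if by_item else []) + ["bin", "score"]
    denom_keys = (["item_id"] if by_item else []) + ["bin"]
    counts = df.groupby(keys, sort=True).size().reindex(grid, fill_value=0)
    denom = df.groupby(denom_keys, sort=True).size()
    return counts / denom


def _transition_pairs(rec: pd.DataFrame, bin_days: int) -> pd.DataFrame:
    df = rec.sort_values(["subject_id", "item_id", "day"], kind="stable")
    sid = df["subject_id"].to_numpy()
    iid = df["item_id"].to_numpy()
    day = df["day"].to_numpy()
    sc = df["score"].to_numpy()
    same = np.zeros(len(df), dtype=bool)
    same[1:] = (sid[1:] == sid[:-1]) & (iid[1:] == iid[:-1])
    return pd.DataFrame(
        {"bin": (day - 1) // bin_days + 1, "prev": np.where(same, np.roll(sc, 1), -1), "cur": sc}
    )[same]


def _transition_stats(rec: pd.DataFrame, bin_days: int, grid) -> pd.Series:
    """Conditional transition proportions P(cur | prev, bin), pooled items.

    Combinations absent from a replicate count as zero; a (bin, prev) cell
    with no transitions at all in a replicate is undefined (NaN).
    """
    tr = _transition_pairs(rec, bin_days)
    counts = tr.groupby(["bin", "prev", "cur"], sort=True).size().reindex(grid, fill_value=0)
    denom = tr.groupby(["bin", "prev"], sort=True).size()
    prop = counts / denom
    return prop


def _total_score_stats(
    rec: pd.DataFrame, items, bin_days: int, qs=(2.5, 50.0, 97.5)
) -> pd.Series:
    from .scoring import _max_raw

    tot = rec.groupby(["subject_id", "day"], sort=False)["score"].sum().reset_index()
    tot["scaled"] = 100.0 * tot["score"] / _max_raw(items)
    tot["bin"] = _attach_bins(tot, bin_days)
    out = tot.groupby("bin")["scaled"].quantile([q / 100 for q in qs])
    out.index = out.index.set_names(["bin", "quantile"])
    return out


def vpc(
    dataset: DiaryDataset,
    pop: PopulationParams,
    kind: str = "item_scores",
    n_sim: int = 1000,
    seed=None,
    bin_days: int = DEFAULT_BIN_DAYS,
    stratify_by: str | None = None,
    replicates: list[pd.DataFrame] | None = None,
) -> VpcResult:
    """Visual predictive check of one statistic family.

    ``kind`` is one of ``item_scores``, ``item_scores_by_item``,
    ``transitions``, ``total_score``.  ``replicates`` allows reusing one
    simulated ensemble across several calls; otherwise ``n_sim`` replicates
    are simulated on the observed design.  ``stratify_by`` names a subject
    covariate column; the VPC is then computed per stratum.
    """
    if replicates is None:
        if n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        replicates = simulate_replicates(dataset, pop, n_sim, seed)
    n_sim = len(replicates)

    strata = {None: None}
    if stratify_by is not None:
        if dataset.covariates is None or stratify_by not in dataset.covariates:
            raise ValueError(f"unknown stratum column {stratify_by!r}")
        cov = dataset.covariates.set_index("subject_id")[stratify_by]
        strata = {lvl: set(cov[cov == lvl].index) for lvl in sorted(cov.unique())}

    # complete statistic grids so that zero counts enter the bands as zeros
    bins = sorted(set((dataset.records["day"] - 1) // bin_days + 1))
    levels = list(range(max(it.n_categories for it in dataset.items)))
    item_ids = sorted(it.item_id for it in dataset.items)
    if kind == "item_scores":
        grid = pd.MultiIndex.from_product([bins, levels], names=["bin", "score"])
    elif kind == "item_scores_by_item":
        grid = pd.MultiIndex.from_tuples(
            [
                (i, b, s)
                for i in item_ids
                for b in bins
                for s in range(dataset.item(i).n_categories)
            ],
            names=["item_id", "bin", "score"],
        )
    elif kind == "transitions":
        grid = pd.MultiIndex.from_product(
            [bins, levels, levels], names=["bin", "prev", "cur"]
        )
    elif kind == "total_score":
        grid = None
    else:
        raise ValueError(f"unknown VPC kind {kind!r}")

    def stat_fn(rec):
        if kind in ("item_scores", "item_scores_by_item"):
            return _item_score_stats(rec, bin_days, kind == "item_scores_by_item", grid)
        if kind == "transitions":
            return _transition_stats(rec, bin_days, grid)
        return _total_score_stats(rec, dataset.items, bin_days)

    frames = []
    for level, members in strata.items():
        def subset(rec):
            if members is None:
                return rec
            return rec[rec["subject_id"].isin(members)]

        obs = stat_fn(subset(dataset.records))
        sims = pd.concat(
            [stat_fn(subset(r)) for r in replicates], axis=1
        )
        sims = sims.reindex(obs.index)
        lo = sims.quantile(0.025, axis=1)
        hi = sims.quantile(0.975, axis=1)
        med = sims.quantile(0.5, axis=1)
        tab = pd.DataFrame(
            {"observed": obs, "lo": lo, "hi": hi, "median": med}
        ).reset_index()
        if level is not None:
            tab.insert(0, "stratum", level)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    return VpcResult(kind=kind, table=table, n_sim=n_sim, stratify_by=stratify_by)


# ---------------------------------------------------------------------------
# plotting (thin matplotlib wrappers)
# ---------------------------------------------------------------------------


def plot_vpc(result: VpcResult, path=None, ax=None):
    """Observed statistic vs simulation band, one panel per statistic group."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = result.table
    group_cols = [c for c in tab.columns if c not in ("bin", "observed", "lo", "hi", "median")]
    groups = list(tab.groupby(group_cols)) if group_cols else [((), tab)]
    n = len(groups)
    ncol = min(5, max(1, int(np.ceil(np.sqrt(n)))))
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    for ax_, (key, grp) in zip(axes.ravel(), groups):
        grp = grp.sort_values("bin")
        ax_.fill_between(grp["bin"], grp["lo"], grp["hi"], alpha=0.3, color="grey")
        ax_.plot(grp["bin"], grp["observed"], "k-", lw=1)
        ax_.set_title(str(key), fontsize=7)
    for ax_ in axes.ravel()[n:]:
        ax_.axis("off")
    fig.suptitle(f"VPC: {result.kind} (n_sim={result.n_sim})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_correlation_map(corr: pd.DataFrame, path=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="residual correlation / autocorr. difference")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
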