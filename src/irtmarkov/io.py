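"""File formats and run configuration.

Diary data travel as long (tidy) CSV with columns
``subject_id, day, item_id, score`` (1-based study days); populations and
fit results as JSON; run configuration as YAML.  Reading validates the
all-or-none day-completeness rule, duplicates and score ranges, reporting
offending line numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import FitResult
from .model import ItemSpec, PopulationParams
from .simulate import DiaryDataset, default_items

__all__ = [
    "RunConfig",
    "read_diary_csv",
    "write_diary_csv",
    "population_to_dict",
    "population_from_dict",
    "write_population_json",
    "read_population_json",
    "write_fit_result",
    "default_config",
]

log = logging.getLogger("irtmarkov")

REQUIRED_COLUMNS = ("subject_id", "day", "item_id", "score")


def read_diary_csv(path, items=None) -> DiaryDataset:
    """Read and validate a long-format diary CSV.

    ``items`` optionally supplies the catalogue.  Without it the reader
    looks for a sibling ``<stem>.items.json`` instrument file (written by
    :func:`write_diary_csv`), then falls back to the standard 14-item
    catalogue when the item ids and observed scores are consistent with it,
    and finally infers category counts from the largest observed score per
    item (logged, since rare top categories may be absent).  A sibling
    ``<stem>.covariates.csv`` file is picked up automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty diary file")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    for col in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad |= coerced.isna() | (coerced != coerced.round())
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:20]  # header is line 1
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df = df[list(REQUIRED_COLUMNS)].astype(int)

    max_scores = df.groupby("item_id")["score"].max()
    if items is None:
        items_path = path.parent / (path.stem + ".items.json")
        defaults = {it.item_id: it for it in default_items()}
        if items_path.exists():
            spec = json.loads(items_path.read_text())
            items = tuple(
                ItemSpec(
                    int(d["item_id"]),
                    int(d["n_categories"]),
                    1.0,
                    tuple(np.linspace(-2, 2, int(d["n_categories"]) - 1)),
                )
                for d in spec
            )
        elif set(max_scores.index) <= set(defaults) and all(
            k <= defaults[i].max_score for i, k in max_scores.items()
        ):
            items = tuple(defaults[i] for i in sorted(max_scores.index))
        else:
            log.warning("%s: inferring category counts from observed scores", path)
            items = tuple(
                ItemSpec(int(i), int(k) + 1, 1.0, tuple(np.linspace(-2, 2, int(k))))
                for i, k in max_scores.items()
            )
    cov_path = path.parent / (path.stem + ".covariates.csv")
    covariates = pd.read_csv(cov_path) if cov_path.exists() else None
    return DiaryDataset(records=df, items=items, covariates=covariates)


def write_diary_csv(dataset: DiaryDataset, path) -> None:
    """Write the records, the instrument sidecar (item category counts) and
    the covariates (sibling files) to CSV/JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.records.to_csv(path, index=False)
    spec = [
        {"item_id": it.item_id, "n_categories": it.n_categories}
        for it in dataset.items
    ]
    (path.parent / (path.stem + ".items.json")).write_text(json.dumps(spec, indent=2))
    if dataset.covariates is not None:
        dataset.covariates.to_csv(path.parent / (path.stem + ".covariates.csv"), index=False)


# ---------------------------------------------------------------------------
# population / fit result JSON
# ---------------------------------------------------------------------------


def population_to_dict(pop: PopulationParams) -> dict:
    return {
        "items": [
            {"item_id": it.item_id, "n_categories": it.n_categories, "a": it.a, "b": list(it.b)}
            for it in pop.items
        ],
        "slope_mean": pop.slope_mean,
        "slope_sd": pop.slope_sd,
        "met0": list(np.atleast_1d(pop.met0)) if pop.met_mode == "per_item" else float(pop.met0),
        "met_tslope": pop.met_tslope,
        "met_iiv_sd": pop.met_iiv_sd,
        "met_mode": pop.met_mode,
        "met_time_mode": pop.met_time_mode,
        "d0_sd": pop.d0_sd,
    }


def population_from_dict(d: dict) -> PopulationParams:
    items = tuple(
        ItemSpec(int(i["item_id"]), int(i["n_categories"]), float(i["a"]), tuple(i["b"]))
        for i in d["items"]
    )
    met0 = d["met0"]
    met0 = tuple(met0) if isinstance(met0, (list, tuple)) else float(met0)
    return PopulationParams(
        items=items,
        slope_mean=float(d.get("slope_mean", 0.0)),
        slope_sd=float(d.get("slope_sd", 0.0)),
        met0=met0,
        met_tslope=float(d.get("met_tslope", 0.0)),
        met_iiv_sd=float(d.get("met_iiv_sd", 0.0)),
        met_mode=d.get("met_mode", "shared"),
        met_time_mode=d.get("met_time_mode", "constant"),
        d0_sd=float(d.get("d0_sd", 1.0)),
    )


def write_population_json(pop: PopulationParams, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(population_to_dict(pop), indent=2))


def read_population_json(path) -> PopulationParams:
    return population_from_dict(json.loads(Path(path).read_text()))


def write_fit_result(result: FitResult, path) -> None:
    """FitResult to JSON (EBEs inline, SEs if computed)."""
    d = {
        "estimates": population_to_dict(result.estimates),
        "ofv": result.ofv,
        "converged": result.converged,
        "n_iter": result.n_iter,
        "message": result.message,
        "fixed": result.fixed,
        "se": result.se,
        "ebes": result.ebes.to_dict(orient="list"),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(d, indent=2))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Run-level options for the command-line pipeline."""

    input: str | None = None
    output_dir: str = "irtmarkov_out"
    seed: int = 1
    met_mode: str = "shared"
    met_time_mode: str = "constant"
    markov: bool = True                  # False fixes MET to 0.1 d (no-Markov)
    estimation_method: str = "laplace"
    max_iter: int = 150
    n_sim: int = 1000
    scoring_transform: str = "linear_0_100"
    vpc_bin_days: int = 28

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def default_config() -> RunConfig:
    return RunConfig()
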