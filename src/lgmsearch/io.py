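"""Wide-CSV readers/writers and run configuration.

Data files are comma-separated UTF-8 with a header row: one row per
subject, wave columns ``y1..yt`` (or any explicit list), an optional
covariate column and an optional subject-id column.  Rows with a missing
wave value are dropped with a warning — the applied workflow analyzes
complete cases.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .population import Dataset

__all__ = ["read_wide_csv", "write_wide_csv", "RunConfig"]


def read_wide_csv(
    path,
    wave_columns: list[str] | None = None,
    wave_prefix: str = "y",
    covariate: str | None = None,
    id_column: str | None = None,
) -> Dataset:
    """Read a wide-format longitudinal CSV into a :class:`Dataset`.

    Wave columns are either listed explicitly or discovered as
    ``<wave_prefix><integer>`` headers sorted by wave number.  Incomplete
    rows are dropped with a warning carrying the count.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if wave_columns is None:
        found = []
        for col in frame.columns:
            if col.startswith(wave_prefix) and col[len(wave_prefix):].isdigit():
                found.append((int(col[len(wave_prefix):]), col))
        wave_columns = [c for _, c in sorted(found)]
    if len(wave_columns) < 3:
        raise ValueError(
            f"found {len(wave_columns)} wave columns "
            f"(prefix {wave_prefix!r}) in {path}; need at least 3"
        )
    missing = [c for c in wave_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"wave columns {missing} not present in {path}")
    if id_column is not None:
        dup = frame[id_column].duplicated()
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate subject ids in column "
                f"{id_column!r} of {path}"
            )

    sub = frame[wave_columns]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & sub.notna()
    if bad_cells.any().any():
        raise ValueError(
            f"non-numeric wave cells in {path} "
            f"(first offending column: {bad_cells.any().idxmax()})"
        )
    complete = numeric.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(
            f"dropped {dropped} incomplete row(s) from {path}", stacklevel=2
        )
    y = numeric[complete].to_numpy(dtype=float)
    w = None
    if covariate is not None:
        if covariate not in frame.columns:
            raise ValueError(f"covariate column {covariate!r} not in {path}")
        w_series = pd.to_numeric(frame[covariate], errors="coerce")
        if (w_series.isna() & frame[covariate].notna()).any():
            raise ValueError(f"non-numeric covariate cells in {path}")
        w = w_series[complete].to_numpy(dtype=float)
    return Dataset(y=y, w=w, meta={"path": str(path), "dropped_rows": dropped})


def write_wide_csv(dataset: Dataset, path) -> None:
    """Write a dataset as wide CSV: columns ``y1..yt`` plus ``w``."""
    t = dataset.n_waves
    frame = pd.DataFrame(
        dataset.y, columns=[f"y{j + 1}" for j in range(t)]
    )
    if dataset.w is not None:
        frame["w"] = dataset.w
    frame.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a Monte Carlo run, YAML round-trippable.

    Grid selectors of ``None`` mean "the full factor"; the switch
    defaults equal the package's documented design choices.
    """

    reps: int = 50
    master_seed: int = 0
    starting_models: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    criteria: list[str] = field(
        default_factory=lambda: ["lrt", "cfi", "rmsea", "srmr", "aic", "bic"]
    )
    trajectories: list[str] | None = None
    residuals: list[str] | None = None
    gammas: list[float] | None = None
    sample_sizes: list[int] | None = None
    alpha_linear: list[float] = field(default_factory=lambda: [1.0, 0.5])
    alpha_quadratic: list[float] = field(
        default_factory=lambda: [1.0, 0.5, 0.1]
    )
    covariate_interpretation: str = "standardized"
    srmr_include_means: bool = True
    lrt_alpha: float = 0.05
    include_flagged: bool = True
    output_dir: str = "results"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    data = yaml.safe_load(fh)
            except (FileNotFoundError, OSError):
                data = yaml.safe_load(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
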