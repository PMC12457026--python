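"""Reading, writing and validation of trait tables and configurations.

On-disk schema (comma-delimited, header row, missing values as empty
fields)::

    clone_id,treatment,generation,age_h,eye_mm,body_mm,repro_count

Header matching is case-insensitive.  Rows with missing trait values are
retained — each analysis applies trait-wise complete-case filtering — but
structural problems (unknown treatment or generation labels, non-numeric or
non-positive age, negative trait values) are hard errors that name the
offending rows.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import COLUMNS, GENERATIONS, TREATMENTS, TraitDataset, ValidationError
from .simulate import SimulationConfig, TraitConfig

log = logging.getLogger("traitvar")


def write_dataset(dataset: TraitDataset, path: str | Path) -> None:
    df = dataset.df[list(COLUMNS)].copy()
    df.to_csv(path, index=False, float_format="%.10g")


def _rows(mask: pd.Series) -> list[int]:
    # 1-based data-row numbers (header is row 0)
    return [int(i) + 1 for i in np.where(mask.to_numpy())[0]]


def read_dataset(path: str | Path) -> TraitDataset:
    """Read and validate a trait table; raises ValidationError naming the
    offending rows on schema violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"clone_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[list(COLUMNS)]
    df["treatment"] = df["treatment"].astype(str).str.strip().str.upper()
    df["generation"] = df["generation"].astype(str).str.strip().str.upper()

    problems = []
    bad = ~df["treatment"].isin(TREATMENTS)
    if bad.any():
        problems.append(f"unknown treatment labels in rows {_rows(bad)}")
    bad = ~df["generation"].isin(GENERATIONS)
    if bad.any():
        problems.append(f"unknown generation labels in rows {_rows(bad)}")
    for col in ("age_h", "eye_mm", "body_mm", "repro_count"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            problems.append(f"non-numeric {col} in rows {_rows(bad)}")
        df[col] = coerced
    bad = df["age_h"].notna() & (df["age_h"] <= 0)
    if bad.any():
        problems.append(f"non-positive age_h in rows {_rows(bad)}")
    for col in ("eye_mm", "body_mm", "repro_count"):
        bad = df[col].notna() & (df[col] < 0)
        if bad.any():
            problems.append(f"negative {col} in rows {_rows(bad)}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    n_missing = int(df[["eye_mm", "body_mm", "repro_count"]].isna().sum().sum())
    if n_missing:
        log.info("%s: %d missing trait values retained (trait-wise complete case)",
                 path, n_missing)
    return TraitDataset(df)


def _cell_key(s: str) -> tuple[str, str]:
    t, g = s.split()
    return (t, g)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for name, tc in d["traits"].items():
        tc["cell_offsets"] = {f"{t} {g}": v for (t, g), v in tc["cell_offsets"].items()}
        if isinstance(tc["residual_sd"], dict):
            tc["residual_sd"] = {f"{t} {g}": v for (t, g), v in tc["residual_sd"].items()}
    d["age_range"] = list(d["age_range"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    traits = {}
    for name, tc in d.get("traits", {}).items():
        tc = dict(tc)
        tc["cell_offsets"] = {_cell_key(k): v for k, v in tc.get("cell_offsets", {}).items()}
        rs = tc.get("residual_sd", 1.0)
        if isinstance(rs, dict):
            tc["residual_sd"] = {_cell_key(k): v for k, v in rs.items()}
        traits[name] = TraitConfig(**tc)
    d["traits"] = traits
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    return SimulationConfig(**d)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_config(path: str | Path) -> SimulationConfig:
    cfg = config_from_dict(yaml.safe_load(Path(path).read_text()))
    cfg.validate()
    return cfg
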