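"""Seeded synthetic data for the clonal split-brood factorial design.

The generator emulates the study design every downstream stage expects:
8 clonal genotypes x 3 dietary treatments (AA, CA, CC) x 2 generations
(G2, G3), ~15 individuals per clone x treatment, measurement age 132 +/- 12 h.
Each trait value is built additively:

    value = grand mean + cell offset + clone intercept
            (+ clone x environment intercept) + age slope * (age - 132)
            + residual with the cell's residual sd

Clone intercepts are drawn once per clone and shared across all of that
clone's cells, mirroring the split-clone design (the same genotype appears
in every treatment).  Cells are treated as independent samples with
cell-specific parameters — no explicit pedigree — because every analysis
conditions only on cell and clone labels.  Reproduction is Gaussian, then
rounded and floored at zero (a Poisson option exists for robustness
experiments); the Gaussian route keeps mean and variance decoupled, which
the count model would forbid.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    CELLS,
    DESIGN_AGE_H,
    GENERATIONS,
    TRAIT_COLUMNS,
    TREATMENTS,
    TraitDataset,
    ValidationError,
)
from .mechanisms import (
    DESIGN_ENVIRONMENTS,
    STRESSED,
    MechanismSpec,
    expected_variance,
    prediction_matrix,
)

_SIGN_VALUE = {"+": 1.0, "=": 0.0, "-": -1.0}


@dataclass
class TraitConfig:
    """Generating parameters for one trait.

    ``residual_sd`` is either a scalar (constant residual sd in every cell)
    or a ``{(treatment, generation): sd}`` map; ``cell_offsets`` shift each
    cell's mean away from ``grand_mean``.
    """

    grand_mean: float
    cell_offsets: dict[tuple[str, str], float] = field(default_factory=dict)
    clone_sd: float = 0.0
    clone_env_sd: float = 0.0  # clone x treatment intercepts (G x E)
    residual_sd: float | dict[tuple[str, str], float] = 1.0
    age_slope: float = 0.0
    integer: bool = False  # round to a non-negative count (reproduction)
    poisson: bool = False  # count alternative: Poisson at the cell mean

    def cell_sd(self, cell: tuple[str, str]) -> float:
        if isinstance(self.residual_sd, dict):
            if cell not in self.residual_sd:
                raise ValidationError(f"residual_sd missing cell {cell}")
            return float(self.residual_sd[cell])
        return float(self.residual_sd)

    def validate(self, name: str) -> None:
        for attr in ("clone_sd", "clone_env_sd"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{name}.{attr} must be >= 0")
        for cell in CELLS:
            if self.cell_sd(cell) < 0:
                raise ValidationError(f"{name}.residual_sd[{cell}] must be >= 0")


@dataclass
class SimulationConfig:
    """Full design + trait configuration for one synthetic dataset."""

    n_clones: int = 8
    n_per_clone_treatment: int = 15
    traits: dict[str, TraitConfig] = field(default_factory=dict)
    age_mean: float = DESIGN_AGE_H
    age_sd: float = 6.0
    age_range: tuple[float, float] = (120.0, 144.0)
    dropout: float = 0.0  # i.i.d. record attrition probability
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 2:
            raise ValidationError("n_clones must be >= 2 (random-effect estimability)")
        if self.n_per_clone_treatment < 2:
            raise ValidationError(
                "n_per_clone_treatment must be >= 2 (within-cell variance estimability)"
            )
        if not self.traits:
            raise ValidationError("traits must contain at least one TraitConfig")
        unknown = set(self.traits) - set(TRAIT_COLUMNS)
        if unknown:
            raise ValidationError(f"unknown trait names: {sorted(unknown)}")
        if self.age_sd < 0:
            raise ValidationError("age_sd must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        for name, tc in self.traits.items():
            tc.validate(name)


def default_config(seed: int = 0, attrition: bool = False) -> SimulationConfig:
    """Study-scale defaults: cell means and dispersions chosen to match the
    printed trait summaries (eye/body contrasts on the mm scale, reproduction
    counts with treatment-by-generation heteroscedasticity).

    ``attrition=True`` adds 1.25% i.i.d. record dropout so the realised n
    lands near the study's 711 of 720 design slots.
    """
    eye = TraitConfig(
        grand_mean=0.300,
        cell_offsets={
            ("AA", "G2"): 0.0,
            ("CA", "G2"): -0.008,
            ("CC", "G2"): -0.009,
            ("AA", "G3"): 0.006,
            ("CA", "G3"): -0.001,
            ("CC", "G3"): -0.016,
        },
        clone_sd=0.0075,  # clone share ~0.19 of total variance
        residual_sd={  # variance differs by treatment; AA ~47% above CC
            ("AA", "G2"): 0.0170,
            ("AA", "G3"): 0.0170,
            ("CA", "G2"): 0.0155,
            ("CA", "G3"): 0.0155,
            ("CC", "G2"): 0.0140,
            ("CC", "G3"): 0.0140,
        },
        age_slope=0.0004,
    )
    body = TraitConfig(
        grand_mean=2.00,
        cell_offsets={
            ("AA", "G2"): 0.0,
            ("CA", "G2"): -0.22,
            ("CC", "G2"): -0.21,
            ("AA", "G3"): 0.02,
            ("CA", "G3"): -0.05,
            ("CC", "G3"): -0.34,
        },
        clone_sd=0.104,  # clone share ~0.29 of total variance
        residual_sd={  # variance grows ~37% from G2 to G3
            ("AA", "G2"): 0.150,
            ("CA", "G2"): 0.150,
            ("CC", "G2"): 0.150,
            ("AA", "G3"): 0.175,
            ("CA", "G3"): 0.175,
            ("CC", "G3"): 0.175,
        },
        age_slope=0.008,
    )
    repro = TraitConfig(
        grand_mean=24.0,
        cell_offsets={
            ("AA", "G2"): 0.0,
            ("CA", "G2"): -3.2,
            ("CC", "G2"): -5.3,
            ("AA", "G3"): 8.1,
            ("CA", "G3"): 8.2,
            ("CC", "G3"): -5.0,
        },
        clone_sd=1.4,  # clone share ~0.02, clone x diet share ~0.15
        clone_env_sd=3.8,
        residual_sd={  # algae-fed cells more variable; CA G3 the most
            ("AA", "G2"): 9.0,
            ("CA", "G2"): 6.5,
            ("CC", "G2"): 6.5,
            ("AA", "G3"): 10.0,
            ("CA", "G3"): 12.5,
            ("CC", "G3"): 7.3,
        },
        integer=True,
    )
    return SimulationConfig(
        traits={"eye_size": eye, "body_size": body, "reproduction": repro},
        dropout=0.0125 if attrition else 0.0,
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, low, high, size):
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return out


def generate_dataset(config: SimulationConfig) -> TraitDataset:
    """Draw one dataset from the configured design. Same config + seed give
    byte-identical output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_clone, rng_age, rng_resid, rng_drop = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    m, k = config.n_clones, config.n_per_clone_treatment
    clones = [f"C{i + 1}" for i in range(m)]
    rows = {
        "clone_id": np.repeat(clones, k * len(TREATMENTS) * len(GENERATIONS)),
        "treatment": np.tile(np.repeat(TREATMENTS, k * len(GENERATIONS)), m),
        "generation": np.tile(np.repeat(GENERATIONS, k), m * len(TREATMENTS)),
    }
    n = m * k * len(TREATMENTS) * len(GENERATIONS)
    low, high = config.age_range
    age = _truncated_normal(rng_age, config.age_mean, config.age_sd, low, high, n)
    df = pd.DataFrame(rows)
    df["age_h"] = age

    clone_idx = np.repeat(np.arange(m), k * len(TREATMENTS) * len(GENERATIONS))
    trt_idx = pd.Categorical(df["treatment"], categories=TREATMENTS).codes
    cell_keys = list(zip(df["treatment"], df["generation"]))

    for trait, col in TRAIT_COLUMNS.items():
        if trait not in config.traits:
            df[col] = np.nan
            continue
        tc = config.traits[trait]
        u = rng_clone.normal(0.0, tc.clone_sd, m) if tc.clone_sd > 0 else np.zeros(m)
        if tc.clone_env_sd > 0:
            ue = rng_clone.normal(0.0, tc.clone_env_sd, (m, len(TREATMENTS)))
        else:
            ue = np.zeros((m, len(TREATMENTS)))
        offsets = np.array([tc.cell_offsets.get(c, 0.0) for c in cell_keys])
        mu = (
            tc.grand_mean
            + offsets
            + u[clone_idx]
            + ue[clone_idx, trt_idx]
            + tc.age_slope * (age - config.age_mean)
        )
        if tc.poisson and tc.integer:
            values = rng_resid.poisson(np.maximum(mu, 1e-9)).astype(float)
        else:
            sds = np.array([tc.cell_sd(c) for c in cell_keys])
            values = mu + rng_resid.normal(0.0, 1.0, n) * sds
            if tc.integer:
                values = np.maximum(np.rint(values), 0.0)
        df[col] = values

    if config.dropout > 0:
        keep = rng_drop.random(n) >= config.dropout
        df = df.loc[keep].reset_index(drop=True)
    return TraitDataset(df)


def mechanism_config(
    mechanism: MechanismSpec | str,
    base_config: SimulationConfig | None = None,
    effect_size: float = 0.5,
    stress_mean_effect: float | None = None,
) -> SimulationConfig:
    """Rewrite a config's cell means and residual variances so the dataset
    realises one transfer mechanism.

    Per-cell residual variances follow the adjusted-variance model relative
    to each trait's baseline variance (its scalar ``residual_sd`` squared, or
    the AA G2 cell's variance if per-cell).  G3 cell means step away from the
    same-treatment G2 mean by ``sign * effect_size * baseline sd`` following
    the mechanism's predicted mean directions; ``stress_mean_effect`` (same
    units of baseline sd; defaults to ``effect_size``) lowers the mean of
    currently-stressed G2 cells.
    """
    spec = MechanismSpec(mechanism) if isinstance(mechanism, str) else mechanism
    pred = prediction_matrix(spec.mechanism)
    cfg = copy.deepcopy(base_config) if base_config is not None else default_config()
    if stress_mean_effect is None:
        stress_mean_effect = effect_size

    for name, tc in cfg.traits.items():
        base_sd = tc.cell_sd(("AA", "G2")) if isinstance(tc.residual_sd, dict) else tc.cell_sd(("AA", "G2"))
        v0 = base_sd**2
        new_offsets: dict[tuple[str, str], float] = {}
        new_sds: dict[tuple[str, str], float] = {}
        for cell in CELLS:
            trt, gen = cell
            env = DESIGN_ENVIRONMENTS[cell]
            rel_var = expected_variance(spec, env)
            new_sds[cell] = float(np.sqrt(rel_var * v0))
            if gen == "G2":
                off = -stress_mean_effect * base_sd if env.current == STRESSED else 0.0
            else:
                g2_env = DESIGN_ENVIRONMENTS[(trt, "G2")]
                g2_off = -stress_mean_effect * base_sd if g2_env.current == STRESSED else 0.0
                sign = _SIGN_VALUE[pred.mean_sign(env)]
                off = g2_off + sign * effect_size * base_sd
            new_offsets[cell] = off
        cfg.traits[name] = replace(
            tc, cell_offsets=new_offsets, residual_sd=new_sds, poisson=False
        )
    return cfg


def generate_mechanism_dataset(
    mechanism: MechanismSpec | str,
    base_config: SimulationConfig | None = None,
    effect_size: float = 0.5,
    seed: int | None = None,
) -> TraitDataset:
    """Generate a dataset whose cell means and variances realise one
    transfer mechanism's predictions."""
    cfg = mechanism_config(mechanism, base_config, effect_size)
    if seed is not None:
        cfg.seed = seed
    return generate_dataset(cfg)
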