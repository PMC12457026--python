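"""Cross-generational variance mechanisms: predictions and classification.

Three non-mutually-exclusive transfer strategies can shape offspring trait
distributions when parents and offspring experience benign or stressful
environments:

* **condition transfer** — parental condition/resources set offspring
  phenotype (well-provisioned mothers produce larger, more variable broods);
* **anticipatory plasticity** — parents prime offspring for the environment
  the parental environment predicts, paying off when the environments match;
* **diversified bet-hedging** — a genotype inflates among-offspring variance
  under unpredictable environments to stabilise geometric-mean fitness.

Each strategy predicts a signed shift of the offspring-generation mean and
variance relative to the parental generation for each parental:offspring
environment combination.  The adjusted variance for condition ``i`` is

    sigma2_i = E_P(i) * E_C(i) + M_i * s

where ``E_P`` and ``E_C`` are the parental- and current-environment baseline
variance factors, ``M_i`` in {-1, 0, +1} is the mechanism's modulation for
that condition, and ``s`` is the additive within-generation stress shift
(``stress_shift`` below).  Stress is assumed to reduce within-generation
variance, so the default baselines are 1 for a benign environment and
``1 - stress_shift`` for a stressed one; both maps are overridable.

Null hypotheses of variance determination: the variance is set by the
current environment alone, by the parental environment alone, or by their
equal-weight product.

The classifier turns observed generation-to-generation mean and variance
shifts (with uncertainties) into signs and scores each mechanism by how many
of the six (condition x moment) predictions it matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .data import TREATMENTS

BENIGN = "benign"
STRESSED = "stressed"
NONE = "none"

MECHANISMS = ("condition_transfer", "anticipatory", "bet_hedging")
NULL_HYPOTHESES = ("null_current", "null_parental", "null_interaction")


@dataclass(frozen=True)
class EnvironmentPair:
    """A parental:current environment combination.

    ``parental`` is ``'none'`` for first-generation (G2) animals, whose
    mothers were raised in a common garden.
    """

    parental: str
    current: str

    def __post_init__(self) -> None:
        if self.parental not in (BENIGN, STRESSED, NONE):
            raise ValueError(f"invalid parental environment {self.parental!r}")
        if self.current not in (BENIGN, STRESSED):
            raise ValueError(f"invalid current environment {self.current!r}")

    def __str__(self) -> str:
        return f"{self.parental}:{self.current}"


#: fixed design mapping from (treatment, generation) to environments.
#: A = algae (benign diet), C = cyanobacteria (stressful diet); the first
#: letter is the maternal diet, the second the offspring diet.
DESIGN_ENVIRONMENTS: dict[tuple[str, str], EnvironmentPair] = {
    ("AA", "G2"): EnvironmentPair(NONE, BENIGN),
    ("CA", "G2"): EnvironmentPair(NONE, STRESSED),
    ("CC", "G2"): EnvironmentPair(NONE, STRESSED),
    ("AA", "G3"): EnvironmentPair(BENIGN, BENIGN),
    ("CA", "G3"): EnvironmentPair(STRESSED, BENIGN),
    ("CC", "G3"): EnvironmentPair(STRESSED, STRESSED),
}

#: the three intergenerational (G3) conditions, in treatment order
G3_CONDITIONS: dict[str, EnvironmentPair] = {
    "AA": EnvironmentPair(BENIGN, BENIGN),
    "CA": EnvironmentPair(STRESSED, BENIGN),
    "CC": EnvironmentPair(STRESSED, STRESSED),
}

# Per-mechanism predicted (mean, variance) shift signs for the three
# intergenerational conditions, offspring relative to parental generation.
_PREDICTIONS: dict[str, dict[str, tuple[str, str]]] = {
    "condition_transfer": {"AA": ("=", "+"), "CA": ("+", "-"), "CC": ("-", "-")},
    "anticipatory": {"AA": ("=", "+"), "CA": ("=", "="), "CC": ("+", "+")},
    "bet_hedging": {"AA": ("=", "="), "CA": ("=", "+"), "CC": ("=", "-")},
}

_SIGN_TO_M = {"+": 1, "=": 0, "-": -1}


@dataclass(frozen=True)
class PredictionMatrix:
    """Predicted mean/variance shift directions for one mechanism."""

    mechanism: str
    rows: Mapping[EnvironmentPair, tuple[str, str]]

    def mean_sign(self, condition: EnvironmentPair) -> str:
        return self.rows[condition][0]

    def variance_sign(self, condition: EnvironmentPair) -> str:
        return self.rows[condition][1]


def prediction_matrix(mechanism: str) -> PredictionMatrix:
    """Return the predicted mean/variance shift signs for one mechanism."""
    if mechanism not in _PREDICTIONS:
        raise ValueError(
            f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}"
        )
    rows = {
        G3_CONDITIONS[t]: _PREDICTIONS[mechanism][t] for t in ("AA", "CA", "CC")
    }
    return PredictionMatrix(mechanism=mechanism, rows=rows)


def _default_env_map(stress_shift: float) -> dict[str, float]:
    # stress reduces within-generation variance; 'none' (common-garden
    # mothers) contributes no parental modulation
    return {BENIGN: 1.0, STRESSED: 1.0 - stress_shift, NONE: 1.0}


@dataclass
class MechanismSpec:
    """Parameters of the adjusted-variance model for one transfer mechanism.

    ``stress_shift`` is the additive variance term itself (the shift applied
    when the mechanism modulation is +/-1).  ``E_P`` / ``E_C`` map
    environments to baseline variance factors; when omitted they default to
    1 (benign) and ``1 - stress_shift`` (stressed).  For the three named
    mechanisms ``M`` is auto-populated from the prediction matrix's variance
    column; explicit ``M`` entries override.
    """

    mechanism: str
    stress_shift: float = 0.2
    E_P: dict[str, float] = field(default_factory=dict)
    E_C: dict[str, float] = field(default_factory=dict)
    M: dict[EnvironmentPair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = MECHANISMS + NULL_HYPOTHESES
        if self.mechanism not in known:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; expected one of {known}")
        if self.stress_shift < 0:
            raise ValueError("stress_shift must be non-negative")
        defaults = _default_env_map(self.stress_shift)
        self.E_P = {**defaults, **self.E_P}
        self.E_C = {**defaults, **self.E_C}
        for env, v in list(self.E_P.items()) + list(self.E_C.items()):
            if v < 0:
                raise ValueError(f"negative baseline variance factor for {env!r}")
        if self.mechanism in MECHANISMS:
            auto = {
                cond: _SIGN_TO_M[signs[1]]
                for cond, signs in prediction_matrix(self.mechanism).rows.items()
            }
            self.M = {**auto, **self.M}

    def modulation(self, condition: EnvironmentPair) -> int:
        if self.mechanism in NULL_HYPOTHESES:
            return 0
        if condition.parental == NONE:
            # first experimental generation: no intergenerational modulation
            return 0
        if condition not in self.M:
            raise ValueError(f"mechanism {self.mechanism!r} has no M entry for {condition}")
        return self.M[condition]


def expected_variance(spec: MechanismSpec, condition: EnvironmentPair) -> float:
    """Adjusted variance for one condition: ``E_P * E_C + M * stress_shift``.

    Raises if the result is not a valid (positive) variance.
    """
    if spec.mechanism in NULL_HYPOTHESES:
        base = null_variance(spec.mechanism, condition, spec.E_P, spec.E_C)
        m = 0
    else:
        base = spec.E_P[condition.parental] * spec.E_C[condition.current]
        m = spec.modulation(condition)
    var = base + m * spec.stress_shift
    if var <= 0:
        raise ValueError(
            "stress shift exceeds baseline variance: "
            f"condition {condition} gives variance {var:g} <= 0"
        )
    return var


def null_variance(
    hypothesis: str,
    condition: EnvironmentPair,
    E_P: Mapping[str, float],
    E_C: Mapping[str, float],
) -> float:
    """Variance under one of the three null hypotheses of determination."""
    if hypothesis == "null_current":
        return E_C[condition.current]
    if hypothesis == "null_parental":
        if condition.parental == NONE:
            raise ValueError("parental null undefined for first generation")
        return E_P[condition.parental]
    if hypothesis == "null_interaction":
        ep = 1.0 if condition.parental == NONE else E_P[condition.parental]
        return ep * E_C[condition.current]
    raise ValueError(f"unknown null hypothesis {hypothesis!r}; expected one of {NULL_HYPOTHESES}")


@dataclass(frozen=True)
class MomentShift:
    """Observed G2 -> G3 shift of one trait's mean and variance in one
    treatment, with standard errors."""

    mean_delta: float
    mean_se: float
    var_delta: float
    var_se: float


@dataclass
class ClassificationResult:
    """Ranked mechanism scores from sign matching.

    ``scores`` maps mechanism -> matched cells out of 6 (3 conditions x 2
    moments); ``observed_signs`` maps treatment -> (mean sign, variance
    sign); ``ranking`` lists mechanisms best-first; mechanisms sharing a
    score form a tie group in ``tie_groups``.
    """

    scores: dict[str, int]
    observed_signs: dict[str, tuple[str, str]]
    sign_tables: dict[str, dict[str, tuple[bool, bool]]]
    alpha: float

    @property
    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda m: (-self.scores[m], m))

    @property
    def tie_groups(self) -> list[list[str]]:
        groups: dict[int, list[str]] = {}
        for m in self.ranking:
            groups.setdefault(self.scores[m], []).append(m)
        return [groups[s] for s in sorted(groups, reverse=True)]

    @property
    def top(self) -> list[str]:
        """Top-scoring mechanism(s); more than one entry means a tie."""
        return self.tie_groups[0]


def _shift_sign(delta: float, se: float, alpha: float) -> str:
    if not math.isfinite(se) or se < 0:
        raise ValueError(f"non-finite or negative uncertainty: {se!r}")
    if se == 0:
        return "+" if delta > 0 else "-" if delta < 0 else "="
    z = stats.norm.ppf(1 - alpha / 2)
    if abs(delta) <= z * se:
        return "="
    return "+" if delta > 0 else "-"


def classify_mechanism(
    observed: Mapping[str, MomentShift], alpha: float = 0.05
) -> ClassificationResult:
    """Score each transfer mechanism against observed mean/variance shifts.

    ``observed`` maps each treatment (AA, CA, CC) to its G2 -> G3
    :class:`MomentShift`.  A shift whose ``(1 - alpha)`` CI covers zero is
    discretised to '='; otherwise to its sign.  Each mechanism scores the
    number of matching (mean, variance) sign pairs out of six.
    """
    missing = [t for t in TREATMENTS if t not in observed]
    if missing:
        raise ValueError(f"missing observed shifts for treatments: {missing}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    obs_signs = {
        t: (
            _shift_sign(observed[t].mean_delta, observed[t].mean_se, alpha),
            _shift_sign(observed[t].var_delta, observed[t].var_se, alpha),
        )
        for t in TREATMENTS
    }
    scores: dict[str, int] = {}
    tables: dict[str, dict[str, tuple[bool, bool]]] = {}
    for mech in MECHANISMS:
        pred = _PREDICTIONS[mech]
        table = {
            t: (obs_signs[t][0] == pred[t][0], obs_signs[t][1] == pred[t][1])
            for t in TREATMENTS
        }
        tables[mech] = table
        scores[mech] = sum(int(a) + int(b) for a, b in table.values())
    return ClassificationResult(
        scores=scores, observed_signs=obs_signs, sign_tables=tables, alpha=alpha
    )


def prediction_table() -> "pd.DataFrame":
    """All three mechanisms' predicted shift signs as a tidy frame
    (exportable as delimited text)."""
    import pandas as pd

    rows = []
    for mech in MECHANISMS:
        for cond, (m, v) in prediction_matrix(mech).rows.items():
            rows.append(
                {
                    "mechanism": mech,
                    "condition": str(cond),
                    "mean": m,
                    "variance": v,
                }
            )
    return pd.DataFrame(rows)


def plot_mechanism_densities(spec_or_mechanism, ax=None, stress_shift: float = 0.2):
    """Reporting helper: density curves of the expected trait distribution
    under one mechanism for the three intergenerational conditions, offset
    on the x-axis for visibility.  Not a tested numerical surface."""
    import matplotlib.pyplot as plt

    if isinstance(spec_or_mechanism, MechanismSpec):
        spec = spec_or_mechanism
    else:
        spec = MechanismSpec(spec_or_mechanism, stress_shift=stress_shift)
    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(-4, 5, 400)
    for i, (t, cond) in enumerate(G3_CONDITIONS.items()):
        var = expected_variance(spec, cond)
        offset = 0.25 * i
        ax.plot(x, stats.norm.pdf(x, loc=offset, scale=np.sqrt(var)), label=f"{t} ({cond})")
    ax.set_xlabel("trait value (offset by 0.25 per condition)")
    ax.set_ylabel("density")
    ax.legend()
    ax.set_title(spec.mechanism)
    return ax
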