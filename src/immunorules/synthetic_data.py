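"""Synthetic cohorts with the statistical structure of a BCP-ALL panel.

The generator stands in for a clinical flow-cytometry cohort: a patient is
assigned one aberration class (ETV6-RUNX1, KMT2A, hyperdiploidy or none)
from imbalanced priors; graded marker scores are drawn from discretized
right-skewed (log-normal) distributions whose location matches pooled
cohort medians, with class-conditional shifts; binary NG2 follows
class-conditional Bernoulli rates; planted antigen-aberration rules are
then enforced with a configurable penetrance; missingness (per-marker
rates plus one correlated seven-marker block) is injected last and never
touches labels.

The planted associations are idealized as class-exclusive -- the
background classes cannot satisfy a planted premise -- so that rule
recovery by the induction machinery is a well-posed property. Real
cohorts are noisier; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (ABERRATIONS, ImmunoDataset, default_marker_specs)
from .rules import ElementaryCondition

__all__ = ["MarkerModel", "PlantedRule", "SyntheticConfig",
           "default_config", "clean_config", "generate",
           "dataset_matching_counts", "CLASSES"]

#: generator classes; "none" carries no aberration label
CLASSES = ("etv6_runx1", "kmt2a", "hyperdiploidy", "none")

_CLASS_TO_LABEL = {"etv6_runx1": "ETV6-RUNX1", "kmt2a": "KMT2A",
                   "hyperdiploidy": "hyperdiploidy"}

#: global cap of graded scores (well above the largest pooled maximum)
VALUE_CAP = 200


@dataclass(frozen=True)
class MarkerModel:
    """Discretized log-normal model of one graded marker.

    ``median``/``maximum`` calibrate location and spread (the maximum sits
    ~3 sigma above the median on the log scale); ``zero_inflation`` is the
    extra point mass at score 0; ``cap`` truncates the support.
    """

    median: float
    maximum: float
    zero_inflation: float = 0.0
    cap: int = VALUE_CAP

    @property
    def mu(self) -> float:
        return math.log(self.median + 1.0)

    @property
    def sigma(self) -> float:
        return max(0.35, (math.log(self.maximum + 1.0) - self.mu) / 3.0)


@dataclass(frozen=True)
class PlantedRule:
    """A known antigen pattern enforced in a known class."""

    conditions: tuple[ElementaryCondition, ...]
    aberration: str  # one of CLASSES except "none"
    penetrance: float = 0.9

    def __post_init__(self) -> None:
        if self.aberration not in CLASSES or self.aberration == "none":
            raise ValueError(f"unknown aberration class {self.aberration!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        for attr, allowed in self.allowed_values().items():
            if allowed.size == 0:
                raise ValueError(
                    f"planted rule has contradictory conditions on {attr!r}")

    def allowed_values(self) -> dict[str, np.ndarray]:
        """Integer values (0..cap) satisfying all conditions, per marker."""
        grid = np.arange(VALUE_CAP + 1, dtype=float)
        out: dict[str, np.ndarray] = {}
        for cond in self.conditions:
            mask = cond.holds(grid)
            if cond.attribute in out:
                prev = np.zeros(VALUE_CAP + 1, dtype=bool)
                prev[out[cond.attribute].astype(int)] = True
                mask &= prev
            out[cond.attribute] = grid[mask]
        return out


# Pooled (median, maximum) per graded marker, cohort-style calibration.
_BACKGROUND = {
    "CD34": (4, 51), "CD45": (2, 10), "CD10": (27, 164), "CD38": (2, 30),
    "CD20": (0, 15), "CD33": (0, 2), "CD13": (2, 37), "CD22": (2, 14),
    "CD24": (22, 151), "CD9": (3, 58), "CD15+CD65": (0, 3),
    "CD66c": (1, 87), "CD123": (0, 9), "CD81": (3, 25), "cyIgM": (2, 20),
    "TdT": (4, 29),
}

# zero inflation for markers that are absent on most blasts
_ZERO_INFLATION = {"CD20": 0.55, "CD33": 0.70, "CD15+CD65": 0.60,
                   "CD123": 1.00, "CD66c": 0.35}

# class-conditional multiplicative shifts of (median+1), log scale;
# CD123 in hyperdiploidy additionally drops its zero inflation.
_CLASS_SHIFTS = {
    "etv6_runx1": {"CD10": 3.0, "CD38": 2.0, "CD34": 0.5, "CD45": 0.7,
                   "CD81": 0.5, "CD24": 1.3},
    "kmt2a": {"CD10": 0.15, "CD34": 0.4, "CD24": 0.2, "TdT": 0.5,
              "CD15+CD65": 2.5, "CD45": 1.8},
    "hyperdiploidy": {"CD123": 4.0, "CD34": 1.8, "CD66c": 1.6, "CD24": 1.3},
    "none": {},
}
_CLASS_ZERO_INFLATION = {"hyperdiploidy": {"CD123": 0.15}}

# very high CD10 occurs only with ETV6-RUNX1 in the generator (keeps the
# planted high-CD10 association class-exclusive)
_CLASS_CAPS = {"kmt2a": {"CD10": 97}, "hyperdiploidy": {"CD10": 97},
               "none": {"CD10": 97}}

_NG2_RATES = {"etv6_runx1": 0.0, "kmt2a": 0.55, "hyperdiploidy": 0.0,
              "none": 0.0}

#: the correlated missing block (seven markers missing together)
BLOCK_MARKERS = ("CD66c", "cyIgM", "CD33", "CD13", "CD22", "CD9", "CD81")

# per-marker independent missing rates; block markers get their cohort
# target minus the 6% block contribution
_MISSING_RATES = {
    "CD13": 0.32, "CD33": 0.26, "cyIgM": 0.24, "CD66c": 0.21,
    "CD22": 0.21, "CD9": 0.20, "CD81": 0.19,
    "CD15+CD65": 0.24, "NG2": 0.10, "CD123": 0.08, "TdT": 0.08,
    "CD20": 0.05, "CD38": 0.05, "CD34": 0.02, "CD45": 0.02,
    "CD10": 0.03, "CD24": 0.04,
}

_LABEL_MISSING = {"ETV6-RUNX1": 0.24, "KMT2A": 0.03, "hyperdiploidy": 0.20}


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int = 818
    seed: int = 0
    class_priors: dict[str, float] = field(default_factory=dict)
    marker_models: dict[str, MarkerModel] = field(default_factory=dict)
    class_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    class_zero_inflation: dict[str, dict[str, float]] = field(default_factory=dict)
    class_caps: dict[str, dict[str, int]] = field(default_factory=dict)
    ng2_rates: dict[str, float] = field(default_factory=dict)
    planted_rules: list[PlantedRule] = field(default_factory=list)
    missing_rates: dict[str, float] = field(default_factory=dict)
    block_markers: tuple[str, ...] = BLOCK_MARKERS
    block_fraction: float = 0.06
    label_missing_rates: dict[str, float] = field(default_factory=dict)
    coaberration_rate: float = 0.0  # chance of a second positive label
    marker_correlation: float = 0.0  # shared latent factor across markers

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.class_priors:
            total = sum(self.class_priors.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError("class priors must sum to 1")
        for rate in list(self.missing_rates.values()) + [self.block_fraction]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")


def default_config(n_patients: int = 818, seed: int = 0) -> SyntheticConfig:
    """The default cohort emulation.

    Class priors follow the cohort's imbalanced distribution
    (ETV6-RUNX1 : KMT2A : hyperdiploidy : none = 52 : 17 : 124 : 257);
    marker models target the pooled descriptive statistics; the planted
    rules encode the headline antigen-aberration associations
    (KMT2A => NG2 = 1 and CD24 <= 4; hyperdiploidy => CD123 >= 1;
    ETV6-RUNX1 => CD81 <= 4 and CD10 >= 98) at penetrance 0.9; missingness
    reaches 36% for CD13 including a correlated seven-marker block on 6%
    of patients.
    """
    counts = {"etv6_runx1": 52, "kmt2a": 17, "hyperdiploidy": 124,
              "none": 257}
    total = sum(counts.values())
    priors = {k: v / total for k, v in counts.items()}
    models = {name: MarkerModel(med, mx,
                                zero_inflation=_ZERO_INFLATION.get(name, 0.0))
              for name, (med, mx) in _BACKGROUND.items()}
    planted = [
        PlantedRule((ElementaryCondition("NG2", "=", 1.0),
                     ElementaryCondition("CD24", "<=", 4.0)), "kmt2a", 0.9),
        PlantedRule((ElementaryCondition("CD123", ">=", 1.0),),
                    "hyperdiploidy", 0.9),
        PlantedRule((ElementaryCondition("CD81", "<=", 4.0),
                     ElementaryCondition("CD10", ">=", 98.0)),
                    "etv6_runx1", 0.9),
    ]
    return SyntheticConfig(
        n_patients=n_patients,
        seed=seed,
        class_priors=priors,
        marker_models=models,
        class_shifts={k: dict(v) for k, v in _CLASS_SHIFTS.items()},
        class_zero_inflation={k: dict(v) for k, v in _CLASS_ZERO_INFLATION.items()},
        class_caps={k: dict(v) for k, v in _CLASS_CAPS.items()},
        ng2_rates=dict(_NG2_RATES),
        planted_rules=planted,
        missing_rates=dict(_MISSING_RATES),
        label_missing_rates=dict(_LABEL_MISSING),
    )


def clean_config(n_patients: int = 500, seed: int = 0,
                 penetrance: float = 1.0) -> SyntheticConfig:
    """Default cohort without missingness and with full-penetrance rules.

    Convenience for rule-recovery experiments: same classes and marker
    structure, but every planted rule holds deterministically and no value
    or label is masked.
    """
    cfg = default_config(n_patients=n_patients, seed=seed)
    cfg.planted_rules = [replace(r, penetrance=penetrance)
                         for r in cfg.planted_rules]
    cfg.missing_rates = {}
    cfg.block_fraction = 0.0
    cfg.label_missing_rates = {}
    return cfg


def _satisfying_value(cond: ElementaryCondition) -> float:
    """Smallest-effort integer value satisfying one condition."""
    v = cond.value
    if cond.relation == "=":
        return v
    if cond.relation == ">":
        return math.floor(v) + 1.0
    if cond.relation == ">=":
        return float(math.ceil(v))
    if cond.relation == "<":
        return max(0.0, math.ceil(v) - 1.0)
    return float(math.floor(v))  # <=


def dataset_matching_counts(premise, aberration: str, p: int, n: int,
                            P: int, N: int,
                            conclusion_is_positive: bool = False
                            ) -> ImmunoDataset:
    """Minimal dataset realizing given contingency counts for a premise.

    Constructs ``P`` patients of the rule's conclusion class (``p`` of them
    satisfying every condition of ``premise``) and ``N`` of the opposite
    class (``n`` satisfying); non-satisfying patients violate the first
    condition. ``aberration`` names the label column;
    ``conclusion_is_positive`` states whether the conclusion class carries
    the aberration (rules often describe its *absence*). Untested markers
    are zero. Useful for reconstructing published rule statistics from
    their printed counts.
    """
    premise = tuple(premise)
    if not premise:
        raise ValueError("premise must be non-empty")
    if aberration not in ABERRATIONS:
        raise ValueError(f"unknown aberration {aberration!r}")
    specs = default_marker_specs()
    names = [m.name for m in specs]
    total = P + N
    values = pd.DataFrame(0.0, index=pd.RangeIndex(total, name="patient"),
                          columns=names)
    sat = {c.attribute: _satisfying_value(c) for c in premise}
    first_violate = _satisfying_value(premise[0].negate())
    conclusion_rows = np.arange(P)
    other_rows = np.arange(P, total)
    covered = np.concatenate([conclusion_rows[:p], other_rows[:n]])
    uncovered = np.concatenate([conclusion_rows[p:], other_rows[n:]])
    for attr, v in sat.items():
        values.loc[covered, attr] = v
        values.loc[uncovered, attr] = sat[attr]
    values.loc[uncovered, premise[0].attribute] = first_violate
    labels = pd.DataFrame(0.0, index=values.index, columns=list(ABERRATIONS))
    positive_rows = conclusion_rows if conclusion_is_positive else other_rows
    labels.loc[positive_rows, aberration] = 1.0
    return ImmunoDataset(values, labels, specs)


def _draw_graded(rng: np.random.Generator, model: MarkerModel, shift: float,
                 zero_inflation: float, cap: int, z: np.ndarray) -> np.ndarray:
    mu = math.log((model.median + 1.0) * shift)
    v = np.round(np.exp(mu + model.sigma * z)) - 1.0
    v = np.clip(v, 0, min(model.cap, cap))
    zero = rng.random(v.size) < zero_inflation
    v[zero] = 0.0
    return v


def generate(cfg: SyntheticConfig) -> ImmunoDataset:
    """Draw one synthetic cohort; deterministic given ``cfg.seed``."""
    for rule in cfg.planted_rules:
        rule.allowed_values()  # raises on contradictions
    rng = np.random.default_rng(cfg.seed)
    specs = default_marker_specs()
    names = [m.name for m in specs]
    classes = list(cfg.class_priors) or list(CLASSES)
    probs = np.array([cfg.class_priors.get(c, 0.0) for c in classes])
    cls = rng.choice(len(classes), size=cfg.n_patients, p=probs / probs.sum())
    cls_names = np.array(classes, dtype=object)[cls]

    values = pd.DataFrame(index=pd.RangeIndex(cfg.n_patients, name="patient"),
                          columns=names, dtype=float)
    # shared latent factor induces optional positive inter-marker correlation
    rho = cfg.marker_correlation
    latent = rng.standard_normal(cfg.n_patients)
    for name in names:
        if name == "NG2":
            continue
        model = cfg.marker_models.get(name)
        if model is None:
            raise ValueError(f"no marker model for {name!r}")
        z = rng.standard_normal(cfg.n_patients)
        if rho:
            z = math.sqrt(1 - rho) * z + math.sqrt(rho) * latent
        col = np.empty(cfg.n_patients)
        for ci, cname in enumerate(classes):
            rows = cls == ci
            if not rows.any():
                continue
            shift = cfg.class_shifts.get(cname, {}).get(name, 1.0)
            zi = cfg.class_zero_inflation.get(cname, {}).get(
                name, model.zero_inflation)
            cap = cfg.class_caps.get(cname, {}).get(name, VALUE_CAP)
            col[rows] = _draw_graded(rng, model, shift, zi, cap, z[rows])
        values[name] = col
    ng2 = np.zeros(cfg.n_patients)
    for ci, cname in enumerate(classes):
        rows = cls == ci
        rate = cfg.ng2_rates.get(cname, 0.0)
        ng2[rows] = (rng.random(int(rows.sum())) < rate).astype(float)
    values["NG2"] = ng2

    # enforce planted rules with their penetrance
    for rule in cfg.planted_rules:
        allowed = rule.allowed_values()
        rows = np.flatnonzero(cls_names == rule.aberration)
        hit = rows[rng.random(rows.size) < rule.penetrance]
        for attr, ok in allowed.items():
            model = cfg.marker_models.get(attr)
            if model is not None:  # stay within the marker's plausible range
                bounded = ok[ok <= model.maximum]
                ok = bounded if bounded.size else ok
            col = values[attr].to_numpy()
            satisfied = np.isin(col[hit], ok)
            fix = hit[~satisfied]
            if fix.size:
                col[fix] = rng.choice(ok, size=fix.size)
                values[attr] = col

    # labels: one positive aberration per patient (optionally a second)
    labels = pd.DataFrame(0.0, index=values.index, columns=list(ABERRATIONS))
    for cname, label in _CLASS_TO_LABEL.items():
        labels.loc[cls_names == cname, label] = 1.0
    if cfg.coaberration_rate:
        extra = rng.random(cfg.n_patients) < cfg.coaberration_rate
        for i in np.flatnonzero(extra):
            others = [l for l in ABERRATIONS
                      if labels.iloc[i][l] == 0.0]
            labels.iloc[i, labels.columns.get_loc(rng.choice(others))] = 1.0
    for label, rate in cfg.label_missing_rates.items():
        mask = rng.random(cfg.n_patients) < rate
        labels.loc[mask, label] = np.nan

    # missingness last: independent per-marker rates, then the block
    for name in names:
        rate = cfg.missing_rates.get(name, 0.0)
        if rate:
            mask = rng.random(cfg.n_patients) < rate
            values.loc[mask, name] = np.nan
    if cfg.block_fraction and cfg.block_markers:
        block = rng.random(cfg.n_patients) < cfg.block_fraction
        values.loc[block, list(cfg.block_markers)] = np.nan

    return ImmunoDataset(values, labels, specs)
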