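"""Sequential-covering rule induction and rule statistics.

Rules have the form ``IF w1 AND w2 AND ... AND wn THEN C`` where each
elementary condition ``wi`` tests one marker against a threshold
(``=`` for binary markers, ``<, <=, >, >=`` for graded ones) and ``C`` is a
decision-class identifier. Induction is separate-and-conquer: grow one rule
greedily maximizing the C2 quality measure, prune it, remove the positive
examples it covers, repeat.

Every statistic derives from the rule's 2x2 contingency table
``(p, n, P, N)``: ``p``/``n`` covered examples of the primary/secondary
class, ``P``/``N`` the class totals (the rule's conclusion class plays the
primary role in its own table). The C2 measure is

    C2 = ((N*p - P*n) / (N*(p+n))) * ((P+p) / (2*P))

i.e. a relative-accuracy term weighted by a coverage term; C2 = 1 exactly
for the perfect rule (p = P, n = 0).

Missing-value semantics: a comparison on a missing value is false, so an
example with a missing tested marker is never covered -- neither by a
condition nor by its negation. No imputation is performed anywhere.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_model import DecisionProblem, ImmunoDataset

__all__ = [
    "ElementaryCondition",
    "ContingencyTable",
    "RuleStats",
    "Rule",
    "covers",
    "contingency",
    "c2",
    "precision",
    "coverage",
    "odds_ratio",
    "fisher_p",
    "adjust_pvalues",
    "grow_rule",
    "prune_rule",
    "induce_ruleset",
    "odds_chain",
    "evaluate_negation",
    "evaluate_rule",
]

#: growth stops unless a candidate improves quality by more than this
QUALITY_TOL = 1e-12

_RELATIONS = ("=", "<", "<=", ">", ">=")
_NEGATION = {"<": ">=", "<=": ">", ">": "<=", ">=": "<"}
_PRETTY = {"<=": "≤", ">=": "≥"}


@dataclass(frozen=True)
class ElementaryCondition:
    """One marker test, e.g. ``CD9 > 1`` or ``NG2 = 1``."""

    attribute: str
    relation: str
    value: float

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not math.isfinite(self.value):
            raise ValueError("condition threshold must be finite")

    def holds(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of rows satisfying the condition; NaN is False."""
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            if self.relation == "=":
                out = v == self.value
            elif self.relation == "<":
                out = v < self.value
            elif self.relation == "<=":
                out = v <= self.value
            elif self.relation == ">":
                out = v > self.value
            else:
                out = v >= self.value
        out[np.isnan(v)] = False
        return out

    def negate(self) -> "ElementaryCondition":
        """Logical complement on observed values (binary ``=`` flips 0/1)."""
        if self.relation == "=":
            if self.value not in (0.0, 1.0):
                raise ValueError("can only negate = on binary 0/1 markers")
            return ElementaryCondition(self.attribute, "=", 1.0 - self.value)
        return ElementaryCondition(self.attribute, _NEGATION[self.relation], self.value)

    def __str__(self) -> str:
        rel = _PRETTY.get(self.relation, self.relation)
        value = int(self.value) if float(self.value).is_integer() else self.value
        return f"{self.attribute} {rel} {value}"

    def to_dict(self) -> dict:
        return {"attribute": self.attribute, "relation": self.relation,
                "value": self.value}


@dataclass(frozen=True)
class ContingencyTable:
    """Counts ``(p, n, P, N)`` underlying every rule statistic."""

    p: int
    n: int
    P: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= self.P and 0 <= self.n <= self.N):
            raise ValueError(f"inconsistent contingency table {self}")


def c2(t: ContingencyTable) -> float:
    """The C2 rule quality measure; 1 iff the rule is perfect."""
    if t.p + t.n == 0:
        raise ValueError("C2 undefined for a rule covering no examples")
    if t.P == 0 or t.N == 0:
        raise ValueError("C2 requires both classes to be non-empty")
    wra = (t.N * t.p - t.P * t.n) / (t.N * (t.p + t.n))
    return wra * (t.P + t.p) / (2 * t.P)


def precision(t: ContingencyTable) -> float:
    """p / (p + n)."""
    if t.p + t.n == 0:
        raise ValueError("precision undefined for a rule covering no examples")
    return t.p / (t.p + t.n)


def coverage(t: ContingencyTable) -> float:
    """p / P."""
    if t.P == 0:
        raise ValueError("coverage undefined for an empty primary class")
    return t.p / t.P


def odds_ratio(t: ContingencyTable, haldane: bool = False) -> float:
    """Sample odds ratio ``(p/(P-p)) / (n/(N-n))`` of the rule's 2x2 table.

    With a zero negative cell (n = 0, p > 0) the ratio diverges and +inf is
    returned; ``haldane=True`` applies the Haldane-Anscombe +0.5 correction
    to all four cells instead, which keeps it finite.
    """
    a, b, c_, d = t.p, t.n, t.P - t.p, t.N - t.n
    if haldane:
        a, b, c_, d = a + 0.5, b + 0.5, c_ + 0.5, d + 0.5
        return (a * d) / (b * c_)
    if a == 0 and b == 0:
        raise ValueError("odds ratio undefined: rule covers no examples")
    if c_ == 0 and d == 0:
        raise ValueError("odds ratio undefined: rule covers every example")
    if b == 0 or c_ == 0:  # zero off-diagonal cell: diverges (if covered)
        return math.inf if a > 0 else 0.0
    if a == 0 or d == 0:
        return 0.0
    return (a / c_) / (b / d)


def fisher_p(t: ContingencyTable) -> float:
    """One-sided Fisher exact p-value of the rule's enrichment.

    The hypergeometric tail probability of covering at least ``p``
    primary-class examples when ``p + n`` examples are drawn at random from
    ``P`` primary and ``N`` secondary ones.
    """
    return float(hypergeom.sf(t.p - 1, t.P + t.N, t.P, t.p + t.n))


def adjust_pvalues(ps, method: str = "fdr_bh") -> list[float]:
    """Multiple-testing adjustment (default Benjamini-Hochberg)."""
    ps = list(ps)
    if not ps:
        return []
    return list(multipletests(ps, method=method)[1])


@dataclass(frozen=True)
class RuleStats:
    """Statistics of a rule evaluated on one dataset/problem."""

    table: ContingencyTable
    precision: float
    coverage: float
    c2: float
    odds_ratio: float
    fisher_p: float
    adjusted_p: float | None = None


@dataclass(frozen=True)
class Rule:
    """A conjunction of elementary conditions with a class conclusion."""

    premise: tuple[ElementaryCondition, ...]
    conclusion: str
    stats: RuleStats | None = None
    enforced: tuple[ElementaryCondition, ...] = ()

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(c.attribute for c in self.premise)

    def __str__(self) -> str:
        if not self.premise:
            return f"IF TRUE THEN {self.conclusion}"
        body = " AND ".join(str(c) for c in self.premise)
        return f"IF {body} THEN {self.conclusion}"

    def to_dict(self) -> dict:
        d = {"premise": [c.to_dict() for c in self.premise],
             "conclusion": self.conclusion}
        if self.stats is not None:
            t = self.stats.table
            d["stats"] = {
                "p": t.p, "n": t.n, "P": t.P, "N": t.N,
                "precision": self.stats.precision,
                "coverage": self.stats.coverage,
                "c2": self.stats.c2,
                "odds_ratio": self.stats.odds_ratio,
                "fisher_p": self.stats.fisher_p,
                "adjusted_p": self.stats.adjusted_p,
            }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @staticmethod
    def from_dict(d: dict) -> "Rule":
        premise = tuple(ElementaryCondition(**c) for c in d["premise"])
        rule = Rule(premise, d["conclusion"])
        s = d.get("stats")
        if s is not None:
            table = ContingencyTable(s["p"], s["n"], s["P"], s["N"])
            rule = replace(rule, stats=RuleStats(
                table, s["precision"], s["coverage"], s["c2"],
                s["odds_ratio"], s["fisher_p"], s.get("adjusted_p")))
        return rule


# ---------------------------------------------------------------------------
# coverage and contingency on datasets
# ---------------------------------------------------------------------------

def _cover_mask(premise, values_by_attr: dict[str, np.ndarray], n_rows: int) -> np.ndarray:
    mask = np.ones(n_rows, dtype=bool)
    for cond in premise:
        mask &= cond.holds(values_by_attr[cond.attribute])
    return mask


def covers(premise, ds: ImmunoDataset):
    """Patients covered by the premise (empty premise covers everyone).

    Returns a ``pd.Index``; a condition on a missing value is false, so
    patients with a missing tested marker are never covered.
    """
    cols = {c.attribute: ds.values[c.attribute].to_numpy(float) for c in premise}
    mask = _cover_mask(tuple(premise), cols, ds.n_patients)
    return ds.patients[mask]


def contingency(premise, ds: ImmunoDataset, problem: DecisionProblem,
                conclusion_class: str | None = None) -> ContingencyTable:
    """Contingency table of a premise, with the conclusion class as primary.

    Patients excluded from the problem are ignored entirely. When
    ``conclusion_class`` is the problem's secondary class, the table's
    ``P``/``p`` count that class, so rules for either class are evaluated
    symmetrically.
    """
    if conclusion_class is None:
        conclusion_class = problem.primary_class_name
    sub = ds.subset(problem.assigned)
    y = problem.y.loc[problem.assigned].to_numpy(float)
    if conclusion_class == problem.primary_class_name:
        pos = y == 1
    elif conclusion_class == problem.secondary_class_name:
        pos = y == 0
    else:
        raise ValueError(
            f"{conclusion_class!r} is neither class of problem {problem.id!r}")
    cols = {c.attribute: sub.values[c.attribute].to_numpy(float) for c in premise}
    mask = _cover_mask(tuple(premise), cols, sub.n_patients)
    return ContingencyTable(int((mask & pos).sum()), int((mask & ~pos).sum()),
                            int(pos.sum()), int((~pos).sum()))


def evaluate_rule(rule: Rule, ds: ImmunoDataset, problem: DecisionProblem) -> Rule:
    """Attach statistics computed on ``ds``/``problem`` to the rule."""
    t = contingency(rule.premise, ds, problem, rule.conclusion)
    if t.p + t.n > 0:
        try:
            ratio = odds_ratio(t)  # undefined e.g. for a cover-all premise
        except ValueError:
            ratio = math.nan
        stats = RuleStats(t, precision(t), coverage(t), c2(t),
                          ratio, fisher_p(t))
    else:
        stats = RuleStats(t, math.nan, 0.0 if t.P else math.nan, math.nan,
                          math.nan, 1.0)
    return replace(rule, stats=stats)


# ---------------------------------------------------------------------------
# induction internals: numpy view of one decision problem
# ---------------------------------------------------------------------------

class _ProblemView:
    """Assigned examples of one problem as numpy arrays, for fast induction."""

    def __init__(self, ds: ImmunoDataset, problem: DecisionProblem,
                 conclusion_class: str):
        sub = ds.subset(problem.assigned)
        y = problem.y.loc[problem.assigned].to_numpy(float)
        if conclusion_class == problem.primary_class_name:
            self.pos = y == 1
        elif conclusion_class == problem.secondary_class_name:
            self.pos = y == 0
        else:
            raise ValueError(
                f"{conclusion_class!r} is neither class of problem {problem.id!r}")
        self.patients = sub.patients
        self.columns = {m.name: sub.values[m.name].to_numpy(float)
                        for m in sub.markers}
        self.binary = {m.name for m in sub.markers if m.scale == "binary"}
        self.marker_names = sub.marker_names
        self.n_rows = sub.n_patients

    def cover(self, premise) -> np.ndarray:
        return _cover_mask(tuple(premise), self.columns, self.n_rows)

    def table(self, mask: np.ndarray, row_mask: np.ndarray) -> ContingencyTable:
        pos = self.pos & row_mask
        neg = ~self.pos & row_mask
        return ContingencyTable(int((mask & pos).sum()), int((mask & neg).sum()),
                                int(pos.sum()), int(neg.sum()))


def _quality_or_none(quality, table: ContingencyTable):
    if table.p + table.n == 0:
        return None
    try:
        return quality(table)
    except (ValueError, ZeroDivisionError):
        return None


def _candidate_conditions(view: _ProblemView, covered: np.ndarray,
                          allowed: set[str]):
    """Candidate elementary conditions given the currently covered examples.

    Graded markers contribute ``<`` and ``>=`` tests at midpoints between
    consecutive distinct observed values (within the covered examples);
    binary markers contribute ``= 0`` and ``= 1``. Yielded in a fixed
    deterministic order.
    """
    for name in view.marker_names:
        if name not in allowed:
            continue
        col = view.columns[name]
        obs = np.unique(col[covered & ~np.isnan(col)])
        if name in view.binary:
            for v in obs:
                yield ElementaryCondition(name, "=", float(v))
            continue
        if len(obs) < 2:
            continue
        mids = (obs[:-1] + obs[1:]) / 2.0
        for m in mids:
            yield ElementaryCondition(name, "<", float(m))
            yield ElementaryCondition(name, ">=", float(m))


def _c2_vec(p, n, P, N):
    """Vectorized C2 over count arrays; covering-nothing maps to -inf."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    covered = p + n
    with np.errstate(divide="ignore", invalid="ignore"):
        q = ((N * p - P * n) / (N * covered)) * ((P + p) / (2.0 * P))
    return np.where(covered > 0, q, -np.inf)


#: quality callables with a known vectorized counterpart
_VECTORIZED_QUALITY: dict = {c2: _c2_vec}


def _cond_key(cond: ElementaryCondition):
    return (_NameDesc(cond.attribute), -cond.value, _NameDesc(cond.relation))


def _pair_search(view, covered, row_mask, cands, quality, min_pos):
    """Best two-condition extension of the current premise (exhaustive).

    Returns ``(key_prefix, (cond_i, cond_j), new_cover)`` or None, where
    ``key_prefix = (quality, p)`` for comparison against single extensions.
    """
    C = len(cands)
    if C < 2:
        return None
    pos = view.pos & row_mask & covered
    neg = ~view.pos & row_mask & covered
    P = int((view.pos & row_mask).sum())
    N = int((~view.pos & row_mask).sum())
    M = np.stack([covered & c.holds(view.columns[c.attribute]) for c in cands])
    p_pair = (M & pos).astype(np.float32) @ M.T.astype(np.float32)
    n_pair = (M & neg).astype(np.float32) @ M.T.astype(np.float32)
    iu = np.triu_indices(C, k=1)
    p_flat, n_flat = p_pair[iu], n_pair[iu]
    vec_quality = _VECTORIZED_QUALITY.get(quality)
    if vec_quality is not None:
        q_flat = vec_quality(p_flat, n_flat, P, N)
    else:
        q_flat = np.full(p_flat.shape, -np.inf)
        for idx in range(len(p_flat)):
            q = _quality_or_none(
                quality, ContingencyTable(int(p_flat[idx]), int(n_flat[idx]),
                                          P, N))
            if q is not None:
                q_flat[idx] = q
    q_flat = np.where(p_flat >= min_pos, q_flat, -np.inf)
    if not np.isfinite(q_flat).any():
        return None
    q_max = q_flat.max()
    best = None
    for idx in np.flatnonzero(q_flat >= q_max - QUALITY_TOL):
        i, j = iu[0][idx], iu[1][idx]
        key = (q_flat[idx], p_flat[idx], *_cond_key(cands[i]),
               *_cond_key(cands[j]))
        if best is None or key > best[0]:
            new_cover = M[i] & M[j]
            best = (key, (cands[i], cands[j]), new_cover)
    return ((best[0][0], best[0][1]), best[1], best[2])


def _grow(view: _ProblemView, row_mask: np.ndarray, quality,
          enforced: tuple[ElementaryCondition, ...],
          forbidden_attributes: frozenset,
          min_covered_positives: int) -> tuple[ElementaryCondition, ...]:
    """Rule growth; returns the premise (enforced conditions first).

    Greedy specialization with one exhaustive two-condition lookahead at
    the first step: the opening move is the best single condition *or*
    the best condition pair, whichever scores higher. This removes the
    classic myopia of pure greedy growth -- C2's coverage term often makes
    a pure-but-partial single condition look better than either member of
    the best pair -- and guarantees the grown rule is at least as good as
    any premise of length <= 2. Subsequent conditions are appended purely
    greedily while they strictly improve quality; growth also stops once
    the rule covers no negatives.
    """
    premise = tuple(enforced)
    covered = view.cover(premise) & row_mask
    t = view.table(covered, row_mask)
    if enforced and t.p == 0:
        raise ValueError("enforced conditions cover no positive examples")
    allowed = set(view.marker_names) - set(forbidden_attributes)
    current_q = -math.inf if not premise else _quality_or_none(quality, t)
    if current_q is None:
        current_q = -math.inf
    first_step = True
    while True:
        t = view.table(covered, row_mask)
        if premise and t.n == 0:
            break  # rule is pure
        cands = list(_candidate_conditions(view, covered, allowed))
        best = None  # ((q, p, *tie), cond, new_cover)
        for cond in cands:
            new_cover = covered & cond.holds(view.columns[cond.attribute])
            nt = view.table(new_cover, row_mask)
            if nt.p < min_covered_positives:
                continue
            q = _quality_or_none(quality, nt)
            if q is None:
                continue
            key = (q, nt.p, *_cond_key(cond))
            if best is None or key > best[0]:
                best = (key, (cond,), new_cover)
        if first_step:
            pair = _pair_search(view, covered, row_mask, cands, quality,
                                min_covered_positives)
            # a pair replaces the single opening only if strictly better
            if pair is not None and (
                    best is None or pair[0][0] > best[0][0] + QUALITY_TOL):
                best = pair
            first_step = False
        if best is None:
            break
        q = best[0][0]
        if q <= current_q + QUALITY_TOL:
            break
        premise = premise + tuple(best[1])
        covered = best[2]
        current_q = q
    return premise


class _NameDesc:
    """Wrapper making lexicographically *smaller* strings compare greater.

    Used inside max-keyed tie-breaking: higher quality first, then higher
    covered-positive count, then attribute name in ascending order, then
    smaller threshold, then relation name ascending.
    """

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __gt__(self, other):
        return self.s < other.s

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def _prune(view: _ProblemView, row_mask: np.ndarray,
           premise: tuple[ElementaryCondition, ...],
           enforced: tuple[ElementaryCondition, ...], quality):
    """Drop non-enforced conditions whose removal does not hurt quality."""
    premise = list(premise)
    enforced_set = set(enforced)

    def q_of(prem):
        mask = view.cover(prem) & row_mask
        return _quality_or_none(quality, view.table(mask, row_mask))

    current_q = q_of(premise)
    if current_q is None:
        return tuple(premise)
    while len(premise) > 1:
        best = None  # (q, index)
        for i, cond in enumerate(premise):
            if cond in enforced_set:
                continue
            q = q_of(premise[:i] + premise[i + 1:])
            if q is None:
                continue
            if best is None or q > best[0]:
                best = (q, i)
        if best is None or best[0] < current_q - QUALITY_TOL:
            break
        current_q = max(current_q, best[0])
        del premise[best[1]]
    return tuple(premise)


# ---------------------------------------------------------------------------
# public induction API
# ---------------------------------------------------------------------------

def grow_rule(ds: ImmunoDataset, problem: DecisionProblem,
              conclusion_class: str | None = None, quality=c2,
              enforced=(), forbidden_attributes=(),
              min_covered_positives: int = 1) -> Rule:
    """Grow a single rule for ``conclusion_class`` by greedy specialization.

    The premise starts from the ``enforced`` conditions (kept verbatim,
    never pruned); candidate conditions -- threshold tests at midpoints of
    consecutive distinct observed values, equality tests for binary
    markers -- are appended greedily while they strictly improve the
    ``quality`` measure, stopping early once no negatives are covered.
    Attributes in ``forbidden_attributes`` are never used for growth.
    """
    if conclusion_class is None:
        conclusion_class = problem.primary_class_name
    view = _ProblemView(ds, problem, conclusion_class)
    if not view.pos.any():
        raise ValueError(f"class {conclusion_class!r} has no examples")
    row_mask = np.ones(view.n_rows, dtype=bool)
    premise = _grow(view, row_mask, quality, tuple(enforced),
                    frozenset(forbidden_attributes), min_covered_positives)
    rule = Rule(premise, conclusion_class, enforced=tuple(enforced))
    return evaluate_rule(rule, ds, problem)


def prune_rule(rule: Rule, ds: ImmunoDataset, problem: DecisionProblem,
               quality=c2) -> Rule:
    """Iteratively remove conditions whose removal does not decrease quality.

    Enforced conditions are never removed; the premise never becomes empty.
    The pruned rule's quality on the same data is >= the input rule's.
    """
    view = _ProblemView(ds, problem, rule.conclusion)
    row_mask = np.ones(view.n_rows, dtype=bool)
    premise = _prune(view, row_mask, rule.premise, rule.enforced, quality)
    return evaluate_rule(replace(rule, premise=premise), ds, problem)


def induce_ruleset(ds: ImmunoDataset, problem: DecisionProblem,
                   conclusion_class: str | None = None, quality=c2,
                   mincov: int = 3, enforced=(), forbidden_attributes=(),
                   adjust_method: str = "fdr_bh") -> list[Rule]:
    """Separate-and-conquer induction of a ruleset for one class.

    Repeats grow + prune, after each accepted rule marking its covered
    positives as satisfied (negatives always stay); stops when fewer than
    ``mincov`` positives remain uncovered or no rule of positive quality
    can be found. Rule statistics are re-evaluated on the full example set
    and Fisher p-values are adjusted across the ruleset (Benjamini-Hochberg
    by default).
    """
    if conclusion_class is None:
        conclusion_class = problem.primary_class_name
    view = _ProblemView(ds, problem, conclusion_class)
    P = int(view.pos.sum())
    if P == 0:
        raise ValueError(f"class {conclusion_class!r} has no examples")
    if mincov > P:
        warnings.warn(
            f"mincov={mincov} exceeds the {P} positives; no rules induced",
            stacklevel=2)
        return []
    uncovered = view.pos.copy()
    rules: list[Rule] = []
    while int(uncovered.sum()) >= mincov:
        row_mask = uncovered | ~view.pos
        try:
            premise = _grow(view, row_mask, quality, tuple(enforced),
                            frozenset(forbidden_attributes), mincov)
        except ValueError:
            break
        if not premise:
            break
        premise = _prune(view, row_mask, premise, tuple(enforced), quality)
        mask = view.cover(premise)
        q = _quality_or_none(quality, view.table(mask & row_mask, row_mask))
        if q is None or q <= 0:
            break
        newly = mask & uncovered
        if not newly.any():
            break
        rules.append(evaluate_rule(Rule(premise, conclusion_class,
                                        enforced=tuple(enforced)), ds, problem))
        uncovered &= ~mask
    if int(uncovered.sum()) > 0:
        warnings.warn(
            f"{int(uncovered.sum())} positive example(s) left uncovered for "
            f"class {conclusion_class!r}", stacklevel=2)
    if rules:
        adjusted = adjust_pvalues([r.stats.fisher_p for r in rules],
                                  method=adjust_method)
        rules = [replace(r, stats=replace(r.stats, adjusted_p=a))
                 for r, a in zip(rules, adjusted)]
    return rules


def odds_chain(rule: Rule, ds: ImmunoDataset, problem: DecisionProblem,
               haldane: bool = False) -> list[float]:
    """Odds ratios of the premise prefixes of length 1..n on the full data.

    Element k is the odds ratio of the rule truncated to its first k
    elementary conditions; the final element equals the full rule's ratio.
    """
    chain = []
    for k in range(1, len(rule.premise) + 1):
        t = contingency(rule.premise[:k], ds, problem, rule.conclusion)
        chain.append(odds_ratio(t, haldane=haldane))
    return chain


def evaluate_negation(rule: Rule, ds: ImmunoDataset,
                      problem: DecisionProblem) -> ContingencyTable:
    """Contingency table of the rule's logical negation.

    The negation is the disjunction of the negated elementary conditions
    and concludes the opposite class, which plays the primary role of the
    returned table. A missing value satisfies neither a condition nor its
    negation, so on incomplete data rule and negation need not partition
    the examples.
    """
    if rule.conclusion == problem.primary_class_name:
        opposite = problem.secondary_class_name
        pos_value = 0.0
    elif rule.conclusion == problem.secondary_class_name:
        opposite = problem.primary_class_name
        pos_value = 1.0
    else:
        raise ValueError(
            f"{rule.conclusion!r} is neither class of problem {problem.id!r}")
    sub = ds.subset(problem.assigned)
    y = problem.y.loc[problem.assigned].to_numpy(float)
    pos = y == pos_value  # the opposite class is primary for this table
    mask = np.zeros(sub.n_patients, dtype=bool)
    for cond in rule.premise:
        mask |= cond.negate().holds(sub.values[cond.attribute].to_numpy(float))
    return ContingencyTable(int((mask & pos).sum()), int((mask & ~pos).sum()),
                            int(pos.sum()), int((~pos).sum()))
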