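"""Dataset representation for antigen-expression / genetic-aberration analysis.

The data model mirrors a diagnostic flow-cytometry study of B-cell precursor
acute lymphoblastic leukaemia (BCP-ALL): each patient carries expression
scores for a panel of 17 antigens -- 16 graded markers on the normalized
median-fluorescence-intensity (nMFI) integer scale plus the binary marker
NG2 -- and binary labels for three recurrent genetic aberrations
(the ETV6-RUNX1 fusion, KMT2A rearrangements, hyperdiploidy).

Five binary decision problems are derived from the labels: one-vs-rest for
each aberration, "no aberration" vs any, and ETV6-RUNX1-only vs
hyperdiploidy-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerSpec",
    "ImmunoDataset",
    "DecisionProblem",
    "ABERRATIONS",
    "PROBLEM_IDS",
    "default_marker_specs",
    "load_marker_specs",
    "load_dataset",
    "write_dataset",
    "filter_missing",
    "build_decision_problem",
    "describe",
]

ABERRATIONS = ("ETV6-RUNX1", "KMT2A", "hyperdiploidy")

PROBLEM_IDS = (
    "etv6_runx1",
    "kmt2a",
    "hyperdiploidy",
    "no_aberration",
    "etv6_vs_hyperdiploidy",
)

#: aberration column required by each one-vs-rest problem
_SINGLE_ABERRATION = {
    "etv6_runx1": "ETV6-RUNX1",
    "kmt2a": "KMT2A",
    "hyperdiploidy": "hyperdiploidy",
}


@dataclass(frozen=True)
class MarkerSpec:
    """A marker of the diagnostic panel.

    Parameters
    ----------
    name:
        Marker name as used in column headers, e.g. ``"CD10"``.
    scale:
        ``"graded"`` for markers scored on the integer nMFI scale,
        ``"binary"`` for presence/absence markers (NG2).
    neg_ref_mfi, pos_ref_mfi:
        Raw MFI of the negative / positive reference cell population,
        needed only to build an nMFI conversion scale.
    """

    name: str
    scale: str = "graded"
    neg_ref_mfi: float | None = None
    pos_ref_mfi: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("graded", "binary"):
            raise ValueError(f"unknown scale {self.scale!r} for marker {self.name!r}")
        if self.neg_ref_mfi is not None:
            if self.neg_ref_mfi < 0:
                raise ValueError(f"{self.name}: neg_ref_mfi must be >= 0")
            if self.pos_ref_mfi is not None and not self.pos_ref_mfi > self.neg_ref_mfi:
                raise ValueError(f"{self.name}: pos_ref_mfi must exceed neg_ref_mfi")


# The 17-antigen EuroFlow-style panel; "CD15+CD65" is a single graded column.
_GRADED_PANEL = (
    "CD34", "CD45", "CD10", "CD38", "CD20", "CD33", "CD13", "CD22",
    "CD24", "CD9", "CD15+CD65", "CD66c", "CD123", "CD81", "cyIgM", "TdT",
)


def default_marker_specs() -> list[MarkerSpec]:
    """The default 17-marker catalogue: 16 graded antigens plus binary NG2."""
    specs = [MarkerSpec(m, "graded") for m in _GRADED_PANEL]
    specs.append(MarkerSpec("NG2", "binary"))
    return specs


def load_marker_specs(path) -> list[MarkerSpec]:
    """Read a marker catalogue from YAML.

    Expected layout::

        markers:
          - name: CD10
            scale: graded
            neg_ref_mfi: 100.0   # optional
            pos_ref_mfi: 1100.0  # optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["markers"] if isinstance(doc, dict) else doc
    return [MarkerSpec(**e) for e in entries]


@dataclass
class ImmunoDataset:
    """Patient x marker table with missing-value mask and aberration labels.

    ``values`` holds integer nMFI scores as floats with NaN encoding missing;
    ``labels`` holds 0/1 aberration status, NaN where the genetic result is
    unavailable. Rows of both frames share the patient index.
    """

    values: pd.DataFrame
    labels: pd.DataFrame
    markers: list[MarkerSpec] = field(default_factory=default_marker_specs)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.labels = self.labels.astype(float)
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the same patient index")
        spec_names = [m.name for m in self.markers]
        if list(self.values.columns) != spec_names:
            unknown = set(self.values.columns) - set(spec_names)
            if unknown:
                raise ValueError(f"unknown marker column(s): {sorted(unknown)}")
            self.values = self.values[spec_names]
        self._validate_domains()

    def _validate_domains(self) -> None:
        for spec in self.markers:
            col = self.values[spec.name]
            obs = col.dropna()
            if obs.empty:
                continue
            if spec.scale == "binary":
                bad = ~obs.isin([0.0, 1.0])
                if bad.any():
                    row = obs.index[bad][0]
                    raise ValueError(
                        f"binary marker {spec.name!r} has value "
                        f"{obs[bad].iloc[0]!r} at row {row!r}; expected 0/1"
                    )
            else:
                frac = obs % 1.0
                if (frac != 0).any() or (obs < 0).any():
                    row = obs.index[(frac != 0) | (obs < 0)][0]
                    raise ValueError(
                        f"graded marker {spec.name!r} has non-integer or negative "
                        f"value {col[row]!r} at row {row!r}"
                    )
        obs = self.labels.stack(future_stack=True).dropna()
        if not obs.isin([0.0, 1.0]).all():
            raise ValueError("aberration labels must be 0/1 or missing")

    # -- convenience accessors -------------------------------------------
    @property
    def patients(self) -> pd.Index:
        return self.values.index

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def n_patients(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where a marker value is missing."""
        return self.values.isna()

    def marker_spec(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def subset(self, index) -> "ImmunoDataset":
        """Dataset restricted to the given patient index (order preserved)."""
        return ImmunoDataset(
            self.values.loc[index].copy(), self.labels.loc[index].copy(), list(self.markers)
        )

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, ImmunoDataset):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.labels.equals(other.labels)
            and self.markers == other.markers
        )


def load_dataset(path, marker_specs: list[MarkerSpec] | None = None) -> ImmunoDataset:
    """Load a patient x (markers + aberrations) CSV/TSV table.

    The header row must name every marker of the catalogue and the aberration
    columns; an optional leading ``patient_id`` column becomes the index.
    Empty cells encode missing values. Unknown columns and domain violations
    (non-integer graded scores, binary values outside {0, 1}) raise
    ``ValueError``.
    """
    specs = marker_specs if marker_specs is not None else default_marker_specs()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    if frame.columns[0] == "patient_id":
        frame = frame.set_index("patient_id")
    spec_names = [m.name for m in specs]
    known = set(spec_names) | set(ABERRATIONS)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown column(s) in {path}: {unknown}")
    missing_cols = [c for c in spec_names if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"marker column(s) absent from {path}: {missing_cols}")
    label_cols = [c for c in ABERRATIONS if c in frame.columns]
    labels = frame[label_cols].reindex(columns=list(ABERRATIONS))
    return ImmunoDataset(frame[spec_names], labels, specs)


def write_dataset(ds: ImmunoDataset, path) -> None:
    """Write the dataset in the dialect ``load_dataset`` reads back.

    Integer values are written without a decimal point; missing cells are
    empty strings, so ``load_dataset(write_dataset(ds)) == ds``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = pd.concat([ds.values, ds.labels], axis=1)
    out.index.name = "patient_id"
    # integer formatting by hand: to_csv's float_format would print "2.0"
    formatted = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep=sep, index=True, lineterminator="\n", encoding="utf-8")


def filter_missing(ds: ImmunoDataset, max_missing_fraction: float = 0.5) -> ImmunoDataset:
    """Remove patients whose marker missing-fraction reaches the threshold.

    The fraction is computed over the marker columns only (labels never
    count); a patient is retained iff fraction < ``max_missing_fraction``,
    matching removal of cases with "50% or more" missing at the default.
    No imputation is ever performed.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must lie in (0, 1]")
    frac = ds.missing_mask.mean(axis=1)
    keep = ds.patients[frac < max_missing_fraction]
    if len(keep) == 0:
        warnings.warn("all patients removed by missing-value filter", stacklevel=2)
    return ds.subset(keep)


@dataclass
class DecisionProblem:
    """A binary decision problem over the dataset's patients.

    ``y`` maps each patient to 1 (primary class), 0 (secondary class) or NaN
    (excluded from this problem, e.g. because a required label is missing).
    """

    id: str
    primary_class_name: str
    secondary_class_name: str
    y: pd.Series

    @property
    def assigned(self) -> pd.Index:
        return self.y.index[self.y.notna()]

    @property
    def primary_count(self) -> int:
        return int((self.y == 1).sum())

    @property
    def secondary_count(self) -> int:
        return int((self.y == 0).sum())

    @property
    def excluded_count(self) -> int:
        return int(self.y.isna().sum())

    def subset(self, index) -> "DecisionProblem":
        return replace(self, y=self.y.loc[index])

    def class_name(self, value: int) -> str:
        return self.primary_class_name if value == 1 else self.secondary_class_name


def build_decision_problem(ds: ImmunoDataset, problem_id: str) -> DecisionProblem:
    """Construct one of the five decision problems from the aberration labels.

    Patients with a missing label required by the problem are excluded from
    that problem only. For ``etv6_vs_hyperdiploidy`` double-positives and
    patients with neither aberration are excluded as well.
    """
    if problem_id not in PROBLEM_IDS:
        raise ValueError(f"unknown decision problem {problem_id!r}; "
                         f"expected one of {PROBLEM_IDS}")
    lab = ds.labels
    y = pd.Series(np.nan, index=ds.patients, dtype=float)
    if problem_id in _SINGLE_ABERRATION:
        col = lab[_SINGLE_ABERRATION[problem_id]]
        y[col == 1] = 1.0
        y[col == 0] = 0.0
        primary = _SINGLE_ABERRATION[problem_id]
        secondary = f"no {primary}"
    elif problem_id == "no_aberration":
        any_pos = (lab == 1).any(axis=1)
        all_neg = (lab == 0).all(axis=1)  # requires all three observed
        y[any_pos] = 0.0
        y[all_neg & ~any_pos] = 1.0
        primary, secondary = "no aberration", "aberration"
    else:  # etv6_vs_hyperdiploidy
        etv6, hyper = lab["ETV6-RUNX1"], lab["hyperdiploidy"]
        y[(etv6 == 1) & (hyper == 0)] = 1.0
        y[(hyper == 1) & (etv6 == 0)] = 0.0
        primary, secondary = "ETV6-RUNX1", "hyperdiploidy"
    problem = DecisionProblem(problem_id, primary, secondary, y)
    if problem.primary_count == 0:
        warnings.warn(f"problem {problem_id!r}: primary class is empty", stacklevel=2)
    return problem


def describe(ds: ImmunoDataset) -> pd.DataFrame:
    """Per-marker min / median / max / missing fraction.

    Statistics are computed over non-missing values only; an all-missing
    marker reports NaN statistics. The layout mirrors the descriptive table
    of a cohort report.
    """
    rows = {}
    for name in ds.marker_names:
        col = ds.values[name]
        obs = col.dropna()
        rows[name] = {
            "min": obs.min() if len(obs) else np.nan,
            "median": obs.median() if len(obs) else np.nan,
            "max": obs.max() if len(obs) else np.nan,
            "missing_fraction": float(col.isna().mean()) if len(col) else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["min", "median", "max", "missing_fraction"])
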