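"""Automated LMS-based growth assessment for pediatric achondroplasia.

Children with achondroplasia follow growth trajectories so different from the
general population that standard charts misclassify them; clinicians instead
read disorder-specific LMS (lambda-mu-sigma) references for nine anthropometric
parameters: height, weight, BMI, head circumference, sitting height, leg
length, arm span, relative sitting height and foot length.  Doing the LMS
arithmetic by hand — look up the age- and sex-specific (L, M, S) triplet,
interpolate between tabulated ages, apply the Box-Cox transform, convert to a
percentile — is slow and error-prone.  This module automates it end to end.

The file is organised in the order the method runs:

  1.  configuration, logging, parameter registry
  2.  errors and domain types
  3.  reference bundles: schema, readers/writers, validation, age interpolation
  4.  the LMS engine: forward/inverse transforms, percentiles, derived measures
  5.  the patient pipeline: per-patient assessment, batch CSV processing,
      centile-curve tables
  6.  synthetic fixtures: seeded reference/cohort generators with known ground
      truth, the engine-vs-manual-oracle agreement check, and a simulated
      inter-rater reliability study

The real European achondroplasia coefficients are published elsewhere and are
not shipped here; users load their own bundle, and the synthetic generator
produces structurally faithful stand-ins (same parameters, sexes, age grids)
for testing.
"""

from __future__ import annotations

import bisect
import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._oracle import manual_zscore

__all__ = [
    "AgreementSummary",
    "AgrowthError",
    "AssessmentReport",
    "BatchSummary",
    "ConfigError",
    "CurveShape",
    "DeviationSample",
    "DomainError",
    "InvalidCoefficientError",
    "InvertibilityError",
    "LMSNode",
    "Measurement",
    "BATCH_OUT_COLUMNS",
    "MissingCurveError",
    "OutOfDomainError",
    "PARAMETER_ORDER",
    "PATIENT_CSV_COLUMNS",
    "REF_CSV_COLUMNS",
    "SEXES",
    "ParameterSpec",
    "PatientRecord",
    "ReferenceCurve",
    "ReferenceSet",
    "REGISTRY",
    "SchemaError",
    "SyntheticRefConfig",
    "ValidationError",
    "Violation",
    "ZScoreResult",
    "age_grid",
    "agreement_check",
    "assess_patient",
    "batch_process",
    "centile_table",
    "decimal_age",
    "derive_bmi",
    "derive_proportions",
    "evaluate",
    "format_summary",
    "generate_cohort",
    "generate_reference",
    "interpolate_lms",
    "load_reference",
    "measurement_from_z",
    "percentile_from_z",
    "rater_case_table",
    "simulate_rater_study",
    "summarize_deviations",
    "read_patients",
    "validate_reference",
    "write_cohort",
    "write_reference",
    "z_from_percentile",
    "zscore_boxcox",
    "zscore_identity",
]

logger = logging.getLogger("agrowth")

# ----------------------------------------------------------------------------
# Configuration constants
# ----------------------------------------------------------------------------

#: Below this |L| the Box-Cox transform switches to its analytic log limit to
#: avoid catastrophic cancellation in ((X/M)^L - 1)/L.
L_EPS = 1e-7

#: |z| beyond which a result is flagged as lying at a percentile extreme.
EXTREME_Z = 3.0

#: Days per year for converting birth/visit dates to decimal age.
DAYS_PER_YEAR = 365.25

#: Exact column header of a reference CSV bundle.
REF_CSV_COLUMNS = ("parameter", "sex", "age_years", "L", "M", "S")

#: Exact column header of a long-format patient CSV.
PATIENT_CSV_COLUMNS = ("patient_id", "sex", "age_years", "parameter", "value")

#: Output header of batch processing.
BATCH_OUT_COLUMNS = (
    "patient_id", "sex", "age_years", "parameter", "value",
    "L", "M", "S", "z", "percentile", "flags",
)

SEXES = ("male", "female")

FLAG_INTERPOLATED_AGE = "interpolated_age"
FLAG_DERIVED_INPUT = "derived_input"
FLAG_EXTREME_PERCENTILE = "extreme_percentile"


# ----------------------------------------------------------------------------
# Errors
# ----------------------------------------------------------------------------

class AgrowthError(Exception):
    """Base class for all package errors."""


class SchemaError(AgrowthError):
    """A file does not match the documented schema (e.g. missing column)."""


class ValidationError(AgrowthError):
    """Reference data violates an invariant (ordering, positivity, ...)."""


class OutOfDomainError(AgrowthError):
    """An age falls outside a curve's closed [age_min, age_max] interval."""

    def __init__(self, message: str, age_min: float | None = None,
                 age_max: float | None = None):
        super().__init__(message)
        self.age_min = age_min
        self.age_max = age_max


class MissingCurveError(AgrowthError):
    """No reference curve for the requested (parameter, sex)."""


class InvalidCoefficientError(AgrowthError):
    """An LMS coefficient is unusable (S <= 0, M <= 0)."""


class DomainError(AgrowthError):
    """A measurement or argument is outside the function's domain."""


class InvertibilityError(AgrowthError):
    """The inverse Box-Cox transform is undefined (1 + L*S*z <= 0)."""


class ConfigError(AgrowthError):
    """A synthetic-generator or CLI configuration is invalid."""


# ----------------------------------------------------------------------------
# Parameter registry
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpec:
    """Registry entry for one anthropometric parameter.

    ``mode`` selects the z-score formula: ``identity`` applies
    Z = (X - M)/S with S an absolute standard deviation in measurement units
    (the convention of references that tabulate L = 1), while ``boxcox``
    applies Cole's full transform Z = ((X/M)^L - 1)/(L*S) with S a coefficient
    of variation.
    """

    parameter_id: str
    units: str
    age_min: float
    age_max: float
    mode: str  # "identity" | "boxcox"


#: Registry order is also the output row order within a patient.
REGISTRY: dict[str, ParameterSpec] = {
    p.parameter_id: p
    for p in (
        ParameterSpec("height", "cm", 0.0, 20.0, "identity"),
        ParameterSpec("weight", "kg", 0.0, 20.0, "boxcox"),
        ParameterSpec("bmi", "kg/m²", 0.0, 20.0, "boxcox"),
        ParameterSpec("head_circumference", "cm", 0.0, 20.0, "identity"),
        ParameterSpec("sitting_height", "cm", 2.0, 20.0, "identity"),
        ParameterSpec("leg_length", "cm", 2.0, 20.0, "identity"),
        ParameterSpec("arm_span", "cm", 2.0, 20.0, "identity"),
        ParameterSpec("relative_sitting_height", "%", 2.0, 20.0, "identity"),
        ParameterSpec("foot_length", "cm", 3.0, 20.0, "identity"),
    )
}

PARAMETER_ORDER: tuple[str, ...] = tuple(REGISTRY)


# ----------------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class LMSNode:
    """One reference-grid entry: an age plus the (L, M, S) triplet.

    L is the Box-Cox power (dimensionless), M the median in parameter units,
    S the scale (coefficient of variation for Box-Cox-mode parameters, an
    absolute SD for identity-mode ones).  Construction does not validate —
    invalid nodes are reported by :func:`validate_reference` instead, so that
    broken bundles can be loaded for inspection.
    """

    age: float
    L: float
    M: float
    S: float


@dataclass
class ReferenceCurve:
    """Ordered LMS nodes for one (parameter, sex) pair."""

    parameter_id: str
    sex: str
    nodes: list[LMSNode]

    @property
    def ages(self) -> list[float]:
        return [n.age for n in self.nodes]

    @property
    def age_min(self) -> float:
        return self.nodes[0].age

    @property
    def age_max(self) -> float:
        return self.nodes[-1].age


@dataclass
class ReferenceSet:
    """A bundle of reference curves keyed by (parameter_id, sex)."""

    curves: dict[tuple[str, str], ReferenceCurve] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def get_curve(self, parameter_id: str, sex: str) -> ReferenceCurve:
        try:
            return self.curves[(parameter_id, sex)]
        except KeyError:
            raise MissingCurveError(
                f"no reference curve for parameter={parameter_id!r} sex={sex!r}"
            ) from None

    def __len__(self) -> int:
        return len(self.curves)


@dataclass(frozen=True)
class Measurement:
    """One patient observation: what was measured, on whom, at what age."""

    parameter_id: str
    sex: str
    age: float
    value: float


@dataclass(frozen=True)
class ZScoreResult:
    """An evaluated measurement: z, percentile, and the coefficients used."""

    z: float
    percentile: float
    lms_used: LMSNode
    flags: frozenset[str] = frozenset()


@dataclass
class PatientRecord:
    """One patient at one visit with any subset of the nine parameters.

    ``age`` may be given directly in decimal years, or derived from
    ``birth_date``/``visit_date`` via :func:`decimal_age`.  ``true_z`` carries
    hidden per-parameter ground truth for synthetic cohorts and is ``None``
    for real data.
    """

    patient_id: str
    sex: str
    age: float | None = None
    birth_date: date | None = None
    visit_date: date | None = None
    measurements: dict[str, float] = field(default_factory=dict)
    true_z: dict[str, float] | None = None

    def resolved_age(self) -> float:
        if self.age is not None:
            return self.age
        if self.birth_date is not None and self.visit_date is not None:
            return decimal_age(self.birth_date, self.visit_date)
        raise DomainError(
            f"patient {self.patient_id!r}: no age and no birth/visit dates"
        )


@dataclass
class AssessmentReport:
    """Per-patient result: one row per evaluated parameter plus skip reasons."""

    patient_id: str
    sex: str
    age: float
    rows: list[tuple[str, float, ZScoreResult]]  # (parameter, value, result)
    skipped: list[tuple[str, str]]               # (parameter, reason)


@dataclass(frozen=True)
class Violation:
    """One reference-bundle rule violation (or warning) found by validation."""

    curve_key: tuple[str, str]
    node_index: int | str  # index or the literal string "curve"
    rule: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass(frozen=True)
class DeviationSample:
    """One |z-deviation| of a rater's reading from the gold standard."""

    rater_id: str
    case_id: str
    parameter_id: str
    method: str  # "manual" | "smart"
    deviation: float


@dataclass(frozen=True)
class AgreementSummary:
    """Median absolute deviation with interquartile bounds for one group."""

    median: float
    iqr_low: float
    iqr_high: float
    n: int


# ----------------------------------------------------------------------------
# Reference bundles: readers, writers, validation
# ----------------------------------------------------------------------------

def _float_or_raise(raw: object, what: str, where: str) -> float:
    try:
        v = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise SchemaError(f"{where}: {what} is not a number: {raw!r}") from None
    return v


def load_reference(path: str | Path, format: str | None = None) -> ReferenceSet:
    """Read a reference bundle from CSV or JSON and validate it.

    CSV schema (exact header): ``parameter,sex,age_years,L,M,S`` — one row per
    node, UTF-8, period decimal separator, sex as literal ``male``/``female``.
    JSON schema: ``{"metadata": {"source", "version"}, "curves": [{"parameter",
    "sex", "nodes": [{"age_years", "L", "M", "S"}, ...]}, ...]}``.

    Duplicate (parameter, sex, age) rows are a schema violation, never
    deduplicated or averaged.  Raises :class:`SchemaError` for structural
    problems and :class:`ValidationError` when curve invariants fail.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        ref = _load_reference_csv(path)
    elif format == "json":
        ref = _load_reference_json(path)
    else:
        raise SchemaError(f"unknown reference format {format!r}")
    violations = [v for v in validate_reference(ref) if v.severity == "error"]
    if violations:
        first = violations[0]
        raise ValidationError(
            f"{path}: invalid reference bundle "
            f"({len(violations)} violation(s); first: {first.message})"
        )
    return ref


def _load_reference_csv(path: Path) -> ReferenceSet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REF_CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    # CSV carries no metadata block; leave it empty so write/load round trips
    # compare equal.
    ref = ReferenceSet(metadata={"source": "", "version": ""})
    seen: set[tuple[str, str, float]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = 1
        where = f"{path}:row {i}"
        parameter = getattr(row, "parameter")
        sex = getattr(row, "sex")
        age = _float_or_raise(getattr(row, "age_years"), "age_years", where)
        node = LMSNode(
            age=age,
            L=_float_or_raise(getattr(row, "L"), "L", where),
            M=_float_or_raise(getattr(row, "M"), "M", where),
            S=_float_or_raise(getattr(row, "S"), "S", where),
        )
        key = (parameter, sex, age)
        if key in seen:
            raise SchemaError(
                f"{where}: duplicate node for parameter={parameter!r} "
                f"sex={sex!r} age_years={age}"
            )
        seen.add(key)
        curve = ref.curves.setdefault(
            (parameter, sex), ReferenceCurve(parameter, sex, [])
        )
        curve.nodes.append(node)
    # Node order comes from the file, never from sorting: a descending file
    # is an ordering error the validator reports, not something to repair.
    return ref


def _load_reference_json(path: Path) -> ReferenceSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "curves" not in doc:
        raise SchemaError(f"{path}: JSON bundle must have a 'curves' list")
    meta = doc.get("metadata", {})
    ref = ReferenceSet(metadata={
        "source": str(meta.get("source", "")),
        "version": str(meta.get("version", "")),
    })
    for ci, entry in enumerate(doc["curves"]):
        for key in ("parameter", "sex", "nodes"):
            if key not in entry:
                raise SchemaError(
                    f"{path}: curve #{ci} missing required key {key!r}"
                )
        parameter, sex = entry["parameter"], entry["sex"]
        if (parameter, sex) in ref.curves:
            raise SchemaError(
                f"{path}: duplicate curve for parameter={parameter!r} "
                f"sex={sex!r}"
            )
        nodes = []
        seen_ages: set[float] = set()
        for ni, nd in enumerate(entry["nodes"]):
            where = f"{path}: curve ({parameter},{sex}) node #{ni}"
            for key in ("age_years", "L", "M", "S"):
                if key not in nd:
                    raise SchemaError(f"{where}: missing required key {key!r}")
            age = _float_or_raise(nd["age_years"], "age_years", where)
            if age in seen_ages:
                raise SchemaError(f"{where}: duplicate age_years={age}")
            seen_ages.add(age)
            nodes.append(LMSNode(
                age=age,
                L=_float_or_raise(nd["L"], "L", where),
                M=_float_or_raise(nd["M"], "M", where),
                S=_float_or_raise(nd["S"], "S", where),
            ))
        ref.curves[(parameter, sex)] = ReferenceCurve(parameter, sex, nodes)
    return ref


def write_reference(ref: ReferenceSet, path: str | Path,
                    format: str | None = None) -> None:
    """Serialize a bundle to CSV or JSON (inferred from the extension).

    Floats are written with ``repr`` so a write/load round trip is exact.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    keys = sorted(ref.curves)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(REF_CSV_COLUMNS)
            for key in keys:
                c = ref.curves[key]
                for n in c.nodes:
                    w.writerow([c.parameter_id, c.sex, repr(n.age),
                                repr(n.L), repr(n.M), repr(n.S)])
    elif format == "json":
        doc = {
            "metadata": {
                "source": ref.metadata.get("source", ""),
                "version": ref.metadata.get("version", ""),
            },
            "curves": [
                {
                    "parameter": ref.curves[k].parameter_id,
                    "sex": ref.curves[k].sex,
                    "nodes": [
                        {"age_years": n.age, "L": n.L, "M": n.M, "S": n.S}
                        for n in ref.curves[k].nodes
                    ],
                }
                for k in keys
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise SchemaError(f"unknown reference format {format!r}")


def validate_reference(ref: ReferenceSet,
                       include_warnings: bool = False) -> list[Violation]:
    """Check every curve invariant; violations are data, not exceptions.

    Returns an empty list iff the bundle is valid.  With
    ``include_warnings=True`` also reports advisory findings, currently the
    S-convention heuristic: an identity-mode node with S < 0.5 while M > 20
    looks like a coefficient of variation supplied where an absolute SD is
    expected.
    """
    out: list[Violation] = []

    def err(key, idx, rule, msg):
        out.append(Violation(key, idx, rule, msg))

    for key, curve in ref.curves.items():
        param, sex = key
        spec = REGISTRY.get(param)
        if sex not in SEXES:
            err(key, "curve", "sex", f"{key}: unknown sex {sex!r}")
        if spec is None:
            err(key, "curve", "unknown-parameter",
                f"{key}: parameter {param!r} not in registry")
        if len(curve.nodes) < 2:
            err(key, "curve", "min-nodes",
                f"{key}: curve needs at least 2 nodes, has {len(curve.nodes)}")
        prev_age = -math.inf
        for i, n in enumerate(curve.nodes):
            if not math.isfinite(n.age) or n.age < 0:
                err(key, i, "age-finite",
                    f"{key} node {i}: age must be finite and >= 0, got {n.age}")
            if n.age <= prev_age:
                err(key, i, "age-order",
                    f"{key} node {i}: ages not strictly increasing at "
                    f"age_years={n.age} (previous {prev_age})")
            prev_age = n.age
            if not (n.M > 0):
                err(key, i, "M-positive",
                    f"{key} node {i} (age {n.age}): M must be > 0, got {n.M}")
            if not (n.S > 0):
                err(key, i, "S-positive",
                    f"{key} node {i} (age {n.age}): S must be > 0, got {n.S}")
            if spec is not None and spec.mode == "identity" and n.L != 1:
                err(key, i, "identity-L",
                    f"{key} node {i} (age {n.age}): identity-mode parameter "
                    f"requires L = 1, got {n.L}")
            if (include_warnings and spec is not None
                    and spec.mode == "identity" and n.S < 0.5 and n.M > 20):
                out.append(Violation(
                    key, i, "s-convention",
                    f"{key} node {i} (age {n.age}): S={n.S} < 0.5 with "
                    f"M={n.M} > 20 — looks like a CV where an absolute SD "
                    f"is expected", severity="warning"))
        if spec is not None and curve.nodes:
            if curve.nodes[0].age != spec.age_min:
                err(key, 0, "domain-start",
                    f"{key}: first node at age {curve.nodes[0].age}, "
                    f"expected {spec.age_min}")
            if curve.nodes[-1].age != spec.age_max:
                err(key, len(curve.nodes) - 1, "domain-end",
                    f"{key}: last node at age {curve.nodes[-1].age}, "
                    f"expected {spec.age_max}")
    return out


def reference_rows(ref: ReferenceSet) -> list[dict]:
    """Flatten a bundle to plain dict rows (the oracle's only input form)."""
    rows = []
    for (param, sex), curve in sorted(ref.curves.items()):
        for n in curve.nodes:
            rows.append({"parameter": param, "sex": sex, "age_years": n.age,
                         "L": n.L, "M": n.M, "S": n.S})
    return rows


# ----------------------------------------------------------------------------
# Age interpolation
# ----------------------------------------------------------------------------

def interpolate_lms(curve: ReferenceCurve, age: float) -> LMSNode:
    """Return the (L, M, S) triplet at ``age``, linearly interpolated.

    Ages exactly on a grid node reproduce that node's coefficients bit-exactly;
    ages strictly between nodes get component-wise linear interpolation of L,
    M and S.  The domain is the closed interval [first node age, last node
    age]; anything outside raises :class:`OutOfDomainError` — no extrapolation
    and no clamping, because a silently clamped age hides a clinically
    meaningful out-of-range query.
    """
    if not math.isfinite(age):
        raise OutOfDomainError(f"age must be finite, got {age}")
    ages = curve.ages
    lo, hi = ages[0], ages[-1]
    if age < lo or age > hi:
        raise OutOfDomainError(
            f"age {age} outside reference domain [{lo}, {hi}] for "
            f"parameter={curve.parameter_id!r} sex={curve.sex!r}",
            age_min=lo, age_max=hi)
    i = bisect.bisect_left(ages, age)
    if i < len(ages) and ages[i] == age:
        n = curve.nodes[i]
        return LMSNode(age=age, L=n.L, M=n.M, S=n.S)
    n0, n1 = curve.nodes[i - 1], curve.nodes[i]
    L = float(np.interp(age, [n0.age, n1.age], [n0.L, n1.L]))
    M = float(np.interp(age, [n0.age, n1.age], [n0.M, n1.M]))
    S = float(np.interp(age, [n0.age, n1.age], [n0.S, n1.S]))
    return LMSNode(age=age, L=L, M=M, S=S)


# ----------------------------------------------------------------------------
# LMS engine: forward and inverse transforms
# ----------------------------------------------------------------------------

def zscore_identity(X: float, node: LMSNode) -> float:
    """Z = (X - M)/S for normally distributed (L = 1) parameters.

    Here S is an absolute standard deviation in measurement units.
    """
    if not (node.S > 0):
        raise InvalidCoefficientError(f"S must be > 0, got {node.S}")
    return (X - node.M) / node.S


def zscore_boxcox(X: float, node: LMSNode) -> float:
    """Cole's full LMS transform Z = ((X/M)^L - 1)/(L*S).

    Used for skewed parameters (weight, BMI), where S is a coefficient of
    variation.  For |L| below ``L_EPS`` the analytic limit ln(X/M)/S is used.
    """
    if not (node.S > 0) or not (node.M > 0):
        raise InvalidCoefficientError(
            f"M and S must be > 0, got M={node.M}, S={node.S}")
    if not (X > 0):
        raise DomainError(f"Box-Cox z-score requires X > 0, got {X}")
    L = node.L
    if abs(L) < L_EPS:
        return math.log(X / node.M) / node.S
    return ((X / node.M) ** L - 1.0) / (L * node.S)


def percentile_from_z(z: float) -> float:
    """100 * Phi(z): the chart percentile of a z-score."""
    if not math.isfinite(z):
        raise DomainError(f"z must be finite, got {z}")
    return float(norm.cdf(z) * 100.0)


def z_from_percentile(p: float) -> float:
    """Inverse of :func:`percentile_from_z` on the open interval (0, 100)."""
    if not (0.0 < p < 100.0):
        raise DomainError(f"percentile must be in (0, 100), got {p}")
    return float(norm.ppf(p / 100.0))


def measurement_from_z(z: float, node: LMSNode, mode: str) -> float:
    """Invert the z-score transform: the measurement at a given z.

    identity: X = M + z*S.  boxcox: X = M*(1 + L*S*z)^(1/L), or M*exp(S*z) in
    the L -> 0 limit.  For Box-Cox, z values with 1 + L*S*z <= 0 are outside
    the transform's support and raise :class:`InvertibilityError` — Cole's
    transform saturates there, e.g. very high BMI z-scores with strongly
    negative L.
    """
    if mode == "identity":
        return node.M + z * node.S
    if mode != "boxcox":
        raise DomainError(f"unknown mode {mode!r}")
    if not (node.S > 0) or not (node.M > 0):
        raise InvalidCoefficientError(
            f"M and S must be > 0, got M={node.M}, S={node.S}")
    L = node.L
    if abs(L) < L_EPS:
        return node.M * math.exp(node.S * z)
    base = 1.0 + L * node.S * z
    if base <= 0:
        raise InvertibilityError(
            f"z={z} beyond Box-Cox support (1 + L*S*z = {base} <= 0 with "
            f"L={L}, S={node.S})")
    return node.M * base ** (1.0 / L)


def derive_bmi(weight: float, height: float) -> float:
    """BMI in kg/m² from weight (kg) and height (cm)."""
    if not (weight > 0 and height > 0):
        raise DomainError(
            f"weight and height must be > 0, got {weight}, {height}")
    return weight / (height / 100.0) ** 2


def derive_proportions(height: float, sitting_height: float
                       ) -> tuple[float, float]:
    """Subischial leg length (cm) and relative sitting height (%).

    leg_length = height - sitting_height; relative sitting height is sitting
    height as a percentage of standing height, the core disproportion index
    in achondroplasia.
    """
    if not (0 < sitting_height < height):
        raise DomainError(
            f"need 0 < sitting_height < height, got sitting={sitting_height}, "
            f"height={height}")
    return height - sitting_height, 100.0 * sitting_height / height


def decimal_age(birth: date, visit: date) -> float:
    """Decimal age in years: (visit - birth) in days / 365.25."""
    days = (visit - birth).days
    if days < 0:
        raise DomainError(f"visit date {visit} precedes birth date {birth}")
    return days / DAYS_PER_YEAR


def evaluate(m: Measurement, ref: ReferenceSet,
             extra_flags: Iterable[str] = ()) -> ZScoreResult:
    """Evaluate one measurement against a reference bundle.

    Interpolates (L, M, S) at the measurement age, dispatches on the
    parameter's registry mode, and returns the z-score, percentile, the
    coefficients actually applied, and flags (``interpolated_age`` when the
    age is off-grid, ``extreme_percentile`` when |z| > 3).
    """
    spec = REGISTRY.get(m.parameter_id)
    if spec is None:
        raise MissingCurveError(f"unknown parameter {m.parameter_id!r}")
    if not (spec.age_min <= m.age <= spec.age_max):
        raise OutOfDomainError(
            f"age {m.age} outside [{spec.age_min}, {spec.age_max}] for "
            f"parameter={m.parameter_id!r}",
            age_min=spec.age_min, age_max=spec.age_max)
    curve = ref.get_curve(m.parameter_id, m.sex)
    node = interpolate_lms(curve, m.age)
    flags = set(extra_flags)
    if m.age not in curve.ages:
        flags.add(FLAG_INTERPOLATED_AGE)
    if spec.mode == "boxcox":
        z = zscore_boxcox(m.value, node)
    else:
        z = zscore_identity(m.value, node)
    if abs(z) > EXTREME_Z:
        flags.add(FLAG_EXTREME_PERCENTILE)
    return ZScoreResult(z=z, percentile=percentile_from_z(z),
                        lms_used=node, flags=frozenset(flags))


# ----------------------------------------------------------------------------
# Patient pipeline
# ----------------------------------------------------------------------------

#: Derivation recipes: target -> (source parameters, function of their values).
_DERIVATIONS: dict[str, tuple[tuple[str, ...], Callable[..., float]]] = {
    "bmi": (("weight", "height"), derive_bmi),
    "leg_length": (("height", "sitting_height"),
                   lambda h, sh: derive_proportions(h, sh)[0]),
    "relative_sitting_height": (("height", "sitting_height"),
                                lambda h, sh: derive_proportions(h, sh)[1]),
}


def assess_patient(rec: PatientRecord, ref: ReferenceSet,
                   derive: bool = True) -> AssessmentReport:
    """Evaluate every present (and, optionally, derivable) parameter.

    Measured values always win over derived ones; derivation only fills a
    target that is absent.  Out-of-domain ages and missing curves become
    ``skipped`` entries with reasons — a single bad parameter never aborts
    the record.
    """
    age = rec.resolved_age()
    if rec.sex not in SEXES:
        raise DomainError(
            f"patient {rec.patient_id!r}: sex must be one of {SEXES}, "
            f"got {rec.sex!r}")
    if not rec.measurements:
        raise DomainError(f"patient {rec.patient_id!r}: no measurements")

    values: dict[str, tuple[float, bool]] = {
        p: (v, False) for p, v in rec.measurements.items()
    }
    if derive:
        for target, (sources, fn) in _DERIVATIONS.items():
            if target in values:
                continue
            if all(s in rec.measurements for s in sources):
                try:
                    values[target] = (
                        fn(*(rec.measurements[s] for s in sources)), True)
                except DomainError as e:
                    values[target] = (math.nan, True)
                    logger.warning("patient %s: cannot derive %s: %s",
                                   rec.patient_id, target, e)

    rows: list[tuple[str, float, ZScoreResult]] = []
    skipped: list[tuple[str, str]] = []
    ordered = [p for p in PARAMETER_ORDER if p in values]
    ordered += [p for p in values if p not in REGISTRY]
    for param in ordered:
        value, derived = values[param]
        extra = {FLAG_DERIVED_INPUT} if derived else set()
        if math.isnan(value):
            skipped.append((param, "derivation failed"))
            continue
        try:
            res = evaluate(Measurement(param, rec.sex, age, value), ref,
                           extra_flags=extra)
        except OutOfDomainError as e:
            skipped.append((param,
                            f"out-of-domain age {age} "
                            f"(valid [{e.age_min}, {e.age_max}])"))
        except MissingCurveError as e:
            skipped.append((param, str(e)))
        except (DomainError, InvalidCoefficientError) as e:
            skipped.append((param, str(e)))
        else:
            rows.append((param, value, res))
    return AssessmentReport(rec.patient_id, rec.sex, age, rows, skipped)


@dataclass
class BatchSummary:
    """Counts and error notes from one batch run."""

    records_processed: int = 0
    rows_written: int = 0
    skips: list[tuple[str, str, str]] = field(default_factory=list)
    malformed: list[tuple[int, str]] = field(default_factory=list)


def read_patients(path: str | Path) -> tuple[list[PatientRecord],
                                             list[tuple[int, str]]]:
    """Parse a long-format patient CSV into records, reporting bad lines.

    Required columns: ``patient_id,sex,parameter,value`` plus either
    ``age_years`` or both ``birth_date`` and ``visit_date`` (ISO-8601).
    Malformed rows are returned as (line number, reason) and never abort the
    file; a missing column does.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for col in ("patient_id", "sex", "parameter", "value"):
            if col not in cols:
                raise SchemaError(f"{path}: missing required column {col!r}")
        has_age = "age_years" in cols
        has_dates = "birth_date" in cols and "visit_date" in cols
        if not has_age and not has_dates:
            raise SchemaError(
                f"{path}: need column 'age_years' or columns "
                f"'birth_date'+'visit_date'")
        records: dict[tuple[str, str, float], PatientRecord] = {}
        order: list[tuple[str, str, float]] = []
        malformed: list[tuple[int, str]] = []
        for line_no, row in enumerate(reader, start=2):
            try:
                pid = (row.get("patient_id") or "").strip()
                sex = (row.get("sex") or "").strip()
                param = (row.get("parameter") or "").strip()
                if not pid:
                    raise DomainError("empty patient_id")
                if sex not in SEXES:
                    raise DomainError(f"sex must be male/female, got {sex!r}")
                age_raw = (row.get("age_years") or "").strip() if has_age else ""
                if age_raw:
                    age = float(age_raw)
                elif has_dates:
                    age = decimal_age(
                        date.fromisoformat((row.get("birth_date") or "").strip()),
                        date.fromisoformat((row.get("visit_date") or "").strip()))
                else:
                    raise DomainError("missing age_years")
                value = float((row.get("value") or "").strip())
                if not math.isfinite(age) or not math.isfinite(value):
                    raise DomainError("non-finite age or value")
            except (ValueError, DomainError) as e:
                malformed.append((line_no, str(e)))
                continue
            key = (pid, sex, age)
            if key not in records:
                records[key] = PatientRecord(pid, sex, age=age)
                order.append(key)
            rec = records[key]
            if param in rec.measurements:
                malformed.append(
                    (line_no, f"duplicate measurement {param!r} for patient "
                              f"{pid!r} at age {age} (first value kept)"))
                continue
            rec.measurements[param] = value
    return [records[k] for k in order], malformed


def batch_process(in_csv: str | Path, ref: ReferenceSet,
                  out_csv: str | Path, derive: bool = True) -> BatchSummary:
    """Evaluate a patient CSV and write one output row per (patient, parameter).

    Output schema: ``patient_id,sex,age_years,parameter,value,L,M,S,z,
    percentile,flags`` (flags semicolon-joined) — the interpolated
    coefficients used are part of the record for auditability.  Row order is
    input order, then registry parameter order within a patient.
    """
    records, malformed = read_patients(in_csv)
    summary = BatchSummary(malformed=malformed)
    out_csv = Path(out_csv)
    with open(out_csv, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BATCH_OUT_COLUMNS)
        for rec in records:
            report = assess_patient(rec, ref, derive=derive)
            summary.records_processed += 1
            for param, value, res in report.rows:
                n = res.lms_used
                w.writerow([
                    report.patient_id, report.sex, repr(report.age), param,
                    repr(value), repr(n.L), repr(n.M), repr(n.S),
                    repr(res.z), repr(res.percentile),
                    ";".join(sorted(res.flags)),
                ])
                summary.rows_written += 1
            for param, reason in report.skipped:
                summary.skips.append((report.patient_id, param, reason))
    logger.info("batch: %d records, %d rows, %d skips, %d malformed lines",
                summary.records_processed, summary.rows_written,
                len(summary.skips), len(summary.malformed))
    return summary


def centile_table(parameter: str, sex: str, ref: ReferenceSet,
                  percentiles: Sequence[float], age_step: float,
                  age_min: float | None = None, age_max: float | None = None,
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Tabulate centile curves: for each age on a grid, X at each percentile.

    Returns (table, warnings).  The table has an ``age_years`` column plus one
    ``P<p>`` column per requested percentile, rows ordered by age.  A grid
    extending beyond the reference domain is truncated to it, with a warning.
    """
    if age_step <= 0:
        raise DomainError(f"age_step must be > 0, got {age_step}")
    for p in percentiles:
        if not (0.0 < p < 100.0):
            raise DomainError(f"percentile must be in (0, 100), got {p}")
    spec = REGISTRY.get(parameter)
    if spec is None:
        raise MissingCurveError(f"unknown parameter {parameter!r}")
    curve = ref.get_curve(parameter, sex)
    lo = spec.age_min if age_min is None else age_min
    hi = spec.age_max if age_max is None else age_max
    warnings: list[str] = []
    if lo < curve.age_min or hi > curve.age_max:
        warnings.append(
            f"age grid [{lo}, {hi}] truncated to reference domain "
            f"[{curve.age_min}, {curve.age_max}]")
        lo, hi = max(lo, curve.age_min), min(hi, curve.age_max)
    ages = list(np.arange(lo, hi + age_step * 1e-9, age_step))
    zs = [z_from_percentile(p) for p in percentiles]
    data: dict[str, list[float]] = {"age_years": ages}
    for p, z in zip(percentiles, zs):
        col = []
        for a in ages:
            node = interpolate_lms(curve, a)
            col.append(measurement_from_z(z, node, spec.mode))
        data[f"P{p:g}"] = col
    return pd.DataFrame(data), warnings


# ----------------------------------------------------------------------------
# Synthetic fixtures: seeded reference bundles with known structure
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveShape:
    """Shape controls for one synthetic curve: endpoint medians, curvature
    (growth front-loading exponent), S range, and L range (Box-Cox only)."""

    m_start: float
    m_end: float
    curvature: float
    s_start: float
    s_end: float
    l_start: float = 1.0
    l_end: float = 1.0


# Median trajectories loosely emulating achondroplasia anthropometry: marked
# short stature (adult height ~125-131 cm), near-normal trunk, short limbs,
# relatively large head, high relative sitting height.  Identity-mode S values
# are absolute SDs in measurement units; Box-Cox S values are CVs.  These are
# synthetic stand-ins with the structure (not the values) of published
# European references.
_DEFAULT_SHAPES: dict[tuple[str, str], CurveShape] = {
    ("height", "male"): CurveShape(47.0, 131.0, 2.2, 2.0, 5.5),
    ("height", "female"): CurveShape(46.0, 124.0, 2.2, 2.0, 5.2),
    ("weight", "male"): CurveShape(3.3, 55.0, 1.5, 0.11, 0.16, -0.2, -1.2),
    ("weight", "female"): CurveShape(3.2, 50.0, 1.5, 0.11, 0.16, -0.2, -1.2),
    ("bmi", "male"): CurveShape(14.0, 27.0, 1.0, 0.08, 0.13, -0.5, -1.5),
    ("bmi", "female"): CurveShape(13.8, 26.5, 1.0, 0.08, 0.13, -0.5, -1.5),
    ("head_circumference", "male"): CurveShape(36.0, 59.5, 4.0, 1.2, 1.8),
    ("head_circumference", "female"): CurveShape(35.2, 58.5, 4.0, 1.2, 1.8),
    ("sitting_height", "male"): CurveShape(45.0, 88.0, 1.8, 1.8, 3.5),
    ("sitting_height", "female"): CurveShape(44.0, 84.0, 1.8, 1.8, 3.5),
    ("leg_length", "male"): CurveShape(18.0, 44.0, 1.8, 1.4, 3.0),
    ("leg_length", "female"): CurveShape(17.5, 41.0, 1.8, 1.4, 3.0),
    ("arm_span", "male"): CurveShape(55.0, 103.0, 1.8, 2.5, 5.0),
    ("arm_span", "female"): CurveShape(53.0, 97.0, 1.8, 2.5, 5.0),
    ("relative_sitting_height", "male"): CurveShape(67.0, 63.0, 1.0, 1.2, 1.8),
    ("relative_sitting_height", "female"): CurveShape(67.5, 63.5, 1.0, 1.2, 1.8),
    ("foot_length", "male"): CurveShape(11.0, 18.5, 1.5, 0.6, 1.1),
    ("foot_length", "female"): CurveShape(10.8, 17.5, 1.5, 0.6, 1.1),
}

#: Parameters whose synthetic median must increase with age (sizes, not
#: proportions — relative sitting height naturally declines).
_SIZE_PARAMETERS = frozenset(PARAMETER_ORDER) - {"relative_sitting_height"}

#: Extremes injected into synthetic cohorts sit at |z| = 4; the generator
#: must keep 1 + L*S*z > 0 with margin for these to be representable.
_EXTREME_Z = 4.0
_MAX_ABS_LS = 1.0 / (_EXTREME_Z + 0.2)


@dataclass
class SyntheticRefConfig:
    """Configuration of the synthetic reference generator.

    ``jitter`` scales the seeded relative perturbation applied to the shape
    endpoints so different seeds give different (but always valid) bundles.
    """

    seed: int = 0
    shapes: dict[tuple[str, str], CurveShape] = field(
        default_factory=lambda: dict(_DEFAULT_SHAPES))
    jitter: float = 0.02
    source: str = "agrowth synthetic fixture"
    version: str = "1"


def age_grid(spec: ParameterSpec) -> list[float]:
    """The tabulation grid: 6-month steps to age 4 then annual, for the
    birth-to-20 parameters; annual from the domain start otherwise."""
    if spec.age_min == 0.0:
        return [i * 0.5 for i in range(9)] + [float(a) for a in range(5, 21)]
    return [float(a) for a in range(int(spec.age_min), 21)]


def generate_reference(cfg: SyntheticRefConfig | int = 0) -> ReferenceSet:
    """Generate a complete, valid synthetic bundle (18 curves).

    Deterministic for a fixed seed.  Median curves follow
    M(a) = M0 + (M1 - M0) * (1 - (1 - u)^c) with u the normalized age —
    monotone for size parameters, with curvature c front-loading infant
    growth.  S and L vary linearly across the grid.  Raises
    :class:`ConfigError` if the shape controls imply M <= 0, S <= 0, or a
    Box-Cox transform that cannot represent |z| = 4.
    """
    if isinstance(cfg, int):
        cfg = SyntheticRefConfig(seed=cfg)
    rng = np.random.default_rng(cfg.seed)
    ref = ReferenceSet(metadata={"source": cfg.source, "version": cfg.version})
    for param in PARAMETER_ORDER:
        spec = REGISTRY[param]
        grid = age_grid(spec)
        for sex in SEXES:
            shape = cfg.shapes[(param, sex)]
            j = 1.0 + cfg.jitter * rng.uniform(-1.0, 1.0, size=4)
            m0, m1 = float(shape.m_start * j[0]), float(shape.m_end * j[1])
            s0, s1 = float(shape.s_start * j[2]), float(shape.s_end * j[3])
            c = float(shape.curvature * (1.0 + 0.1 * cfg.jitter / 0.02
                                         * rng.uniform(-1.0, 1.0)))
            if m0 <= 0 or m1 <= 0 or s0 <= 0 or s1 <= 0 or c <= 0:
                raise ConfigError(
                    f"shape for ({param}, {sex}) implies non-positive "
                    f"M, S or curvature")
            if spec.mode == "boxcox":
                worst = max(abs(shape.l_start), abs(shape.l_end)) * max(s0, s1)
                if worst > _MAX_ABS_LS:
                    raise ConfigError(
                        f"({param}, {sex}): |L*S| = {worst:.3f} cannot "
                        f"represent |z| = {_EXTREME_Z} "
                        f"(limit {_MAX_ABS_LS:.3f})")
            span = spec.age_max - spec.age_min
            nodes = []
            for a in grid:
                u = (a - spec.age_min) / span
                f = 1.0 - (1.0 - u) ** c
                M = m0 + (m1 - m0) * f
                S = s0 + (s1 - s0) * u
                if spec.mode == "boxcox":
                    L = shape.l_start + (shape.l_end - shape.l_start) * u
                else:
                    L = 1.0
                nodes.append(LMSNode(age=a, L=L, M=M, S=S))
            if param in _SIZE_PARAMETERS:
                ms = [n.M for n in nodes]
                if any(b <= a for a, b in zip(ms, ms[1:])):
                    raise ConfigError(
                        f"({param}, {sex}): median not increasing")
            ref.curves[(param, sex)] = ReferenceCurve(param, sex, nodes)
    return ref


# ----------------------------------------------------------------------------
# Synthetic cohorts with known ground truth
# ----------------------------------------------------------------------------

def generate_cohort(ref: ReferenceSet, n: int, seed: int,
                    z_dist: str = "normal", z0: float | None = None,
                    include_extremes: bool | None = None,
                    ) -> list[PatientRecord]:
    """Sample ``n`` synthetic patients with exactly known true z per parameter.

    Ages are stratified — even-indexed patients sit on grid nodes, odd-indexed
    ones strictly between nodes — so interpolation is always exercised.  Each
    patient carries every parameter whose domain contains their age; values
    come from :func:`measurement_from_z`, so the generating z is the ground
    truth (stored in ``PatientRecord.true_z``).

    ``z_dist`` is ``"normal"`` (standard normal draws) or ``"fixed"`` (every
    true z equals ``z0``).  With the normal distribution, |z| = 4 extremes are
    additionally injected for every parameter (one +4 and one -4 item),
    probing the percentile boundaries; pass ``include_extremes`` to override.
    """
    if n < 1:
        raise ConfigError(f"cohort size must be >= 1, got {n}")
    if z_dist not in ("normal", "fixed"):
        raise ConfigError(f"z_dist must be 'normal' or 'fixed', got {z_dist!r}")
    if z_dist == "fixed" and z0 is None:
        raise ConfigError("z_dist='fixed' requires z0")
    if include_extremes is None:
        include_extremes = z_dist == "normal"
    rng = np.random.default_rng(seed)
    grid_ages = age_grid(REGISTRY["height"])

    cohort: list[PatientRecord] = []
    for i in range(n):
        sex = SEXES[i % 2]
        if i % 2 == 0:
            age = float(rng.choice(grid_ages))
        else:
            a0 = float(rng.uniform(0.0, 19.0))
            frac = float(rng.uniform(0.1, 0.9))
            lo = max(g for g in grid_ages if g <= a0)
            hi = min(g for g in grid_ages if g > a0)
            age = lo + frac * (hi - lo)
        rec = PatientRecord(patient_id=f"SYN{i:03d}", sex=sex, age=age,
                            measurements={}, true_z={})
        for param in PARAMETER_ORDER:
            spec = REGISTRY[param]
            if not (spec.age_min <= age <= spec.age_max):
                continue
            z = float(rng.standard_normal()) if z_dist == "normal" else float(z0)
            node = interpolate_lms(ref.get_curve(param, sex), age)
            rec.measurements[param] = measurement_from_z(z, node, spec.mode)
            rec.true_z[param] = z
        cohort.append(rec)

    if include_extremes:
        for k, param in enumerate(PARAMETER_ORDER):
            spec = REGISTRY[param]
            placed = 0
            for rec in cohort[k % n:] + cohort[:k % n]:
                if param not in rec.measurements:
                    continue
                z = _EXTREME_Z if placed == 0 else -_EXTREME_Z
                node = interpolate_lms(ref.get_curve(param, rec.sex), rec.age)
                rec.measurements[param] = measurement_from_z(z, node, spec.mode)
                rec.true_z[param] = z
                placed += 1
                if placed == 2:
                    break
    return cohort


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path,
                 truth_path: str | Path | None = None) -> None:
    """Write a cohort as a long-format patient CSV (plus optional truth CSV)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_CSV_COLUMNS)
        for rec in cohort:
            for param in PARAMETER_ORDER:
                if param in rec.measurements:
                    w.writerow([rec.patient_id, rec.sex, repr(rec.age), param,
                                repr(rec.measurements[param])])
    if truth_path is not None:
        with open(truth_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "sex", "age_years", "parameter",
                        "true_z"])
            for rec in cohort:
                for param in PARAMETER_ORDER:
                    if rec.true_z and param in rec.true_z:
                        w.writerow([rec.patient_id, rec.sex, repr(rec.age),
                                    param, repr(rec.true_z[param])])


# ----------------------------------------------------------------------------
# Engine-vs-manual-oracle agreement check
# ----------------------------------------------------------------------------

def agreement_check(ref: ReferenceSet, cohort: Sequence[PatientRecord],
                    tol: float = 1e-9,
                    oracle: Callable[..., float] | None = None) -> float:
    """Percentage of (patient, parameter) pairs where the engine agrees with
    the independent manual oracle within ``tol`` on the z-score.

    The oracle (:func:`agrowth._oracle.manual_zscore`) re-derives every step —
    bracketing-node lookup, linear interpolation of L/M/S, the printed
    formulas — from plain table rows using only the stdlib, sharing no code
    with the engine; 100% agreement is therefore evidence, not tautology.
    A different callable may be injected for testing.
    """
    if oracle is None:
        oracle = manual_zscore
    rows = reference_rows(ref)
    modes = {p: REGISTRY[p].mode for p in REGISTRY}
    total = matches = 0
    for rec in cohort:
        age = rec.resolved_age()
        for param, value in rec.measurements.items():
            z_engine = evaluate(Measurement(param, rec.sex, age, value), ref).z
            z_manual = oracle(rows, param, rec.sex, age, value, modes[param])
            total += 1
            if abs(z_engine - z_manual) <= tol:
                matches += 1
    if total == 0:
        raise DomainError("agreement_check: empty cohort")
    return 100.0 * matches / total


# ----------------------------------------------------------------------------
# Simulated inter-rater reliability study
# ----------------------------------------------------------------------------

def simulate_rater_study(ref: ReferenceSet, n_raters: int = 10,
                         n_cases: int = 3, manual_error_sd: float = 0.2,
                         seed: int = 0) -> list[DeviationSample]:
    """Replicate the reliability study design with a synthetic error model.

    Each of ``n_raters`` raters evaluates all 9 parameters for ``n_cases``
    patients by two methods — 9 * n_cases * 2 calculations per rater (54 in
    the default 3-case design).  Manual chart reading is modelled as the gold
    z plus zero-mean normal noise of SD ``manual_error_sd`` (so recorded
    deviations are half-normal); the automated method reproduces the gold
    standard exactly, so its deviations are identically 0.  This is a
    documented stand-in for human rater data, not a reproduction of it.
    """
    if manual_error_sd < 0:
        raise ConfigError(f"manual_error_sd must be >= 0, got {manual_error_sd}")
    rng = np.random.default_rng(seed)
    # Full-panel cases: ages >= 3 so all 9 parameters are in domain.
    cases: list[PatientRecord] = []
    cohort = generate_cohort(ref, max(2 * n_cases, 8), seed=seed + 1,
                             include_extremes=False)
    for rec in cohort:
        if len(rec.measurements) == len(PARAMETER_ORDER):
            cases.append(rec)
        if len(cases) == n_cases:
            break
    while len(cases) < n_cases:  # degenerate seeds: force in-domain ages
        i = len(cases)
        age = 3.5 + i
        rec = PatientRecord(f"CASE{i}", SEXES[i % 2], age=age,
                            measurements={}, true_z={})
        for param in PARAMETER_ORDER:
            node = interpolate_lms(ref.get_curve(param, rec.sex), age)
            z = float(rng.standard_normal())
            rec.measurements[param] = measurement_from_z(
                z, node, REGISTRY[param].mode)
            rec.true_z[param] = z
        cases.append(rec)

    samples: list[DeviationSample] = []
    for r in range(1, n_raters + 1):
        for c, rec in enumerate(cases, start=1):
            for param in PARAMETER_ORDER:
                noise = float(rng.normal(0.0, manual_error_sd)) \
                    if manual_error_sd > 0 else 0.0
                samples.append(DeviationSample(
                    rater_id=str(r), case_id=str(c), parameter_id=param,
                    method="manual", deviation=abs(noise)))
                samples.append(DeviationSample(
                    rater_id=str(r), case_id=str(c), parameter_id=param,
                    method="smart", deviation=0.0))
    return samples


def summarize_deviations(samples: Sequence[DeviationSample],
                         group_by: Sequence[str] = ("method",),
                         ) -> dict[tuple[str, ...], AgreementSummary]:
    """Median [IQR] of absolute deviations per group.

    Quantiles use the SPSS/Weibull estimator (h = (n+1)p, linear between
    order statistics), the convention under which three samples
    {0.07, 0.17, 0.30} summarize to 0.17 [0.07-0.30].
    """
    if not samples:
        raise DomainError("summarize_deviations: no samples")
    for key in group_by:
        if key not in ("rater_id", "case_id", "parameter_id", "method"):
            raise DomainError(f"unknown group_by key {key!r}")
    groups: dict[tuple[str, ...], list[float]] = {}
    for s in samples:
        k = tuple(getattr(s, key) for key in group_by)
        groups.setdefault(k, []).append(s.deviation)
    out: dict[tuple[str, ...], AgreementSummary] = {}
    for k, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="weibull")
        out[k] = AgreementSummary(median=float(med), iqr_low=float(q1),
                                  iqr_high=float(q3), n=len(vals))
    return out


def rater_case_table(samples: Sequence[DeviationSample]) -> pd.DataFrame:
    """Tidy reliability table: per rater x case x method, plus per-rater
    'total' rows and pooled 'all' rows."""
    rows = []
    per = summarize_deviations(samples, ("rater_id", "case_id", "method"))
    for (rater, case, method), s in sorted(per.items()):
        rows.append((rater, case, method, s.median, s.iqr_low, s.iqr_high, s.n))
    totals = summarize_deviations(samples, ("rater_id", "method"))
    for (rater, method), s in sorted(totals.items()):
        rows.append((rater, "total", method,
                     s.median, s.iqr_low, s.iqr_high, s.n))
    pooled_case = summarize_deviations(samples, ("case_id", "method"))
    for (case, method), s in sorted(pooled_case.items()):
        rows.append(("all", case, method,
                     s.median, s.iqr_low, s.iqr_high, s.n))
    pooled = summarize_deviations(samples, ("method",))
    for (method,), s in sorted(pooled.items()):
        rows.append(("all", "total", method,
                     s.median, s.iqr_low, s.iqr_high, s.n))
    return pd.DataFrame(rows, columns=[
        "rater", "case", "method", "median", "iqr_low", "iqr_high", "n"])


def format_summary(s: AgreementSummary, ndigits: int = 2) -> str:
    """Render a summary the way reliability tables print it: 'm [q1-q3]'."""
    f = f"{{:.{ndigits}f}}"
    return (f"{f.format(s.median)} "
            f"[{f.format(s.iqr_low)}–{f.format(s.iqr_high)}]")
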