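"""Domain types shared by every stage of the synthesis pipeline.

A :class:`DataTable` couples a pandas DataFrame with an explicit
per-column :class:`VariableSchema`; a :class:`SynthesisPlan` is the
declarative contract for one synthesis run (visit order, per-column
method, predictor sets, smoothing, deterministic rules, seed).
``validate_plan`` checks a plan against a schema and returns named
violations instead of raising, so a CLI can show all problems at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"
NOMINAL = "nominal"
ORDINAL = "ordinal"
KINDS = (CONTINUOUS, BINARY, NOMINAL, ORDINAL)
CATEGORICAL_KINDS = (BINARY, NOMINAL, ORDINAL)

METHODS = ("sample", "cart", "norm", "logit", "polytomous")

#: methods compatible with each variable kind
_METHOD_KINDS = {
    "sample": KINDS,
    "cart": KINDS,
    "norm": (CONTINUOUS,),
    "logit": (BINARY,),
    "polytomous": (NOMINAL, ORDINAL, BINARY),
}

FALSE_DATA_COLUMN = "FALSE_DATA"
FALSE_DATA_VALUE = "FALSE_DATA"


class ContractError(ValueError):
    """An operation was called with inputs violating its contract."""


@dataclass(frozen=True)
class VariableSchema:
    """Declared type of one column.

    Parameters
    ----------
    name : str
        Column name, unique within a table schema.
    kind : str
        One of ``continuous``, ``binary``, ``nominal``, ``ordinal``.
    levels : tuple of str
        Ordered category labels; empty iff ``kind`` is continuous.
    missing_allowed : bool
        Whether missing markers may appear in the column.
    """

    name: str
    kind: str
    levels: tuple = ()
    missing_allowed: bool = True

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ContractError(f"unknown kind {self.kind!r} for {self.name!r}")
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if self.kind == CONTINUOUS and self.levels:
            raise ContractError(f"{self.name!r}: continuous variables have no levels")
        if self.kind in CATEGORICAL_KINDS and not self.levels:
            raise ContractError(f"{self.name!r}: categorical variables need levels")
        if len(set(self.levels)) != len(self.levels):
            raise ContractError(f"{self.name!r}: duplicate level labels")
        if self.kind == BINARY and len(self.levels) != 2:
            raise ContractError(f"{self.name!r}: binary variables need exactly 2 levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind in CATEGORICAL_KINDS


def _canonical_column(values: pd.Series, schema: VariableSchema) -> pd.Series:
    """Coerce a column to the internal canonical representation.

    Continuous columns become float64 with NaN as the single missing
    marker; categorical columns become object dtype holding ``str``
    labels with NaN missing. Extended missing encodings (pd.NA, None,
    empty strings) collapse to NaN.
    """
    if schema.kind == CONTINUOUS:
        return pd.to_numeric(values, errors="coerce").astype(float)
    out = values.astype(object).where(~pd.isna(values), np.nan)
    out = out.map(lambda v: np.nan if (not isinstance(v, str) and pd.isna(v))
                  else str(v))
    out = out.where(out != "", np.nan)
    return out.astype(object)


@dataclass
class DataTable:
    """Typed rectangular dataset: a DataFrame plus explicit schema.

    Values are stored canonically (floats with NaN for continuous,
    string labels with NaN for categorical) so that row equality in the
    disclosure-control stage is exact.
    """

    data: pd.DataFrame
    schema: tuple

    def __post_init__(self):
        self.schema = tuple(self.schema)
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise ContractError("duplicate variable names in schema")
        if list(self.data.columns) != names:
            raise ContractError("DataFrame columns do not match schema order")
        if len(self.data) < 1:
            raise ContractError("DataTable needs at least one row")
        cols = {}
        for s in self.schema:
            col = _canonical_column(self.data[s.name], s)
            if s.is_categorical:
                bad = set(col.dropna()) - set(s.levels)
                if bad:
                    raise ContractError(
                        f"{s.name!r}: values {sorted(bad)} outside declared levels")
            cols[s.name] = col
        self.data = pd.DataFrame(cols, columns=names).reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list:
        return [s.name for s in self.schema]

    def schema_for(self, name: str) -> VariableSchema:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_data(self, df: pd.DataFrame) -> "DataTable":
        return DataTable(df[self.columns].copy(), self.schema)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       overrides: Mapping[str, VariableSchema] | None = None,
                       max_levels: int = 40) -> "DataTable":
        """Build a table, inferring a schema from dtypes.

        Object/categorical/boolean columns become nominal (binary when
        exactly two observed levels); numeric columns become continuous.
        ``overrides`` replaces the inferred schema for named columns.
        """
        overrides = dict(overrides or {})
        schema = []
        for name in df.columns:
            if name in overrides:
                schema.append(overrides[name])
                continue
            col = df[name]
            if isinstance(col.dtype, pd.CategoricalDtype):
                levels = tuple(str(c) for c in col.cat.categories)
                kind = BINARY if len(levels) == 2 else NOMINAL
                schema.append(VariableSchema(name, kind, levels))
            elif col.dtype == object or col.dtype == bool:
                levels = tuple(sorted({str(v) for v in col.dropna().unique()}))
                if len(levels) > max_levels:
                    raise ContractError(
                        f"{name!r}: {len(levels)} levels exceed max_levels={max_levels}")
                kind = BINARY if len(levels) == 2 else NOMINAL
                schema.append(VariableSchema(name, kind, levels))
            else:
                schema.append(VariableSchema(name, CONTINUOUS))
        return cls(df.copy(), tuple(schema))


@dataclass(frozen=True)
class Condition:
    """One clause of a rule predicate: ``var <op> value``.

    Missing values never satisfy a condition, so rules do not fire on
    rows where a predicate variable is missing.
    """

    var: str
    op: str
    value: object

    _OPS = ("==", "!=", "<", "<=", ">", ">=", "in")

    def __post_init__(self):
        if self.op not in self._OPS:
            raise ContractError(f"unknown condition operator {self.op!r}")

    def evaluate(self, column: pd.Series) -> pd.Series:
        notna = column.notna()
        if self.op == "==":
            hit = column == self.value
        elif self.op == "!=":
            hit = column != self.value
        elif self.op == "in":
            hit = column.isin(list(self.value))
        else:
            col = pd.to_numeric(column, errors="coerce")
            val = float(self.value)
            hit = {"<": col < val, "<=": col <= val,
                   ">": col > val, ">=": col >= val}[self.op]
        return (hit & notna).fillna(False).astype(bool)


@dataclass(frozen=True)
class Rule:
    """Deterministic consistency rule: when every condition holds on a
    row, the target column is forced to ``value`` (e.g. never-smokers
    get 0 cigarettes per day)."""

    target: str
    value: object
    conditions: tuple

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.conditions:
            raise ContractError(f"rule for {self.target!r} has no conditions")

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=df.index)
        for c in self.conditions:
            m &= c.evaluate(df[c.var])
        return m


@dataclass(frozen=True)
class CartControls:
    """Tree-growing controls for CART column models.

    ``min_leaf`` keeps leaves small enough for faithful conditional
    donor pools but large enough to avoid one-donor leaves;
    ``complexity`` is the cost-complexity pruning threshold (near zero
    so trees grow deep, matching conditional-distribution fidelity).
    """

    min_leaf: int = 5
    complexity: float = 1e-8
    max_depth: int | None = None


@dataclass
class SynthesisPlan:
    """Declarative description of one synthesis run."""

    visit_sequence: tuple
    method: dict
    predictors: dict           # target -> tuple of predictor names
    smoothing: frozenset = frozenset()
    rules: tuple = ()
    seed: int = 0
    cart_controls: CartControls = field(default_factory=CartControls)

    def __post_init__(self):
        self.visit_sequence = tuple(self.visit_sequence)
        self.method = dict(self.method)
        self.predictors = {k: tuple(v) for k, v in self.predictors.items()}
        self.smoothing = frozenset(self.smoothing)
        self.rules = tuple(self.rules)

    def digest(self) -> str:
        """Stable SHA-256 digest of the plan (provenance)."""
        doc = {
            "visit_sequence": list(self.visit_sequence),
            "method": {k: self.method[k] for k in sorted(self.method)},
            "predictors": {k: list(v) for k, v in sorted(self.predictors.items())},
            "smoothing": sorted(self.smoothing),
            "rules": [
                {"target": r.target, "value": r.value,
                 "conditions": [[c.var, c.op, c.value] for c in r.conditions]}
                for r in self.rules
            ],
            "seed": self.seed,
            "cart_controls": [self.cart_controls.min_leaf,
                              self.cart_controls.complexity,
                              self.cart_controls.max_depth],
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()


@dataclass(frozen=True)
class PlanViolation:
    """One broken plan invariant, naming the offending variable."""

    variable: str
    rule: str
    message: str
    severity: str = "error"   # "error" | "warning"

    def __str__(self):
        return f"[{self.severity}] {self.variable}: {self.rule} — {self.message}"


def default_plan(table: DataTable, seed: int = 0,
                 method: str = "cart",
                 visit_sequence: Sequence[str] | None = None,
                 outcome_last: Sequence[str] = (),
                 smoothing: Iterable[str] = (),
                 rules: Sequence[Rule] = (),
                 cart_controls: CartControls | None = None) -> SynthesisPlan:
    """Build the default plan for a table.

    Visit order follows the column order of the input unless
    ``visit_sequence`` is given; ``outcome_last`` moves the named
    columns (typically exposure and outcome) to the end of the order,
    a heuristic that can preserve their mutual relations more
    faithfully. The first visited column is always sampled from its
    marginal; every earlier column predicts every later one.
    """
    if visit_sequence is None:
        visit_sequence = list(table.columns)
    else:
        visit_sequence = list(visit_sequence)
    for name in outcome_last:
        if name in visit_sequence:
            visit_sequence.remove(name)
            visit_sequence.append(name)
    methods = {}
    for i, name in enumerate(visit_sequence):
        if i == 0:
            methods[name] = "sample"
        elif method == "parametric" and name in table.columns:
            kind = table.schema_for(name).kind
            methods[name] = {CONTINUOUS: "norm", BINARY: "logit",
                             NOMINAL: "polytomous", ORDINAL: "polytomous"}[kind]
        else:
            methods[name] = method if method != "parametric" else "cart"
    predictors = {name: tuple(visit_sequence[:i])
                  for i, name in enumerate(visit_sequence)}
    return SynthesisPlan(
        visit_sequence=tuple(visit_sequence),
        method=methods,
        predictors=predictors,
        smoothing=frozenset(smoothing),
        rules=tuple(rules),
        seed=seed,
        cart_controls=cart_controls or CartControls(),
    )


def validate_plan(plan: SynthesisPlan, schema: Sequence[VariableSchema]):
    """Check a plan against a table schema.

    Returns a list of :class:`PlanViolation`; empty iff every plan
    invariant holds. Unknown variable names yield named violations, not
    exceptions. Chained rules (a rule target feeding a later rule's
    predicate) are supported but flagged as warnings.
    """
    schema = list(schema)
    if not schema or not plan.visit_sequence:
        raise ContractError("plan and schema must be non-empty")
    by_name = {s.name: s for s in schema}
    names = set(by_name)
    out: list[PlanViolation] = []
    seq = list(plan.visit_sequence)
    pos = {v: i for i, v in enumerate(seq)}

    extra = [v for v in seq if v not in names]
    for v in extra:
        out.append(PlanViolation(v, "unknown-variable",
                                 "visit_sequence names a variable absent from the schema"))
    missing = sorted(names - set(seq))
    for v in missing:
        out.append(PlanViolation(v, "not-visited",
                                 "schema variable missing from visit_sequence"))
    dupes = {v for v in seq if seq.count(v) > 1}
    for v in sorted(dupes):
        out.append(PlanViolation(v, "duplicate-visit",
                                 "variable appears more than once in visit_sequence"))

    first = seq[0]
    if plan.method.get(first) != "sample":
        out.append(PlanViolation(first, "first-not-sample",
                                 "the first visited variable must use method 'sample'"))
    for v in seq:
        m = plan.method.get(v)
        if m is None:
            out.append(PlanViolation(v, "no-method", "no method assigned"))
        elif m not in METHODS:
            out.append(PlanViolation(v, "unknown-method", f"method {m!r} not recognised"))
        elif v in by_name and by_name[v].kind not in _METHOD_KINDS[m]:
            out.append(PlanViolation(
                v, "method-kind-mismatch",
                f"method {m!r} incompatible with kind {by_name[v].kind!r}"))

    for target, preds in plan.predictors.items():
        if target not in pos:
            out.append(PlanViolation(target, "unknown-variable",
                                     "predictor map names a variable not in visit_sequence"))
            continue
        for p in preds:
            if p not in pos:
                out.append(PlanViolation(target, "unknown-predictor",
                                         f"predictor {p!r} not in visit_sequence"))
            elif pos[p] >= pos[target]:
                out.append(PlanViolation(
                    target, "non-lower-triangular",
                    f"predictor {p!r} is not synthesised before {target!r}"))

    forced_so_far: set = set()
    for r in plan.rules:
        if r.target not in pos:
            out.append(PlanViolation(r.target, "unknown-variable",
                                     "rule targets a variable not in visit_sequence"))
            continue
        for c in r.conditions:
            if c.var not in pos:
                out.append(PlanViolation(r.target, "unknown-predictor",
                                         f"rule predicate uses unknown variable {c.var!r}"))
            elif pos[c.var] >= pos[r.target]:
                out.append(PlanViolation(
                    r.target, "rule-ordering",
                    f"rule predicate variable {c.var!r} is not synthesised "
                    f"before its target {r.target!r}"))
            elif c.var in forced_so_far:
                out.append(PlanViolation(
                    r.target, "chained-rule",
                    f"predicate variable {c.var!r} is itself a rule target; "
                    "chained rules are applied in rule order", severity="warning"))
        forced_so_far.add(r.target)
    return out


def plan_errors(violations) -> list:
    return [v for v in violations if v.severity == "error"]


def make_release_frame(table: DataTable) -> pd.DataFrame:
    """Return the released view: FALSE_DATA marker column first."""
    df = table.data.copy()
    df.insert(0, FALSE_DATA_COLUMN, FALSE_DATA_VALUE)
    return df


@dataclass
class SyntheticRelease:
    """Synthetic table plus provenance and the FALSE_DATA marker.

    ``table`` stores the synthetic data without the marker column;
    :meth:`frame` returns the released view with FALSE_DATA first.
    """

    table: DataTable
    provenance: dict
    disclaimer: str = ""

    def frame(self) -> pd.DataFrame:
        return make_release_frame(self.table)

    def with_table(self, table: DataTable, **prov) -> "SyntheticRelease":
        p = dict(self.provenance)
        p.update(prov)
        return SyntheticRelease(table=table, provenance=p,
                                disclaimer=self.disclaimer)
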