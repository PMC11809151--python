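"""File I/O, release packaging and the release audit.

Tables travel as CSV (RFC-4180, empty fields are missing) or Stata
.dta (value labels become categorical levels; all Stata missing codes
collapse to the single missing marker). A packaged release always
carries the FALSE_DATA marker column first, a provenance JSON (seed,
plan digest, rows removed) and a plain-text disclaimer, and passes a
release audit implementing the releasable-synthetic-data guideline
checks: variable minimisation (< 50 variables), zero replicated
uniques plus a clean manual check, marginal and model comparisons
generated, the FALSE_DATA marker, the disclaimer, and recorded
generation provenance.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CartControls,
    Condition,
    ContractError,
    DataTable,
    FALSE_DATA_COLUMN,
    FALSE_DATA_VALUE,
    Rule,
    SynthesisPlan,
    SyntheticRelease,
    VariableSchema,
)
from .disclosure import find_replicated_uniques, manual_check_sample

log = logging.getLogger("cohortsynth")

#: Statement shipped alongside every release. Synthetic records are
#: simulations: relations between variables are not guaranteed to match
#: the source data, so these files support code reproduction and
#: teaching only.
DISCLAIMER = (
    "This dataset is wholly synthetic and is NOT suitable for research "
    "purposes. It was simulated from models of an observed study dataset; "
    "relations between variables are unlikely to be preserved perfectly, "
    "so results obtained from it may differ from the real data. Any formal "
    "research or published analysis must use the actual observed data."
)

MAX_RELEASE_VARIABLES = 50


class FormatError(ContractError):
    """A file could not be parsed under the requested format."""


def read_table(path, fmt: str | None = None,
               overrides=None) -> DataTable:
    """Read a CSV or Stata .dta file into a typed :class:`DataTable`.

    The schema is inferred (Stata value labels and pandas categoricals
    become categorical levels; numeric columns become continuous) with
    per-column ``overrides`` honoured. Empty CSV fields and every Stata
    missing code map to the single missing marker.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower().lstrip(".")
        if ext not in ("csv", "dta"):
            raise ContractError(
                f"cannot infer format from {path.name!r}; pass fmt='csv' or 'dta'")
        fmt = ext
    if fmt not in ("csv", "dta"):
        raise ContractError(f"unknown format {fmt!r}")
    try:
        if fmt == "csv":
            df = pd.read_csv(path)
        else:
            df = pd.read_stata(path, convert_categoricals=True)
            df = df.drop(columns=[c for c in ("index",) if c in df.columns])
    except (ContractError, FileNotFoundError):
        raise
    except Exception as exc:
        raise FormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return DataTable.from_dataframe(df, overrides=overrides)


def _stata_frame(df: pd.DataFrame, table: DataTable) -> pd.DataFrame:
    """Categorical columns as pandas Categorical so .dta gets value labels."""
    out = df.copy()
    for s in table.schema:
        if s.is_categorical:
            out[s.name] = pd.Categorical(out[s.name], categories=list(s.levels))
    return out


def write_release(release: SyntheticRelease, basename: str,
                  formats=("csv",), outdir=".",
                  audit: "ReleaseAuditReport | None" = None,
                  force: bool = False) -> dict:
    """Write a release: data files (FALSE_DATA first), provenance JSON
    and the disclaimer sidecar. Refuses a release whose audit failed
    unless ``force`` (and logs the refusal)."""
    if audit is not None and not audit.overall and not force:
        log.error("refusing to write release %s: audit failed (%s)",
                  basename, ", ".join(c["id"] for c in audit.checks
                                      if c["status"] == "fail"))
        raise ContractError("release audit failed; use force=True to override")
    if release.table.n < 1:
        raise ContractError("refusing to write an empty release")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = release.frame()
    written = {}
    for fmt in formats:
        if fmt == "csv":
            p = outdir / f"{basename}.csv"
            frame.to_csv(p, index=False)
        elif fmt == "dta":
            p = outdir / f"{basename}.dta"
            _stata_frame(frame, release.table).to_stata(
                p, write_index=False, version=117)
        else:
            raise ContractError(f"unknown format {fmt!r}")
        written[fmt] = p
        log.info("release stage=write format=%s path=%s n=%d", fmt, p,
                 release.table.n)
    prov = dict(release.provenance)
    prov["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    prov_path = outdir / f"{basename}_provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, default=str))
    written["provenance"] = prov_path
    disc_path = outdir / f"{basename}_DISCLAIMER.txt"
    disc_path.write_text(release.disclaimer or DISCLAIMER)
    written["disclaimer"] = disc_path
    return written


@dataclass
class ReleaseAuditReport:
    """Outcome of the guideline release checks."""

    checks: list = field(default_factory=list)
    overall: bool = True

    def add(self, check_id: str, name: str, status: str, detail: str = ""):
        self.checks.append({"id": check_id, "name": name,
                            "status": status, "detail": detail})
        if status == "fail":
            self.overall = False

    def status_of(self, check_id: str) -> str:
        for c in self.checks:
            if c["id"] == check_id:
                return c["status"]
        raise KeyError(check_id)

    def to_dict(self) -> dict:
        return {"overall": self.overall, "checks": list(self.checks)}


def release_audit(observed: DataTable, release: SyntheticRelease,
                  model_spec: str | None = None,
                  family: str = "binomial",
                  manual_check_k: int = 10,
                  seed: int = 0) -> ReleaseAuditReport:
    """Run the guideline checks on a prepared release (read-only).

    Checks: variable minimisation, replicated uniques + manual spot
    check, marginal comparison, model comparison (skipped without a
    ``model_spec`` formula), FALSE_DATA marker, disclaimer, provenance.
    """
    from .utility import compare_marginals, fit_glm_both

    report = ReleaseAuditReport()
    table = release.table
    n_vars = len(table.columns)
    detail = f"{n_vars} variables (excluding {FALSE_DATA_COLUMN})"
    if model_spec:
        import re as _re
        used = set(_re.findall(r"[A-Za-z_][A-Za-z0-9_]*", model_spec))
        extra = [c for c in table.columns if c not in used]
        if extra:
            detail += f"; columns beyond the model spec: {extra}"
    report.add("G2", "variable minimisation",
               "pass" if n_vars < MAX_RELEASE_VARIABLES else "fail", detail)

    try:
        rep, _ = find_replicated_uniques(observed, table)
        manual = manual_check_sample(observed, table, k=manual_check_k,
                                     seed=seed)
        ok = rep.n_replicated_uniques == 0 and manual == 0
        report.add("G3", "no replicated uniques",
                   "pass" if ok else "fail",
                   f"{rep.n_replicated_uniques} replicated uniques "
                   f"({rep.pct_replicated:.2f}% of observed); "
                   f"manual check matches: {manual}")
    except ContractError as exc:
        report.add("G3", "no replicated uniques", "fail", str(exc))

    try:
        marg = compare_marginals(observed, table)
        report.add("G4", "marginal comparison generated", "pass",
                   f"max per-cell difference "
                   f"{marg.max_pct_point_diff():.2f} percentage points")
    except Exception as exc:
        report.add("G4", "marginal comparison generated", "fail", str(exc))

    if model_spec:
        try:
            comp = fit_glm_both(model_spec, family, observed, table)
            status = "pass" if comp.converged else "fail"
            report.add("G5", "model comparison generated", status,
                       f"{model_spec} ({family})")
        except Exception as exc:
            report.add("G5", "model comparison generated", "fail", str(exc))
    else:
        report.add("G5", "model comparison generated", "skipped",
                   "no model specification provided")

    frame = release.frame()
    ok = (list(frame.columns)[0] == FALSE_DATA_COLUMN
          and (frame[FALSE_DATA_COLUMN] == FALSE_DATA_VALUE).all())
    report.add("G6", "FALSE_DATA marker first", "pass" if ok else "fail",
               f"first column: {list(frame.columns)[0]!r}")

    report.add("G7", "disclaimer present",
               "pass" if release.disclaimer.strip() else "fail",
               "disclaimer text attached" if release.disclaimer.strip()
               else "disclaimer missing")

    prov = release.provenance
    ok = bool(prov.get("plan_digest")) and prov.get("seed") is not None
    report.add("G10", "generation provenance recorded",
               "pass" if ok else "fail",
               f"seed={prov.get('seed')}, plan_digest="
               f"{str(prov.get('plan_digest'))[:12]}…")
    log.info("release stage=audit overall=%s", report.overall)
    return report


# ---------------------------------------------------------------------------
# plan (de)serialisation

def plan_to_yaml(plan: SynthesisPlan, path=None) -> str:
    doc = {
        "visit_sequence": list(plan.visit_sequence),
        "method": dict(plan.method),
        "predictors": {k: list(v) for k, v in plan.predictors.items()},
        "smoothing": sorted(plan.smoothing),
        "rules": [{"target": r.target, "value": r.value,
                   "conditions": [{"var": c.var, "op": c.op, "value": c.value}
                                  for c in r.conditions]}
                  for r in plan.rules],
        "seed": plan.seed,
        "cart_controls": {"min_leaf": plan.cart_controls.min_leaf,
                          "complexity": plan.cart_controls.complexity,
                          "max_depth": plan.cart_controls.max_depth},
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def plan_from_yaml(source) -> SynthesisPlan:
    """Load a plan from a YAML string or path."""
    text = source
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    doc = yaml.safe_load(text)
    cc = doc.get("cart_controls") or {}
    rules = tuple(
        Rule(target=r["target"], value=r["value"],
             conditions=tuple(Condition(c["var"], c["op"], c["value"])
                              for c in r["conditions"]))
        for r in doc.get("rules", ()))
    return SynthesisPlan(
        visit_sequence=tuple(doc["visit_sequence"]),
        method=dict(doc["method"]),
        predictors={k: tuple(v) for k, v in doc.get("predictors", {}).items()},
        smoothing=frozenset(doc.get("smoothing", ())),
        rules=rules,
        seed=int(doc.get("seed", 0)),
        cart_controls=CartControls(
            min_leaf=int(cc.get("min_leaf", 5)),
            complexity=float(cc.get("complexity", 1e-8)),
            max_depth=cc.get("max_depth"),
        ),
    )
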