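"""Statistical disclosure control.

A *replicated unique* is a synthetic record whose full value
combination (missing markers included) matches an observed record that
is unique in the observed table — the one way a wholly synthetic row
can still point at a real individual. These are tabulated
(:func:`find_replicated_uniques`), removed along with optional
top/bottom coding (:func:`apply_sdc`), and a manual spot check over
unique rows (:func:`manual_check_sample`) confirms the release is
clean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CONTINUOUS, ContractError, DataTable

_NA_KEY = "\x00<NA>"


def _row_keys(table: DataTable) -> pd.Series:
    """Hashable per-row key: the tuple of canonical values with a
    sentinel for missing, so NaN == NaN for row-matching purposes."""
    df = table.data
    cols = []
    for s in table.schema:
        col = df[s.name]
        if s.kind == CONTINUOUS:
            # bitwise equality on floats: repr of the float64 value
            cols.append(col.map(lambda v: _NA_KEY if pd.isna(v) else float(v).hex()))
        else:
            cols.append(col.map(lambda v: _NA_KEY if pd.isna(v) else str(v)))
    return pd.Series(list(zip(*cols)), index=df.index)


@dataclass
class DisclosureReport:
    """Tabulation of replicated uniques for one observed/synthetic pair."""

    n_synthetic_before: int
    n_replicated_uniques: int
    pct_replicated: float          # of the OBSERVED sample size
    removed_row_indices: list = field(default_factory=list)
    manual_check_matches: int | None = None

    def __post_init__(self):
        if self.n_replicated_uniques != len(self.removed_row_indices):
            raise ContractError("count does not match flagged indices")
        if not (0.0 <= self.pct_replicated <= 100.0):
            raise ContractError("pct_replicated outside [0, 100]")

    def to_dict(self) -> dict:
        return {
            "n_synthetic_before": self.n_synthetic_before,
            "n_replicated_uniques": self.n_replicated_uniques,
            "pct_replicated": self.pct_replicated,
            "removed_row_indices": list(map(int, self.removed_row_indices)),
            "manual_check_matches": self.manual_check_matches,
        }


def _check_same_columns(observed: DataTable, synthetic: DataTable):
    obs, syn = set(observed.columns), set(synthetic.columns)
    if obs != syn:
        raise ContractError(
            f"column mismatch: only observed {sorted(obs - syn)}, "
            f"only synthetic {sorted(syn - obs)}")


def find_replicated_uniques(observed: DataTable, synthetic: DataTable):
    """Flag synthetic rows replicating unique observed rows.

    A synthetic row is flagged iff its full value combination occurs
    exactly once in the observed table. Returns the
    :class:`DisclosureReport` and the per-row boolean flags; the
    percentage is reported against the observed sample size.
    """
    _check_same_columns(observed, synthetic)
    synthetic = synthetic.with_data(synthetic.data[observed.columns])
    obs_keys = _row_keys(observed)
    syn_keys = _row_keys(synthetic)
    counts = obs_keys.value_counts()
    unique_obs = set(counts.index[counts == 1])
    flags = syn_keys.isin(unique_obs).to_numpy()
    idx = list(np.flatnonzero(flags))
    report = DisclosureReport(
        n_synthetic_before=synthetic.n,
        n_replicated_uniques=len(idx),
        pct_replicated=100.0 * len(idx) / observed.n,
        removed_row_indices=idx,
    )
    return report, flags


def apply_sdc(observed: DataTable, synthetic: DataTable,
              flags: np.ndarray | None = None,
              top_bottom: dict | None = None) -> DataTable:
    """Remove flagged replicated uniques and optionally top/bottom code.

    ``top_bottom`` maps a continuous column to ``(lower_q, upper_q)``
    quantile bounds (either side may be None); values beyond a bound
    are replaced by the bound's quantile value. Because censoring can
    itself create new replicated uniques, flagging is re-run after
    coding and any fresh replicates removed, so the returned table
    always contains zero replicated uniques.
    """
    if flags is None:
        _, flags = find_replicated_uniques(observed, synthetic)
    flags = np.asarray(flags, bool)
    if len(flags) != synthetic.n:
        raise ContractError("flags do not match the synthetic table")
    df = synthetic.data.loc[~flags].reset_index(drop=True)
    if df.empty:
        raise ContractError("disclosure control would remove every synthetic row")
    if top_bottom:
        for name, (lo_q, hi_q) in top_bottom.items():
            sch = synthetic.schema_for(name)
            if sch.kind != CONTINUOUS:
                raise ContractError(f"top/bottom coding needs a continuous "
                                    f"column, got {name!r} ({sch.kind})")
            col = df[name].to_numpy(float)
            finite = col[~np.isnan(col)]
            if lo_q is not None:
                lo = float(np.quantile(finite, lo_q))
                col = np.where(~np.isnan(col) & (col < lo), lo, col)
            if hi_q is not None:
                hi = float(np.quantile(finite, hi_q))
                col = np.where(~np.isnan(col) & (col > hi), hi, col)
            df[name] = col.astype(object)
    result = synthetic.with_data(df)
    # release gate: censoring may have minted new replicates
    for _ in range(synthetic.n):
        report, new_flags = find_replicated_uniques(observed, result)
        if report.n_replicated_uniques == 0:
            return result
        df = result.data.loc[~new_flags].reset_index(drop=True)
        if df.empty:
            raise ContractError("disclosure control would remove every synthetic row")
        result = result.with_data(df)
    raise ContractError("disclosure control failed to converge")  # pragma: no cover


def manual_check_sample(observed: DataTable, synthetic: DataTable,
                        k: int = 10, seed: int = 0) -> int:
    """Spot check: draw ``k`` rows uniformly from the observed rows that
    are unique within the observed table and count exact matches among
    synthetic rows unique within the synthetic table. After
    :func:`apply_sdc` this must be 0."""
    if k < 1:
        raise ContractError("k must be at least 1")
    _check_same_columns(observed, synthetic)
    obs_keys = _row_keys(observed)
    syn_keys = _row_keys(synthetic.with_data(synthetic.data[observed.columns]))
    obs_unique = obs_keys[~obs_keys.duplicated(keep=False)]
    syn_unique = set(syn_keys[~syn_keys.duplicated(keep=False)])
    if len(obs_unique) == 0:
        warnings.warn("no unique observed rows to check", RuntimeWarning)
        return 0
    if k > len(obs_unique):
        warnings.warn(f"only {len(obs_unique)} unique observed rows; "
                      "checking all of them", RuntimeWarning)
        k = len(obs_unique)
    rng = np.random.default_rng(seed)
    picked = obs_unique.iloc[rng.choice(len(obs_unique), size=k, replace=False)]
    return int(sum(key in syn_unique for key in picked))
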