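"""Utility assessment: does the synthetic table behave like the observed?

Two complementary checks, mirroring standard synthetic-data practice:
marginal distributions compared cell by cell (missing tallied as its
own category, continuous binned on shared observed-data breaks), and
identical generalised linear models refitted on both tables with
coefficients put on a common z-value scale plus a symmetrised
confidence-interval overlap per term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
import statsmodels.api as sm
from scipy import stats

from .core import CONTINUOUS, ContractError, DataTable

NA_CATEGORY = "NA"


@dataclass
class MarginalComparison:
    """Per-variable observed vs synthetic category counts."""

    tables: dict                    # variable -> DataFrame
    n_observed: int
    n_synthetic: int

    def max_pct_point_diff(self) -> float:
        """Largest absolute per-cell difference in percentage share."""
        return max(float(t["pct_point_diff"].abs().max())
                   for t in self.tables.values())

    def to_frame(self) -> pd.DataFrame:
        out = []
        for var, t in self.tables.items():
            t = t.copy()
            t.insert(0, "variable", var)
            out.append(t)
        return pd.concat(out, ignore_index=True)


def _binned(values: pd.Series, breaks: np.ndarray) -> pd.Series:
    labels = [f"[{breaks[i]:.4g}, {breaks[i+1]:.4g}]" if i == 0
              else f"({breaks[i]:.4g}, {breaks[i+1]:.4g}]"
              for i in range(len(breaks) - 1)]
    v = pd.to_numeric(values, errors="coerce")
    cut = pd.cut(v, bins=breaks, labels=labels, include_lowest=True)
    out = cut.astype(object)
    # values outside the observed break range get edge bins
    out[v.notna() & (v < breaks[0])] = labels[0]
    out[v.notna() & (v > breaks[-1])] = labels[-1]
    out[v.isna()] = NA_CATEGORY
    return out


def compare_marginals(observed: DataTable, synthetic: DataTable,
                      n_bins: int = 4) -> MarginalComparison:
    """Tabulate observed vs synthetic counts per variable.

    Categorical columns use the observed level set (a synthetic
    category outside it is reported with observed count 0 — a synthesis
    bug signal); continuous columns are binned on quantile breaks of
    the observed column so counts are comparable. Differences are
    reported both absolutely and in percentage points of each table's
    own size.
    """
    if set(observed.columns) != set(synthetic.columns):
        raise ContractError("tables have different column sets")
    tables = {}
    for s in observed.schema:
        obs_col, syn_col = observed.data[s.name], synthetic.data[s.name]
        if s.kind == CONTINUOUS:
            finite = obs_col.dropna().to_numpy(float)
            qs = np.linspace(0, 1, n_bins + 1)
            breaks = np.unique(np.quantile(finite, qs)) if len(finite) else np.array([0., 1.])
            if len(breaks) < 2:
                breaks = np.array([breaks[0] - 0.5, breaks[0] + 0.5])
            obs_cat = _binned(obs_col, breaks)
            syn_cat = _binned(syn_col, breaks)
            cats = [l for l in pd.unique(obs_cat) if l != NA_CATEGORY]
            cats = sorted(set(cats) | set(pd.unique(syn_cat)) - {NA_CATEGORY})
        else:
            obs_cat = obs_col.astype(object).where(obs_col.notna(), NA_CATEGORY)
            syn_cat = syn_col.astype(object).where(syn_col.notna(), NA_CATEGORY)
            cats = list(s.levels)
            extra = sorted(set(syn_cat.unique()) - set(cats) - {NA_CATEGORY})
            cats += extra
        cats = list(cats) + [NA_CATEGORY]
        oc = obs_cat.value_counts()
        sc = syn_cat.value_counts()
        rows = []
        for c in cats:
            o, y = int(oc.get(c, 0)), int(sc.get(c, 0))
            rows.append({
                "category": c, "observed": o, "synthetic": y,
                "abs_diff": abs(o - y),
                "pct_point_diff": 100.0 * o / observed.n - 100.0 * y / synthetic.n,
            })
        tables[s.name] = pd.DataFrame(rows)
    return MarginalComparison(tables=tables, n_observed=observed.n,
                              n_synthetic=synthetic.n)


def ci_overlap(interval_obs, interval_syn) -> float:
    """Symmetrised confidence-interval overlap fraction.

    ``mean(overlap/width_obs, overlap/width_syn)`` where overlap is the
    shared interval length; 1 for identical intervals, 0 for disjoint.
    Degenerate zero-width intervals compare as points.
    """
    l1, u1 = map(float, interval_obs)
    l2, u2 = map(float, interval_syn)
    if l1 > u1 or l2 > u2:
        raise ContractError("interval bounds out of order")
    shared = max(0.0, min(u1, u2) - max(l1, l2))
    w1, w2 = u1 - l1, u2 - l2
    if w1 == 0 and w2 == 0:
        return 1.0 if (l1 == l2) else 0.0
    f1 = shared / w1 if w1 > 0 else float(l2 <= l1 <= u2)
    f2 = shared / w2 if w2 > 0 else float(l1 <= l2 <= u1)
    return 0.5 * (f1 + f2)


@dataclass
class ModelComparison:
    """Identical GLM refitted on observed and synthetic tables."""

    formula: str
    family: str
    table: pd.DataFrame          # one row per coefficient
    n_observed: int
    n_synthetic: int
    converged: bool = True

    def overlap_for(self, term: str) -> float:
        row = self.table.set_index("term").loc[term]
        return float(row["ci_overlap"])


def _glm_fit(formula: str, family: str, df: pd.DataFrame):
    fam = {"gaussian": sm.families.Gaussian(),
           "binomial": sm.families.Binomial()}[family]
    model = smf.glm(formula, data=df, family=fam, missing="drop")
    return model.fit()


def _modelling_frame(table: DataTable, formula: str) -> pd.DataFrame:
    """Complete cases with binary columns coded 0/1 on their level order."""
    df = table.data.copy()
    for s in table.schema:
        if s.kind == "binary":
            code = {s.levels[0]: 0.0, s.levels[1]: 1.0}
            df[s.name] = df[s.name].map(lambda v, c=code: c.get(v, np.nan))
    return df


def fit_glm_both(formula: str, family: str, observed: DataTable,
                 synthetic: DataTable) -> ModelComparison:
    """Fit one GLM specification separately to the observed and
    synthetic complete cases and line the results up per coefficient:
    estimate, SE, z = estimate/SE, Wald 95% CI and the symmetrised CI
    overlap."""
    if family not in ("gaussian", "binomial"):
        raise ContractError(f"unsupported family {family!r}")
    frames, fits, ns = [], [], []
    import warnings as _w
    for tbl in (observed, synthetic):
        df = _modelling_frame(tbl, formula)
        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit = _glm_fit(formula, family, df)
            if df.shape[0] < 10 * len(fit.params):
                _w.warn("fewer than 10 complete cases per fitted parameter",
                        RuntimeWarning)
        except Exception:
            fits.append(None)
            ns.append(len(df))
            continue
        fits.append(fit)
        ns.append(int(fit.nobs))
    fit_o, fit_s = fits
    terms = list(fit_o.params.index) if fit_o is not None else (
        list(fit_s.params.index) if fit_s is not None else [])
    rows = []
    for t in terms:
        row = {"term": t}
        for tag, fit in (("obs", fit_o), ("syn", fit_s)):
            if fit is None or t not in fit.params.index:
                row.update({f"est_{tag}": np.nan, f"se_{tag}": np.nan,
                            f"z_{tag}": np.nan, f"ci_lo_{tag}": np.nan,
                            f"ci_hi_{tag}": np.nan})
                continue
            est, se = float(fit.params[t]), float(fit.bse[t])
            row[f"est_{tag}"] = est
            row[f"se_{tag}"] = se
            row[f"z_{tag}"] = est / se if se > 0 else np.nan
            half = stats.norm.ppf(0.975) * se
            row[f"ci_lo_{tag}"] = est - half
            row[f"ci_hi_{tag}"] = est + half
        if np.isfinite(row.get("ci_lo_obs", np.nan)) and \
           np.isfinite(row.get("ci_lo_syn", np.nan)):
            row["ci_overlap"] = ci_overlap(
                (row["ci_lo_obs"], row["ci_hi_obs"]),
                (row["ci_lo_syn"], row["ci_hi_syn"]))
        else:
            row["ci_overlap"] = np.nan
        rows.append(row)
    return ModelComparison(
        formula=formula, family=family, table=pd.DataFrame(rows),
        n_observed=ns[0], n_synthetic=ns[1],
        converged=fit_o is not None and fit_s is not None)


def plot_marginals(comparison: MarginalComparison, ncol: int = 5):
    """Grouped bar chart per variable (observed vs synthetic counts)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    vars_ = list(comparison.tables)
    nrow = int(np.ceil(len(vars_) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax in axes.ravel()[len(vars_):]:
        ax.set_visible(False)
    for ax, var in zip(axes.ravel(), vars_):
        t = comparison.tables[var]
        x = np.arange(len(t))
        ax.bar(x - 0.2, t["observed"], width=0.4, label="observed")
        ax.bar(x + 0.2, t["synthetic"], width=0.4, label="synthetic")
        ax.set_xticks(x)
        ax.set_xticklabels(t["category"], rotation=45, ha="right", fontsize=6)
        ax.set_title(var, fontsize=8)
    axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    return fig


def plot_coefficients(comparison: ModelComparison):
    """Dot plot of observed vs synthetic coefficients on the z scale."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    t = comparison.table
    y = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(t) + 1.5))
    ax.scatter(t["z_obs"], y - 0.1, label="observed")
    ax.scatter(t["z_syn"], y + 0.1, label="synthetic")
    ax.set_yticks(y)
    ax.set_yticklabels(t["term"])
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("z value")
    ax.legend()
    fig.tight_layout()
    return fig
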