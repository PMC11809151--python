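"""Growth-curve validation of synthetic repeated-measures data.

Panels are synthesised in wide format (one row per individual) and then
reshaped to long format for analysis. Trajectory fidelity is judged by
fitting the same multilevel quadratic growth model to observed and
synthetic long tables: fixed intercept, centred age and age squared
(optionally a female main effect and both interactions), with
individual-level random intercept and random slopes for age and age²
under an unstructured covariance, estimated by maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .core import ContractError

_Z95 = float(stats.norm.ppf(0.975))

#: internal rescaling factor for the squared-age term (years²); keeps
#: the random-effect variances on comparable scales during optimisation
_AGE2_SCALE = 10.0


def wide_to_long(wide: pd.DataFrame, id_col: str,
                 value_stubs, age_columns) -> pd.DataFrame:
    """Reshape a wide panel to one row per non-missing (id, occasion).

    ``value_stubs`` and ``age_columns`` pair the measurement column and
    its per-occasion age column, in occasion order. Occasions with a
    missing measurement are dropped. Extra wide columns (e.g. sex) are
    carried along unchanged.
    """
    value_stubs, age_columns = list(value_stubs), list(age_columns)
    if len(value_stubs) != len(age_columns):
        raise ContractError("value and age column lists differ in length")
    if wide[id_col].duplicated().any():
        raise ContractError("duplicated ids in wide input")
    carry = [c for c in wide.columns
             if c not in value_stubs + age_columns + [id_col]]
    frames = []
    for occ, (vcol, acol) in enumerate(zip(value_stubs, age_columns), start=1):
        block = wide[[id_col] + carry].copy()
        block["occasion"] = occ
        block["age"] = pd.to_numeric(wide[acol], errors="coerce")
        block["value"] = pd.to_numeric(wide[vcol], errors="coerce")
        frames.append(block)
    long = pd.concat(frames, ignore_index=True)
    long = long[long["value"].notna()].reset_index(drop=True)
    cols = [id_col] + carry + ["occasion", "age", "value"]
    return long[cols].sort_values([id_col, "occasion"]).reset_index(drop=True)


def long_to_wide(long: pd.DataFrame, id_col: str,
                 value_stub: str = "value", age_stub: str = "age") -> pd.DataFrame:
    """Inverse reshape (round-trips :func:`wide_to_long` up to occasion
    ordering; missing occasions come back as NaN)."""
    carry = [c for c in long.columns
             if c not in {id_col, "occasion", "age", "value"}]
    wide = long.pivot(index=id_col, columns="occasion", values=["value", "age"])
    occasions = sorted(long["occasion"].unique())
    out = pd.DataFrame({id_col: wide.index})
    base = long.drop_duplicates(id_col).set_index(id_col)
    for c in carry:
        out[c] = base.loc[wide.index, c].to_numpy()
    for occ in occasions:
        out[f"{value_stub}{occ}"] = wide[("value", occ)].to_numpy()
        out[f"{age_stub}{occ}"] = wide[("age", occ)].to_numpy()
    return out.reset_index(drop=True)


@dataclass
class GrowthModelEstimates:
    """Estimates from one multilevel quadratic growth fit.

    ``fixed`` has one row per fixed effect (estimate, se, Wald 95% CI,
    p); ``random`` one row per random-effect (co)variance. Random-effect
    SEs are delta-method approximations from the profiled likelihood
    (the residual variance is reported without an SE).
    """

    fixed: pd.DataFrame
    random: pd.DataFrame
    resid_var: float
    n: int
    n_obs: int
    center_age: float
    sex_interaction: bool
    converged: bool = True

    def __post_init__(self):
        if self.n_obs < self.n:
            raise ContractError("n_obs cannot be below the individual count")
        bad = self.random[self.random["param"].str.startswith("var")]
        if (bad["estimate"] < -1e-8).any():
            raise ContractError("negative variance estimate")

    def fixed_effect(self, term: str) -> dict:
        row = self.fixed.set_index("term").loc[term]
        return {k: float(row[k]) for k in ("estimate", "se", "ci_lo", "ci_hi", "p")}

    def predict_mean(self, ages, female: float = 0.0) -> np.ndarray:
        """Population-mean trajectory at the given ages (years)."""
        a = np.asarray(ages, float) - self.center_age
        fe = self.fixed.set_index("term")["estimate"]
        out = fe["Intercept"] + fe["age_c"] * a + fe["age_c2"] * a ** 2
        if self.sex_interaction:
            out = out + female * (fe["female"] + fe["female:age_c"] * a
                                  + fe["female:age_c2"] * a ** 2)
        return out


class GrowthFitError(RuntimeError):
    """The mixed model failed to converge after all retries."""


def fit_quadratic_growth(long: pd.DataFrame, id_col: str = "id",
                         center_age: float = 12.0,
                         sex_interaction: bool = False,
                         sex_col: str = "female") -> GrowthModelEstimates:
    """ML fit of the quadratic multilevel growth model.

    ``value ~ age_c + age_c2`` (plus female and its interactions when
    requested) with random intercept and random slopes for ``age_c``
    and ``age_c2``, unstructured covariance. Age is centred by
    subtracting ``center_age`` (years) so the intercept is the expected
    measurement at that age. Non-convergence triggers a retry from a
    diagonal-covariance start before reporting failure.
    """
    df = long[[id_col, "age", "value"] +
              ([sex_col] if sex_interaction else [])].dropna().copy()
    df["age_c"] = df["age"] - center_age
    # the quadratic term is rescaled internally so the random-effect
    # variances are of comparable magnitude (the likelihood surface is
    # badly conditioned otherwise); estimates are transformed back
    s = _AGE2_SCALE
    df["age_c2s"] = df["age_c"] ** 2 / s
    per_id = df.groupby(id_col)["age"].nunique()
    if per_id.max() < 3:
        raise ContractError("need at least 3 occasions for a quadratic model")
    if sex_interaction:
        df["female"] = pd.to_numeric(df[sex_col], errors="coerce")
        df = df.dropna(subset=["female"])
        formula = ("value ~ age_c + age_c2s + female + female:age_c "
                   "+ female:age_c2s")
    else:
        formula = "value ~ age_c + age_c2s"
    model = smf.mixedlm(formula, df, groups=df[id_col],
                        re_formula="~age_c + age_c2s")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
            # iterated warm restarts: a single quasi-Newton pass often
            # stalls short of the optimum on growth data; restarting from
            # the previous solution converges to the ML solution
            for _ in range(5):
                prev = res.llf
                nxt = model.fit(reml=False, method="lbfgs", maxiter=500,
                                start_params=res.params_object)
                if not np.isfinite(nxt.llf):
                    break
                res = nxt
                if abs(res.llf - prev) < 1e-4:
                    break
        except Exception:
            res = None
        if res is None or not np.all(np.isfinite(res.fe_params)):
            try:  # sturdier derivative-free fallback
                res = model.fit(reml=False, method="powell", maxiter=2000)
            except Exception:
                res = None
    if res is None or not np.all(np.isfinite(res.fe_params)):
        raise GrowthFitError("growth model failed to converge")

    def _unscale_term(term: str) -> float:
        return s if "age_c2s" in term else 1.0

    fixed_rows = []
    for t in res.fe_params.index:
        f = _unscale_term(t)
        est, se = float(res.fe_params[t]) / f, float(res.bse_fe[t]) / f
        if not np.isfinite(se):
            se = 0.0      # degenerate (noise-free) fit: point interval
        p = float(res.pvalues[t])
        if not np.isfinite(p):
            p = 0.0 if (se == 0 and est != 0) else 1.0
        fixed_rows.append({
            "term": t.replace("age_c2s", "age_c2"), "estimate": est, "se": se,
            "ci_lo": est - _Z95 * se, "ci_hi": est + _Z95 * se,
            "p": p,
        })
    fixed = pd.DataFrame(fixed_rows)

    cov_re = res.cov_re                       # data-scale RE covariance
    scale = float(res.scale)                  # residual variance
    re_names = list(cov_re.index)
    re_factor = {n: (1.0 / s if n == "age_c2s" else 1.0) for n in re_names}
    # SEs of the (co)variances come from the profiled-likelihood bse of
    # the packed covariance params (labelled "... Var"/"... Cov"),
    # rescaled by the residual variance — a delta-method approximation
    bse = res.bse
    label = {"Group": "Intercept", "Intercept": "Intercept",
             "age_c": "age", "age_c2s": "age2"}

    def _cov_bse(ni, nj):
        i_lab = "Group" if ni in ("Group", "Intercept") else ni
        j_lab = "Group" if nj in ("Group", "Intercept") else nj
        for key in (f"{i_lab} Var", f"{i_lab} x {j_lab} Cov",
                    f"{j_lab} x {i_lab} Cov"):
            if (ni == nj and key.endswith("Var") and key in bse.index) or \
               (ni != nj and key.endswith("Cov") and key in bse.index):
                return float(bse[key]) * scale
        return np.nan

    random_rows = []
    for i, ni in enumerate(re_names):
        for j in range(i + 1):
            nj = re_names[j]
            f = re_factor[ni] * re_factor[nj]
            est = float(cov_re.iloc[i, j]) * f
            se = _cov_bse(ni, nj) * f
            name = (f"var({label.get(ni, ni)})" if i == j
                    else f"cov({label.get(ni, ni)}, {label.get(nj, nj)})")
            est = max(est, 0.0) if i == j else est
            random_rows.append({
                "param": name, "estimate": est, "se": se,
                "ci_lo": est - _Z95 * se if np.isfinite(se) else np.nan,
                "ci_hi": est + _Z95 * se if np.isfinite(se) else np.nan,
            })
    random = pd.DataFrame(random_rows)

    return GrowthModelEstimates(
        fixed=fixed, random=random, resid_var=scale,
        n=int(df[id_col].nunique()), n_obs=int(len(df)),
        center_age=center_age, sex_interaction=sex_interaction,
        converged=bool(getattr(res, "converged", True)),
    )


def compare_growth_estimates(fit_obs: GrowthModelEstimates,
                             fit_syn: GrowthModelEstimates) -> pd.DataFrame:
    """Per-parameter fixed-effect comparison of two growth fits:
    difference, SE ratio and symmetrised CI overlap."""
    from .utility import ci_overlap
    a = fit_obs.fixed.set_index("term")
    b = fit_syn.fixed.set_index("term")
    if set(a.index) != set(b.index):
        raise ContractError("fits have different fixed-effect terms")
    rows = []
    for t in a.index:
        rows.append({
            "term": t,
            "est_obs": float(a.loc[t, "estimate"]),
            "est_syn": float(b.loc[t, "estimate"]),
            "difference": float(b.loc[t, "estimate"] - a.loc[t, "estimate"]),
            "se_ratio": (float(b.loc[t, "se"] / a.loc[t, "se"])
                         if a.loc[t, "se"] > 0 else np.nan),
            "ci_overlap": ci_overlap(
                (a.loc[t, "ci_lo"], a.loc[t, "ci_hi"]),
                (b.loc[t, "ci_lo"], b.loc[t, "ci_hi"])),
        })
    return pd.DataFrame(rows)


def refuse_long_synthesis(df: pd.DataFrame, id_col: str):
    """Synthesis of repeated measures must happen in wide format: in
    long format the within-individual structure is broken because rows
    of one individual are synthesised independently."""
    if df[id_col].duplicated().any():
        raise ContractError(
            "panel appears to be in long format (repeated ids); synthesise "
            "panels in wide format — one row per individual with one column "
            "per occasion — and reshape afterwards")


def plot_trajectories(fits: dict, ages=None, by_sex: bool = False):
    """Predicted mean height-for-age curves, one line per fit (and per
    sex when requested)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ages is None:
        ages = np.linspace(7, 18, 50)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, fit in fits.items():
        if by_sex and fit.sex_interaction:
            ax.plot(ages, fit.predict_mean(ages, female=0.0), label=f"{name} male")
            ax.plot(ages, fit.predict_mean(ages, female=1.0), "--",
                    label=f"{name} female")
        else:
            ax.plot(ages, fit.predict_mean(ages), label=name)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("predicted mean")
    ax.legend()
    fig.tight_layout()
    return fig
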