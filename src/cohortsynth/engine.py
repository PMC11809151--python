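"""Sequential conditional synthesis.

Each column is synthesised in visit order: the first by resampling its
observed marginal, later ones by a model of ``target ~ earlier
predictors`` fitted on the observed data and *sampled* at the already
synthesised predictor rows. The default model is CART donor-sampling:
a tree partitions the observed rows, each synthetic row is routed to a
leaf, and the synthetic value is drawn uniformly from the observed
values in that leaf (so, without smoothing, every synthetic value is an
observed value). Parametric alternatives (linear, logistic,
multinomial) are available per column.

Missing data are synthesised alongside values: categorical columns
treat the missing marker as an ordinary level, while continuous columns
are synthesised in two stages — a binary missingness indicator first,
then values modelled on the observed non-missing rows — so relations
between missingness and other variables are preserved.

Column models follow the scikit-learn estimator protocol
(``fit(X, y)`` then ``sample(X, rng)``); :class:`SequentialSynthesizer`
composes them and is itself an estimator with ``fit`` / ``sample``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .core import (
    CONTINUOUS,
    CartControls,
    ContractError,
    DataTable,
    SynthesisPlan,
    SyntheticRelease,
    VariableSchema,
    plan_errors,
    validate_plan,
)

_NA_LEVEL = "\x00NA"   # internal code for "missing" as a category level


# ---------------------------------------------------------------------------
# predictor encoding

class _PredictorEncoder:
    """Deterministic numeric encoding of a mixed predictor frame.

    Continuous columns become (mean-filled value, missing indicator);
    categorical columns become one indicator per observed level plus a
    missing indicator. The encoding is frozen at fit time so synthetic
    frames align column-for-column.
    """

    def fit(self, df: pd.DataFrame, schemas: dict) -> "_PredictorEncoder":
        self.schemas_ = {name: schemas[name] for name in df.columns}
        self.fill_ = {}
        self.levels_ = {}
        for name, s in self.schemas_.items():
            if s.kind == CONTINUOUS:
                v = pd.to_numeric(df[name], errors="coerce")
                self.fill_[name] = float(v.mean()) if v.notna().any() else 0.0
            else:
                self.levels_[name] = list(s.levels)
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, s in self.schemas_.items():
            col = df[name]
            if s.kind == CONTINUOUS:
                v = pd.to_numeric(col, errors="coerce")
                miss = v.isna().to_numpy(float)
                cols.append(v.fillna(self.fill_[name]).to_numpy(float))
                cols.append(miss)
            else:
                miss = col.isna()
                for lev in self.levels_[name]:
                    cols.append(((col == lev) & ~miss).to_numpy(float))
                cols.append(miss.to_numpy(float))
        if not cols:
            return np.zeros((len(df), 0))
        return np.column_stack(cols)


def _categorical_codes(values: pd.Series) -> pd.Series:
    """Missing marker mapped to an explicit level code."""
    return values.where(values.notna(), _NA_LEVEL).astype(str)


def _decode_categorical(values: np.ndarray) -> np.ndarray:
    out = values.astype(object)
    out[out == _NA_LEVEL] = np.nan
    return out


# ---------------------------------------------------------------------------
# column models

class MarginalSampler(BaseEstimator):
    """Method ``sample``: resample the observed marginal with replacement,
    uniform over rows, missing markers included."""

    def fit(self, X, y):
        y = pd.Series(y)
        if len(y) == 0:
            raise ContractError("observed column is empty")
        self.donors_ = y.to_numpy(object)
        return self

    def sample(self, X, rng: np.random.Generator) -> np.ndarray:
        m = len(X) if hasattr(X, "__len__") else int(X)
        if m <= 0:
            raise ContractError("requested sample size must be positive")
        idx = rng.integers(0, len(self.donors_), size=m)
        return self.donors_[idx]


class CartColumnSynthesizer(BaseEstimator):
    """CART donor-sampling model for one column.

    A decision tree (regression tree for continuous targets,
    classification tree otherwise) is fitted on the observed rows; each
    leaf keeps the list of observed target values falling in it.
    Synthetic predictor rows are routed down the tree and the returned
    value is drawn uniformly from the leaf's donors, so the conditional
    distribution of the synthetic column approximates the observed
    conditional distribution. Predictor values outside any trained
    split range simply follow the tree's comparison rule at each node
    (never an error).
    """

    def __init__(self, kind: str = CONTINUOUS,
                 controls: CartControls | None = None,
                 random_state: int = 0):
        self.kind = kind
        self.controls = controls
        self.random_state = random_state

    def _make_tree(self):
        c = self.controls or CartControls()
        kw = dict(min_samples_leaf=c.min_leaf, ccp_alpha=c.complexity,
                  max_depth=c.max_depth, random_state=self.random_state)
        if self.kind == CONTINUOUS:
            return DecisionTreeRegressor(criterion="squared_error", **kw)
        return DecisionTreeClassifier(criterion="gini", **kw)

    def fit(self, X: np.ndarray, y: pd.Series):
        y = pd.Series(y).reset_index(drop=True)
        self.two_stage_ = self.kind == CONTINUOUS and bool(y.isna().any())
        if self.two_stage_:
            ind = y.isna().to_numpy()
            self.missing_model_ = CartColumnSynthesizer(
                kind="binary", controls=self.controls,
                random_state=self.random_state).fit(
                    X, pd.Series(np.where(ind, "miss", "obs")))
            keep = ~ind
            X, y = X[keep], y[keep].reset_index(drop=True)
        if self.kind == CONTINUOUS:
            target = y.to_numpy(float)
            donors = y.to_numpy(object)
        else:
            coded = _categorical_codes(y)
            target = coded.to_numpy()
            donors = coded.to_numpy(object)
        self.tree_ = self._make_tree().fit(X, target)
        leaves = self.tree_.apply(X)
        self.donors_ = {}
        order = np.argsort(leaves, kind="stable")
        for leaf, grp in pd.Series(order).groupby(leaves[order]):
            self.donors_[int(leaf)] = donors[grp.to_numpy()]
        return self

    def sample(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.two_stage_:
            miss = self.missing_model_.sample(X, rng) == "miss"
        else:
            miss = np.zeros(len(X), dtype=bool)
        leaves = self.tree_.apply(X)
        out = np.empty(len(X), dtype=object)
        for i, leaf in enumerate(leaves):
            pool = self.donors_[int(leaf)]
            out[i] = pool[rng.integers(0, len(pool))]
        if self.kind != CONTINUOUS:
            out = _decode_categorical(out)
        out[miss] = np.nan
        return out

    def leaf_assignments(self, X: np.ndarray) -> np.ndarray:
        """Leaf id per row of the value tree (diagnostics / tests)."""
        return self.tree_.apply(X)


class NormColumnSynthesizer(BaseEstimator):
    """Method ``norm``: least-squares linear fit plus Gaussian residual
    noise; missing values handled by a two-stage CART indicator."""

    def __init__(self, controls: CartControls | None = None,
                 random_state: int = 0):
        self.controls = controls
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: pd.Series):
        y = pd.Series(y).reset_index(drop=True)
        self.two_stage_ = bool(y.isna().any())
        if self.two_stage_:
            ind = y.isna().to_numpy()
            self.missing_model_ = CartColumnSynthesizer(
                kind="binary", controls=self.controls,
                random_state=self.random_state).fit(
                    X, pd.Series(np.where(ind, "miss", "obs")))
            keep = ~ind
            X, y = X[keep], y[keep].reset_index(drop=True)
        yv = y.to_numpy(float)
        design = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        resid = yv - design @ beta
        dof = max(len(yv) - np.linalg.matrix_rank(design), 1)
        self.coef_ = beta
        self.resid_sd_ = float(np.sqrt(resid @ resid / dof))
        return self

    def sample(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.two_stage_:
            miss = self.missing_model_.sample(X, rng) == "miss"
        else:
            miss = np.zeros(len(X), dtype=bool)
        design = np.column_stack([np.ones(len(X)), X])
        mu = design @ self.coef_
        out = (mu + rng.standard_normal(len(X)) * self.resid_sd_).astype(object)
        out[miss] = np.nan
        return out


class CategoricalGLMSynthesizer(BaseEstimator):
    """Methods ``logit``/``polytomous``: multinomial logistic fit, values
    drawn from the per-row predicted class probabilities.

    The missing marker participates as an extra class when present. A
    degenerate fit (separation, singular design) falls back to CART
    donor-sampling for this column with a warning.
    """

    def __init__(self, controls: CartControls | None = None,
                 random_state: int = 0):
        self.controls = controls
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: pd.Series):
        y = pd.Series(y).reset_index(drop=True)
        coded = _categorical_codes(y).to_numpy()
        self.fallback_ = None
        classes = np.unique(coded)
        if len(classes) < 2:
            self.classes_ = classes
            self.model_ = None
            return self
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                model.fit(X, coded)
            if not np.all(np.isfinite(model.coef_)):
                raise FloatingPointError("non-finite coefficients")
            self.model_ = model
            self.classes_ = model.classes_
        except Exception as exc:  # separation / singular design
            warnings.warn(
                f"parametric categorical fit failed ({exc}); "
                "falling back to CART donor-sampling", RuntimeWarning)
            self.fallback_ = CartColumnSynthesizer(
                kind="nominal", controls=self.controls,
                random_state=self.random_state).fit(X, y)
        return self

    def sample(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.fallback_ is not None:
            return self.fallback_.sample(X, rng)
        if self.model_ is None:
            out = np.repeat(self.classes_[0], len(X)).astype(object)
            return _decode_categorical(out)
        proba = self.model_.predict_proba(X)
        cum = np.cumsum(proba, axis=1)
        u = rng.random(len(X))
        idx = (u[:, None] > cum).sum(axis=1)
        out = self.model_.classes_[idx].astype(object)
        return _decode_categorical(out)


# ---------------------------------------------------------------------------
# functional operations

def sample_marginal(observed_column, m: int, seed: int = 0) -> np.ndarray:
    """Resample a column's observed marginal (missing markers included),
    with replacement, uniform over rows."""
    model = MarginalSampler().fit(None, observed_column)
    return model.sample(m, np.random.default_rng(seed))


def _fit_encoder(predictors_obs: pd.DataFrame,
                 schemas: dict) -> _PredictorEncoder:
    return _PredictorEncoder().fit(predictors_obs, schemas)


def cart_synthesize_column(target, predictors_obs: pd.DataFrame,
                           predictors_syn: pd.DataFrame,
                           schemas: dict, kind: str = CONTINUOUS,
                           controls: CartControls | None = None,
                           seed: int = 0) -> np.ndarray:
    """Fit a CART model of ``target ~ predictors`` on the observed rows
    and donor-sample a synthetic column at the synthetic predictor rows."""
    target = pd.Series(target)
    if len(target) != len(predictors_obs):
        raise ContractError("target and predictors_obs have different lengths")
    if list(predictors_obs.columns) != list(predictors_syn.columns):
        raise ContractError("synthetic predictors do not match observed by name")
    enc = _fit_encoder(predictors_obs, schemas)
    model = CartColumnSynthesizer(kind=kind, controls=controls,
                                  random_state=seed % (2**31))
    model.fit(enc.transform(predictors_obs), target)
    return model.sample(enc.transform(predictors_syn),
                        np.random.default_rng(seed))


def parametric_synthesize_column(target, predictors_obs: pd.DataFrame,
                                 predictors_syn: pd.DataFrame,
                                 schemas: dict, family: str,
                                 controls: CartControls | None = None,
                                 seed: int = 0) -> np.ndarray:
    """Parametric alternative to CART: ``norm`` (linear + Gaussian
    noise), ``logit`` or ``polytomous`` (draws from predicted class
    probabilities)."""
    if family not in ("norm", "logit", "polytomous"):
        raise ContractError(f"unknown parametric family {family!r}")
    target = pd.Series(target)
    enc = _fit_encoder(predictors_obs, schemas)
    rs = seed % (2**31)
    if family == "norm":
        model = NormColumnSynthesizer(controls=controls, random_state=rs)
    else:
        model = CategoricalGLMSynthesizer(controls=controls, random_state=rs)
    model.fit(enc.transform(predictors_obs), target)
    return model.sample(enc.transform(predictors_syn),
                        np.random.default_rng(seed))


def normal_reference_bandwidth(values: np.ndarray) -> float:
    """Silverman's normal-reference rule:
    ``0.9 * min(sd, IQR/1.34) * n^(-1/5)`` on the non-missing values."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n < 2:
        return 0.0
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def apply_smoothing(column, bandwidth: float | None = None,
                    clip_range: tuple | None = None,
                    seed: int = 0,
                    exempt_mask: np.ndarray | None = None) -> np.ndarray:
    """Jitter a continuous synthetic column by Gaussian kernel noise.

    The bandwidth defaults to the normal-reference rule on the column's
    non-missing values; results are clipped to ``clip_range`` (default:
    the column's own non-missing min/max) so smoothing cannot extend
    the observed support. Missing markers, and cells in
    ``exempt_mask`` (rule-forced values), are untouched. A constant
    column is returned unchanged with a warning.
    """
    v = pd.to_numeric(pd.Series(column), errors="coerce").to_numpy(float)
    obs = v[~np.isnan(v)]
    if len(np.unique(obs)) < 2:
        warnings.warn("constant column: smoothing skipped", RuntimeWarning)
        return v.astype(object)
    if bandwidth is None:
        bandwidth = normal_reference_bandwidth(v)
    if clip_range is None:
        clip_range = (float(obs.min()), float(obs.max()))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, bandwidth, size=len(v)) if bandwidth > 0 else 0.0
    out = np.clip(v + noise, clip_range[0], clip_range[1])
    keep = np.isnan(v)
    if exempt_mask is not None:
        keep = keep | np.asarray(exempt_mask, bool)
    out = np.where(keep, v, out)
    return out.astype(object)


def apply_rules(table: DataTable, rules) -> DataTable:
    """Force rule targets to their stated values on rows where every
    predicate condition holds (missing never satisfies a condition)."""
    df = table.data.copy()
    for rule in rules:
        mask = rule.mask(df)
        sch = table.schema_for(rule.target)
        value = float(rule.value) if sch.kind == CONTINUOUS else str(rule.value)
        df.loc[mask, rule.target] = value
    return table.with_data(df)


# ---------------------------------------------------------------------------
# the sequential synthesizer

class SequentialSynthesizer(BaseEstimator):
    """Sequential conditional synthesizer for a whole table.

    Parameters
    ----------
    plan : SynthesisPlan or None
        Synthesis contract; ``None`` builds the default plan (visit
        order = column order, CART everywhere after the first column,
        all earlier columns as predictors) at ``fit`` time.
    seed : int or None
        Overrides ``plan.seed`` when given.

    Attributes
    ----------
    plan_ : SynthesisPlan
        The plan actually used.
    models_ : dict
        Fitted column model per variable.
    trace_ : list
        Per generated column, the tuple of predictor columns read —
        populated by :meth:`sample`, used to assert sequentiality.
    """

    def __init__(self, plan: SynthesisPlan | None = None,
                 seed: int | None = None):
        self.plan = plan
        self.seed = seed

    def _column_seed(self, j: int) -> np.random.Generator:
        return np.random.default_rng([self.seed_, j])

    def fit(self, table: DataTable, y=None):
        from .core import default_plan  # local import avoids cycle at module load
        if table.n < 1:
            raise ContractError("observed table is empty")
        plan = self.plan or default_plan(table)
        self.seed_ = int(self.seed if self.seed is not None else plan.seed)
        violations = validate_plan(plan, table.schema)
        errs = plan_errors(violations)
        if errs:
            raise ContractError(
                "invalid plan: " + "; ".join(str(v) for v in errs))
        self.plan_ = plan
        self.observed_ = table
        self.models_ = {}
        self.encoders_ = {}
        schemas = {s.name: s for s in table.schema}
        for j, name in enumerate(plan.visit_sequence):
            method = plan.method[name]
            preds = list(plan.predictors.get(name, ()))
            y_col = table.data[name]
            rs = (self.seed_ * 1000003 + j) % (2**31)
            try:
                if method == "sample" or not preds:
                    self.models_[name] = MarginalSampler().fit(None, y_col)
                    self.encoders_[name] = None
                    continue
                enc = _PredictorEncoder().fit(table.data[preds], schemas)
                X = enc.transform(table.data[preds])
                kind = schemas[name].kind
                if method == "cart":
                    model = CartColumnSynthesizer(
                        kind=kind, controls=plan.cart_controls, random_state=rs)
                elif method == "norm":
                    model = NormColumnSynthesizer(
                        controls=plan.cart_controls, random_state=rs)
                else:  # logit / polytomous
                    model = CategoricalGLMSynthesizer(
                        controls=plan.cart_controls, random_state=rs)
                model.fit(X, y_col)
                self.models_[name] = model
                self.encoders_[name] = enc
            except ContractError:
                raise
            except Exception as exc:
                raise ContractError(
                    f"column {name!r} (method {method!r}) failed to fit: {exc}"
                ) from exc
        return self

    def sample(self, m: int | None = None) -> SyntheticRelease:
        """Generate a synthetic release of ``m`` rows (default: the
        observed row count), apply rules then smoothing, and attach
        provenance. Deterministic given (observed, plan, seed)."""
        if not hasattr(self, "models_"):
            raise ContractError("synthesizer is not fitted")
        table, plan = self.observed_, self.plan_
        m = table.n if m is None else int(m)
        if m <= 0:
            raise ContractError("requested sample size must be positive")
        out = {}
        self.trace_ = []
        forced = {r.target: np.zeros(m, dtype=bool) for r in plan.rules}
        for j, name in enumerate(plan.visit_sequence):
            rng = self._column_seed(j)
            model = self.models_[name]
            enc = self.encoders_[name]
            preds = list(plan.predictors.get(name, ()))
            if enc is None:
                values = model.sample(m, rng)
                self.trace_.append((name, ()))
            else:
                for p in preds:
                    if p not in out:
                        raise ContractError(
                            f"sequentiality breach: {name!r} needs {p!r} "
                            "before it is synthesised")
                X_syn = enc.transform(pd.DataFrame(
                    {p: out[p] for p in preds}, columns=preds))
                values = model.sample(X_syn, rng)
                self.trace_.append((name, tuple(preds)))
            col = pd.Series(values, dtype=object)
            # rules fire as soon as their target exists so later columns
            # condition on rule-consistent values
            for r in plan.rules:
                if r.target == name:
                    df_so_far = pd.DataFrame({k: out[k] for k in out} | {name: col})
                    mask = r.mask(df_so_far).to_numpy()
                    sch = table.schema_for(name)
                    val = float(r.value) if sch.kind == CONTINUOUS else str(r.value)
                    col = col.mask(pd.Series(mask), val)
                    forced[name] |= mask
            out[name] = col
        df = pd.DataFrame({c: out[c] for c in table.columns},
                          columns=table.columns)
        for j, name in enumerate(plan.visit_sequence):
            if name in plan.smoothing:
                sch = table.schema_for(name)
                if sch.kind != CONTINUOUS:
                    warnings.warn(f"smoothing requested for non-continuous "
                                  f"column {name!r}; skipped", RuntimeWarning)
                    continue
                obs = table.data[name].to_numpy(float)
                obs = obs[~np.isnan(obs)]
                rng_seed = np.random.default_rng(
                    [self.seed_, len(plan.visit_sequence) + j])
                df[name] = apply_smoothing(
                    df[name], clip_range=(float(obs.min()), float(obs.max())),
                    seed=rng_seed.integers(2**31),
                    exempt_mask=forced.get(name))
        syn_table = DataTable(df, table.schema)
        provenance = {
            "seed": self.seed_,
            "plan_digest": plan.digest(),
            "n_observed": table.n,
            "n_before_sdc": syn_table.n,
            "n_removed": 0,
            "sdc_applied": False,
        }
        from .io import DISCLAIMER
        return SyntheticRelease(table=syn_table, provenance=provenance,
                                disclaimer=DISCLAIMER)

    # transform-style alias so the estimator composes with pipelines
    def transform(self, table: DataTable | None = None) -> pd.DataFrame:
        return self.sample().table.data


def synthesize(observed: DataTable, plan: SynthesisPlan | None = None,
               seed: int | None = None) -> SyntheticRelease:
    """One-call sequential synthesis (pre-disclosure-control)."""
    return SequentialSynthesizer(plan=plan, seed=seed).fit(observed).sample()
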