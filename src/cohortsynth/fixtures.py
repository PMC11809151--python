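"""Synthetic cohort fixtures with known ground truth.

Two generators emulate the structure of a birth-cohort release so the
whole pipeline is exercisable without any restricted data:

* :func:`simulate_cohort` — a 15-variable cross-sectional analysis
  dataset: a non-negative integer maternal depression score (EPDS-like,
  0–30) as the exposure, a binary offspring depression diagnosis as the
  outcome, sociodemographic confounders, auxiliary perinatal variables
  and MAR missingness.
* :func:`simulate_height_panel` — a wide-format height panel of up to 8
  occasions (ages ≈ 7–18) generated from a random intercept + random
  slope quadratic growth model with sex offsets.

All generating parameters are the implementer's own choices of
realistic magnitudes; they are returned in a truth record sufficient to
recompute every expectation asserted in the tests. Generation is fully
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BINARY,
    CONTINUOUS,
    ContractError,
    DataTable,
    NOMINAL,
    VariableSchema,
)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


# ---------------------------------------------------------------------------
# MAR missingness

@dataclass(frozen=True)
class MARMechanism:
    """Missing-at-random rule for one column.

    The probability a cell goes missing is
    ``expit(intercept + sum(terms))`` where each term is
    ``(var, level, coef)``: for categorical ``var`` the term contributes
    ``coef`` when the row equals ``level``; for continuous ``var``
    (``level is None``) it contributes ``coef * value``. Referencing the
    target column itself (MNAR) is rejected.
    """

    target: str
    intercept: float
    terms: tuple = ()

    def __post_init__(self):
        for var, _, _ in self.terms:
            if var == self.target:
                raise ContractError(
                    f"mechanism for {self.target!r} references its own value "
                    "(MNAR is not supported)")

    def probability(self, df: pd.DataFrame) -> np.ndarray:
        logit = np.full(len(df), self.intercept, float)
        for var, level, coef in self.terms:
            col = df[var]
            if level is None:
                logit += coef * pd.to_numeric(col, errors="coerce").fillna(0.0)
            else:
                logit += coef * ((col == level) & col.notna()).to_numpy(float)
        return _expit(logit)


def inject_missingness(table: DataTable, mechanisms, seed: int = 0) -> DataTable:
    """Apply MAR mechanisms to a complete table.

    All probabilities are computed from the pre-injection values, so
    one column's mechanism may reference another column that also has a
    mechanism without ordering effects.
    """
    df = table.data.copy()
    probs = {m.target: m.probability(df) for m in mechanisms}
    rng = np.random.default_rng(seed)
    for m in mechanisms:
        hit = rng.random(len(df)) < probs[m.target]
        df.loc[hit, m.target] = np.nan
    return table.with_data(df)


# ---------------------------------------------------------------------------
# cross-sectional cohort

EDUCATION_LEVELS = ("cse", "vocational", "o_level", "a_level", "degree")
SOCIAL_CLASS_LEVELS = ("i", "ii", "iii_nonmanual", "iii_manual", "iv_v")
HOUSING_LEVELS = ("owned", "rented", "other")
MARITAL_LEVELS = ("married", "cohabiting", "single")
ETHNIC_LEVELS = ("white", "non_white")
PARITY_LEVELS = ("0", "1", "2+")


@dataclass
class CohortSimConfig:
    """Generating model for the cross-sectional depression fixture.

    Probabilities are category distributions; coefficient dicts are on
    the logit scale. ``exposure_coefs``/``outcome_coefs`` use centred
    maternal age (per 5 years above 28) and level indicators.
    """

    n: int = 5000
    seed: int = 0
    matage_mean: float = 28.0
    matage_sd: float = 5.0
    p_female: float = 0.5
    p_education: tuple = (0.18, 0.10, 0.37, 0.20, 0.15)
    p_social_class: tuple = (0.06, 0.26, 0.24, 0.30, 0.14)
    p_housing: tuple = (0.72, 0.22, 0.06)
    p_marital: tuple = (0.72, 0.18, 0.10)
    p_ethnic: tuple = (0.95, 0.05)
    p_parity: tuple = (0.45, 0.35, 0.20)
    bwt_mean: float = 3.40
    bwt_sd: float = 0.55
    gest_mean: float = 39.4
    gest_sd: float = 1.9
    epds_max: int = 30
    # logit of the per-point EPDS binomial probability
    exposure_coefs: dict = field(default_factory=lambda: {
        "intercept": -1.6, "low_education": 0.30, "rented": 0.25,
        "non_white": 0.10, "matage_c5": -0.05,
    })
    # logit of P(offspring depression at 17)
    outcome_coefs: dict = field(default_factory=lambda: {
        "intercept": -2.9, "mat_dep": 0.08, "female": 0.55,
        "rented": 0.25, "low_education": 0.20, "non_white": 0.10,
        "matage_c5": -0.05,
    })
    # column -> MARMechanism; None = the default mechanisms, () = none
    missingness: tuple | None = None

    def __post_init__(self):
        for name in ("p_education", "p_social_class", "p_housing",
                     "p_marital", "p_ethnic", "p_parity"):
            p = np.asarray(getattr(self, name), float)
            if (p < 0).any() or (p > 1).any() or not np.isclose(p.sum(), 1.0):
                raise ContractError(f"{name} is not a probability distribution")
        if not 0.0 <= self.p_female <= 1.0:
            raise ContractError("p_female outside [0, 1]")

    def default_missingness(self) -> tuple:
        """MAR mechanisms referencing always-complete covariates
        (housing tenure and maternal age), ~5–12% per column."""
        def mech(target, intercept):
            return MARMechanism(target, intercept, (
                ("housing", "rented", 0.5),
                ("matage", None, -0.01),
            ))
        return (
            mech("bwt", -2.6), mech("gest", -2.6),
            mech("mated", -2.1), mech("pated", -1.8),
            mech("msoc", -1.9), mech("psoc", -1.7),
            mech("marital", -2.4), mech("parity", -2.4),
            mech("ethnic", -2.6),
            mech("mat_dep", -2.0), mech("depression_17", -1.9),
        )


COHORT_SCHEMA = (
    VariableSchema("gender", BINARY, ("male", "female")),
    VariableSchema("bwt", CONTINUOUS),
    VariableSchema("gest", CONTINUOUS),
    VariableSchema("ethnic", BINARY, ETHNIC_LEVELS),
    VariableSchema("matage", CONTINUOUS),
    VariableSchema("mated", NOMINAL, EDUCATION_LEVELS),
    VariableSchema("pated", NOMINAL, EDUCATION_LEVELS),
    VariableSchema("msoc", NOMINAL, SOCIAL_CLASS_LEVELS),
    VariableSchema("psoc", NOMINAL, SOCIAL_CLASS_LEVELS),
    VariableSchema("housing", NOMINAL, HOUSING_LEVELS),
    VariableSchema("marital", NOMINAL, MARITAL_LEVELS),
    VariableSchema("parity", NOMINAL, PARITY_LEVELS),
    VariableSchema("pregSize", CONTINUOUS),
    VariableSchema("mat_dep", CONTINUOUS),
    VariableSchema("depression_17", BINARY, ("no", "yes")),
)


def simulate_cohort(config: CohortSimConfig | None = None):
    """Generate the cross-sectional fixture; returns (table, truth).

    The truth record holds every generating parameter so tests can
    recompute implied prevalences and coefficients independently.
    """
    cfg = config or CohortSimConfig()
    if cfg.n < 1:
        raise ContractError("n must be at least 1")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    def cat(levels, probs):
        return rng.choice(levels, size=n, p=np.asarray(probs, float))

    gender = cat(("male", "female"), (1 - cfg.p_female, cfg.p_female))
    matage = np.clip(rng.normal(cfg.matage_mean, cfg.matage_sd, n), 16, 45)
    mated = cat(EDUCATION_LEVELS, cfg.p_education)
    pated = cat(EDUCATION_LEVELS, cfg.p_education)
    msoc = cat(SOCIAL_CLASS_LEVELS, cfg.p_social_class)
    psoc = cat(SOCIAL_CLASS_LEVELS, cfg.p_social_class)
    housing = cat(HOUSING_LEVELS, cfg.p_housing)
    marital = cat(MARITAL_LEVELS, cfg.p_marital)
    ethnic = cat(ETHNIC_LEVELS, cfg.p_ethnic)
    parity = cat(PARITY_LEVELS, cfg.p_parity)
    bwt = np.round(rng.normal(cfg.bwt_mean, cfg.bwt_sd, n), 3)
    gest = np.round(rng.normal(cfg.gest_mean, cfg.gest_sd, n), 1)
    preg_size = np.where(rng.random(n) < 0.985, 1.0, 2.0)

    low_ed = np.isin(mated, ("cse", "vocational")).astype(float)
    rented = (housing == "rented").astype(float)
    non_white = (ethnic == "non_white").astype(float)
    female = (gender == "female").astype(float)
    matage_c5 = (matage - 28.0) / 5.0

    e = cfg.exposure_coefs
    p_point = _expit(e["intercept"] + e["low_education"] * low_ed
                     + e["rented"] * rented + e["non_white"] * non_white
                     + e["matage_c5"] * matage_c5)
    mat_dep = rng.binomial(cfg.epds_max, p_point).astype(float)

    o = cfg.outcome_coefs
    p_dep = _expit(o["intercept"] + o["mat_dep"] * mat_dep
                   + o["female"] * female + o["rented"] * rented
                   + o["low_education"] * low_ed
                   + o["non_white"] * non_white
                   + o["matage_c5"] * matage_c5)
    depression = np.where(rng.random(n) < p_dep, "yes", "no")

    df = pd.DataFrame({
        "gender": gender, "bwt": bwt, "gest": gest, "ethnic": ethnic,
        "matage": matage, "mated": mated, "pated": pated, "msoc": msoc,
        "psoc": psoc, "housing": housing, "marital": marital,
        "parity": parity, "pregSize": preg_size, "mat_dep": mat_dep,
        "depression_17": depression,
    })
    table = DataTable(df, COHORT_SCHEMA)
    mechanisms = cfg.missingness
    if mechanisms is None:
        mechanisms = cfg.default_missingness()
    if mechanisms:
        table = inject_missingness(table, mechanisms,
                                   seed=np.random.default_rng(
                                       [cfg.seed, 9001]).integers(2**31))
    truth = asdict(cfg)
    truth["mechanisms"] = [
        {"target": m.target, "intercept": m.intercept,
         "terms": [list(t) for t in m.terms]} for m in (mechanisms or ())]
    return table, truth


# ---------------------------------------------------------------------------
# height panel

@dataclass
class PanelSimConfig:
    """Generating model for the wide height panel.

    Heights follow ``150 + 5.6·a − 0.15·a²`` (a = age − 12 years) for
    males, with female offsets on the intercept and both slopes, plus
    individual random effects drawn from ``re_cov`` (intercept, age,
    age² — cm² scale) and Gaussian residual noise. Occasion ages are
    jittered around the target schedule; occasion-wise missingness is
    applied to the height cells.
    """

    n: int = 2000
    seed: int = 0
    target_ages: tuple = (7.5, 9.0, 10.5, 11.5, 12.5, 13.5, 15.5, 17.5)
    age_jitter_sd: float = 0.25
    intercept: float = 150.0
    age: float = 5.6
    age2: float = -0.15
    female: float = -0.5
    female_age: float = -1.0
    female_age2: float = -0.25
    sex_effects: bool = True
    re_cov: tuple = ((45.0, 0.9, -0.5),
                     (0.9, 0.4, 0.05),
                     (-0.5, 0.05, 0.02))
    resid_sd: float = 2.5
    missing_rate: float = 0.10
    p_female: float = 0.5

    def __post_init__(self):
        if len(self.target_ages) < 3:
            raise ContractError("need at least 3 occasions")
        cov = np.asarray(self.re_cov, float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ContractError("re_cov must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ContractError("re_cov is not positive semi-definite")

    @property
    def occasions(self) -> int:
        return len(self.target_ages)

    def fixed_effects(self) -> dict:
        """Truth on the fitted model's parameterisation."""
        fx = {"Intercept": self.intercept, "age_c": self.age,
              "age_c2": self.age2}
        if self.sex_effects:
            fx.update({"female": self.female, "female:age_c": self.female_age,
                       "female:age_c2": self.female_age2})
        return fx


def simulate_height_panel(config: PanelSimConfig | None = None):
    """Generate the wide height panel; returns (table, truth).

    The table has one row per individual: ``female`` ("0"/"1"), then
    paired ``age{k}``/``ht{k}`` columns per occasion. Missing height
    cells carry the missing marker; their age columns stay observed
    (the measurement schedule is known even when the visit is missed).
    """
    cfg = config or PanelSimConfig()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n, cfg.occasions
    female = (rng.random(n) < cfg.p_female).astype(float)
    cov = np.asarray(cfg.re_cov, float)
    re = rng.multivariate_normal(np.zeros(3), cov, size=n,
                                 method="cholesky" if
                                 np.linalg.eigvalsh(cov).min() > 1e-12
                                 else "svd")
    ages = (np.asarray(cfg.target_ages)[None, :]
            + rng.normal(0.0, cfg.age_jitter_sd, (n, k)))
    a = ages - 12.0
    fem_main = cfg.female if cfg.sex_effects else 0.0
    fem_age = cfg.female_age if cfg.sex_effects else 0.0
    fem_age2 = cfg.female_age2 if cfg.sex_effects else 0.0
    mu = ((cfg.intercept + re[:, [0]] + fem_main * female[:, None])
          + (cfg.age + re[:, [1]] + fem_age * female[:, None]) * a
          + (cfg.age2 + re[:, [2]] + fem_age2 * female[:, None]) * a ** 2)
    ht = mu + rng.normal(0.0, cfg.resid_sd, (n, k))
    miss = rng.random((n, k)) < cfg.missing_rate
    ht = np.where(miss, np.nan, ht)

    cols = {"female": np.where(female > 0, "1", "0")}
    schema = [VariableSchema("female", BINARY, ("0", "1"))]
    for j in range(k):
        cols[f"age{j+1}"] = ages[:, j]
        schema.append(VariableSchema(f"age{j+1}", CONTINUOUS))
    for j in range(k):
        cols[f"ht{j+1}"] = ht[:, j]
        schema.append(VariableSchema(f"ht{j+1}", CONTINUOUS))
    table = DataTable(pd.DataFrame(cols), tuple(schema))
    truth = asdict(cfg)
    truth["fixed_effects"] = cfg.fixed_effects()
    return table, truth


def panel_value_columns(table: DataTable):
    """(height columns, age columns) of a wide panel fixture, in
    occasion order."""
    hts = sorted((c for c in table.columns if c.startswith("ht")),
                 key=lambda c: int(c[2:]))
    ages = sorted((c for c in table.columns if c.startswith("age")),
                  key=lambda c: int(c[3:]))
    return hts, ages


def panel_long(table: DataTable) -> pd.DataFrame:
    """Long view of a wide panel fixture with sequential ids."""
    from .longitudinal import wide_to_long
    hts, ages = panel_value_columns(table)
    wide = table.data.copy()
    wide.insert(0, "id", np.arange(len(wide)))
    return wide_to_long(wide, "id", hts, ages)
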