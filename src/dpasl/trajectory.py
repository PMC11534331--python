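"""Adaptive hinge-spline (MARS-style) lifespan trajectory regression.

Each regional feature is regressed on age with optional sex main effects and
sex-by-age-hinge interactions.  The forward pass greedily adds the reflected
hinge pair (or sex/linear term) that most reduces the residual sum of
squares; the backward pass prunes terms while the generalized
cross-validation (GCV) criterion improves; the surviving basis is refit by
ordinary least squares, from which per-segment slopes with 95% confidence
intervals are derived by linear contrasts.

Two distinct "cross-validation" quantities are reported and must not be
confused: GCV, the penalized lack-of-fit criterion used for pruning
(rss/n) / (1 - C/n)^2 with C = M + d (M - 1) / 2, and a genuine 10-fold
cross-validated R^2 (1 - PRESS/TSS) computed on mutually exclusive folds.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarsConfig",
    "BasisTerm",
    "HingeModel",
    "hinge",
    "gcv_score",
    "mars_fit",
    "refit_slopes",
    "regional_association",
]

log = logging.getLogger(__name__)


def hinge(x, knot: float, direction: int):
    """Hockey-stick basis function max(0, x - knot) (+1) or max(0, knot - x) (-1)."""
    x = np.asarray(x, dtype=float)
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    out = np.maximum(0.0, direction * (x - knot))
    return out if out.ndim else float(out)


def gcv_score(rss: float, n: int, n_terms: int, d: float = 3.0) -> float:
    """Generalized cross-validation: (rss/n) / (1 - C/n)^2, C = M + d(M-1)/2.

    ``n_terms`` counts basis functions including the intercept.
    """
    c = n_terms + d * (n_terms - 1) / 2.0
    if c >= n:
        raise ValueError(f"effective parameters C={c} >= n={n}")
    return (rss / n) / (1.0 - c / n) ** 2


@dataclasses.dataclass(frozen=True)
class BasisTerm:
    """One non-intercept basis function.

    ``var`` is ``"age"`` (linear), ``"sex"`` (indicator), or ``"hinge"``;
    hinge terms carry a knot and direction and may be multiplied by the sex
    indicator (``with_sex``).  ``"age"`` terms with ``with_sex`` are the
    linear age-by-sex product.
    """

    var: str
    knot: float | None = None
    direction: int = 0
    with_sex: bool = False

    def evaluate(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        if self.var == "age":
            col = np.asarray(age, dtype=float)
        elif self.var == "sex":
            col = np.asarray(sex, dtype=float)
        elif self.var == "hinge":
            col = hinge(age, self.knot, self.direction)
        else:  # pragma: no cover - guarded at construction
            raise ValueError(self.var)
        if self.with_sex and self.var != "sex":
            col = col * np.asarray(sex, dtype=float)
        return col

    def label(self) -> str:
        if self.var == "sex":
            return "sex"
        base = "age" if self.var == "age" else (
            f"h(age-{self.knot:g})" if self.direction > 0 else f"h({self.knot:g}-age)"
        )
        return f"sex*{base}" if self.with_sex else base


@dataclasses.dataclass
class MarsConfig:
    max_terms: int = 8
    gcv_penalty: float = 3.0
    min_knot_spacing: int = 5
    cv_folds: int = 10
    cv_seed: int = 0
    candidate_vars: tuple[str, ...] = ("age", "sex", "age_sex")
    race_covariate: bool = True

    def __post_init__(self) -> None:
        if self.max_terms < 2:
            raise ValueError("max_terms must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclasses.dataclass
class HingeModel:
    """Selected hinge basis with refit coefficients and summaries."""

    terms: list[BasisTerm]
    coefficients: np.ndarray  # refit OLS (intercept, terms..., extra covariates...)
    column_names: list[str]
    cov: np.ndarray
    df_resid: int
    gcv: float
    cv_r2: float
    age_range: tuple[float, float]
    segment_slopes: list[dict] = dataclasses.field(default_factory=list)
    n_obs: int = 0

    @property
    def knots(self) -> list[float]:
        return sorted({t.knot for t in self.terms if t.var == "hinge"})

    @property
    def has_sex_terms(self) -> bool:
        return any(t.var == "sex" or t.with_sex for t in self.terms)

    def slope_at(self, age: float, sex: str | None = None) -> dict:
        """Segment slope entry covering ``age`` (for the given sex if the
        model carries sex terms).  Reading the post-knee slope at the center
        of the oldest age group is robust to occasional spurious end knots."""
        want = sex if self.has_sex_terms else None
        for seg in self.segment_slopes:
            if seg["sex"] == want and seg["age_lo"] <= age <= seg["age_hi"]:
                return seg
        raise ValueError(f"age {age} outside the fitted range")

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {
                        "name": t.label(),
                        "var": t.var,
                        "knot": t.knot,
                        "direction": t.direction,
                        "with_sex": t.with_sex,
                        "coefficient": float(self.coefficients[i + 1]),
                    }
                    for i, t in enumerate(self.terms)
                ],
                "intercept": float(self.coefficients[0]),
                "gcv": self.gcv,
                "cv_r2": self.cv_r2,
                "knots": self.knots,
                "segment_slopes": self.segment_slopes,
                "n_obs": self.n_obs,
            },
            indent=2,
        )


def _sex_indicator(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "UO":
        return (s == "M").astype(float)  # F = 0, M = 1
    return s.astype(float)


def _candidate_knots(age: np.ndarray, spacing: int) -> np.ndarray:
    """Unique observed ages with >= spacing observations strictly each side."""
    uniq = np.unique(age)
    keep = []
    for k in uniq:
        if (age < k).sum() >= spacing and (age > k).sum() >= spacing:
            keep.append(k)
    return np.asarray(keep)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _race_dummies(cohort: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    race = cohort["race"].astype(str)
    levels = sorted(race.unique())
    ref = "White" if "White" in levels else levels[0]
    others = [r for r in levels if r != ref]
    cols = np.column_stack([(race == r).astype(float) for r in others]) if others else np.empty((len(race), 0))
    return cols, [f"race[{r}]" for r in others]


def mars_fit(
    cohort: pd.DataFrame,
    response: str,
    config: MarsConfig | None = None,
    age_col: str = "age",
    sex_col: str = "sex",
) -> HingeModel:
    """Fit the adaptive hinge-spline model of ``response`` against age (+sex).

    Deterministic given ``config.cv_seed``.  Requires at least 20 complete
    rows.  Race (when present and ``config.race_covariate``) enters the final
    OLS refit as additive dummies but is never a split candidate.
    """
    config = config or MarsConfig()
    cols = [age_col, response] + ([sex_col] if sex_col in cohort.columns else [])
    data = cohort.dropna(subset=cols)
    if len(data) < 20:
        raise ValueError("need at least 20 complete rows")
    age = np.asarray(data[age_col], dtype=float)
    sex = (
        _sex_indicator(data[sex_col])
        if sex_col in data.columns
        else np.zeros(len(data))
    )
    y = np.asarray(data[response], dtype=float)
    n = len(y)
    sex_varies = len(np.unique(sex)) > 1
    knots = _candidate_knots(age, config.min_knot_spacing)

    def design(terms: list[BasisTerm]) -> np.ndarray:
        cols = [np.ones(n)] + [t.evaluate(age, sex) for t in terms]
        return np.column_stack(cols)

    # ---- forward pass -----------------------------------------------------
    terms: list[BasisTerm] = []
    rss_cur, _ = _rss(design(terms), y)
    tss = float(((y - y.mean()) ** 2).sum())
    while len(terms) < config.max_terms:
        candidates: list[list[BasisTerm]] = []
        have = set(terms)
        if "age" in config.candidate_vars and BasisTerm("age") not in have:
            candidates.append([BasisTerm("age")])
        if sex_varies and "sex" in config.candidate_vars and BasisTerm("sex") not in have:
            candidates.append([BasisTerm("sex")])
        if (
            sex_varies
            and "age_sex" in config.candidate_vars
            and BasisTerm("age", with_sex=True) not in have
        ):
            candidates.append([BasisTerm("age", with_sex=True)])
        for k in knots:
            pair = [BasisTerm("hinge", k, +1), BasisTerm("hinge", k, -1)]
            if not any(t in have for t in pair):
                candidates.append(pair)
            if sex_varies and "age_sex" in config.candidate_vars:
                spair = [
                    BasisTerm("hinge", k, +1, with_sex=True),
                    BasisTerm("hinge", k, -1, with_sex=True),
                ]
                if not any(t in have for t in spair):
                    candidates.append(spair)
        best = None
        for cand in candidates:
            trial = terms + cand
            x = design(trial)
            rss_t, rank = _rss(x, y)
            if rank < x.shape[1]:
                continue
            if best is None or rss_t < best[0] - 1e-12:
                best = (rss_t, cand)
        if best is None:
            break
        rss_best, cand = best
        if rss_cur - rss_best <= 1e-10 * max(tss, 1e-300):
            break
        terms = terms + cand
        rss_cur = rss_best

    # ---- backward pass ----------------------------------------------------
    def model_gcv(t: list[BasisTerm]) -> float:
        rss_v, _ = _rss(design(t), y)
        return gcv_score(rss_v, n, len(t) + 1, config.gcv_penalty)

    gcv_cur = model_gcv(terms)
    while terms:
        best = None
        for i in range(len(terms)):
            trial = terms[:i] + terms[i + 1 :]
            g = model_gcv(trial)
            if best is None or g < best[0]:
                best = (g, trial)
        if best is not None and best[0] <= gcv_cur + 1e-12:
            gcv_cur, terms = best[0], best[1]
        else:
            break

    # ---- final OLS refit (optionally with race dummies) -------------------
    x = design(terms)
    names = ["intercept"] + [t.label() for t in terms]
    if config.race_covariate and "race" in data.columns:
        race_x, race_names = _race_dummies(data)
        if race_x.shape[1]:
            x = np.column_stack([x, race_x])
            names += race_names
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        log.warning("rank-deficient refit basis; dropping race covariates")
        x = design(terms)
        names = ["intercept"] + [t.label() for t in terms]
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df_resid = n - x.shape[1]
    s2 = float(resid @ resid) / df_resid if df_resid > 0 else 0.0
    xtx_inv = np.linalg.pinv(x.T @ x)
    cov = s2 * xtx_inv

    # ---- 10-fold CV R^2 ---------------------------------------------------
    rng = np.random.default_rng(config.cv_seed)
    order = rng.permutation(n)
    folds = np.array_split(order, config.cv_folds)
    press = 0.0
    for fold in folds:
        if len(fold) == 0:
            continue
        train = np.setdiff1d(order, fold)
        bt, _, _, _ = np.linalg.lstsq(x[train], y[train], rcond=None)
        press += float(((y[fold] - x[fold] @ bt) ** 2).sum())
    cv_r2 = 1.0 - press / tss if tss > 0 else float("nan")

    model = HingeModel(
        terms=terms,
        coefficients=beta,
        column_names=names,
        cov=cov,
        df_resid=df_resid,
        gcv=gcv_cur,
        cv_r2=cv_r2,
        age_range=(float(age.min()), float(age.max())),
        n_obs=n,
    )
    model.segment_slopes = refit_slopes(model)
    return model


def _slope_contrast(model: HingeModel, age_mid: float, sex_val: float) -> np.ndarray:
    """Derivative of the fitted mean with respect to age within a segment."""
    c = np.zeros(len(model.coefficients))
    for i, t in enumerate(model.terms):
        j = i + 1
        if t.var == "age":
            c[j] = sex_val if t.with_sex else 1.0
        elif t.var == "hinge":
            if t.direction > 0 and age_mid > t.knot:
                c[j] = sex_val if t.with_sex else 1.0
            elif t.direction < 0 and age_mid < t.knot:
                c[j] = -(sex_val if t.with_sex else 1.0)
    return c


def refit_slopes(model: HingeModel, conf: float = 0.95) -> list[dict]:
    """Per-segment (and per-sex, if interactions present) slopes with CIs.

    The slope in each inter-knot segment is the appropriate signed sum of
    active hinge coefficients; its variance follows from the refit OLS
    covariance via the linear contrast c' Cov c.
    """
    lo_age, hi_age = model.age_range
    bounds = [lo_age] + [k for k in model.knots if lo_age < k < hi_age] + [hi_age]
    tcrit = (
        stats.t.ppf(0.5 + conf / 2.0, model.df_resid) if model.df_resid > 0 else 0.0
    )
    sexes = [("F", 0.0), ("M", 1.0)] if model.has_sex_terms else [(None, 0.0)]
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        for label, val in sexes:
            c = _slope_contrast(model, mid, val)
            slope = float(c @ model.coefficients)
            se = float(np.sqrt(max(c @ model.cov @ c, 0.0)))
            entry = {
                "age_lo": lo,
                "age_hi": hi,
                "sex": label,
                "slope": slope,
                "ci_lo": slope - tcrit * se,
                "ci_hi": slope + tcrit * se,
            }
            out.append(entry)
    return out


def regional_association(
    cohort: pd.DataFrame,
    y: str,
    x: str,
    covariates=("sex",),
    strata=((8, 61), (62, 92)),
) -> pd.DataFrame:
    """Linear regression of a regional feature on another within age strata.

    For each stratum [lo, hi] an OLS of ``y`` on ``x`` plus covariates (sex
    by default) is fit and the two-sided t-test on the ``x`` coefficient
    reported.  A rank-deficient design (e.g. x collinear with sex) raises.
    """
    import statsmodels.api as sm

    rows = []
    for lo, hi in strata:
        sub = cohort[(cohort["age"] >= lo) & (cohort["age"] <= hi)].dropna(
            subset=[y, x]
        )
        design = {x: np.asarray(sub[x], dtype=float)}
        for cov_name in covariates:
            col = sub[cov_name]
            design[cov_name] = (
                _sex_indicator(col) if cov_name == "sex" else np.asarray(col, float)
            )
        xmat = sm.add_constant(pd.DataFrame(design), has_constant="add")
        if np.linalg.matrix_rank(np.asarray(xmat)) < xmat.shape[1]:
            raise ValueError(f"collinear design in stratum {lo}-{hi}")
        fit = sm.OLS(np.asarray(sub[y], dtype=float), np.asarray(xmat)).fit()
        ci = fit.conf_int()[1]  # x is the first column after the constant
        rows.append(
            {
                "stratum": f"{lo}-{hi}",
                "n": int(fit.nobs),
                "coef": fit.params[1],
                "se": fit.bse[1],
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "t": fit.tvalues[1],
                "p": fit.pvalues[1],
            }
        )
    return pd.DataFrame(rows)
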