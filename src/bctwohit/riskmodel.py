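"""Logistic risk calculators for carrier and two-hit status, with validation.

The package ships the two published calculators (carrier risk and two-hit
risk) as :class:`RiskModelSpec` objects with fixed intercept and named
coefficients; ``score = intercept + sum(coef_i * x_i)`` on the documented
covariate coding (age in years, grade 1-3, T 0-4, N 0-3, binaries 0/1,
Ki67 in percent) and ``P = 1 / (1 + exp(-score))``.

Refitting follows the statsmodels idiom: :class:`LogisticRiskModel` is
constructed from a clinical table, ``fit()`` returns a
:class:`RiskModelResults` carrying estimates, standard errors, confidence
intervals, a ``summary()`` table, and ``validate()`` for the held-out set
(ROC/AUC, Hosmer-Lemeshow calibration, sensitivity = specificity threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskModelSpec",
    "LogisticRiskModel",
    "RiskModelResults",
    "ValidationReport",
    "bcdg_model",
    "two_hit_model",
    "linear_predictor",
    "split_train_validation",
    "impute_chained",
    "ImputationResult",
    "pool_rubin",
    "roc_auc",
    "hosmer_lemeshow",
    "choose_threshold",
]


@dataclass(frozen=True)
class RiskModelSpec:
    """Intercept + named coefficients of a logistic linear predictor."""

    name: str
    intercept: float
    coefficients: dict
    coding: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.coefficients) - set(self.coding or self.coefficients)
        if self.coding and missing:
            raise ValueError(f"coding manifest does not cover {sorted(missing)}")

    @classmethod
    def from_json(cls, path_or_file) -> "RiskModelSpec":
        if hasattr(path_or_file, "read"):
            obj = json.load(path_or_file)
        else:
            with open(path_or_file) as fh:
                obj = json.load(fh)
        return cls(name=obj.get("name", "model"), intercept=float(obj["intercept"]),
                   coefficients={k: float(v) for k, v in obj["coefficients"].items()},
                   coding=obj.get("coding", {}))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "intercept": self.intercept,
                       "coefficients": self.coefficients, "coding": self.coding},
                      fh, indent=2)
            fh.write("\n")

    @property
    def covariates(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, data) -> np.ndarray:
        """Risk score(s) for one patient row or a table of patients."""
        if isinstance(data, pd.Series):
            data = data.to_frame().T
        unknown = [c for c in self.coefficients if c not in data.columns]
        if unknown:
            raise KeyError(f"missing covariate(s) {unknown} in input")
        x = data[self.covariates].astype(float).to_numpy()
        if np.isnan(x).any():
            raise ValueError("missing covariate values; impute before scoring")
        beta = np.array([self.coefficients[c] for c in self.covariates])
        return self.intercept + x @ beta

    def predict_proba(self, data) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(data)))


def _load_packaged(name: str) -> RiskModelSpec:
    ref = resources.files("bctwohit").joinpath(f"data/{name}.json")
    with ref.open() as fh:
        return RiskModelSpec.from_json(fh)


def bcdg_model() -> RiskModelSpec:
    """The published carrier-risk calculator (thirteen clinical covariates)."""
    return _load_packaged("bcdg_model")


def two_hit_model() -> RiskModelSpec:
    """The published two-hit-inactivation risk calculator."""
    return _load_packaged("two_hit_model")


def linear_predictor(model: RiskModelSpec, patient) -> tuple[np.ndarray, np.ndarray]:
    """(score, probability) of a patient record under a risk model spec."""
    score = model.linear_predictor(patient)
    return score, 1.0 / (1.0 + np.exp(-score))


# ---------------------------------------------------------------------------
# model fitting


class LogisticRiskModel:
    """Maximum-likelihood logistic model over named clinical covariates.

    Parameters
    ----------
    endog : array-like of 0/1 outcomes
    exog : DataFrame of covariates (no constant column; one is added)
    """

    def __init__(self, endog, exog: pd.DataFrame):
        self.endog = np.asarray(endog, dtype=float)
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("outcome is constant; need both classes to fit")
        self.exog = exog.astype(float)
        if self.exog.isna().any().any():
            raise ValueError("covariates contain missing values; impute first")
        self.covariate_names = list(exog.columns)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       covariates: list[str] | None = None) -> "LogisticRiskModel":
        if covariates is None:
            covariates = [c for c in data.columns
                          if c not in (outcome, "patient_id", "subtype")]
        return cls(data[outcome], data[covariates])

    def fit(self, ridge_on_failure: bool = True) -> "RiskModelResults":
        """Fit by Newton MLE; falls back to a small L2 penalty on separation."""
        import warnings

        X = sm.add_constant(self.exog, has_constant="add")
        penalized = False
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(self.endog, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged and ridge_on_failure:
                raise RuntimeError("no convergence")
        except Exception:
            if not ridge_on_failure:
                raise
            res = sm.GLM(self.endog, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0)
            penalized = True
            converged = True
        return RiskModelResults(self, res, converged=converged, penalized=penalized)


class RiskModelResults:
    """Fitted logistic risk model: estimates, uncertainty, validation."""

    def __init__(self, model: LogisticRiskModel, smres, converged: bool, penalized: bool):
        self.model = model
        self._res = smres
        self.converged = converged
        self.penalized = penalized
        params = pd.Series(np.asarray(smres.params).ravel(),
                           index=["const"] + model.covariate_names)
        self.params = params

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.bse).ravel(), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.asarray(self._res.conf_int(alpha))
        return pd.DataFrame(ci, index=self.params.index, columns=["lo", "hi"])

    @property
    def spec(self) -> RiskModelSpec:
        """The fitted coefficients as a reusable risk-model spec."""
        coefs = {c: float(self.params[c]) for c in self.model.covariate_names}
        return RiskModelSpec("refit", float(self.params["const"]), coefs,
                             coding={c: "as fitted" for c in coefs})

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted probabilities for new patients."""
        return self.spec.predict_proba(data)

    def validate(self, data: pd.DataFrame, labels, groups: int = 10) -> "ValidationReport":
        """Discrimination and calibration on a (held-out) set."""
        scores = self.spec.linear_predictor(data)
        probs = 1.0 / (1.0 + np.exp(-scores))
        labels = np.asarray(labels, dtype=float)
        auc, ci = roc_auc(scores, labels)
        chi2, hl_p = hosmer_lemeshow(probs, labels, groups=groups)
        thr, sens, spec_ = choose_threshold(scores, labels)
        return ValidationReport(auc=auc, auc_ci=ci, hl_chi2=chi2, hl_p=hl_p,
                                threshold=thr, sensitivity=sens, specificity=spec_)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [f"Logistic risk model ({'penalized' if self.penalized else 'MLE'}, "
                 f"n={len(self.model.endog)}, events={int(self.model.endog.sum())})",
                 f"{'covariate':<22}{'coef':>10}{'se':>10}{'95% CI':>24}"]
        for name in self.params.index:
            lines.append(f"{name:<22}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}"
                         f"{'[%.3f, %.3f]' % (ci.loc[name, 'lo'], ci.loc[name, 'hi']):>24}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ValidationReport:
    """Discrimination/calibration report of a risk model on one dataset."""

    auc: float
    auc_ci: tuple
    hl_chi2: float
    hl_p: float
    threshold: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {"auc": self.auc, "auc_ci_lo": self.auc_ci[0], "auc_ci_hi": self.auc_ci[1],
                "hl_chi2": self.hl_chi2, "hl_p": self.hl_p, "threshold": self.threshold,
                "sensitivity": self.sensitivity, "specificity": self.specificity}


# ---------------------------------------------------------------------------
# train/validation machinery


def split_train_validation(data: pd.DataFrame, fraction: float = 0.7,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint-and-exhaustive split; train gets floor(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(data)
    if n < 10:
        raise ValueError(f"cohort too small to split (n={n} < 10)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(np.floor(fraction * n))
    return (data.iloc[np.sort(perm[:k])].copy(),
            data.iloc[np.sort(perm[k:])].copy())


@dataclass(frozen=True)
class ImputationResult:
    """Completed dataset(s) plus the mask of originally missing cells."""

    data: pd.DataFrame  # first (or only) completed dataset
    mask: pd.DataFrame  # True where the cell was imputed
    datasets: tuple = ()  # all m completed datasets when m > 1


def impute_chained(data: pd.DataFrame, n_iterations: int = 10, seed: int = 0,
                   m: int = 1, columns: list[str] | None = None) -> ImputationResult:
    """Chained-equation imputation of the clinical covariates.

    Each missing column is initialized at its median (continuous) or mode
    (few-level discrete) and then repeatedly re-imputed by least-squares
    regression on the other covariates, cycling ``n_iterations`` times;
    discrete columns are rounded and clipped back onto their observed
    domain.  The default ``m = 1`` is a deterministic single completion;
    with ``m > 1``, each completed dataset adds residual-scale Gaussian
    noise to the regression draws (for Rubin pooling across datasets).
    """
    if columns is None:
        columns = [c for c in data.columns
                   if c not in ("patient_id", "subtype") and
                   pd.api.types.is_numeric_dtype(data[c])]
    sub = data[columns].astype(float)
    mask = sub.isna()
    if not mask.any().any():
        return ImputationResult(data.copy(), mask, (data.copy(),))
    for col in columns:
        if mask[col].all():
            raise ValueError(f"column {col!r} is fully missing; cannot impute")

    discrete = {c: np.sort(sub[c].dropna().unique())
                for c in columns if sub[c].dropna().nunique() <= 10}
    rng = np.random.default_rng(seed)
    completed_sets = []
    for _ in range(max(m, 1)):
        work = sub.copy()
        for col in columns:  # initialization
            if col in discrete:
                fill = sub[col].mode().iloc[0]
            else:
                fill = sub[col].median()
            work[col] = work[col].fillna(fill)
        for _ in range(n_iterations):
            for col in columns:
                miss = mask[col]
                if not miss.any():
                    continue
                others = [c for c in columns if c != col]
                X = np.column_stack([np.ones(len(work)), work[others].to_numpy()])
                y = work[col].to_numpy()
                beta, *_ = np.linalg.lstsq(X[~miss], y[~miss], rcond=None)
                pred = X[miss] @ beta
                if m > 1:
                    resid = y[~miss] - X[~miss] @ beta
                    scale = resid.std(ddof=min(len(beta), max(len(resid) - 1, 0)))
                    pred = pred + rng.normal(0.0, scale, size=len(pred))
                if col in discrete:
                    dom = discrete[col]
                    pred = dom[np.argmin(np.abs(pred[:, None] - dom[None, :]), axis=1)]
                else:
                    pred = np.clip(pred, sub[col].min(), sub[col].max())
                work.loc[miss, col] = pred
        out = data.copy()
        out[columns] = work
        completed_sets.append(out)
    return ImputationResult(completed_sets[0], mask, tuple(completed_sets))


def pool_rubin(results: list[RiskModelResults]) -> pd.DataFrame:
    """Rubin's rules across models fitted on multiply-imputed datasets."""
    if not results:
        raise ValueError("nothing to pool")
    params = pd.concat([r.params for r in results], axis=1)
    variances = pd.concat([r.bse ** 2 for r in results], axis=1)
    m = params.shape[1]
    qbar = params.mean(axis=1)
    ubar = variances.mean(axis=1)
    b = params.var(axis=1, ddof=1) if m > 1 else 0.0 * qbar
    total = ubar + (1 + 1 / m) * b
    return pd.DataFrame({"coef": qbar, "se": np.sqrt(total)})


# ---------------------------------------------------------------------------
# discrimination / calibration metrics


def roc_auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUC via the tie-corrected rank statistic, with Hanley-McNeil 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2) + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    half = 1.96 * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def hosmer_lemeshow(probs, labels, groups: int = 10) -> tuple[float, float]:
    """Decile-of-risk goodness-of-fit chi-square with df = groups - 2.

    Patients are split into ``groups`` equal-count bins of predicted
    probability; the statistic sums (O - E)^2 / (n_g * pbar_g * (1 - pbar_g))
    over bins.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.unique(probs).size == 1:
        raise ValueError("all predicted probabilities identical; degenerate grouping")
    order = np.argsort(probs, kind="mergesort")
    bins = np.array_split(order, groups)
    bins = [b for b in bins if len(b)]
    if len(bins) < 3:
        raise ValueError("fewer than 3 nonempty groups")
    chi2 = 0.0
    for b in bins:
        n_g = len(b)
        obs = labels[b].sum()
        pbar = np.clip(probs[b].mean(), 1e-10, 1 - 1e-10)
        chi2 += (obs - n_g * pbar) ** 2 / (n_g * pbar * (1 - pbar))
    df = len(bins) - 2
    return float(chi2), float(stats.chi2.sf(chi2, df))


def choose_threshold(scores, labels) -> tuple[float, float, float]:
    """Score cut where sensitivity and specificity curves intersect.

    Candidates are midpoints between adjacent sorted unique scores
    (positive call at score >= threshold); the candidate minimizing
    |sensitivity - specificity| wins, ties broken toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = uniq
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2
    best = None
    for t in cands:
        pos = scores >= t
        sens = (pos & (labels == 1)).sum() / n1
        spec = (~pos & (labels == 0)).sum() / n0
        key = (abs(sens - spec), -sens)
        if best is None or key < best[0]:
            best = (key, float(t), float(sens), float(spec))
    return best[1], best[2], best[3]
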