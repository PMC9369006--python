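"""Demographic comparisons and stepwise brain-behavior regression.

Two-sample t-tests come in pooled and Welch variants and accept either raw
samples or the (n, mean, sd) summaries printed in cohort tables, reducing to
identical formulas. The 2x2 chi-square is the plain Pearson statistic
without continuity correction. Stepwise multiple regression follows the
classic forward-entry (p <= 0.05) / backward-removal (p >= 0.10) iteration,
reporting standardized betas, adjusted R^2 and the model F — the layout of a
per-outcome brain-behavior association table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TwoSampleResult",
    "two_sample_t",
    "two_sample_t_from_samples",
    "chi_square_2x2",
    "StepwiseOLS",
    "StepwiseModel",
    "stepwise_regression",
    "group_comparison_table",
    "association_table",
]


@dataclass(frozen=True)
class TwoSampleResult:
    t: float
    df: float
    p: float
    variant: str


def two_sample_t(n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float,
                 variant: str = "pooled") -> TwoSampleResult:
    """Two-sample t-test from group summaries.

    pooled: t = (m1-m2) / (s_p sqrt(1/n1 + 1/n2)), df = n1+n2-2, with s_p^2
    the df-weighted average variance. welch: t = (m1-m2)/sqrt(s1^2/n1 +
    s2^2/n2) with Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be nonnegative and not both zero")
    diff = mean1 - mean2
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TwoSampleResult(t=float(t), df=float(df), p=p, variant=variant)


def two_sample_t_from_samples(x1: np.ndarray, x2: np.ndarray, variant: str = "pooled") -> TwoSampleResult:
    """Same test from raw samples (ddof=1 summaries)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return two_sample_t(
        len(x1), float(x1.mean()), float(x1.std(ddof=1)),
        len(x2), float(x2.mean()), float(x2.std(ddof=1)),
        variant=variant,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Cells are [[a, b], [c, d]]; returns (chi2, df=1, p). Zero marginals
    raise.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("cell counts must be nonnegative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal in the 2x2 table")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


def _variance_gate(x1: np.ndarray, x2: np.ndarray, alpha: float = 0.05) -> str:
    """Pooled unless a two-sided variance-ratio F test rejects equality."""
    v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    if v1 <= 0 or v2 <= 0:
        return "pooled"
    f = v1 / v2
    d1, d2 = len(x1) - 1, len(x2) - 1
    p = 2.0 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2))
    return "welch" if p < alpha else "pooled"


def group_comparison_table(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Patient-vs-control comparison per column, with a per-row variance gate
    choosing pooled vs Welch. Returns one row per variable."""
    pat = table[table["group_code"] == 1]
    con = table[table["group_code"] == 0]
    rows = []
    for col in columns:
        x1 = pat[col].dropna().to_numpy(float)
        x2 = con[col].dropna().to_numpy(float)
        variant = _variance_gate(x1, x2)
        res = two_sample_t_from_samples(x1, x2, variant=variant)
        rows.append(
            dict(variable=col, patient_mean=x1.mean(), patient_sd=x1.std(ddof=1),
                 control_mean=x2.mean(), control_sd=x2.std(ddof=1),
                 t=res.t, df=res.df, p=res.p, variant=variant)
        )
    return pd.DataFrame(rows)


@dataclass
class StepwiseModel:
    selected: list[str]
    coef: dict[str, float]
    std_coef: dict[str, float]
    coef_p: dict[str, float]
    intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    model_p: float

    @property
    def is_empty(self) -> bool:
        return not self.selected


class StepwiseOLS(BaseEstimator, RegressorMixin):
    """Forward-entry / backward-removal stepwise linear regression.

    At each step the candidate with the smallest partial p enters if that p
    is at most ``entry_p``; then any retained predictor whose p has risen to
    at least ``removal_p`` leaves (largest first). Iteration stops when no
    move is possible; a cycle guard returns the last stable model. An empty
    model is a legitimate outcome.

    Attributes (after ``fit``): ``selected_``, ``coef_``, ``std_coef_``,
    ``intercept_``, ``adj_r2_``, ``f_``, ``model_p_``, ``model_``.
    """

    def __init__(self, entry_p: float = 0.05, removal_p: float = 0.10, max_steps: int = 200):
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.max_steps = max_steps

    @staticmethod
    def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Returns (beta, two-sided p per column excluding intercept, rss)."""
        n, p = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df = n - p
        if df <= 0:
            return beta, np.ones(p - 1), rss
        sigma2 = rss / df
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        return beta, np.nan_to_num(pvals[1:], nan=1.0), rss

    def fit(self, X: pd.DataFrame | np.ndarray, y: np.ndarray) -> "StepwiseOLS":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            names = [f"x{i + 1}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        n, k = X.shape
        if n <= k + 2:
            raise ValueError(f"need n > n_candidates + 2 (n={n}, candidates={k})")
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [names[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant candidate predictors: {bad}")

        selected: list[int] = []
        seen_states: set[tuple[int, ...]] = set()
        ones = np.ones((n, 1))
        tss = float(((y - y.mean()) ** 2).sum())
        for _ in range(self.max_steps):
            changed = False
            if selected:
                _, _, rss_cur = self._ols(y, np.hstack([ones, X[:, selected]]))
                if rss_cur <= 1e-10 * max(tss, 1.0):
                    break  # perfect fit: further partial tests are numerical noise
            # forward entry
            remaining = [j for j in range(k) if j not in selected]
            best_j, best_p = None, np.inf
            for j in remaining:
                Xc = np.hstack([ones, X[:, selected + [j]]])
                _, pvals, _ = self._ols(y, Xc)
                if pvals[-1] < best_p:
                    best_p, best_j = pvals[-1], j
            if best_j is not None and best_p <= self.entry_p:
                selected.append(best_j)
                changed = True
            # backward removal
            while selected:
                Xc = np.hstack([ones, X[:, selected]])
                _, pvals, _ = self._ols(y, Xc)
                worst = int(np.argmax(pvals))
                if pvals[worst] >= self.removal_p:
                    selected.pop(worst)
                    changed = True
                else:
                    break
            state = tuple(sorted(selected))
            if not changed or state in seen_states:
                break
            seen_states.add(state)

        self._finalize(X, y, names, selected)
        return self

    def _finalize(self, X: np.ndarray, y: np.ndarray, names: list[str], selected: list[int]) -> None:
        n = len(y)
        sy = y.std(ddof=1)
        tss = float(((y - y.mean()) ** 2).sum())
        if not selected:
            self.selected_ = []
            self.coef_ = {}
            self.std_coef_ = {}
            self.coef_p_ = {}
            self.intercept_ = float(y.mean())
            self.r2_ = 0.0
            self.adj_r2_ = 0.0
            self.f_ = 0.0
            self.model_p_ = 1.0
        else:
            Xs = X[:, selected]
            Xc = np.hstack([np.ones((n, 1)), Xs])
            beta, pvals, rss = self._ols(y, Xc)
            p = len(selected)
            r2 = 1.0 - rss / tss if tss > 0 else 0.0
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
            if rss <= 1e-12 * max(tss, 1.0):
                f, model_p = np.inf, 0.0
            else:
                f = (tss - rss) / p / (rss / (n - p - 1))
                model_p = float(stats.f.sf(f, p, n - p - 1))
            self.selected_ = [names[j] for j in selected]
            self.coef_ = {names[j]: float(beta[i + 1]) for i, j in enumerate(selected)}
            self.std_coef_ = {
                names[j]: float(beta[i + 1] * X[:, j].std(ddof=1) / sy)
                for i, j in enumerate(selected)
            }
            self.coef_p_ = {names[j]: float(pvals[i]) for i, j in enumerate(selected)}
            self.intercept_ = float(beta[0])
            self.r2_ = float(r2)
            self.adj_r2_ = float(adj)
            self.f_ = float(f)
            self.model_p_ = model_p
        self._names = names
        self.model_ = StepwiseModel(
            selected=self.selected_, coef=self.coef_, std_coef=self.std_coef_,
            coef_p=self.coef_p_, intercept=self.intercept_, r2=self.r2_,
            adj_r2=self.adj_r2_, f_stat=self.f_, model_p=self.model_p_,
        )

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self._names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(X.shape[0], self.intercept_)
        for name, b in self.coef_.items():
            out = out + b * X[:, self._names.index(name)]
        return out


def stepwise_regression(y: np.ndarray, candidates: pd.DataFrame | np.ndarray,
                        entry_p: float = 0.05, removal_p: float = 0.10) -> StepwiseModel:
    """Functional wrapper over :class:`StepwiseOLS`."""
    est = StepwiseOLS(entry_p=entry_p, removal_p=removal_p).fit(candidates, y)
    return est.model_


def association_table(table: pd.DataFrame, region_nh: pd.DataFrame,
                      outcomes: list[str], entry_p: float = 0.05,
                      removal_p: float = 0.10) -> pd.DataFrame:
    """Per-outcome stepwise regression in the patient group.

    Candidates are the regional NH features plus age, education and illness
    duration; each outcome gets its own stepwise run over the same candidate
    set. One output row per (outcome, selected predictor); outcomes with an
    empty model produce a single row with blank predictor fields.
    """
    pat = table[table["group_code"] == 1]
    cand = region_nh.loc[pat["subject_id"]].copy()
    cand.index = pat.index
    for extra in ("age", "education", "duration"):
        cand[extra] = pat[extra].to_numpy(float)
    rows = []
    for outcome in outcomes:
        y = pat[outcome].to_numpy(float)
        ok = np.isfinite(y)
        model = stepwise_regression(y[ok], cand[ok], entry_p=entry_p, removal_p=removal_p)
        if model.is_empty:
            rows.append(dict(dependent=outcome, adj_r2=0.0, B=model.intercept,
                             F=np.nan, model_p=np.nan, variable="",
                             std_beta=np.nan, p=np.nan))
        for name in model.selected:
            rows.append(dict(dependent=outcome, adj_r2=model.adj_r2, B=model.intercept,
                             F=model.f_stat, model_p=model.model_p, variable=name,
                             std_beta=model.std_coef[name], p=model.coef_p[name]))
    return pd.DataFrame(rows)
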