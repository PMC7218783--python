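"""Multilinear response-surface metamodel of the simulated mean wait.

The surrogate regressed on a 2^k factorial is multilinear in the coded
factors: an intercept plus main effects and interaction products up to a
chosen order (here at most three-way),

    y = b0 + sum_j b_j * prod_{i in term_j} x_i ,

fit by least squares on the coded design.  On a balanced orthogonal
+/-1 factorial every coefficient equals the contrast average
``b_j = (1/n) sum_i x_ij y_i``, each term carries a sum of squares
``n b_j^2``, and all coefficients share the standard error
``sqrt(MS_res / n)`` — identities this module exploits and verifies
internally.

Diagnostics follow standard response-surface practice: per-term F tests
against the residual mean square, R^2 / adjusted R^2, the PRESS
leave-one-out prediction error (with its balanced-orthogonal closed form
``SS_res / (1 - p'/n)^2``), and the adequate-precision signal-to-noise
ratio ``(max yhat - min yhat) / sqrt(p' MS_res / n)``.

Model reduction keeps terms significant at a chosen level together with
any terms forced in for hierarchy or domain reasons, and refits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "TermKey",
    "term_label",
    "candidate_terms",
    "ResponseSurfaceRegressor",
    "AnovaTable",
    "adjusted_r2",
    "select_terms",
    "select_interaction_order",
    "summary_reconstruction",
    "fit_experiment_table",
]

#: A model term: sorted tuple of 0-based factor indices; () is the intercept.
TermKey = tuple[int, ...]


def term_label(term: TermKey) -> str:
    """Human-readable term name, e.g. ``(0, 4)`` -> ``'X1X5'``."""
    if not term:
        return "Intercept"
    return "".join(f"X{i + 1}" for i in term)


def candidate_terms(n_factors: int, max_order: int) -> list[TermKey]:
    """All interaction terms up to ``max_order`` (intercept excluded)."""
    if not 1 <= max_order <= n_factors:
        raise ValueError("max_order must be in 1..n_factors")
    terms: list[TermKey] = []
    for order in range(1, max_order + 1):
        terms.extend(itertools.combinations(range(n_factors), order))
    return terms


def _model_matrix(X: np.ndarray, terms: list[TermKey]) -> np.ndarray:
    cols = [np.ones(X.shape[0])]
    cols.extend(np.prod(X[:, list(t)], axis=1) for t in terms)
    return np.column_stack(cols)


def _is_coded_orthogonal(Z: np.ndarray) -> bool:
    """True when columns are +/-1 contrasts with Z'Z = n I (intercept incl.)."""
    n = Z.shape[0]
    if not np.all(np.isin(Z, (-1.0, 1.0))):
        return False
    return bool(np.allclose(Z.T @ Z, n * np.eye(Z.shape[1]), atol=1e-8))


@dataclass
class AnovaTable:
    """Per-term ANOVA rows plus whole-model diagnostics.

    ``frame`` has one row per term and a final ``Model`` row with columns
    term, sum_of_squares, coefficient, standard_error, f_value, p_value.
    Diagnostics are ``nan`` (and ``degenerate`` is set) when the residual
    degrees of freedom are zero — they are never fabricated.
    """

    frame: pd.DataFrame
    r2: float
    adjusted_r2: float
    press: float
    adequate_precision: float
    residual_ss: float
    residual_df: int
    total_ss: float
    degenerate: bool = False

    def p_values(self) -> dict[TermKey, float]:
        rows = self.frame[self.frame["term"] != "Model"]
        return dict(zip(rows["term_key"], rows["p_value"]))

    def to_csv(self, path) -> None:
        self.frame.drop(columns=["term_key"]).assign(
            r2=self.r2,
            adjusted_r2=self.adjusted_r2,
            press=self.press,
            adequate_precision=self.adequate_precision,
        ).to_csv(path, index=False)


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Least-squares multilinear surface over coded factors.

    Parameters
    ----------
    max_order : int, default 3
        Highest interaction order when ``terms`` is not given.
    terms : list of tuple of int, optional
        Explicit term set (0-based factor indices, intercept implied);
        overrides ``max_order``.
    check_orthogonal : bool, default True
        On balanced orthogonal +/-1 designs, verify that the
        least-squares solution matches the contrast-average identity
        ``b_j = (1/n) sum_i x_ij y_i``.

    Attributes
    ----------
    terms_ : list of TermKey (intercept excluded)
    intercept_ : float
    coef_ : ndarray aligned with ``terms_`` (coded units)
    residual_ss_, total_ss_, r2_ : fit summaries
    """

    def __init__(self, max_order: int = 3, terms: list[TermKey] | None = None,
                 check_orthogonal: bool = True):
        self.max_order = max_order
        self.terms = terms
        self.check_orthogonal = check_orthogonal

    # ------------------------------------------------------------------ fit
    def fit(self, X, y) -> "ResponseSurfaceRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        k = X.shape[1]
        if self.terms is not None:
            terms = [tuple(sorted(t)) for t in self.terms]
            for t in terms:
                if len(set(t)) != len(t) or any(not 0 <= i < k for i in t):
                    raise ValueError(f"invalid term {t!r} for {k} factors")
        else:
            terms = candidate_terms(k, self.max_order)
        Z = _model_matrix(X, terms)
        n, p = Z.shape
        if p > n:
            raise ValueError(
                f"model has {p} terms (incl. intercept) but only {n} observations"
            )
        rank = np.linalg.matrix_rank(Z)
        if rank < p:
            raise ValueError(
                "rank-deficient model matrix; collinear terms: "
                + ", ".join(self._collinear_labels(Z, terms))
            )
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        if self.check_orthogonal and _is_coded_orthogonal(Z):
            contrast = Z.T @ y / n
            if not np.allclose(beta, contrast, atol=1e-8):
                raise AssertionError(
                    "orthogonal-contrast identity violated; "
                    "least-squares solution is inconsistent"
                )
        fitted = Z @ beta
        self.n_features_in_ = k
        self.terms_ = terms
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.fitted_values_ = fitted
        self.residual_ss_ = float(np.sum((y - fitted) ** 2))
        self.total_ss_ = float(np.sum((y - np.mean(y)) ** 2))
        self.r2_ = 1.0 - self.residual_ss_ / self.total_ss_ if self.total_ss_ > 0 else 1.0
        self.X_ = X
        self.y_ = np.asarray(y, dtype=float)
        self.model_matrix_ = Z
        return self

    @staticmethod
    def _collinear_labels(Z: np.ndarray, terms: list[TermKey]) -> list[str]:
        labels = ["Intercept"] + [term_label(t) for t in terms]
        norms = np.linalg.norm(Z, axis=0)
        bad: list[str] = []
        corr = (Z / norms).T @ (Z / norms)
        for a, b in zip(*np.where(np.abs(np.triu(corr, 1)) > 1 - 1e-10)):
            bad.extend((labels[a], labels[b]))
        return sorted(set(bad)) or labels

    # -------------------------------------------------------------- predict
    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "terms_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} factors, got {X.shape[1]}"
            )
        if np.any(np.abs(X) > 1 + 1e-12):
            warnings.warn(
                "predicting outside the coded design box [-1, +1]^k "
                "(extrapolation)", UserWarning, stacklevel=2,
            )
        return _model_matrix(X, self.terms_) @ np.concatenate(
            ([self.intercept_], self.coef_)
        )

    # ---------------------------------------------------------- diagnostics
    @property
    def residual_df_(self) -> int:
        check_is_fitted(self, "terms_")
        return len(self.y_) - len(self.terms_) - 1

    def leverages(self) -> np.ndarray:
        check_is_fitted(self, "terms_")
        Q, _ = np.linalg.qr(self.model_matrix_)
        return np.sum(Q ** 2, axis=1)

    def press(self) -> float:
        """Leave-one-out prediction error sum of squares.

        General path: ``sum_i (e_i / (1 - h_ii))^2`` with hat leverages
        ``h_ii``.  On a balanced orthogonal 2^k design every leverage is
        ``p'/n``, giving the closed form ``SS_res / (1 - p'/n)^2``; when
        the design is orthogonal both paths are computed and must agree.
        """
        check_is_fitted(self, "terms_")
        h = self.leverages()
        if np.any(h >= 1 - 1e-12):
            raise ValueError("PRESS undefined: a leverage equals 1 (saturated row)")
        e = self.y_ - self.fitted_values_
        general = float(np.sum((e / (1 - h)) ** 2))
        if _is_coded_orthogonal(self.model_matrix_):
            n = len(self.y_)
            p_prime = len(self.terms_) + 1
            closed = self.residual_ss_ / (1 - p_prime / n) ** 2
            if not np.isclose(general, closed, rtol=1e-8, atol=1e-12):
                raise AssertionError("PRESS leverage path disagrees with closed form")
        return general

    def adequate_precision(self) -> float:
        """Signal-to-noise: fitted range over average prediction error."""
        check_is_fitted(self, "terms_")
        df = self.residual_df_
        if df < 1 or self.residual_ss_ <= 0:
            raise ValueError("adequate precision undefined: zero residual variance")
        n = len(self.y_)
        p_prime = len(self.terms_) + 1
        ms_res = self.residual_ss_ / df
        signal = float(np.max(self.fitted_values_) - np.min(self.fitted_values_))
        return signal / np.sqrt(p_prime * ms_res / n)

    def anova(self) -> AnovaTable:
        """Per-term ANOVA with shared SE, F and p, plus model diagnostics.

        Requires a balanced orthogonal +/-1 design (the factorial this
        package generates), where term sums of squares ``n b_j^2``
        decompose the total exactly.
        """
        check_is_fitted(self, "terms_")
        Z = self.model_matrix_
        if not _is_coded_orthogonal(Z):
            raise ValueError(
                "ANOVA decomposition requires a balanced orthogonal +/-1 design"
            )
        n = len(self.y_)
        df_res = self.residual_df_
        ss_terms = n * self.coef_ ** 2
        ss_model = float(np.sum(ss_terms))
        degenerate = df_res < 1
        if degenerate:
            ms_res = np.nan
            se = np.nan
            f_terms = np.full(len(self.terms_), np.nan)
            p_terms = np.full(len(self.terms_), np.nan)
            f_model = p_model = np.nan
        else:
            ms_res = self.residual_ss_ / df_res
            if ms_res == 0:
                # exact fit: a term is "active" only if its SS is not
                # numerical noise relative to the total variation
                active = ss_terms > self.total_ss_ * 1e-20
                se = 0.0
                f_terms = np.where(active, np.inf, np.nan)
                p_terms = np.where(active, 0.0, np.nan)
                f_model = np.inf if ss_model > 0 else np.nan
                p_model = 0.0 if ss_model > 0 else np.nan
            else:
                se = float(np.sqrt(ms_res / n))
                f_terms = ss_terms / ms_res
                p_terms = stats.f.sf(f_terms, 1, df_res)
                f_model = (ss_model / len(self.terms_)) / ms_res
                p_model = float(stats.f.sf(f_model, len(self.terms_), df_res))
        rows = [
            {
                "term": term_label(t),
                "term_key": t,
                "sum_of_squares": float(ss),
                "coefficient": float(b),
                "standard_error": se,
                "f_value": float(f),
                "p_value": float(p),
            }
            for t, ss, b, f, p in zip(
                self.terms_, ss_terms, self.coef_, f_terms, p_terms
            )
        ]
        rows.append(
            {
                "term": "Model",
                "term_key": None,
                "sum_of_squares": ss_model,
                "coefficient": self.intercept_,
                "standard_error": se,
                "f_value": float(f_model),
                "p_value": float(p_model),
            }
        )
        if degenerate or ms_res == 0:
            press = np.nan if degenerate else 0.0
            adeq = np.nan
        else:
            press = self.press()
            adeq = self.adequate_precision()
        return AnovaTable(
            frame=pd.DataFrame(rows),
            r2=self.r2_,
            adjusted_r2=(
                adjusted_r2(self.r2_, n, len(self.terms_)) if not degenerate else np.nan
            ),
            press=press,
            adequate_precision=adeq,
            residual_ss=self.residual_ss_,
            residual_df=df_res,
            total_ss=self.total_ss_,
            degenerate=degenerate,
        )

    # ------------------------------------------------------------ reduction
    def reduce(self, alpha: float = 0.05,
               forced_terms: list[TermKey] | None = None) -> "ResponseSurfaceRegressor":
        """Refit keeping terms with p < alpha plus any forced terms."""
        table = self.anova()
        retained = select_terms(table.p_values(), alpha, forced_terms or [])
        reduced = ResponseSurfaceRegressor(
            terms=retained, check_orthogonal=self.check_orthogonal
        )
        return reduced.fit(self.X_, self.y_)

    def coefficients(self) -> dict[TermKey, float]:
        check_is_fitted(self, "terms_")
        out: dict[TermKey, float] = {(): self.intercept_}
        out.update({t: float(b) for t, b in zip(self.terms_, self.coef_)})
        return out


def adjusted_r2(r2: float, n_obs: int, n_terms: int) -> float:
    """Degrees-of-freedom-adjusted R^2; ``n_terms`` excludes the intercept."""
    df = n_obs - n_terms - 1
    if df < 1:
        raise ValueError("adjusted R^2 requires n_obs - n_terms - 1 >= 1")
    return 1.0 - (1.0 - r2) * (n_obs - 1) / df


def select_terms(p_values: dict[TermKey, float], alpha: float,
                 forced_terms: list[TermKey]) -> list[TermKey]:
    """Reduction rule: keep p < alpha, union forced terms; intercept implied."""
    candidates = set(p_values)
    forced = {tuple(sorted(t)) for t in forced_terms}
    if not forced <= candidates:
        raise ValueError(f"forced terms not among candidates: {forced - candidates}")
    kept = {t for t, p in p_values.items() if np.isfinite(p) and p < alpha} | forced
    return sorted(kept, key=lambda t: (len(t), t))


def select_interaction_order(X, y, alpha: float = 0.05,
                             max_order: int = 3) -> tuple[int, dict[int, float]]:
    """Pick the lowest interaction order whose overall model F has p < alpha.

    Fits surfaces of order 1..max_order and compares each model-row
    p-value; falls back to ``max_order`` when none is significant.
    """
    p_by_order: dict[int, float] = {}
    for order in range(1, max_order + 1):
        fit = ResponseSurfaceRegressor(max_order=order).fit(X, y)
        model_row = fit.anova().frame.query("term == 'Model'").iloc[0]
        p_by_order[order] = float(model_row["p_value"])
    for order, p in p_by_order.items():
        if np.isfinite(p) and p < alpha:
            return order, p_by_order
    return max_order, p_by_order


def summary_reconstruction(ss_model: float, r2: float, n_obs: int,
                           n_terms: int) -> dict[str, float]:
    """Rebuild the ANOVA decomposition from reported model SS and R^2.

    Given only the model sum of squares, the coefficient of
    determination, the run count and the number of non-intercept terms —
    the summary a fitted-surface report typically prints — recover the
    residual decomposition and the shared-SE / F / PRESS diagnostics of a
    balanced orthogonal design.
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    df_res = n_obs - n_terms - 1
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    ss_total = ss_model / r2
    ss_res = ss_total - ss_model
    ms_res = ss_res / df_res
    p_prime = n_terms + 1
    return {
        "ss_total": ss_total,
        "ss_residual": ss_res,
        "ms_residual": ms_res,
        "model_f": (ss_model / n_terms) / ms_res,
        "model_p": float(stats.f.sf((ss_model / n_terms) / ms_res, n_terms, df_res)),
        "standard_error": float(np.sqrt(ms_res / n_obs)),
        "press": ss_res / (1 - p_prime / n_obs) ** 2,
        "adjusted_r2": adjusted_r2(r2, n_obs, n_terms),
    }


def fit_experiment_table(table, max_order: int = 3) -> ResponseSurfaceRegressor:
    """Fit the surface to an :class:`~edsimopt.design.ExperimentTable`.

    Uses the coded design rows and per-row replicate means, the classical
    one-response-per-run factorial analysis.
    """
    X = table.design.rows
    y = table.cell_means()
    return ResponseSurfaceRegressor(max_order=max_order).fit(X, y)
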