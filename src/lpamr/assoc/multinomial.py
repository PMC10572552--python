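"""Multinomial (baseline-category) logistic regression by Newton-Raphson.

`MultinomialLogit` maximizes the multinomial log-likelihood over K - 1
coefficient blocks relative to a reference category, using the exact stacked
score and Fisher information with step-halving, so the log-likelihood is
non-decreasing across iterations. Results expose Wald odds ratios with 95%
confidence intervals per non-reference category.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("lpamr")


class PerfectSeparationError(RuntimeError):
    pass


class MultinomialLogit:
    """Baseline-category multinomial logit model.

    Parameters
    ----------
    endog : array-like of shape (n,)
        Category labels.
    exog : array-like of shape (n, p)
        Design matrix; a leading intercept column is added unless
        ``add_intercept=False``.
    reference : label, optional
        Baseline category (defaults to the first label in sorted order).
    freq : array-like, optional
        Per-row frequency weights, for count-expanded aggregate data.
    """

    def __init__(
        self,
        endog,
        exog,
        reference=None,
        exog_names=None,
        add_intercept: bool = True,
        freq=None,
    ) -> None:
        y = np.asarray(endog)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
            exog_names = ["const"] + list(
                exog_names or [f"x{i}" for i in range(1, X.shape[1])]
            )
        else:
            exog_names = list(exog_names or [f"x{i}" for i in range(X.shape[1])])
        cats = sorted(pd.unique(y).tolist(), key=str)
        if len(cats) < 2:
            raise ValueError("need at least two outcome categories")
        if reference is None:
            reference = cats[0]
        if reference not in cats:
            raise ValueError(f"reference category {reference!r} not among {cats}")
        self.categories = [reference] + [c for c in cats if c != reference]
        # indicator matrix n x K
        self._Y = np.column_stack([(y == c).astype(float) for c in self.categories])
        self._X = X
        self.exog_names = exog_names
        self.reference = reference
        self._freq = np.ones(len(X)) if freq is None else np.asarray(freq, dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, covariates: list[str], reference=None
    ) -> "MultinomialLogit":
        return cls(
            data[response].to_numpy(),
            data[covariates].to_numpy(dtype=float),
            reference=reference,
            exog_names=list(covariates),
        )

    # ---- likelihood machinery -------------------------------------------

    def _probs(self, B: np.ndarray) -> np.ndarray:
        """n x K category probabilities; B is (K-1) x p."""
        eta = self._X @ B.T  # n x (K-1)
        eta = np.column_stack([np.zeros(len(eta)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        ex = np.exp(eta)
        return ex / ex.sum(axis=1, keepdims=True)

    def loglike(self, B: np.ndarray) -> float:
        P = self._probs(B)
        return float(np.sum(self._freq[:, None] * self._Y * np.log(np.clip(P, 1e-300, None))))

    def _score_info(self, B: np.ndarray):
        n, p = self._X.shape
        K = len(self.categories)
        P = self._probs(B)
        f = self._freq
        score = np.concatenate(
            [self._X.T @ (f * (self._Y[:, k] - P[:, k])) for k in range(1, K)]
        )
        info = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(1, K):
                wkl = f * P[:, k] * ((k == l) - P[:, l])
                info[
                    (k - 1) * p : k * p, (l - 1) * p : l * p
                ] = self._X.T @ (wkl[:, None] * self._X)
        return score, info

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "MultinomialLogitResults":
        """Newton-Raphson with step-halving and a ridge fallback.

        Convergence when the largest score component or the largest
        parameter update falls below ``tol``. Diverging coefficients
        (|coef| > 30 on the log-odds scale) raise
        :class:`PerfectSeparationError`.
        """
        n, p = self._X.shape
        K = len(self.categories)
        B = np.zeros((K - 1, p))
        ll = self.loglike(B)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            score, info = self._score_info(B)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                ridge = 1e-6 * np.trace(info) / info.shape[0]
                logger.warning(
                    "multinomial_logit: singular information, adding ridge %.2e", ridge
                )
                step = np.linalg.solve(info + ridge * np.eye(info.shape[0]), score)
            # step-halving keeps the log-likelihood non-decreasing
            alpha = 1.0
            for _ in range(30):
                B_new = B + alpha * step.reshape(K - 1, p)
                ll_new = self.loglike(B_new)
                if ll_new >= ll - 1e-12:
                    break
                alpha /= 2
            delta = float(np.max(np.abs(alpha * step)))
            B, ll = B_new, ll_new
            if np.max(np.abs(B)) > 30:
                raise PerfectSeparationError(
                    "coefficients diverging; data are likely perfectly separated"
                )
            if float(np.max(np.abs(score))) < tol or delta < tol:
                converged = True
                break
        if not converged:
            logger.warning("multinomial_logit: no convergence in %d iterations", max_iter)
        _, info = self._score_info(B)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        return MultinomialLogitResults(
            model=self, params=B, cov_params=cov, llf=ll, converged=converged, iterations=it
        )


class MultinomialLogitResults:
    """Fitted multinomial logit: coefficients, covariance, Wald odds ratios."""

    def __init__(self, model, params, cov_params, llf, converged, iterations) -> None:
        self.model = model
        self.params = params  # (K-1) x p, rows ordered as model.categories[1:]
        self.cov_params = cov_params
        self.llf = llf
        self.converged = converged
        self.iterations = iterations

    def bse(self) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("model did not converge; estimates withheld")
        p = self.model._X.shape[1]
        se = np.sqrt(np.diag(self.cov_params))
        return se.reshape(len(self.model.categories) - 1, p)

    def predicted_probs(self) -> np.ndarray:
        return self.model._probs(self.params)

    def odds_ratios(self) -> pd.DataFrame:
        """Wald odds ratios with 95% CIs, one row per category x covariate."""
        se = self.bse()
        crit = stats.norm.ppf(0.975)
        rows = []
        for i, cat in enumerate(self.model.categories[1:]):
            for j, name in enumerate(self.model.exog_names):
                b, s = self.params[i, j], se[i, j]
                z = b / s if s > 0 else np.inf
                rows.append(
                    {
                        "category": cat,
                        "covariate": name,
                        "coef": b,
                        "se": s,
                        "or": np.exp(b),
                        "ci_low": np.exp(b - crit * s),
                        "ci_high": np.exp(b + crit * s),
                        "pval": float(2 * stats.norm.sf(abs(z))),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multinomial logistic regression "
            f"(reference: {self.model.reference}, "
            f"{'converged' if self.converged else 'NOT converged'} "
            f"in {self.iterations} iterations, llf = {self.llf:.3f})"
        ]
        df = self.odds_ratios()
        lines.append(
            f"{'category':<12}{'covariate':<14}{'OR':>8}{'95% CI':>18}{'p':>10}"
        )
        for _, r in df.iterrows():
            ci = f"({r.ci_low:.2f}-{r.ci_high:.2f})"
            lines.append(
                f"{r.category:<12}{r.covariate:<14}{r['or']:>8.3f}{ci:>18}{r.pval:>10.4f}"
            )
        return "\n".join(lines)
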