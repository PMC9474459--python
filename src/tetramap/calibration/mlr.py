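"""Multiple linear regression baseline with classical diagnostics.

The linear comparison model regresses MAP on the same compound fractions
as the network.  Alongside the least-squares coefficients it reports the
multiple correlation R, the residual scale s, per-coefficient standard
errors and t statistics (from the inverse centred cross-product matrix),
the overall F statistic and variance inflation factors from auxiliary
regressions — the full textbook diagnostic set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..containers import CalibrationDataset
from ..errors import CollinearityError
from .dataset import DEFAULT_FEATURES
from .metrics import FitMetrics, evaluate

__all__ = ["MlrModel", "MlrResults", "fit_mlr"]

_COND_LIMIT = 1e12


@dataclass
class MlrResults:
    """Fitted coefficients and diagnostics of the linear baseline."""

    intercept: float
    coefficients: np.ndarray       # b_1 .. b_k
    feature_names: tuple[str, ...]
    r: float                       # multiple correlation, in [0, 1]
    r2: float
    s: float                       # residual scale, df = n - m - 1
    std_errors: np.ndarray         # s_bj = sqrt(p_jj) * s
    t_values: np.ndarray           # b_j / s_bj (inf when s = 0)
    p_values: np.ndarray           # two-sided, Student t with n - m - 1 df
    f_statistic: float
    vif: np.ndarray
    n: int
    fitted: np.ndarray
    training_metrics: FitMetrics | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self.intercept + X @ self.coefficients

    def evaluate(self, X, observed) -> FitMetrics:
        return evaluate(self.predict(X), observed)

    def summary(self) -> str:
        head = (f"{'':12s}{'coef':>12s}{'std err':>12s}{'t':>10s}"
                f"{'P>|t|':>10s}{'VIF':>8s}")
        rows = [f"{'intercept':12s}{self.intercept:12.4f}"
                + " " * 30 + f"{'':8s}"]
        for j, name in enumerate(self.feature_names):
            rows.append(
                f"{name:12s}{self.coefficients[j]:12.4f}"
                f"{self.std_errors[j]:12.4f}{self.t_values[j]:10.3f}"
                f"{self.p_values[j]:10.4f}{self.vif[j]:8.3f}"
            )
        tail = (f"n={self.n}  R={self.r:.4f}  R2={self.r2:.4f}  "
                f"s={self.s:.4f}  F={self.f_statistic:.3f}")
        return "\n".join(["Multiple linear regression", "=" * 64,
                          head, *rows, "-" * 64, tail])


class MlrModel:
    """Ordinary least squares of MAP on compound fractions."""

    def __init__(self, endog, exog, feature_names=DEFAULT_FEATURES):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("exog must be (n, k) aligned with endog")
        self.feature_names = tuple(feature_names)[: self.exog.shape[1]]
        if len(self.feature_names) != self.exog.shape[1]:
            self.feature_names = tuple(
                f"x{j + 1}" for j in range(self.exog.shape[1]))

    @classmethod
    def from_dataset(cls, ds: CalibrationDataset,
                     features=DEFAULT_FEATURES) -> "MlrModel":
        return cls(ds.map_mm.to_numpy(dtype=float), ds.features(features),
                   feature_names=features)

    def fit(self) -> MlrResults:
        from scipy import stats

        X, y = self.exog, self.endog
        n, m = X.shape
        if n <= m + 1:
            raise ValueError(f"need n > m + 1 samples (n={n}, m={m})")

        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc                       # centred cross-product matrix
        if np.linalg.cond(S) > _COND_LIMIT:
            # name the columns involved in the (near-)exact dependency
            corr = np.corrcoef(Xc, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            worst = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise CollinearityError(
                "singular normal matrix; near-collinear columns include "
                f"{self.feature_names[worst[0]]!r} and "
                f"{self.feature_names[worst[1]]!r}"
            )
        P = np.linalg.inv(S)

        b = P @ (Xc.T @ (y - y.mean()))
        a = float(y.mean() - X.mean(axis=0) @ b)
        fitted = a + X @ b
        resid = y - fitted
        sse = float(resid @ resid)
        ssr = float(((fitted - y.mean()) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        r = float(np.sqrt(min(ssr / sst, 1.0))) if sst > 0 else float("nan")
        s = float(np.sqrt(sse / (n - m - 1)))
        se = np.sqrt(np.diag(P)) * s
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b / np.where(se > 0, se, 1.0),
                         np.sign(b) * np.inf)
            f = ssr / (m * s * s) if s > 0 else float("inf")
        df = n - m - 1
        p = np.where(np.isfinite(t),
                     2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)),
                                      df), 0.0)

        # VIF from auxiliary regressions of each predictor on the others
        vif = np.empty(m)
        for j in range(m):
            xj = Xc[:, j]
            others = np.delete(Xc, j, axis=1)
            if others.shape[1] == 0 or (xj == 0).all():
                vif[j] = 1.0
                continue
            coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
            res_j = xj - others @ coef
            ss_j = float(xj @ xj)
            r2_j = 1.0 - float(res_j @ res_j) / ss_j if ss_j > 0 else 0.0
            vif[j] = np.inf if r2_j >= 1.0 else 1.0 / (1.0 - r2_j)

        results = MlrResults(
            intercept=a, coefficients=b, feature_names=self.feature_names,
            r=r, r2=r * r, s=s, std_errors=se, t_values=t, p_values=p,
            f_statistic=float(f), vif=vif, n=n, fitted=fitted,
        )
        results.training_metrics = evaluate(fitted, y)
        return results


def fit_mlr(X, y, feature_names=DEFAULT_FEATURES) -> MlrResults:
    """Functional entry point: least squares of y on X with diagnostics."""
    return MlrModel(y, X, feature_names=feature_names).fit()
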