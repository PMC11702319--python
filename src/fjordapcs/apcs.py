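"""Absolute principal component scores and contribution regression (APCS-MLR).

Receptor-model quantification in the Thurston-Spengler tradition: component
scores are re-zeroed against the score of an artificial sample whose raw
concentrations are all zero, turning them into absolute scores with a
physically meaningful origin.  Each parameter's concentrations are then
regressed on the absolute scores; backward elimination drops factors whose
coefficients are indistinguishable from zero, and the surviving factors'
mean absolute modeled contributions are normalized into percentage shares
R_S of the parameter's distributional change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .factors import FactorModel
from .geochem import StandardizationModel

__all__ = [
    "RegressionRecord",
    "ApportionmentResult",
    "absolute_scores",
    "fit_apportionment",
    "contributions",
    "apportion",
    "significance_code",
]

#: drop a factor from the regression when its two-sided p-value is >= this
DEFAULT_ALPHA_DROP = 0.1


def significance_code(p_value: float) -> str:
    """Conventional star codes for coefficient p-values."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    if p_value < 0.1:
        return "·"
    return "removed"


def absolute_scores(model: FactorModel, std: StandardizationModel
                    ) -> pd.DataFrame:
    """Re-zero component scores against the all-zero-concentration sample.

    The artificial zero sample standardizes to z0_j = -mean_j / sd_j; its
    projection P0 through the model's score-coefficient matrix is subtracted
    from every observed score, so an absolute score of zero means "as if no
    material were present".
    """
    model_params = list(model.score_coefficients.index)
    if set(model_params) != set(std.parameters):
        raise ValueError("parameter sets of factor model and standardization "
                         "model do not match")
    z0 = -(std.mean[model_params] / std.sd[model_params]).to_numpy()
    p0 = z0 @ model.score_coefficients.to_numpy()
    return model.scores - p0


@dataclass
class RegressionRecord:
    """OLS fit of one parameter's concentrations on the absolute scores."""

    parameter: str
    intercept: float
    coefficients: dict[str, float]      # retained factor -> coefficient
    p_values: dict[str, float]          # retained factor -> p-value
    codes: dict[str, str]               # all factors -> code or "removed"
    retained: list[str]
    r_squared: float
    dropped_order: list[str] = field(default_factory=list)

    @property
    def intercept_only(self) -> bool:
        return not self.retained


def fit_apportionment(c_j: pd.Series, apcs: pd.DataFrame,
                      alpha_drop: float = DEFAULT_ALPHA_DROP,
                      parameter: str = "") -> RegressionRecord:
    """Backward-eliminated OLS of one parameter on the absolute scores.

    The model always keeps an intercept.  At each round the factor with the
    largest coefficient p-value is removed if that p-value is >= alpha_drop,
    and the model is refitted; elimination stops when every retained factor
    is significant at alpha_drop.  Concentrations are used in their original
    units — the contribution shares are invariant to that choice, the
    coefficients are not.
    """
    y = np.asarray(c_j, dtype=float)
    apcs = pd.DataFrame(apcs)
    factors = list(apcs.columns)
    if len(y) <= len(factors) + 1:
        raise ValueError("need n > k + 1 observations for the regression")
    retained = list(factors)
    dropped: list[str] = []
    res = None
    while retained:
        x = sm.add_constant(apcs[retained].to_numpy())
        res = sm.OLS(y, x).fit()
        # an exact fit yields 0/0 t-statistics for zero coefficients; an
        # undetermined p-value cannot justify keeping the factor, and a
        # numerically negligible contribution (relative to the response
        # scale) is noise regardless of its formal t-statistic
        pvals = pd.Series(np.nan_to_num(res.pvalues[1:], nan=1.0),
                          index=retained)
        y_scale = max(np.std(y), np.abs(y).max(), 1e-300)
        for i, f in enumerate(retained):
            contrib = np.abs(res.params[1 + i]) * np.std(apcs[f].to_numpy())
            if contrib < 1e-10 * y_scale:
                pvals[f] = 1.0
        worst = pvals.idxmax()
        if pvals[worst] >= alpha_drop:
            retained.remove(worst)
            dropped.append(worst)
        else:
            break

    if not retained:
        res = sm.OLS(y, np.ones((len(y), 1))).fit()
        return RegressionRecord(
            parameter=parameter, intercept=float(res.params[0]),
            coefficients={}, p_values={},
            codes={f: "removed" for f in factors}, retained=[],
            r_squared=0.0, dropped_order=dropped,
        )
    coeffs = dict(zip(retained, map(float, res.params[1:])))
    pvals = dict(zip(retained, map(float, res.pvalues[1:])))
    codes = {f: significance_code(pvals[f]) if f in pvals else "removed"
             for f in factors}
    return RegressionRecord(
        parameter=parameter, intercept=float(res.params[0]),
        coefficients=coeffs, p_values=pvals, codes=codes, retained=retained,
        r_squared=float(res.rsquared), dropped_order=dropped,
    )


def contributions(fits: dict[str, RegressionRecord], apcs: pd.DataFrame
                  ) -> pd.DataFrame:
    """Percentage share R_S of each retained factor per parameter.

    The contribution of factor f to parameter j is the sample mean of
    |a_jf * APCS_if|; shares are normalized over the retained factors to sum
    to 100.  Absolute values prevent sign cancellation for negatively loaded
    parameters.  Factors eliminated from a parameter's regression get NaN,
    and a parameter whose regression kept no factor has an all-NaN row.
    """
    apcs = pd.DataFrame(apcs)
    rows = {}
    for name, rec in fits.items():
        row = pd.Series(np.nan, index=apcs.columns)
        if rec.retained:
            mean_abs = {
                f: np.mean(np.abs(rec.coefficients[f] * apcs[f].to_numpy()))
                for f in rec.retained
            }
            total = sum(mean_abs.values())
            if total > 0:
                for f in rec.retained:
                    row[f] = 100.0 * mean_abs[f] / total
            else:  # all-zero contributions: spread evenly
                for f in rec.retained:
                    row[f] = 100.0 / len(rec.retained)
        rows[name] = row
    return pd.DataFrame(rows).T


@dataclass
class ApportionmentResult:
    """Absolute scores plus all per-parameter regressions and R_S shares."""

    apcs: pd.DataFrame
    fits: dict[str, RegressionRecord]
    r_s: pd.DataFrame

    def summary_table(self, loadings: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
        """Report-shaped frame: per factor, loading / R_S / code columns."""
        cols = {}
        for comp in self.apcs.columns:
            if loadings is not None:
                cols[f"{comp} loading"] = loadings[comp]
            cols[f"{comp} R_S (%)"] = self.r_s[comp]
            cols[f"{comp} P"] = pd.Series(
                {p: rec.codes.get(comp, "removed")
                 for p, rec in self.fits.items()}
            )
        return pd.DataFrame(cols)


def apportion(concentrations: pd.DataFrame, model: FactorModel,
              std: StandardizationModel,
              alpha_drop: float = DEFAULT_ALPHA_DROP) -> ApportionmentResult:
    """Run the full APCS-MLR quantification for every parameter."""
    apcs = absolute_scores(model, std)
    fits = {
        name: fit_apportionment(concentrations[name], apcs,
                                alpha_drop=alpha_drop, parameter=name)
        for name in concentrations.columns
    }
    return ApportionmentResult(apcs=apcs, fits=fits,
                               r_s=contributions(fits, apcs))
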