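"""Endmember estimation from mixing-component partial values.

When one rotated component resolves conservative mixing along the salinity
gradient, the component-times-loading product for a parameter isolates the
part of its signal explained by mixing alone.  De-standardized and regressed
against salinity, these partial values extrapolate to a freshwater endmember
at S = 0 (subglacial discharge composition) and a marine endmember at the
reference salinity.  River endmembers are summarized directly from the
terrestrial outlet samples, and a simple removal factor quantifies estuarine
loss between a river source and receiving surface water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .factors import FactorModel, LoadingSignificance, significant_loadings
from .geochem import StandardizationModel, destandardize
from .hydrography import REFERENCE_SALINITY

__all__ = [
    "EndmemberEstimate",
    "RiverEndmember",
    "partial_values",
    "endmember_regression",
    "river_endmember",
    "removal_factor",
    "round_sig",
]


def round_sig(x: float, digits: int) -> float:
    """Round to a number of significant figures (report-table policy)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


@dataclass
class EndmemberEstimate:
    """Linear mixing relationship of one parameter against salinity."""

    parameter: str
    slope: float                # unit per PSU
    intercept: float            # unit
    r_squared: float
    s_marine: float = REFERENCE_SALINITY

    @property
    def endmember_s0(self) -> float:
        """Freshwater endmember: the regression intercept."""
        return self.intercept

    @property
    def endmember_marine(self) -> float:
        return self.intercept + self.s_marine * self.slope

    @property
    def negative_flag(self) -> bool:
        """Extrapolation below zero is reported, never clipped; it marks a
        non-conservative artifact (for example scavenging in the plume)."""
        return self.endmember_s0 < 0


@dataclass
class RiverEndmember:
    """Mean and dispersion of the terrestrial outlet concentrations."""

    parameter: str
    mean: float
    sd: float | None          # population SD (divisor n); None when n < 2
    n_rivers: int

    def rounded(self, mean_sig: int = 2, sd_sig: int = 1) -> tuple:
        sd = None if self.sd is None else round_sig(self.sd, sd_sig)
        return round_sig(self.mean, mean_sig), sd


def partial_values(model: FactorModel, std: StandardizationModel,
                   component: str | int = "PC1",
                   significance: LoadingSignificance | None = None
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample parameter values attributable to a single component.

    partial_ij = P_i,comp * B_j,comp in standardized units, then mapped back
    to original units.  Only parameters whose loading on the component is
    significant under the broken-stick screen are returned; the excluded
    names are reported alongside.
    """
    if significance is None:
        significance = significant_loadings(model)
    comp = component if isinstance(component, str) else \
        model.loadings.columns[component]
    if comp not in model.loadings.columns:
        raise ValueError(f"component {component!r} not in model")
    keep = significance.parameters_on(comp)
    excluded = [p for p in model.parameters if p not in keep]
    scores = model.scores[comp].to_numpy()[:, None]
    loads = model.loadings.loc[keep, comp].to_numpy()[None, :]
    partial_z = pd.DataFrame(scores * loads, index=model.scores.index,
                             columns=keep)
    return destandardize(partial_z, std), excluded


def endmember_regression(partial_j, salinity,
                         s_marine: float = REFERENCE_SALINITY,
                         parameter: str = "") -> EndmemberEstimate:
    """OLS of a parameter's partial values against salinity."""
    y = np.asarray(partial_j, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if y.size != s.size:
        raise ValueError("partial values and salinity differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(s) == 0:
        raise ValueError("constant salinity")
    fit = stats.linregress(s, y)
    return EndmemberEstimate(
        parameter=parameter,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        s_marine=s_marine,
    )


def river_endmember(values, parameter: str = "") -> RiverEndmember:
    """Mean and population SD (divisor n) of the river outlet values."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("no river values")
    sd = float(np.std(vals, ddof=0)) if vals.size >= 2 else None
    return RiverEndmember(parameter=parameter, mean=float(vals.mean()),
                          sd=sd, n_rivers=int(vals.size))


def removal_factor(source_conc: float, receiving_conc: float) -> float:
    """Percentage of a constituent lost between source and receiving water.

    100 * (1 - receiving / source); negative values signal enrichment and
    are reported as-is.
    """
    if source_conc <= 0:
        raise ValueError("source concentration must be positive")
    return 100.0 * (1.0 - receiving_conc / source_conc)
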