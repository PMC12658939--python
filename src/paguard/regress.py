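"""Species-level and bioanthrome-level linear models of protection vs loss.

Four ordinary-least-squares models relate range contraction to protection
history:

1. ``rangelost% ~ ln(proportional change in protected range + 0.01)`` —
   the 0.01 constant (a 1% increase in protection extent) keeps species
   whose protected proportion did not change in the model.
2. ``rangelost% ~ ln(extent protected since 1970 [km^2] + 1)``
3. ``rangelost% ~ ln(extent protected in 2015 but not since 1970 + 1)`` —
   the +1 km^2 constant keeps entirely unprotected species.
4. ``species locally extinct% ~ change in PA coverage + bioanthrome area``
   with the area either in km^2 or its natural logarithm.

Percentages are on the 0-100 scale. The transform constants are part of the
model definitions and are asserted, not configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "fit_eq1",
    "fit_eq2_eq3",
    "fit_eq4",
    "EQ1_CONSTANT",
    "EQ23_CONSTANT",
]

EQ1_CONSTANT = 0.01   # proportional-change offset (1% of protection extent)
EQ23_CONSTANT = 1.0   # extent offset (1 km^2)


@dataclass
class RegressionFit:
    """OLS coefficient table with fit diagnostics."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    nobs: int
    formula: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        return (
            f"{self.formula}\nn = {self.nobs}, R^2 = {self.rsquared:.4f}\n"
            + self.to_frame().to_string(float_format=lambda v: f"{v:.6g}")
        )


def _ols(y: np.ndarray, X: pd.DataFrame, formula: str) -> RegressionFit:
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations for the number of coefficients")
    for col in X.columns:
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"predictor {col!r} is constant: model not identifiable")
    if X.shape[1] == 2:
        r = np.corrcoef(X.iloc[:, 0], X.iloc[:, 1])[0, 1]
        if abs(r) > 1 - 1e-12:
            raise ValueError("predictors are perfectly collinear")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        rsquared=float(res.rsquared),
        nobs=int(res.nobs),
        formula=formula,
    )


def fit_eq1(species: pd.DataFrame) -> RegressionFit:
    """% range lost vs ln(proportional change in protected range + 0.01).

    Species whose protected proportion shrank by more than the offset
    (delta <= -0.01, log undefined) are excluded with a warning.
    """
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    delta = species["delta_prop_protected"].to_numpy(dtype=float)
    ok = delta > -EQ1_CONSTANT
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} species with protection loss beyond the "
            f"{EQ1_CONSTANT} offset excluded from the model",
            stacklevel=2,
        )
    X = pd.DataFrame({"ln_delta_prop": np.log(delta[ok] + EQ1_CONSTANT)})
    y = species["pct_range_lost"].to_numpy(dtype=float)[ok]
    return _ols(y, X, "pct_range_lost ~ ln(delta_prop_protected + 0.01)")


def fit_eq2_eq3(species: pd.DataFrame) -> tuple[RegressionFit, RegressionFit]:
    """% range lost vs ln(protected extent + 1 km^2), separately for the
    extent protected continuously since 1970 and the extent protected in
    2015 but not since 1970."""
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    y = species["pct_range_lost"].to_numpy(dtype=float)
    fits = []
    for col, tag in (("extent_P70_km2", "since 1970"), ("extent_P15only_km2", "2015 only")):
        X = pd.DataFrame({f"ln_{col}": np.log(species[col].to_numpy(dtype=float) + EQ23_CONSTANT)})
        fits.append(_ols(y, X, f"pct_range_lost ~ ln(extent protected {tag} + 1)"))
    return fits[0], fits[1]


def fit_eq4(bioanthromes: pd.DataFrame, area_transform: str = "identity") -> RegressionFit:
    """% species locally extinct vs change in PA coverage + bioanthrome area.

    ``area_transform`` selects the raw area in km^2 ('identity') or its
    natural logarithm ('ln').
    """
    if len(bioanthromes) < 4:
        raise ValueError("need at least 4 bioanthromes")
    area = bioanthromes["area_km2"].to_numpy(dtype=float)
    if area_transform == "ln":
        area_var = np.log(area)
        area_name = "ln_area_km2"
    elif area_transform == "identity":
        area_var = area
        area_name = "area_km2"
    else:
        raise ValueError("area_transform must be 'identity' or 'ln'")
    X = pd.DataFrame(
        {
            "delta_pa_coverage": bioanthromes["delta_pa_coverage"].to_numpy(dtype=float),
            area_name: area_var,
        }
    )
    y = bioanthromes["pct_species_locally_extinct"].to_numpy(dtype=float)
    return _ols(y, X, f"pct_species_locally_extinct ~ delta_pa_coverage + {area_name}")
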