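"""Editing level versus ADAR expression: OLS fit with a 95% confidence band.

Relates each cell's edit percent at a site to that cell's ADAR mRNA
abundance (TPM) with an ordinary least-squares line and the pointwise 95%
confidence band for the mean response (t-distribution, n−2 df), mirroring a
best-fit line with confidence intervals over the observed expression range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .profiles import SiteLevelProfile

__all__ = [
    "DegenerateFitError",
    "FitResult",
    "fit_edit_vs_expression",
    "join_expression",
    "site_percent_series",
]


class DegenerateFitError(ValueError):
    """Raised when the regression is undefined (too few points, constant x)."""


@dataclass(frozen=True)
class FitResult:
    """An OLS line with its pointwise 95% mean-response confidence band."""

    slope: float
    intercept: float
    r: float                     # Pearson correlation of x and y
    p_value: float               # two-sided p for slope = 0
    n: int
    slope_stderr: float
    slope_ci: tuple[float, float]
    x_grid: np.ndarray           # over the observed x-range
    band_low: np.ndarray
    band_high: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slope": [self.slope],
                "intercept": [self.intercept],
                "r": [self.r],
                "p_value": [self.p_value],
                "n": [self.n],
                "slope_ci_low": [self.slope_ci[0]],
                "slope_ci_high": [self.slope_ci[1]],
            }
        )


def fit_edit_vs_expression(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    n_grid: int = 100,
) -> FitResult:
    """Fit edit percent (y) against expression (x) by ordinary least squares.

    Requires at least three paired observations and non-constant x.  The
    confidence band is for the mean response, evaluated on ``n_grid`` points
    spanning the observed x-range, so the band always contains the fitted
    line itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    if len(x) < 3:
        raise DegenerateFitError(f"need at least 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x has zero variance; slope is undefined")

    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    intercept, slope = res.params
    ci_low, ci_high = res.conf_int(alpha=alpha)[1]

    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = res.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=alpha)

    r = float(np.corrcoef(x, y)[0, 1]) if y.std() > 0 else 0.0

    return FitResult(
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        p_value=float(res.pvalues[1]),
        n=len(x),
        slope_stderr=float(res.bse[1]),
        slope_ci=(float(ci_low), float(ci_high)),
        x_grid=grid,
        band_low=band[:, 0],
        band_high=band[:, 1],
    )


def site_percent_series(
    profiles: Sequence[SiteLevelProfile], site_id: str
) -> pd.Series:
    """Per-cell edit percent at one site, indexed by cell_id."""
    return pd.Series(
        {p.cell_id: p.edit_percent[site_id] for p in profiles}, name=site_id
    )


def join_expression(
    editing: Mapping[str, float] | pd.Series,
    expression: pd.DataFrame,
    gene: str = "Adar",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair per-cell editing values with per-cell TPM of ``gene``.

    ``expression`` is a table with columns ``cell_id, gene, tpm``.  The join
    is inner: cells missing either value are dropped (count logged via a
    returned cell list the caller can compare); duplicate expression rows for
    one cell or zero overlap are errors.
    """
    for col in ("cell_id", "gene", "tpm"):
        if col not in expression.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    expr = expression[expression["gene"] == gene]
    dup = expr["cell_id"][expr["cell_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"duplicate expression rows for cell_id {sorted(dup.unique())} (gene {gene!r})"
        )
    if (expr["tpm"] < 0).any():
        raise ValueError("TPM values must be non-negative")
    editing = pd.Series(dict(editing)) if not isinstance(editing, pd.Series) else editing
    editing = editing.dropna()

    tpm = expr.set_index("cell_id")["tpm"]
    cells = sorted(set(editing.index) & set(tpm.index))
    if not cells:
        raise ValueError(f"no shared cell_ids between editing values and {gene!r} TPM")
    return (
        tpm.loc[cells].to_numpy(dtype=float),
        editing.loc[cells].to_numpy(dtype=float),
        cells,
    )
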