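"""Activation energies of rotational motion from temperature series of tau_c.

Thermally activated rotation follows the Arrhenius law

    tau_c(T) = tau_0 exp(dEa / (R T)),

so ln tau_c is linear in 1/T with slope dEa / R.  `ArrheniusModel` fits
that line by ordinary least squares (optionally inverse-variance
weighted) and reports the activation energy in kJ/mol with the OLS
slope standard error; the published convention in this field prints
"value +/- error" to one decimal, which `activation_energy_table`
reproduces.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bpp import CorrelationTime
from .constants import GAS_CONSTANT

__all__ = [
    "ArrheniusModel",
    "ArrheniusResults",
    "fit_arrhenius",
    "activation_energy_table",
    "format_value_pm_error",
]


@dataclass
class ArrheniusResults:
    """Fitted Arrhenius parameters for one phase.

    Attributes
    ----------
    delta_ea : float
        Activation energy dEa in kJ/mol (slope * R / 1000).
    delta_ea_se : float
        Standard error of dEa (kJ/mol), from the OLS slope SE.
    tau_0 : float
        Pre-exponential correlation time (s), exp(intercept).
    tau_0_se : float
        Delta-method SE of tau_0 (s).
    r_squared : float
        Coefficient of determination of the ln tau_c vs 1/T line.
    n_points : int
    phase : str
    """

    delta_ea: float
    delta_ea_se: float
    tau_0: float
    tau_0_se: float
    r_squared: float
    n_points: int
    phase: str = "unassigned"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("an Arrhenius fit needs at least 3 points")
        if self.delta_ea_se < 0:
            raise ValueError("delta_ea_se must be non-negative")
        if not self.tau_0 > 0:
            raise ValueError("tau_0 must be positive")

    def predict_tau_c(self, temperature_k: np.ndarray) -> np.ndarray:
        """tau_c at the given temperatures under the fitted law."""
        t = np.asarray(temperature_k, dtype=float)
        return self.tau_0 * np.exp(self.delta_ea * 1e3 / (GAS_CONSTANT * t))

    def summary(self) -> str:
        return (
            f"Arrhenius fit ({self.phase}), n = {self.n_points}\n"
            f"  dEa   = {self.delta_ea:.4g} +/- {self.delta_ea_se:.2g} kJ/mol\n"
            f"  tau_0 = {self.tau_0:.4g} +/- {self.tau_0_se:.2g} s\n"
            f"  R^2   = {self.r_squared:.6f}"
        )


class ArrheniusModel:
    """OLS of ln tau_c on 1/T.

    Parameters
    ----------
    tau_c : array
        Correlation times (s), all positive.
    temperature_k : array
        Absolute temperatures (K), at least 3 distinct values.
    weights : array, optional
        Weights for ln tau_c (e.g. inverse variances via the delta
        method from upstream tau_c uncertainties); default unweighted.
    phase : str
        Label carried through to the results.
    """

    def __init__(self, tau_c, temperature_k, weights=None, phase: str = "unassigned"):
        tau_c = np.asarray(tau_c, dtype=float)
        temperature_k = np.asarray(temperature_k, dtype=float)
        if tau_c.shape != temperature_k.shape or tau_c.ndim != 1:
            raise ValueError("tau_c and temperature_k must be 1-D arrays of equal length")
        if len(tau_c) < 3:
            raise ValueError(f"need at least 3 points, got {len(tau_c)}")
        if len(np.unique(temperature_k)) < 3:
            raise ValueError("need at least 3 distinct temperatures")
        if np.any(temperature_k <= 0):
            raise ValueError("temperatures must be positive (kelvin)")
        with np.errstate(divide="ignore", invalid="ignore"):
            log_tau = np.log(np.where(tau_c > 0, tau_c, np.nan))
        bad = ~np.isfinite(log_tau)
        if np.any(bad):
            raise ValueError(
                "non-finite ln(tau_c) at temperature(s) "
                f"{temperature_k[bad].tolist()} K"
            )
        self.tau_c = tau_c
        self.temperature_k = temperature_k
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.phase = phase

    @classmethod
    def from_points(cls, points: list[CorrelationTime], phase: str = "unassigned"):
        """Build from `CorrelationTime` objects carrying temperatures."""
        missing = [p for p in points if p.temperature_k is None]
        if missing:
            raise ValueError("all points must carry temperature_k")
        return cls(
            tau_c=[p.tau_c for p in points],
            temperature_k=[p.temperature_k for p in points],
            phase=phase,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, tau_col: str = "tau_c_s",
        temp_col: str = "temperature_k", phase: str = "unassigned",
    ):
        return cls(df[tau_col].to_numpy(), df[temp_col].to_numpy(), phase=phase)

    def fit(self) -> ArrheniusResults:
        x = 1.0 / self.temperature_k
        y = np.log(self.tau_c)
        exog = sm.add_constant(x)
        if self.weights is None:
            res = sm.OLS(y, exog).fit()
        else:
            res = sm.WLS(y, exog, weights=self.weights).fit()
        intercept, slope = res.params
        se_intercept, se_slope = res.bse
        # with only 2 points per parameter the SE can be nan; report 0 for
        # an exact 2-parameter interpolation is impossible here (n >= 3)
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
        tau_0 = math.exp(intercept)
        return ArrheniusResults(
            delta_ea=slope * GAS_CONSTANT / 1e3,
            delta_ea_se=float(se_slope) * GAS_CONSTANT / 1e3,
            tau_0=tau_0,
            tau_0_se=tau_0 * float(se_intercept),
            r_squared=r2,
            n_points=len(self.tau_c),
            phase=self.phase,
        )


def fit_arrhenius(points: list[CorrelationTime], phase: str = "unassigned") -> ArrheniusResults:
    """Fit the Arrhenius law to correlation times tagged with temperatures."""
    return ArrheniusModel.from_points(points, phase=phase).fit()


def format_value_pm_error(value: float, error: float, decimals: int = 1) -> str:
    """Render "value +/- error" with half-up rounding to ``decimals``."""
    q = decimal.Decimal(1).scaleb(-decimals)

    def r(v):
        return decimal.Decimal(repr(float(v))).quantize(q, rounding=decimal.ROUND_HALF_UP)

    return f"{r(value)} ± {r(error)}"


_TABLE_COLUMNS = [
    "starch", "concentration_g_per_g", "fat", "phase",
    "delta_ea_kj_mol", "se_kj_mol", "formatted",
]


def activation_energy_table(
    fits: list[ArrheniusResults],
    metadata: list[dict] | dict | None = None,
) -> pd.DataFrame:
    """Long-format activation-energy table, one row per (condition, phase).

    Parameters
    ----------
    fits : list of ArrheniusResults
    metadata : dict or list of dict, optional
        Condition keys per fit (``starch``, ``concentration_g_per_g``,
        ``fat``); a single dict applies to all fits.

    Returns
    -------
    DataFrame with columns starch, concentration_g_per_g, fat, phase,
    delta_ea_kj_mol, se_kj_mol and a display column ``formatted``
    rendered "value +/- error" to one decimal (half-up).
    """
    if metadata is None:
        metadata = [{} for _ in fits]
    elif isinstance(metadata, dict):
        metadata = [metadata for _ in fits]
    if len(metadata) != len(fits):
        raise ValueError("metadata must match fits one-to-one")
    rows = []
    for fit, meta in zip(fits, metadata):
        rows.append(
            {
                "starch": meta.get("starch"),
                "concentration_g_per_g": meta.get("concentration_g_per_g"),
                "fat": meta.get("fat"),
                "phase": fit.phase,
                "delta_ea_kj_mol": fit.delta_ea,
                "se_kj_mol": fit.delta_ea_se,
                "formatted": format_value_pm_error(fit.delta_ea, fit.delta_ea_se),
            }
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    if len(df):
        keys = ["starch", "concentration_g_per_g", "fat", "phase"]
        if df.duplicated(subset=keys).any():
            dupes = df[df.duplicated(subset=keys, keep=False)][keys]
            raise ValueError(f"duplicate (condition, phase) keys:\n{dupes}")
    return df
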