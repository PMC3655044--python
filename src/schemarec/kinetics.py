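"""Enzyme-kinetics characterization: Michaelis-Menten, pH profile, Arrhenius.

Each model follows the Model/Results idiom: construct the model from data,
call ``fit()``, and read estimates, standard errors and a ``summary()``
table off the returned Results object.

Units: substrate concentration in uM, temperatures in degrees Celsius,
activation energy in kJ/mol, specific activity in umol.min^-1.mg^-1,
turnover number k_cat in s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.314  # J mol^-1 K^-1
KELVIN_OFFSET = 273.15


class KineticsDomainError(ValueError):
    """Input data cannot support the requested fit."""


def specific_activity_to_kcat(v_max: float, molar_mass: float) -> float:
    """Convert v_max in umol min^-1 mg^-1 to k_cat in s^-1.

    k_cat = v_max * molar_mass / 60000 (umol -> mol, min -> s, mg -> g).
    """
    if v_max <= 0 or molar_mass <= 0:
        raise KineticsDomainError("v_max and molar mass must be positive")
    return v_max * molar_mass / 60000.0


def kcat_to_specific_activity(k_cat: float, molar_mass: float) -> float:
    if k_cat <= 0 or molar_mass <= 0:
        raise KineticsDomainError("k_cat and molar mass must be positive")
    return k_cat * 60000.0 / molar_mass


def catalytic_efficiency(k_cat: float, k_m: float) -> float:
    """k_cat / K_M in s^-1 uM^-1 at full precision (0 when k_cat is 0)."""
    if k_m <= 0:
        raise KineticsDomainError("K_M must be positive")
    return k_cat / k_m


def round_sigfigs(x: float, n: int = 2) -> float:
    """Round to n significant figures (display convention for efficiencies)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))


def _covariance_se(jac: np.ndarray, residuals: np.ndarray, n_params: int) -> np.ndarray:
    """Standard errors from the Jacobian at the optimum."""
    n = len(residuals)
    dof = max(n - n_params, 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

def michaelis_menten(s, v_max, k_m):
    s = np.asarray(s, dtype=float)
    return v_max * s / (k_m + s)


@dataclass(frozen=True)
class MichaelisMentenResults:
    v_max: float
    k_m: float
    v_max_se: float
    k_m_se: float
    rss: float
    converged: bool
    n_obs: int
    rate_unit: str
    molar_mass: float | None

    @property
    def params(self) -> tuple[float, float]:
        return (self.v_max, self.k_m)

    @property
    def bse(self) -> tuple[float, float]:
        return (self.v_max_se, self.k_m_se)

    @property
    def k_cat(self) -> float | None:
        """Turnover number in s^-1.

        Equal to v_max when rates were already turnover numbers; converted
        through the molar mass when rates were specific activities.
        """
        if self.rate_unit == "per_second":
            return self.v_max
        if self.molar_mass is not None:
            return specific_activity_to_kcat(self.v_max, self.molar_mass)
        return None

    @property
    def k_cat_se(self) -> float | None:
        if self.rate_unit == "per_second":
            return self.v_max_se
        if self.molar_mass is not None:
            return self.v_max_se * self.molar_mass / 60000.0
        return None

    @property
    def efficiency(self) -> float | None:
        """k_cat / K_M in s^-1 uM^-1 (full precision)."""
        kc = self.k_cat
        return None if kc is None else catalytic_efficiency(kc, self.k_m)

    def predict(self, s):
        return michaelis_menten(s, self.v_max, self.k_m)

    def summary(self) -> str:
        unit = "s^-1" if self.rate_unit == "per_second" else "umol/min/mg"
        lines = [
            "Michaelis-Menten fit",
            f"  n observations : {self.n_obs}",
            f"  v_max          : {self.v_max:.4g} +/- {self.v_max_se:.2g} {unit}",
            f"  K_M            : {self.k_m:.4g} +/- {self.k_m_se:.2g} uM",
        ]
        if self.k_cat is not None:
            lines.append(f"  k_cat          : {self.k_cat:.4g} s^-1")
            lines.append(
                f"  k_cat/K_M      : {self.efficiency:.4g} s^-1 uM^-1 "
                f"(displays as {round_sigfigs(self.efficiency, 2):g})"
            )
        lines.append(f"  RSS            : {self.rss:.4g}")
        lines.append(f"  converged      : {self.converged}")
        return "\n".join(lines)


class MichaelisMentenModel:
    """Nonlinear least squares for v = v_max * S / (K_M + S).

    Parameters
    ----------
    substrate_uM, rate : array-like
        Initial-rate measurements; rates may be turnover numbers
        (``rate_unit='per_second'``, the default) or specific activities
        (``rate_unit='specific_activity'``, converted to k_cat through
        ``molar_mass`` when given).
    weights : {'none', '1/v2'}
        Unweighted by default; '1/v2' weights residuals by 1/rate^2.
    """

    def __init__(self, substrate_uM, rate, rate_unit: str = "per_second",
                 molar_mass: float | None = None, weights: str = "none"):
        self.s = np.asarray(substrate_uM, dtype=float)
        self.v = np.asarray(rate, dtype=float)
        if self.s.shape != self.v.shape or self.s.ndim != 1:
            raise KineticsDomainError("substrate and rate must be 1-D and equal length")
        if np.any(self.s <= 0):
            raise KineticsDomainError("substrate concentrations must be positive")
        if np.any(self.v < 0):
            raise KineticsDomainError("rates must be non-negative")
        if len(np.unique(self.s)) < 3:
            raise KineticsDomainError("need at least 3 distinct substrate concentrations")
        if rate_unit not in ("per_second", "specific_activity"):
            raise ValueError(f"unknown rate_unit {rate_unit!r}")
        if weights not in ("none", "1/v2"):
            raise ValueError(f"unknown weights {weights!r}")
        self.rate_unit = rate_unit
        self.molar_mass = molar_mass
        self.weights = weights

    @classmethod
    def from_dataframe(cls, df, substrate_col="substrate_uM", rate_col="rate", **kw):
        return cls(df[substrate_col].to_numpy(), df[rate_col].to_numpy(), **kw)

    def _initial_guess(self) -> tuple[float, float]:
        # Hanes-Woolf linearization: S/v = S/v_max + K_M/v_max
        mask = self.v > 0
        if mask.sum() >= 2:
            x, y = self.s[mask], self.s[mask] / self.v[mask]
            slope, intercept = np.polyfit(x, y, 1)
            if slope > 0 and intercept > 0:
                return 1.0 / slope, intercept / slope
        return float(self.v.max() or 1.0), float(np.median(self.s))

    def fit(self) -> MichaelisMentenResults:
        w = 1.0 / np.clip(self.v, 1e-300, None) if self.weights == "1/v2" else np.ones_like(self.v)

        def resid(p):
            return w * (michaelis_menten(self.s, *p) - self.v)

        p0 = self._initial_guess()
        res = least_squares(
            resid, p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=500,
        )
        converged = bool(res.success) and np.all(res.x > 0)
        se = _covariance_se(res.jac, res.fun, 2)
        raw = michaelis_menten(self.s, *res.x) - self.v
        return MichaelisMentenResults(
            v_max=float(res.x[0]), k_m=float(res.x[1]),
            v_max_se=float(se[0]), k_m_se=float(se[1]),
            rss=float(raw @ raw), converged=converged, n_obs=len(self.v),
            rate_unit=self.rate_unit, molar_mass=self.molar_mass,
        )


# ---------------------------------------------------------------------------
# pH profile (diprotic bell)
# ---------------------------------------------------------------------------

def diprotic_rate(ph, v_opt, pka_acidic, pka_basic):
    """Bell-shaped activity from two ionizable catalytic residues."""
    ph = np.asarray(ph, dtype=float)
    return v_opt / (1.0 + 10.0 ** (pka_acidic - ph) + 10.0 ** (ph - pka_basic))


@dataclass(frozen=True)
class PHProfileResults:
    v_opt: float
    pka_acidic: float
    pka_basic: float
    bse: tuple[float, float, float]
    rss: float
    converged: bool
    boundary_warning: bool
    n_obs: int
    argmax_ph: float

    @property
    def ph_optimum(self) -> float:
        """Model optimum: midpoint of the two pKa values."""
        return 0.5 * (self.pka_acidic + self.pka_basic)

    def predict(self, ph):
        return diprotic_rate(ph, self.v_opt, self.pka_acidic, self.pka_basic)

    def summary(self) -> str:
        return "\n".join([
            "Diprotic pH-profile fit",
            f"  n observations : {self.n_obs}",
            f"  v_opt          : {self.v_opt:.4g} +/- {self.bse[0]:.2g}",
            f"  pKa (acidic)   : {self.pka_acidic:.4g} +/- {self.bse[1]:.2g}",
            f"  pKa (basic)    : {self.pka_basic:.4g} +/- {self.bse[2]:.2g}",
            f"  pH optimum     : {self.ph_optimum:.4g} (model), {self.argmax_ph:g} (argmax of data)",
            f"  converged      : {self.converged}"
            + ("  [boundary warning: optimum at edge of measured range]" if self.boundary_warning else ""),
        ])


class PHProfileModel:
    """Fit v(pH) = v_opt / (1 + 10^(pKa1 - pH) + 10^(pH - pKa2)).

    The model optimum (pKa1 + pKa2)/2 is reported alongside the plain argmax
    of the measured profile, which makes no model assumption.
    """

    def __init__(self, ph, rate):
        self.ph = np.asarray(ph, dtype=float)
        self.v = np.asarray(rate, dtype=float)
        if self.ph.shape != self.v.shape or self.ph.ndim != 1:
            raise KineticsDomainError("pH and rate must be 1-D and equal length")
        if len(np.unique(self.ph)) < 4:
            raise KineticsDomainError("need at least 4 distinct pH points")

    @classmethod
    def from_dataframe(cls, df, ph_col="pH", rate_col="rate"):
        return cls(df[ph_col].to_numpy(), df[rate_col].to_numpy())

    def fit(self) -> PHProfileResults:
        imax = int(np.argmax(self.v))
        ph_max = float(self.ph[imax])
        boundary = imax in (int(np.argmin(self.ph)), int(np.argmax(self.ph)))
        p0 = (float(self.v[imax]) or 1.0, ph_max - 1.0, ph_max + 1.0)

        def resid(p):
            return diprotic_rate(self.ph, *p) - self.v

        res = least_squares(resid, p0, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
        v_opt, pka1, pka2 = (float(x) for x in res.x)
        converged = bool(res.success) and v_opt > 0 and pka1 < pka2
        se = _covariance_se(res.jac, res.fun, 3)
        return PHProfileResults(
            v_opt=v_opt, pka_acidic=pka1, pka_basic=pka2,
            bse=tuple(float(x) for x in se), rss=float(res.fun @ res.fun),
            converged=converged, boundary_warning=boundary,
            n_obs=len(self.v), argmax_ph=ph_max,
        )


# ---------------------------------------------------------------------------
# Temperature: Arrhenius and optimum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrheniusResults:
    activation_energy: float  # kJ/mol
    ln_a: float
    activation_energy_se: float
    ln_a_se: float
    temperatures_used: tuple[float, ...]  # degrees C
    n_obs: int
    rss: float = field(default=float("nan"))

    @property
    def params(self) -> tuple[float, float]:
        return (self.activation_energy, self.ln_a)

    def predict(self, temp_C):
        t_k = np.asarray(temp_C, dtype=float) + KELVIN_OFFSET
        return np.exp(self.ln_a - self.activation_energy * 1000.0 / (R_GAS * t_k))

    def summary(self) -> str:
        lo, hi = min(self.temperatures_used), max(self.temperatures_used)
        return "\n".join([
            "Arrhenius fit  (ln k vs 1/T)",
            f"  n observations : {self.n_obs}",
            f"  E_a            : {self.activation_energy:.4g} +/- "
            f"{self.activation_energy_se:.2g} kJ/mol",
            f"  ln A           : {self.ln_a:.4g} +/- {self.ln_a_se:.2g}",
            f"  T range used   : {lo:g}-{hi:g} C",
        ])


class ArrheniusModel:
    """Linear least squares of ln(rate) on 1/T(K); E_a = -slope * R.

    Only the ascending limb of the activity-temperature profile (at or below
    the measured optimum) obeys Arrhenius behaviour; above the optimum
    inactivation dominates, so those points are excluded by default. An
    optional per-temperature ``correction`` factor column multiplies the
    rates before fitting (e.g. for temperature-dependent readout intensity).
    """

    def __init__(self, temp_C, rate, correction=None):
        self.t = np.asarray(temp_C, dtype=float)
        self.v = np.asarray(rate, dtype=float)
        if correction is not None:
            self.v = self.v * np.asarray(correction, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise KineticsDomainError("temperature and rate must be 1-D and equal length")
        if np.any(self.v <= 0):
            raise KineticsDomainError("rates must be positive for the log transform")

    @classmethod
    def from_dataframe(cls, df, temp_col="temp_C", rate_col="rate", correction_col=None):
        corr = df[correction_col].to_numpy() if correction_col else None
        return cls(df[temp_col].to_numpy(), df[rate_col].to_numpy(), correction=corr)

    def fit(self, ascending_limb_only: bool = True) -> ArrheniusResults:
        t, v = self.t, self.v
        if ascending_limb_only:
            t_opt = t[int(np.argmax(v))]
            keep = t <= t_opt
            t, v = t[keep], v[keep]
        if len(np.unique(t)) < 3:
            raise KineticsDomainError("need at least 3 temperatures on the ascending limb")
        x = 1.0 / (t + KELVIN_OFFSET)
        y = np.log(v)
        # closed-form simple linear regression
        xbar, ybar = x.mean(), y.mean()
        sxx = float(((x - xbar) ** 2).sum())
        slope = float(((x - xbar) * (y - ybar)).sum()) / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        rss = float(resid @ resid)
        n = len(x)
        s2 = rss / (n - 2) if n > 2 else float("nan")
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
        return ArrheniusResults(
            activation_energy=-slope * R_GAS / 1000.0,
            ln_a=intercept,
            activation_energy_se=float(slope_se * R_GAS / 1000.0),
            ln_a_se=float(intercept_se),
            temperatures_used=tuple(float(x) for x in sorted(set(t))),
            n_obs=n,
            rss=rss,
        )


@dataclass(frozen=True)
class TemperatureOptimum:
    temperature_C: float
    is_boundary: bool
    is_tie: bool


def temperature_optimum(temp_C, rate) -> TemperatureOptimum:
    """Argmax of activity over the measured temperature grid.

    Ties resolve to the lowest temperature; an optimum at the edge of the
    grid or a tie raises a warning since the true optimum may lie outside.
    """
    t = np.asarray(temp_C, dtype=float)
    v = np.asarray(rate, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or len(t) == 0:
        raise KineticsDomainError("temperature and rate must be 1-D, equal length, non-empty")
    vmax = v.max()
    winners = t[v == vmax]
    is_tie = len(winners) > 1
    topt = float(winners.min())
    is_boundary = topt in (float(t.min()), float(t.max()))
    if is_tie:
        warnings.warn("tied maximal activity; reporting the lowest temperature")
    if is_boundary:
        warnings.warn("optimum at the edge of the measured grid")
    return TemperatureOptimum(topt, is_boundary, is_tie)
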