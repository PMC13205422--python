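"""Release-curve processing, kinetic model fitting, AUC summarization and
descriptor–release correlation.

Kinetic models (fractional release f = Mt/M∞ as a function of time t in h):

    zero order        f = k0 · t
    first order       f = 1 − exp(−k1 · t)
    Higuchi           f = kH · sqrt(t)
    Korsmeyer–Peppas  f = kKP · t^n

The Korsmeyer–Peppas exponent classifies the transport mechanism:
n < 0.5 is Fickian (diffusion-controlled) for this geometry convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

KINETIC_MODELS = ("zero_order", "first_order", "higuchi", "korsmeyer_peppas")


class FitFailureError(RuntimeError):
    pass


class InsufficientPointsError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class SystemID:
    """Parsed 'Polymer-AAcPct-{L,H}-{298,310}' system identifier."""

    polymer: str
    aac_mol_pct: int
    ph_label: str    # 'L' (pH 2.75) or 'H' (pH 7.4)
    temp_K: int
    urea: bool = False

    @classmethod
    def parse(cls, text: str, urea: bool = False) -> "SystemID":
        parts = text.replace("–", "-").split("-")
        if len(parts) != 4 or parts[2] not in ("L", "H"):
            raise ValueError(f"malformed system id {text!r}")
        return cls(polymer=parts[0], aac_mol_pct=int(parts[1]),
                   ph_label=parts[2], temp_K=int(parts[3]), urea=urea)

    @property
    def material(self) -> str:
        """Material key (composition), e.g. 'CA-15'."""
        return f"{self.polymer}-{self.aac_mol_pct}"

    def __str__(self) -> str:
        return f"{self.polymer}-{self.aac_mol_pct}-{self.ph_label}-{self.temp_K}"


@dataclass
class ReleaseProfile:
    system_id: str
    times_h: np.ndarray
    cumulative_pct: np.ndarray
    sd_pct: np.ndarray | None = None
    n_replicates: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, float)
        self.cumulative_pct = np.asarray(self.cumulative_pct, float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sd_pct is not None:
            self.sd_pct = np.asarray(self.sd_pct, float)


@dataclass
class KineticFit:
    model: str
    params: dict
    r_squared: float
    mechanism: str | None = None  # Korsmeyer–Peppas only


def cumulative_release(concentrations_mg_ml, V_ml: float, M_mg: float,
                       times_h, withdrawn_ml: float = 1.0,
                       replace: bool = True, system_id: str = "",
                       **profile_kw) -> ReleaseProfile:
    """Cumulative release (%) from sampled medium concentrations.

    With ``replace=False`` the literal running-sum formula
    Σ C_t·V/M·100 is used.  With ``replace=True`` (default, matching a
    sample-and-replenish protocol) the standard withdrawal correction is
    applied: release_t = (C_t·V + withdrawn·Σ_{s<t} C_s) / M · 100.
    """
    if M_mg <= 0 or V_ml <= 0:
        raise ValueError("V and M must be positive")
    c = np.asarray(concentrations_mg_ml, float)
    if replace:
        prior = np.concatenate(([0.0], np.cumsum(c)[:-1]))
        release = (c * V_ml + withdrawn_ml * prior) / M_mg * 100.0
    else:
        release = np.cumsum(c) * V_ml / M_mg * 100.0
    if np.any(release > 100.0):
        warnings.warn("cumulative release exceeds 100% (mass-balance violation)")
    meta = dict(profile_kw.pop("metadata", {}))
    meta["withdrawal_corrected"] = replace
    return ReleaseProfile(system_id=system_id, times_h=times_h,
                          cumulative_pct=release, metadata=meta, **profile_kw)


def _model_fn(model: str):
    return {
        "zero_order": lambda t, k0: k0 * t,
        "first_order": lambda t, k1: 1.0 - np.exp(-k1 * t),
        "higuchi": lambda t, kH: kH * np.sqrt(t),
        "korsmeyer_peppas": lambda t, k, n: k * np.power(t, n),
    }[model]


def fit_kinetics(profile: ReleaseProfile, model: str, log_log: bool = False) -> KineticFit:
    """Least-squares fit of one kinetic model to a release profile.

    Cumulative percent is converted to fractional release (/100).  The
    zero-order and Higuchi models are linear through the origin and solved
    in closed form; first-order and Korsmeyer–Peppas use nonlinear least
    squares on the untransformed model (``log_log=True`` switches the
    Korsmeyer–Peppas fit to the classical log–log regression).  R² is
    1 − SSres/SStot and can go negative for the through-origin models.
    """
    if model not in KINETIC_MODELS:
        raise ValueError(f"unknown model {model!r}")
    t = profile.times_h
    y = profile.cumulative_pct / 100.0
    n_min = 4 if model == "korsmeyer_peppas" else 3
    if len(t) < n_min:
        raise InsufficientPointsError(f"{model} needs >= {n_min} points")
    fn = _model_fn(model)
    mechanism = None
    if model == "zero_order":
        params = {"k0": float(np.sum(t * y) / np.sum(t * t))}
    elif model == "higuchi":
        s = np.sqrt(t)
        params = {"kH": float(np.sum(s * y) / np.sum(s * s))}
    elif model == "first_order":
        try:
            popt, _ = optimize.curve_fit(fn, t, y, p0=[0.1], maxfev=10_000)
        except RuntimeError as err:
            raise FitFailureError(f"first-order fit failed: {err}") from err
        params = {"k1": float(popt[0])}
    else:
        pos = (t > 0) & (y > 0)
        if pos.sum() >= 2:
            b, a = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)
            p0 = [float(np.exp(a)), float(b)]
        else:
            p0 = [0.3, 0.4]
        if log_log:
            if pos.sum() < n_min:
                raise InsufficientPointsError("log-log fit needs positive data")
            params = {"kKP": p0[0], "n": p0[1]}
        else:
            try:
                popt, _ = optimize.curve_fit(fn, t, y, p0=p0, maxfev=20_000)
            except RuntimeError as err:
                raise FitFailureError(f"Korsmeyer-Peppas fit failed: {err}") from err
            params = {"kKP": float(popt[0]), "n": float(popt[1])}
        if params["n"] <= 0:
            warnings.warn("Korsmeyer-Peppas exponent at or below zero")
        mechanism = classify_transport(params["n"]) if params["n"] > 0 else None
    if any(v < 0 for v in params.values()):
        warnings.warn(f"negative parameter at optimum: {params}")
    pred = fn(t, *params.values())
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return KineticFit(model=model, params=params, r_squared=float(r2), mechanism=mechanism)


def classify_transport(n: float) -> str:
    """Transport mechanism label from the Korsmeyer–Peppas exponent.

    n < 0.5 → Fickian diffusion; n = 0.5 exactly coincides with the
    Higuchi model (labelled as the boundary); 0.5 < n → anomalous
    (non-Fickian) transport.
    """
    if n <= 0:
        raise ValueError("exponent must be positive")
    if n < 0.5:
        return "Fickian"
    if n == 0.5:
        return "case-II-boundary/Higuchi"
    return "anomalous"


def auc_release(profile: ReleaseProfile, t_start: float = 1.0, t_end: float = 24.0) -> float:
    """Trapezoidal area under the cumulative-release curve on
    [t_start, t_end] (%·h), linearly interpolating absent endpoints."""
    t, y = profile.times_h, profile.cumulative_pct
    inside = (t > t_start) & (t < t_end)
    if t_start < t[0] or t_end > t[-1]:
        raise InsufficientPointsError("AUC window extends beyond the profile")
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    yy = np.concatenate(([np.interp(t_start, t, y)], y[inside], [np.interp(t_end, t, y)]))
    if len(tt) < 2:
        raise InsufficientPointsError("need at least 2 points in the AUC window")
    return float(np.trapezoid(yy, tt))


# ---------------------------------------------------------------------------
# descriptor table, centering, correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    descriptor: str
    rho: float
    p_value: float
    n: int
    method: str = "spearman (t-approximation)"


def center_within_material(records: pd.DataFrame, material_key: str = "material",
                           columns: list[str] | None = None) -> pd.DataFrame:
    """Subtract each material's own mean from every numeric descriptor.

    Removes composition baseline differences before correlation; rows with
    missing values in the centered columns are dropped (logged via warning).
    """
    df = records.copy()
    if columns is None:
        columns = [c for c in df.columns
                   if c != material_key and pd.api.types.is_numeric_dtype(df[c])]
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} record(s) with missing values")
        df = df[~bad]
    df[columns] = df[columns] - df.groupby(material_key)[columns].transform("mean")
    return df


def spearman(x, y, descriptor: str = "") -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks with a
    two-sided p-value from the t-approximation (n − 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise UndefinedCorrelationError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(descriptor=descriptor, rho=float(rho),
                             p_value=float(p), n=len(x))


def correlate_descriptors(records: pd.DataFrame, descriptors: list[str],
                          response: str = "auc_1_24h",
                          material_key: str = "material",
                          centered: bool = True) -> list[CorrelationResult]:
    """Spearman correlation of each descriptor with the release response,
    optionally after within-material centering."""
    cols = descriptors + [response]
    df = center_within_material(records, material_key, cols) if centered else records
    return [spearman(df[d].to_numpy(), df[response].to_numpy(), descriptor=d)
            for d in descriptors]
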