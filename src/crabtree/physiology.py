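"""Fermentation physiology: growth rates, specific rates, yields, gas
transfer and carbon balance for batch and chemostat cultures.

Conventions
-----------
* Biomass in gDW/L, species concentrations in g/L, time in hours.
* Specific glucose uptake is reported in C-mmol/gDW/h using 30.026 mg per
  C-mmol of glucose (180.156 / 6).
* Off-gas balances use an inert-gas (N2) correction for the outlet flow and
  a molar gas volume of 24.055 L/mol (25 degC, 1 atm) by default.
* Biomass carbon content follows the standard C-mol formula CH1.8O0.5N0.2
  (24.63 g per C-mol), configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FermentationProfile",
    "PhysioSummary",
    "GrowthFit",
    "fit_growth_rate",
    "compute_specific_uptake",
    "compute_yields",
    "gas_rates",
    "carbon_balance",
    "steady_state_windows",
    "physio_summary",
    "GLUCOSE_MG_PER_CMMOL",
    "MOLAR_GAS_VOLUME",
    "BIOMASS_G_PER_CMOL",
    "CARBON_CONTENT",
]

GLUCOSE_MG_PER_CMMOL = 30.026     # mg glucose per C-mmol (180.156 / 6)
MOLAR_GAS_VOLUME = 24.055         # L/mol at 25 degC, 1 atm
BIOMASS_G_PER_CMOL = 24.63        # CH1.8O0.5N0.2
O2_G_PER_MMOL = 0.032
CO2_G_PER_MMOL = 0.04401

# C-mmol per gram
CARBON_CONTENT = {
    "glucose": 6000.0 / 180.156,
    "ethanol": 2000.0 / 46.069,
    "glycerol": 3000.0 / 92.094,
    "acetate": 2000.0 / 60.052,
    "pyruvate": 3000.0 / 88.062,
}

PRODUCT_SPECIES = ("ethanol", "glycerol", "acetate", "pyruvate")

OFFGAS_COLUMNS = ("y_o2_in", "y_co2_in", "y_o2_out", "y_co2_out", "gas_flow", "volume")


@dataclass
class FermentationProfile:
    """Time series of a batch or chemostat cultivation.

    ``data`` has one row per time point with columns: time, biomass,
    glucose, and optionally the product species and the off-gas columns
    (inlet/outlet O2 and CO2 mole fractions, gas flow L/h, liquid volume L).
    Chemostat profiles additionally carry the dilution rate ``D`` (1/h) and
    feed glucose ``S_in`` (g/L).
    """

    mode: str
    data: pd.DataFrame
    D: Optional[float] = None
    S_in: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("batch", "chemostat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        t = self.data["time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        for col in ("biomass", "glucose") + tuple(
                c for c in PRODUCT_SPECIES if c in self.data.columns):
            if (self.data[col] < 0).any():
                raise ValueError(f"negative values in column {col}")
        if self.mode == "chemostat" and (self.D is None or self.S_in is None):
            raise ValueError("chemostat profiles require D and S_in")

    @property
    def has_offgas(self) -> bool:
        return all(c in self.data.columns for c in OFFGAS_COLUMNS)

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.attrs = {}
        header = [f"# mode={self.mode}"]
        if self.mode == "chemostat":
            header.append(f"# D={self.D}")
            header.append(f"# S_in={self.S_in}")
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FermentationProfile":
        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        df = pd.read_csv(path, skiprows=skip)
        mode = meta.get("mode", "batch")
        D = float(meta["D"]) if "D" in meta else None
        S_in = float(meta["S_in"]) if "S_in" in meta else None
        return cls(mode, df, D, S_in)


@dataclass
class GrowthFit:
    mu: float
    r_squared: float
    window: tuple[float, float]
    warning: Optional[str] = None


@dataclass
class PhysioSummary:
    mu_max: float
    mu_r_squared: float
    q_s_cmmol: float           # C-mmol/gDW/h
    q_s_mass: float            # g glucose/gDW/h
    yields: dict[str, float]   # Ysx, YsEtOH, YsGly, YsAc, YsPyr (g/g glucose)
    otr: Optional[float]       # mmol O2/L/h (window mean)
    ctr: Optional[float]       # mmol CO2/L/h
    otr_specific: Optional[float]  # g O2/gDW/h
    ctr_specific: Optional[float]  # g CO2/gDW/h
    rq: Optional[float]
    carbon_recovery: Optional[float]
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("mu_max [1/h]", self.mu_max),
                ("q_s [C-mmol/gDW/h]", self.q_s_cmmol),
                ("Ysx [g/g]", self.yields.get("Ysx")),
                ("YsEtOH [g/g]", self.yields.get("YsEtOH")),
                ("YsGly [g/g]", self.yields.get("YsGly")),
                ("YsAc [g/g]", self.yields.get("YsAc")),
                ("YsPyr [g/g]", self.yields.get("YsPyr")),
                ("OTR [mmol/L/h]", self.otr),
                ("CTR [mmol/L/h]", self.ctr),
                ("OTR [g/gDW/h]", self.otr_specific),
                ("RQ [-]", self.rq),
                ("carbon recovery [-]", self.carbon_recovery)]
        return pd.DataFrame(rows, columns=["parameter", "value"])


# ---------------------------------------------------------------------------
# Growth rate
# ---------------------------------------------------------------------------

def _linreg(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2 (R^2 = 1 for constant y)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    if sxx == 0:
        raise ValueError("degenerate regression: no spread in x")
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 1.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2


def fit_growth_rate(profile: FermentationProfile,
                    window: Optional[tuple[float, float]] = None,
                    r2_threshold: float = 0.999) -> GrowthFit:
    """Maximum specific growth rate from ln(biomass) vs time.

    With an explicit ``window`` (t_start, t_end) the regression runs over
    the points inside it.  Otherwise the longest contiguous window with
    R^2 >= ``r2_threshold`` (ties broken toward the earlier window) is
    auto-selected; if no 3-point window qualifies, the full range is used
    and a warning flag set.
    """
    df = profile.data
    mask = df["biomass"] > 0
    t = df.loc[mask, "time"].to_numpy(dtype=float)
    lnx = np.log(df.loc[mask, "biomass"].to_numpy(dtype=float))
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, lnx = t[sel], lnx[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 points with positive biomass")
    warning = None
    if window is None:
        best = None
        n = len(t)
        for i in range(n - 2):
            for j in range(i + 2, n):
                _, _, r2 = _linreg(t[i:j + 1], lnx[i:j + 1])
                if r2 >= r2_threshold:
                    length = j - i
                    key = (length, -i)
                    if best is None or key > best[0]:
                        best = (key, (i, j))
        if best is None:
            i, j = 0, n - 1
            warning = f"no window reached R^2 >= {r2_threshold}; used full range"
        else:
            i, j = best[1]
        t, lnx = t[i:j + 1], lnx[i:j + 1]
    slope, _, r2 = _linreg(t, lnx)
    if slope <= 0 and warning is None:
        warning = "non-increasing biomass: mu <= 0"
    return GrowthFit(mu=float(slope), r_squared=float(r2),
                     window=(float(t[0]), float(t[-1])), warning=warning)


# ---------------------------------------------------------------------------
# Specific rates and yields
# ---------------------------------------------------------------------------

def _exponential_window(profile: FermentationProfile) -> np.ndarray:
    fit = fit_growth_rate(profile)
    t = profile.data["time"].to_numpy(dtype=float)
    return (t >= fit.window[0]) & (t <= fit.window[1])


def compute_specific_uptake(profile: FermentationProfile,
                            mu: Optional[float] = None) -> float:
    """Specific glucose consumption rate q_s in C-mmol/gDW/h.

    Batch: q_s = mu * |dS/dX| with dS/dX from regressing glucose on biomass
    over the exponential window.  Chemostat: q_s = D (S_in - S) / X.
    """
    df = profile.data
    if profile.mode == "chemostat":
        X = float(df["biomass"].iloc[-1])
        S = float(df["glucose"].iloc[-1])
        if X <= 0:
            raise ValueError("zero biomass in chemostat profile")
        q_mass = profile.D * (profile.S_in - S) / X    # g/gDW/h
        return q_mass * 1000.0 / GLUCOSE_MG_PER_CMMOL
    if mu is None:
        mu = fit_growth_rate(profile).mu
    sel = _exponential_window(profile)
    X = df.loc[sel, "biomass"].to_numpy(dtype=float)
    S = df.loc[sel, "glucose"].to_numpy(dtype=float)
    if np.allclose(S, S[0]):
        return 0.0
    slope, _, _ = _linreg(X, S)
    q_mass = mu * abs(slope)
    return q_mass * 1000.0 / GLUCOSE_MG_PER_CMMOL


def compute_yields(profile: FermentationProfile) -> dict[str, float]:
    """Yields on glucose in g/g: Ysx plus product yields.

    Batch yields are slopes over the exponential window (concentration
    regressed on glucose); chemostat yields are X/(S_in - S), P/(S_in - S).
    """
    df = profile.data
    label = {"ethanol": "YsEtOH", "glycerol": "YsGly",
             "acetate": "YsAc", "pyruvate": "YsPyr"}
    out: dict[str, float] = {}
    if profile.mode == "chemostat":
        S = float(df["glucose"].iloc[-1])
        dS = profile.S_in - S
        if dS <= 0:
            raise ValueError("no glucose consumed (S_in <= S)")
        out["Ysx"] = float(df["biomass"].iloc[-1]) / dS
        for sp, name in label.items():
            out[name] = float(df[sp].iloc[-1]) / dS if sp in df.columns else 0.0
        return out
    sel = _exponential_window(profile)
    S = df.loc[sel, "glucose"].to_numpy(dtype=float)
    if np.allclose(S, S[0]):
        raise ValueError("no glucose consumed over the exponential window")
    slope, _, _ = _linreg(S, df.loc[sel, "biomass"].to_numpy(dtype=float))
    out["Ysx"] = abs(slope)
    for sp, name in label.items():
        if sp in df.columns:
            slope, _, _ = _linreg(S, df.loc[sel, sp].to_numpy(dtype=float))
            out[name] = abs(slope) if not np.allclose(df.loc[sel, sp], df.loc[sel, sp].iloc[0]) else 0.0
        else:
            out[name] = 0.0
    return out


# ---------------------------------------------------------------------------
# Gas transfer
# ---------------------------------------------------------------------------

def gas_rates(profile: FermentationProfile,
              molar_volume: float = MOLAR_GAS_VOLUME) -> pd.DataFrame:
    """Per-time-point OTR and CTR (mmol/L/h) from the off-gas balance.

    The outlet flow is corrected by the inert-gas balance
    F_out = F_in (1 - yO2_in - yCO2_in) / (1 - yO2_out - yCO2_out);
    OTR = (F_in yO2_in - F_out yO2_out) / (V Vm) and CTR analogously with
    reversed signs.  Also returns RQ = CTR/OTR per point (NaN if OTR = 0).
    """
    if not profile.has_offgas:
        raise ValueError("profile has no off-gas data")
    df = profile.data
    y_o2_in = df["y_o2_in"].to_numpy(dtype=float)
    y_co2_in = df["y_co2_in"].to_numpy(dtype=float)
    y_o2_out = df["y_o2_out"].to_numpy(dtype=float)
    y_co2_out = df["y_co2_out"].to_numpy(dtype=float)
    F_in = df["gas_flow"].to_numpy(dtype=float)
    V = df["volume"].to_numpy(dtype=float)
    inert_out = 1.0 - y_o2_out - y_co2_out
    if np.any(inert_out <= 0):
        raise ValueError("degenerate off-gas composition: outlet inert fraction <= 0")
    F_out = F_in * (1.0 - y_o2_in - y_co2_in) / inert_out
    otr = 1000.0 * (F_in * y_o2_in - F_out * y_o2_out) / (V * molar_volume)
    ctr = 1000.0 * (F_out * y_co2_out - F_in * y_co2_in) / (V * molar_volume)
    with np.errstate(divide="ignore", invalid="ignore"):
        rq = np.where(otr != 0, ctr / otr, np.nan)
    return pd.DataFrame({"time": df["time"], "otr": otr, "ctr": ctr, "rq": rq})


# ---------------------------------------------------------------------------
# Carbon balance and steady state
# ---------------------------------------------------------------------------

def carbon_balance(profile: FermentationProfile, summary: "PhysioSummary",
                   biomass_g_per_cmol: float = BIOMASS_G_PER_CMOL) -> tuple[float, bool]:
    """Carbon recovery fraction on a specific-rate basis.

    recovery = (C into biomass + CO2 + secreted products) / (C from
    glucose), evaluated with the summary's specific rates.  Returns the
    recovery and a flag that is True when the CO2 term was available.
    """
    q_s = summary.q_s_cmmol
    if q_s <= 0:
        raise ValueError("no glucose consumption in summary")
    mu = summary.mu_max
    c_bio = mu * 1000.0 / biomass_g_per_cmol
    q_mass = summary.q_s_mass
    c_prod = 0.0
    for sp, name in (("ethanol", "YsEtOH"), ("glycerol", "YsGly"),
                     ("acetate", "YsAc"), ("pyruvate", "YsPyr")):
        y = summary.yields.get(name, 0.0)
        c_prod += y * q_mass * CARBON_CONTENT[sp]
    has_gas = summary.ctr_specific is not None
    c_co2 = (summary.ctr_specific / CO2_G_PER_MMOL) if has_gas else 0.0
    recovery = (c_bio + c_prod + c_co2) / q_s
    return float(recovery), has_gas


def steady_state_windows(profile: FermentationProfile,
                         max_drift: float = 0.02,
                         residence_times: float = 5.0) -> bool:
    """Flag whether the chemostat profile is at steady state.

    True when relative biomass drift over at least ``residence_times``/D
    hours stays below ``max_drift``.
    """
    if profile.mode != "chemostat":
        raise ValueError("steady-state detection applies to chemostat profiles")
    df = profile.data
    span = df["time"].iloc[-1] - df["time"].iloc[0]
    if span < residence_times / profile.D - 1e-9:
        return False
    X = df["biomass"].to_numpy(dtype=float)
    return bool((X.max() - X.min()) <= max_drift * max(X.mean(), 1e-12))


def physio_summary(profile: FermentationProfile) -> PhysioSummary:
    """Full physiological characterization of a profile (Table-1 style)."""
    flags: list[str] = []
    if profile.mode == "chemostat":
        mu, r2 = float(profile.D), 1.0
        if not steady_state_windows(profile):
            flags.append("chemostat not at steady state")
    else:
        fit = fit_growth_rate(profile)
        mu, r2 = fit.mu, fit.r_squared
        if fit.warning:
            flags.append(fit.warning)
    q_s = compute_specific_uptake(profile, mu)
    q_mass = q_s * GLUCOSE_MG_PER_CMMOL / 1000.0
    yields = compute_yields(profile)
    otr = ctr = rq = otr_sp = ctr_sp = None
    if profile.has_offgas:
        gas = gas_rates(profile)
        if profile.mode == "batch":
            sel = _exponential_window(profile)
        else:
            sel = np.ones(len(gas), dtype=bool)
        otr = float(gas.loc[sel, "otr"].mean())
        ctr = float(gas.loc[sel, "ctr"].mean())
        X = profile.data.loc[sel, "biomass"].to_numpy(dtype=float)
        t = profile.data.loc[sel, "time"].to_numpy(dtype=float)
        # specific rates averaged pointwise (gas rate per unit biomass)
        with np.errstate(divide="ignore", invalid="ignore"):
            otr_sp = float(np.nanmean(np.where(X > 0, gas.loc[sel, "otr"] * O2_G_PER_MMOL / X, np.nan)))
            ctr_sp = float(np.nanmean(np.where(X > 0, gas.loc[sel, "ctr"] * CO2_G_PER_MMOL / X, np.nan)))
        if otr == 0 and ctr == 0:
            rq = None
            flags.append("no gas composition change: RQ undefined")
        elif otr != 0:
            rq = float(ctr / otr)
    else:
        flags.append("no off-gas data: carbon recovery lacks the CO2 term")
    summary = PhysioSummary(mu_max=mu, mu_r_squared=r2, q_s_cmmol=q_s,
                            q_s_mass=q_mass, yields=yields, otr=otr, ctr=ctr,
                            otr_specific=otr_sp, ctr_specific=ctr_sp, rq=rq,
                            carbon_recovery=None, flags=flags)
    try:
        recovery, full = carbon_balance(profile, summary)
        summary.carbon_recovery = recovery
        if not full:
            summary.flags.append("carbon recovery computed without CO2 term")
    except ValueError:
        summary.flags.append("carbon recovery unavailable")
    return summary
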