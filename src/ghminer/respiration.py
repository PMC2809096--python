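"""Reactor respiration rates from gas mass balances.

With a known air flow F (mg air / day / gdw) and influent/effluent gas mass
fractions (mg gas / mg air), the only mass balance consistent with those
units is

    CER = F * (CO2_out - CO2_in)        (mg CO2 / day / gdw)
    OUR = F * (O2_in  - O2_out)         (mg O2  / day / gdw, uptake positive)

Cumulative respiration over the incubation is the composite trapezoid over
the sampling grid.  Rows flagged with mixing/water-addition events are real
measurements (the brief rate drops they cause are genuine) and are included
in the integral; sensor gaps are simply spanned by the trapezoid, never
interpolated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GAS_COLUMNS = ["t_day", "F", "co2_in", "co2_out", "o2_in", "o2_out"]


def _validate(df: pd.DataFrame) -> None:
    for col in GAS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gas table missing column {col!r}")
    if (df["F"] <= 0).any():
        raise ValueError("air flow F must be positive everywhere")
    conc = df[["co2_in", "co2_out", "o2_in", "o2_out"]]
    if (conc < 0).to_numpy().any():
        raise ValueError("gas concentrations must be non-negative")
    t = df["t_day"].to_numpy()
    if (np.diff(t) <= 0).any():
        raise ValueError("sample times must be strictly increasing")


def cer(df: pd.DataFrame) -> pd.Series:
    """Carbon dioxide evolution rate, mg CO2 / day / gdw."""
    _validate(df)
    return df["F"] * (df["co2_out"] - df["co2_in"])


def our(df: pd.DataFrame) -> pd.Series:
    """Oxygen uptake rate, mg O2 / day / gdw (uptake positive)."""
    _validate(df)
    return df["F"] * (df["o2_in"] - df["o2_out"])


def integrate(
    t: np.ndarray | pd.Series,
    rate: np.ndarray | pd.Series,
    window: tuple[float, float] | None = None,
) -> float:
    """Composite-trapezoid integral of a rate series, mg gas / gdw.

    ``window=(a, b)`` restricts to samples with ``a <= t <= b``; at least two
    samples must remain.
    """
    t = np.asarray(t, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if window is not None:
        a, b = window
        mask = (t >= a) & (t <= b)
        t, rate = t[mask], rate[mask]
    if len(t) < 2:
        raise ValueError("need at least two samples to integrate")
    return float(np.trapezoid(rate, t))


def rate_series(df: pd.DataFrame) -> pd.DataFrame:
    """Both rates on the sampling grid: columns ``t_day, CER, OUR``."""
    return pd.DataFrame({"t_day": df["t_day"], "CER": cer(df), "OUR": our(df)})


def summarize(df: pd.DataFrame) -> dict[str, float]:
    """Peak rates and cumulative totals over the whole series."""
    rates = rate_series(df)
    return {
        "peak_CER": float(rates["CER"].max()),
        "peak_OUR": float(rates["OUR"].max()),
        "total_CO2": integrate(rates["t_day"], rates["CER"]),
        "total_O2": integrate(rates["t_day"], rates["OUR"]),
    }


def load_gas_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate(df)
    return df
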