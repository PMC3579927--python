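"""Enzyme-inhibition model fitting: dose–response IC50 and inhibition kinetics.

Two models cover the standard fluorogenic protease assay readout (rate in
RFU/min against substrate and inhibitor concentrations in µM):

* a four-parameter logistic dose–response,
      y = Bottom + (Top − Bottom) / (1 + 10^((log10 IC50 − log10 X) · h)),
  where Top and Bottom are plateaus in rate units, IC50 is the
  concentration giving the half-way response, and h is the Hill slope
  (fit freely by default or fixed to 1);

* uncompetitive inhibition, where the inhibitor binds only the
  enzyme–substrate complex,
      v = Vmax · S / (Km + S · (1 + I / αKi)),
  reducing to Michaelis–Menten at I = 0.  A mixed-inhibition variant,
      v = Vmax · S / (Km · (1 + I/Ki) + S · (1 + I/αKi)),
  is provided for data sets where the pure uncompetitive mechanism is in
  doubt (it nests both uncompetitive, Ki → ∞, and non-competitive,
  Ki = αKi, behaviour).

Fits are unweighted least squares with IC50, Km, Ki and αKi parameterised
on the log scale to enforce positivity; standard errors for the natural-
scale parameters come from the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "InhibitionFit",
    "dose_response_model",
    "uncompetitive_model",
    "mixed_model",
    "fit_dose_response",
    "fit_uncompetitive",
    "fit_mixed",
    "simulate_kinetics",
    "simulate_dose_response",
    "serial_dilution",
    "read_kinetics_csv",
]

LN10 = np.log(10.0)


def serial_dilution(start_uM: float = 500.0, factor: float = 2.0, n: int = 16):
    """Concentrations (µM) of an n-step serial dilution from ``start_uM``.

    The default 2-fold, 16-step series from 500 µM reaches ~15 nM, covering
    the 10 nM – 500 µM window a plate-based IC50 titration typically spans.
    """
    if start_uM <= 0 or factor <= 1 or n < 1:
        raise ValueError("need start_uM > 0, factor > 1, n >= 1")
    return start_uM * (1.0 / factor) ** np.arange(n)


def dose_response_model(conc, top, bottom, log10_ic50, hill):
    """Four-parameter logistic in concentration (µM); conc must be > 0."""
    logx = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ic50 - logx) * hill))


def uncompetitive_model(s, i, vmax, km, alpha_ki):
    """v = Vmax·S / (Km + S·(1 + I/αKi)); rates in Vmax units, conc in µM."""
    return vmax * s / (km + s * (1.0 + i / alpha_ki))


def mixed_model(s, i, vmax, km, ki, alpha_ki):
    """v = Vmax·S / (Km·(1 + I/Ki) + S·(1 + I/αKi))."""
    return vmax * s / (km * (1.0 + i / ki) + s * (1.0 + i / alpha_ki))


@dataclass
class DoseResponseFit:
    """Dose–response fit result; ic50 in µM, plateaus in rate units."""

    top: float
    bottom: float
    log10_ic50: float
    hill: float
    se: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = False
    n_obs: int = 0
    cov: Optional[np.ndarray] = None

    @property
    def ic50(self) -> float:
        return float(10.0**self.log10_ic50)

    def predict(self, conc) -> np.ndarray:
        return dose_response_model(
            np.asarray(conc, float), self.top, self.bottom, self.log10_ic50, self.hill
        )


@dataclass
class InhibitionFit:
    """Kinetic fit result; vmax in rate units, km / (α)Ki in µM."""

    vmax: float
    km: float
    alpha_ki: float
    ki: Optional[float] = None  # mixed model only
    se: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = False
    n_obs: int = 0
    cov: Optional[np.ndarray] = None
    model: str = "uncompetitive"

    def predict(self, s, i) -> np.ndarray:
        s, i = np.asarray(s, float), np.asarray(i, float)
        if self.model == "mixed":
            return mixed_model(s, i, self.vmax, self.km, self.ki, self.alpha_ki)
        return uncompetitive_model(s, i, self.vmax, self.km, self.alpha_ki)


def _check_finite(name, arr):
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")


def fit_dose_response(
    conc: Sequence[float],
    response: Sequence[float],
    hill_mode: str = "variable",
) -> DoseResponseFit:
    """Fit the four-parameter logistic to (concentration, response) data.

    Zero concentrations are dropped with a warning (the model is defined on
    log10 X).  Needs at least 5 distinct concentrations spanning >= 2
    decades.  ``hill_mode='fixed_1'`` pins the Hill slope at 1.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(response, dtype=float)
    _check_finite("response", resp)
    if conc.shape != resp.shape:
        raise ValueError("concentration and response lengths differ")
    if np.any(conc < 0):
        raise ValueError("negative concentration")
    if np.any(conc == 0):
        warnings.warn("dropping zero-concentration rows (log scale)", stacklevel=2)
        keep = conc > 0
        conc, resp = conc[keep], resp[keep]
    distinct = np.unique(conc)
    if distinct.size < 5:
        raise ValueError("need >= 5 distinct non-zero concentrations")
    if np.log10(distinct.max() / distinct.min()) < 2.0:
        raise ValueError("concentrations must span >= 2 log units")
    if np.ptp(resp) == 0:
        raise ValueError("all responses equal; nothing to fit")

    top0, bottom0 = float(resp.max()), float(resp.min())
    half = (top0 + bottom0) / 2.0
    ic50_0 = float(conc[np.argmin(np.abs(resp - half))])
    if hill_mode == "variable":
        # crude slope sign from the data so the optimiser starts on the right branch
        hill0 = 1.0 if resp[np.argmax(conc)] >= resp[np.argmin(conc)] else -1.0
        p0 = [top0, bottom0, np.log10(ic50_0), hill0]

        def f(x, top, bottom, lic50, hill):
            return dose_response_model(x, top, bottom, lic50, hill)

    elif hill_mode == "fixed_1":
        p0 = [top0, bottom0, np.log10(ic50_0)]

        def f(x, top, bottom, lic50):
            return dose_response_model(x, top, bottom, lic50, 1.0)

    else:
        raise ValueError(f"unknown hill_mode {hill_mode!r}")

    converged = True
    try:
        popt, pcov = curve_fit(f, conc, resp, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"dose-response fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((f(conc, *popt) - resp) ** 2))
    if hill_mode == "fixed_1":
        popt = np.append(popt, 1.0)
        perr = np.append(perr, 0.0)
    names = ["top", "bottom", "log10_ic50", "hill"]
    se = dict(zip(names, perr))
    se["ic50"] = float(10.0 ** popt[2] * LN10 * se["log10_ic50"])  # delta method
    return DoseResponseFit(
        top=float(popt[0]),
        bottom=float(popt[1]),
        log10_ic50=float(popt[2]),
        hill=float(popt[3]),
        se=se,
        rss=rss,
        converged=converged,
        n_obs=len(conc),
        cov=pcov,
    )


def _kinetic_arrays(data: pd.DataFrame):
    need = {"substrate_uM", "inhibitor_uM", "rate_rfu_min"}
    if not need <= set(data.columns):
        raise ValueError(f"need columns {sorted(need)}")
    s = data["substrate_uM"].to_numpy(dtype=float)
    i = data["inhibitor_uM"].to_numpy(dtype=float)
    v = data["rate_rfu_min"].to_numpy(dtype=float)
    if np.any(s < 0) or np.any(i < 0):
        raise ValueError("negative concentration")
    _check_finite("rate", v)
    keep = s > 0  # v(0) = 0 carries no information and breaks relative scaling
    return s[keep], i[keep], v[keep]


def _init_km(s, i, v) -> float:
    base = i == i.min()
    vmax0 = v[base].max()
    half_idx = np.argmin(np.abs(v[base] - vmax0 / 2.0))
    return float(max(s[base][half_idx], 1e-3))


def fit_uncompetitive(data: pd.DataFrame) -> InhibitionFit:
    """Joint least-squares fit of the uncompetitive model over all (S, I) rows.

    ``data`` needs columns ``substrate_uM, inhibitor_uM, rate_rfu_min`` with
    at least two inhibitor levels and four substrate levels.  Without I = 0
    rows Km and Vmax are only weakly identified; a warning is issued.
    """
    s, i, v = _kinetic_arrays(data)
    if np.unique(i).size < 2:
        raise ValueError("need >= 2 inhibitor concentrations")
    if np.unique(s).size < 4:
        raise ValueError("need >= 4 substrate concentrations")
    if not np.any(i == 0):
        warnings.warn("no I=0 rows: Km and Vmax weakly identified", stacklevel=2)

    vmax0 = float(v.max()) * 1.05
    km0 = _init_km(s, i, v)
    aki0 = float(max(np.median(i[i > 0]), 1e-3)) if np.any(i > 0) else 1.0

    def f(si, vmax, log_km, log_aki):
        ss, ii = si
        return uncompetitive_model(ss, ii, vmax, 10.0**log_km, 10.0**log_aki)

    try:
        popt, pcov = curve_fit(
            f, (s, i), v, p0=[vmax0, np.log10(km0), np.log10(aki0)], maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"uncompetitive fit did not converge: {exc}") from exc
    vmax, km, aki = float(popt[0]), float(10.0 ** popt[1]), float(10.0 ** popt[2])
    perr = np.sqrt(np.diag(pcov))
    se = {
        "vmax": float(perr[0]),
        "km": km * LN10 * float(perr[1]),
        "alpha_ki": aki * LN10 * float(perr[2]),
    }
    rss = float(np.sum((f((s, i), *popt) - v) ** 2))
    return InhibitionFit(
        vmax=vmax, km=km, alpha_ki=aki, se=se, rss=rss,
        converged=True, n_obs=len(v), cov=pcov, model="uncompetitive",
    )


def fit_mixed(data: pd.DataFrame) -> InhibitionFit:
    """Fit the mixed-inhibition model (both Ki and αKi free)."""
    s, i, v = _kinetic_arrays(data)
    if np.unique(i).size < 3:
        raise ValueError("mixed model needs >= 3 inhibitor concentrations")
    if np.unique(s).size < 4:
        raise ValueError("need >= 4 substrate concentrations")

    vmax0 = float(v.max()) * 1.05
    km0 = _init_km(s, i, v)
    aki0 = float(max(np.median(i[i > 0]), 1e-3))

    def f(si, vmax, log_km, log_ki, log_aki):
        ss, ii = si
        return mixed_model(ss, ii, vmax, 10.0**log_km, 10.0**log_ki, 10.0**log_aki)

    try:
        popt, pcov = curve_fit(
            f,
            (s, i),
            v,
            p0=[vmax0, np.log10(km0), np.log10(aki0), np.log10(aki0)],
            maxfev=40000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"mixed fit did not converge: {exc}") from exc
    vmax = float(popt[0])
    km, ki, aki = (float(10.0**p) for p in popt[1:])
    perr = np.sqrt(np.diag(pcov))
    se = {
        "vmax": float(perr[0]),
        "km": km * LN10 * float(perr[1]),
        "ki": ki * LN10 * float(perr[2]),
        "alpha_ki": aki * LN10 * float(perr[3]),
    }
    rss = float(np.sum((f((s, i), *popt) - v) ** 2))
    return InhibitionFit(
        vmax=vmax, km=km, alpha_ki=aki, ki=ki, se=se, rss=rss,
        converged=True, n_obs=len(v), cov=pcov, model="mixed",
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_kinetics(
    params: dict,
    design: Sequence,
    noise_sd: float,
    seed: int,
    model: str = "uncompetitive",
) -> pd.DataFrame:
    """Simulate assay rates on a (substrate, inhibitor) design grid.

    ``params`` holds vmax, km, alpha_ki (and ki for the mixed model);
    ``design`` is a sequence of (S µM, I µM) pairs.  Gaussian noise with SD
    ``noise_sd`` (rate units) is added; the output is a deterministic
    function of the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    s = np.array([d[0] for d in design], dtype=float)
    i = np.array([d[1] for d in design], dtype=float)
    if model == "uncompetitive":
        v = uncompetitive_model(s, i, params["vmax"], params["km"], params["alpha_ki"])
    elif model == "mixed":
        v = mixed_model(
            s, i, params["vmax"], params["km"], params["ki"], params["alpha_ki"]
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    v = v + rng.normal(0.0, noise_sd, size=v.shape) if noise_sd else v
    return pd.DataFrame(
        {"substrate_uM": s, "inhibitor_uM": i, "rate_rfu_min": v}
    )


def simulate_dose_response(
    params: dict, concentrations: Sequence[float], noise_sd: float, seed: int
) -> pd.DataFrame:
    """Simulate dose–response data; params: top, bottom, ic50 (µM), hill."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    y = dose_response_model(
        conc, params["top"], params["bottom"], np.log10(params["ic50"]), params["hill"]
    )
    y = y + rng.normal(0.0, noise_sd, size=y.shape) if noise_sd else y
    return pd.DataFrame({"conc_uM": conc, "response": y})


def read_kinetics_csv(path) -> pd.DataFrame:
    """Read an assay CSV with columns substrate_uM,inhibitor_uM,rate_rfu_min."""
    df = pd.read_csv(path)
    _kinetic_arrays(df)  # validates columns and values
    return df
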