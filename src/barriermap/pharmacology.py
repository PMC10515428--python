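"""Dose arithmetic: tissue-concentration conversion, fold-over-IC50, 4PL fits.

A drug concentration measured as mass per tissue mass (ug drug / g tissue)
converts to molarity through the tissue density and the drug's molecular
weight:

    nM = (ug/g) * density[g/mL] * 1e6 / MW[g/mol]

(ug/g -> ug/mL -> mol/L -> nM).  For doxorubicin, MW = 579.98 g/mol and
brain density 1.046 g/mL.  Achieved tissue concentrations are compared to
in vitro IC50 values as integer fold ratios.

IC50 estimation uses the standard four-parameter logistic (4PL,
variable-slope) dose-response model of mean endpoint confluence versus
log10 concentration:

    y(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

with hill > 0 describing growth inhibition (confluence falls as the
concentration rises); the fit runs on the log10 concentration axis for
conditioning and reports the IC50 in nM with a delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TissueConcentration",
    "DoseResponsePlate",
    "IC50Result",
    "NonConvergenceError",
    "ug_per_g_to_nM",
    "fold_over_ic50",
    "fit_ic50",
    "four_param_logistic",
]

DOXORUBICIN_MW = 579.98  # g/mol
BRAIN_DENSITY = 1.046  # g/mL


class NonConvergenceError(RuntimeError):
    """Raised when the dose-response fit cannot converge (e.g. flat data)."""


@dataclass(frozen=True)
class TissueConcentration:
    """Drug amount per tissue mass with conversion constants."""

    value: float  # ug drug per g tissue
    density: float = BRAIN_DENSITY  # g/mL
    mw: float = DOXORUBICIN_MW  # g/mol

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("concentration must be >= 0")
        if self.density <= 0 or self.mw <= 0:
            raise ValueError("density and molecular weight must be > 0")


@dataclass(frozen=True)
class DoseResponsePlate:
    """Endpoint confluence readings: rows (concentration_nM, well, confluence_pct)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"concentration_nM", "well", "confluence_pct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if (self.data["concentration_nM"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        conf = self.data["confluence_pct"]
        if ((conf < 0) | (conf > 100)).any():
            raise ValueError("confluence must lie in [0, 100]")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration_nM"].unique())

    def mean_confluence(self) -> pd.Series:
        return self.data.groupby("concentration_nM")["confluence_pct"].mean()


@dataclass(frozen=True)
class IC50Result:
    ic50: float  # nM
    hill: float
    top: float
    bottom: float
    ic50_se: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be > 0")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")


def ug_per_g_to_nM(c: TissueConcentration) -> float:
    """Convert ug drug / g tissue to nM via density and molecular weight."""
    return c.value * c.density * 1e6 / c.mw


def fold_over_ic50(conc_nM: float, ic50_nM: float) -> int:
    """How many times the achieved concentration exceeds the IC50 (rounded)."""
    if ic50_nM <= 0:
        raise ValueError("IC50 must be > 0")
    return round(conc_nM / ic50_nM)


def four_param_logistic(conc_nM, ic50: float, hill: float, top: float, bottom: float):
    """4PL response at concentration(s) in nM; hill > 0 means inhibition."""
    conc_nM = np.asarray(conc_nM, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc_nM > 0, conc_nM / ic50, 0.0)
        out = bottom + (top - bottom) / (1.0 + ratio**hill)
    return out if out.ndim else float(out)


def fit_ic50(plate: DoseResponsePlate) -> IC50Result:
    """Fit the 4PL model to mean confluence per concentration.

    Zero-concentration (vehicle) wells anchor the top plateau but cannot be
    placed on the log axis; they are assigned a pseudo-log position two
    decades below the lowest nonzero dose.  Raises
    :class:`NonConvergenceError` when the data carry no dose dependence.
    """
    means = plate.mean_confluence()
    conc = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    nonzero = conc > 0
    if nonzero.sum() < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations")
    if float(np.ptp(y)) < 1.0:
        raise NonConvergenceError("confluence shows no dose dependence")

    floor = conc[nonzero].min() * 1e-2
    logc = np.log10(np.where(nonzero, conc, floor))

    def model(logc, log_ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - log_ic50) * hill))

    p0 = (
        float(np.median(logc[nonzero])),
        1.0,
        float(y.max()),
        float(y.min()),
    )
    bounds = ((logc.min() - 3, 0.05, 0.0, 0.0), (logc.max() + 3, 10.0, 100.0, 100.0))
    try:
        popt, pcov = curve_fit(model, logc, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise NonConvergenceError(f"4PL fit did not converge: {exc}") from exc

    log_ic50, hill, top, bottom = popt
    if top < bottom:
        top, bottom = bottom, top
    ic50 = float(10.0**log_ic50)
    se_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    ic50_se = ic50 * np.log(10.0) * se_log  # delta method
    return IC50Result(ic50=ic50, hill=float(hill), top=float(top),
                      bottom=float(bottom), ic50_se=float(ic50_se))
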