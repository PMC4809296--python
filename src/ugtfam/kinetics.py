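"""Michaelis–Menten kinetics, specificity constants and UDP calibration.

Saturation data (substrate concentration in μM, rate in pKat·mg⁻¹) are
fitted to v = Vmax·S / (Km + S) either by nonlinear least squares on the
hyperbola (default, statistically preferred) or by the classical
double-reciprocal (Lineweaver–Burk) line fit, which is provided for
comparability with published plots but inherits that method's known
noise-amplification at low S.

Turnover numbers (kcat, s⁻¹) are derived from Vmax and the enzyme molar
mass, or accepted directly when the mass is unknown; kcat/Km is the
specificity constant in s⁻¹·μM⁻¹.  A linear UDP calibration curve
(peak area vs concentration) is fitted and inverted for unknowns, with
extrapolation outside the standards' range flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "KineticDataset",
    "KineticFit",
    "FitError",
    "CalibratedSample",
    "fit_mm",
    "kcat_from_vmax",
    "specificity_constant",
    "attach_kcat",
    "relative_activity",
    "udp_calibration",
    "read_kinetics_csv",
    "MIN_DISTINCT_CONCENTRATIONS",
]

MIN_DISTINCT_CONCENTRATIONS = 4


class FitError(RuntimeError):
    """Raised on non-convergence or non-positive parameter estimates."""


@dataclass(frozen=True)
class KineticDataset:
    """(S, v) observations for one enzyme/substrate pair.

    Concentrations in μM (must be positive), rates in pKat·mg⁻¹ (must
    be non-negative).  Replicates are stored pooled; an optional
    replicate index is kept for bookkeeping only.
    """

    enzyme: str
    substrate: str
    concentrations_uM: tuple[float, ...]
    rates: tuple[float, ...]
    replicate: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in self.concentrations_uM)
        v = tuple(float(x) for x in self.rates)
        if len(s) != len(v):
            raise ValueError("concentrations and rates differ in length")
        if len(s) == 0:
            raise ValueError("dataset is empty")
        if any(x <= 0 for x in s):
            raise ValueError("substrate concentrations must be > 0")
        if any(x < 0 for x in v):
            raise ValueError("rates must be >= 0")
        if self.replicate is not None and len(self.replicate) != len(s):
            raise ValueError("replicate index length mismatch")
        object.__setattr__(self, "concentrations_uM", s)
        object.__setattr__(self, "rates", v)

    @property
    def n(self) -> int:
        return len(self.rates)

    @property
    def n_distinct_concentrations(self) -> int:
        return len(set(self.concentrations_uM))


@dataclass(frozen=True)
class KineticFit:
    """Fitted Km (μM), Vmax (pKat·mg⁻¹) and derived constants.

    ``kcat`` (s⁻¹) and ``specificity`` (kcat/Km, s⁻¹·μM⁻¹) are filled by
    :func:`attach_kcat` once a turnover number is available.
    """

    km: float
    vmax: float
    method: str
    rss: float
    kcat: float | None = None
    specificity: float | None = None


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm(data: KineticDataset, method: str = "hyperbolic") -> KineticFit:
    """Fit the Michaelis–Menten hyperbola to a dataset.

    ``hyperbolic``: nonlinear least squares on v = Vmax·S/(Km+S),
    initialised at Vmax₀ = max(v), Km₀ = median(S), both constrained
    positive.  ``double_reciprocal``: ordinary least squares on 1/v vs
    1/S with Km = slope/intercept and Vmax = 1/intercept; any zero rate
    makes the transform undefined and raises :class:`FitError`.

    The residual sum of squares is always reported on the original
    (v vs S) scale, so methods are comparable.
    """
    if data.n_distinct_concentrations < MIN_DISTINCT_CONCENTRATIONS:
        raise ValueError(
            f"fitting needs >= {MIN_DISTINCT_CONCENTRATIONS} distinct "
            f"concentrations, got {data.n_distinct_concentrations}"
        )
    s = np.asarray(data.concentrations_uM, dtype=float)
    v = np.asarray(data.rates, dtype=float)

    if method == "hyperbolic":
        p0 = (float(v.max()), float(np.median(s)))
        try:
            popt, _ = curve_fit(
                _mm, s, v, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"hyperbolic fit failed: {exc}") from exc
        vmax, km = float(popt[0]), float(popt[1])
    elif method == "double_reciprocal":
        if np.any(v == 0):
            raise FitError("double-reciprocal fit undefined for zero rates")
        line = linregress(1.0 / s, 1.0 / v)
        if line.intercept <= 0:
            raise FitError(
                f"double-reciprocal intercept {line.intercept:.3g} <= 0; "
                "no positive Vmax estimate"
            )
        vmax = 1.0 / line.intercept
        km = line.slope / line.intercept
    else:
        raise ValueError(f"unknown fit method {method!r}")

    if not (np.isfinite(km) and np.isfinite(vmax)) or km <= 0 or vmax <= 0:
        raise FitError(
            f"{method} fit produced non-positive estimates "
            f"(Km={km:.4g}, Vmax={vmax:.4g})"
        )
    rss = float(np.sum((v - _mm(s, vmax, km)) ** 2))
    return KineticFit(km=km, vmax=vmax, method=method, rss=rss)


def kcat_from_vmax(vmax_pkat_per_mg: float, enzyme_molar_mass: float) -> float:
    """Turnover number from a specific activity and an enzyme molar mass.

    Vmax in pKat·mg⁻¹ is 1e-12 mol·s⁻¹ per mg, i.e. 1e-9 mol·s⁻¹ per g;
    multiplying by the molar mass (g·mol⁻¹) gives mol substrate per mol
    enzyme per second:

        kcat [s⁻¹] = Vmax × 1e-12 × 1e3 × M
    """
    if vmax_pkat_per_mg <= 0 or enzyme_molar_mass <= 0:
        raise ValueError("vmax and molar mass must be positive")
    return vmax_pkat_per_mg * 1e-12 * 1e3 * enzyme_molar_mass


def specificity_constant(kcat: float, km: float) -> float:
    """kcat/Km in s⁻¹·μM⁻¹ (reported to 3 significant figures in tables)."""
    if kcat <= 0 or km <= 0:
        raise ValueError("kcat and Km must be positive")
    return kcat / km


def attach_kcat(
    fit: KineticFit,
    kcat: float | None = None,
    enzyme_molar_mass: float | None = None,
) -> KineticFit:
    """Return a fit carrying kcat and the specificity constant.

    ``kcat`` may be supplied directly (the usual path when the enzyme —
    e.g. a fusion protein — has no well-defined mass) or derived from
    the fitted Vmax and a molar mass.
    """
    if kcat is None:
        if enzyme_molar_mass is None:
            raise ValueError("supply kcat or an enzyme molar mass")
        kcat = kcat_from_vmax(fit.vmax, enzyme_molar_mass)
    return replace(fit, kcat=kcat, specificity=specificity_constant(kcat, fit.km))


def relative_activity(
    rates: Mapping[str, float], reference: str = "gallic acid"
) -> dict[str, float]:
    """Rates as percent of the reference substrate's rate.

    The reference maps to exactly 100; missing or zero reference rates
    are errors.  Scale-invariant in the input rates.
    """
    if reference not in rates:
        raise ValueError(f"reference substrate {reference!r} missing")
    ref_rate = float(rates[reference])
    if ref_rate <= 0:
        raise ValueError(f"reference substrate {reference!r} has non-positive rate")
    out = {sub: 100.0 * float(rate) / ref_rate for sub, rate in rates.items()}
    out[reference] = 100.0
    return out


@dataclass(frozen=True)
class CalibratedSample:
    """An unknown's back-calculated concentration (μM) and range flag."""

    area: float
    concentration_uM: float
    extrapolated: bool


def udp_calibration(
    standards: Sequence[tuple[float, float]],
    unknowns: Iterable[float],
) -> list[CalibratedSample]:
    """Invert a linear calibration curve area = a·conc + b.

    ``standards`` are (concentration μM, peak area) pairs — at least two
    distinct concentrations.  Unknown areas are mapped back to
    concentrations; results outside the standards' concentration range
    are flagged as extrapolated.
    """
    concs = np.array([c for c, _ in standards], dtype=float)
    areas = np.array([a for _, a in standards], dtype=float)
    if len(set(concs.tolist())) < 2:
        raise ValueError("calibration needs >= 2 distinct standard concentrations")
    line = linregress(concs, areas)
    if line.slope == 0:
        raise ValueError("calibration line has zero slope; cannot invert")
    lo, hi = float(concs.min()), float(concs.max())
    out = []
    for area in unknowns:
        conc = (float(area) - line.intercept) / line.slope
        out.append(
            CalibratedSample(
                area=float(area),
                concentration_uM=conc,
                extrapolated=not (lo <= conc <= hi),
            )
        )
    return out


def read_kinetics_csv(path) -> list[KineticDataset]:
    """Read assay tables with columns enzyme, substrate, conc_uM,
    rate_pkat_per_mg and optional replicate; one dataset per
    (enzyme, substrate) pair, rows pooled."""
    frame = pd.read_csv(path)
    required = {"enzyme", "substrate", "conc_uM", "rate_pkat_per_mg"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"kinetics CSV missing column(s) {sorted(missing)}")
    datasets = []
    for (enzyme, substrate), group in frame.groupby(
        ["enzyme", "substrate"], sort=False
    ):
        replicate = (
            tuple(int(x) for x in group["replicate"])
            if "replicate" in group.columns
            else None
        )
        datasets.append(
            KineticDataset(
                enzyme=str(enzyme),
                substrate=str(substrate),
                concentrations_uM=tuple(group["conc_uM"]),
                rates=tuple(group["rate_pkat_per_mg"]),
                replicate=replicate,
            )
        )
    return datasets
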