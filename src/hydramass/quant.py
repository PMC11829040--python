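"""Calibration-based nucleoside quantification and dose-response fitting.

Isotope-dilution LC-MS/MS quantifies each nucleoside through the response
ratio analyte/SILIS (stable-isotope-labelled internal standard) against an
external calibration series (a 1:1 serial dilution, 12 points by default).
Absolute amounts are turned into per-molecule counts by normalising on
guanosine, whose count per molecule is known from the sequence; the
conversion yield of the hydrazine reaction is 1 - treated/control.  The
concentration dependence of the remaining fraction is fitted with a
log-logistic dose-response curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .registry import DoseResponseParams, TreatmentCondition

__all__ = [
    "CalibrationSeries",
    "CalibrationCurve",
    "Quantified",
    "YieldResult",
    "QuantResult",
    "DoseResponseFit",
    "TreatmentCondition",
    "fit_calibration",
    "quantify",
    "per_molecule_counts",
    "conversion_yield",
    "fit_dose_response",
]

DEFAULT_CALIBRATION_POINTS = 12
# Default calibration maxima (pmol): canonicals at 100, Psi and D at 20,
# other modified nucleosides at 5.
CALIBRATION_MAXIMA = {"A": 100.0, "C": 100.0, "G": 100.0, "U": 100.0,
                      "Psi": 20.0, "D": 20.0}
DEFAULT_MODIFIED_MAX_PMOL = 5.0


def calibration_maximum(code: str) -> float:
    return CALIBRATION_MAXIMA.get(code, DEFAULT_MODIFIED_MAX_PMOL)


@dataclass(frozen=True)
class CalibrationSeries:
    """Per-nucleoside calibration points (amount pmol, response ratio)."""

    code: str
    points: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(a), float(r)) for a, r in self.points)
        if any(a <= 0 for a, _ in pts):
            raise ValueError("calibration amounts must be strictly positive")
        object.__setattr__(self, "points", pts)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([a for a, _ in self.points])

    @property
    def responses(self) -> np.ndarray:
        return np.array([r for _, r in self.points])

    @classmethod
    def serial_dilution(
        cls,
        code: str,
        responses: Sequence[float],
        max_pmol: Optional[float] = None,
    ) -> "CalibrationSeries":
        """Build a 1:1 serial-dilution design from the top concentration."""
        top = calibration_maximum(code) if max_pmol is None else float(max_pmol)
        amounts = [top / 2**i for i in range(len(responses))]
        return cls(code, tuple(zip(amounts, responses)))


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response model: response = slope * amount + intercept."""

    code: str
    slope: float
    intercept: float
    r_squared: float
    valid_range: Tuple[float, float]

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def invert(self, response: float) -> float:
        if self.slope <= 0:
            raise ValueError(f"calibration for {self.code} has non-positive slope")
        return (response - self.intercept) / self.slope


class Quantified(NamedTuple):
    amount_pmol: float
    in_range: bool

    def __float__(self) -> float:
        return self.amount_pmol


@dataclass(frozen=True)
class YieldResult:
    """Conversion yield 1 - treated/control, clipped to [0, 1].

    The raw (unclipped) value is retained: measurement noise can make the
    treated abundance exceed the control.
    """

    value: float
    raw: float
    clipped: bool

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class QuantResult:
    code: str
    amount_pmol: float
    per_molecule: float
    conversion_yield: Optional[YieldResult] = None
    condition: Optional[TreatmentCondition] = None


@dataclass(frozen=True)
class DoseResponseFit:
    params: DoseResponseParams
    stderr: Dict[str, float]
    flags: Tuple[str, ...]
    residual_rms: float


def fit_calibration(
    series: CalibrationSeries,
    weighting: str = "none",
    through_origin: bool = False,
) -> CalibrationCurve:
    """Least-squares line through the calibration points.

    Unweighted ordinary least squares with intercept by default; 1/x
    weighting (``weighting='1/x'``) and forcing through the origin are
    available for labs that calibrate that way.
    """
    x, y = series.amounts, series.responses
    if len(x) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all amounts equal")
    if weighting not in ("none", "1/x"):
        raise ValueError("weighting must be 'none' or '1/x'")
    w = np.ones_like(x) if weighting == "none" else 1.0 / x
    if through_origin:
        slope = float(np.sum(w * x * y) / np.sum(w * x * x))
        intercept = 0.0
    else:
        W = np.sum(w)
        xbar = np.sum(w * x) / W
        ybar = np.sum(w * y) / W
        slope = float(np.sum(w * (x - xbar) * (y - ybar)) / np.sum(w * (x - xbar) ** 2))
        intercept = float(ybar - slope * xbar)
    fitted = slope * x + intercept
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    ss_tot = float(np.sum(w * (y - np.sum(w * y) / np.sum(w)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        code=series.code,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        valid_range=(float(x.min()), float(x.max())),
    )


def quantify(response_ratio: float, curve: CalibrationCurve) -> Quantified:
    """Inverse-predict an amount from a response ratio."""
    amount = curve.invert(response_ratio)
    lo, hi = curve.valid_range
    in_range = lo <= amount <= hi
    if not in_range:
        warnings.warn(
            f"{curve.code}: {amount:.4g} pmol outside calibrated range "
            f"[{lo:.4g}, {hi:.4g}]",
            stacklevel=2,
        )
    return Quantified(amount, in_range)


def per_molecule_counts(
    amounts: Mapping[str, float],
    reference: str = "G",
    reference_count: float = 1.0,
) -> Dict[str, float]:
    """Convert absolute amounts to counts per RNA molecule.

    The reference nucleoside (guanosine by default) anchors the number of
    injected molecules: molecules = amount(ref) / count(ref); every other
    count is amount / molecules.
    """
    if reference not in amounts:
        raise KeyError(f"reference nucleoside {reference!r} missing from amounts")
    ref_amount = amounts[reference]
    if ref_amount <= 0:
        raise ValueError("reference amount must be positive")
    if reference_count <= 0:
        raise ValueError("reference count per molecule must be positive")
    molecules = ref_amount / reference_count
    return {code: amount / molecules for code, amount in amounts.items()}


def conversion_yield(control: float, treated: float) -> YieldResult:
    """Fraction of a nucleoside consumed by the reaction: 1 - treated/control."""
    if control <= 0:
        raise ValueError("control abundance must be positive")
    raw = float(1.0 - treated / control)
    value = min(max(raw, 0.0), 1.0)
    return YieldResult(value=value, raw=raw, clipped=value != raw)


def _remaining_fraction(c, ec50, hill, ceiling):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        p = np.where(c > 0, ceiling / (1.0 + (ec50 / np.maximum(c, 1e-300)) ** hill), 0.0)
    return 1.0 - p


def fit_dose_response(
    concentrations: Sequence[float],
    remaining: Sequence[float],
    censored_as_zero: bool = True,
) -> DoseResponseFit:
    """Fit a log-logistic dose-response to remaining-fraction data.

    ``remaining`` is the relative abundance (treated/control) at each
    hydrazine concentration; NaN entries (below LOQ) are treated as 0 with a
    censoring flag rather than dropped.  Returns EC50 (% v/v), slope and
    ceiling with standard errors; pathological data are flagged (flat data:
    ceiling ~ 0 and EC50 unidentifiable; step data: slope at its bound).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(remaining, dtype=float)
    flags: List[str] = []
    if c.size != r.size:
        raise ValueError("concentration and remaining arrays differ in length")
    if c.size < 4 or 0.0 not in c:
        raise ValueError("need >=4 concentrations including 0")
    if np.isnan(r).any():
        if not censored_as_zero:
            keep = ~np.isnan(r)
            c, r = c[keep], r[keep]
        else:
            r = np.where(np.isnan(r), 0.0, r)
            flags.append("censored-points-as-zero")

    drop = 1.0 - float(np.min(r))
    p0 = [max(float(np.median(c[c > 0])), 1e-3), 2.0, min(max(drop, 1e-3), 1.0)]
    bounds = ([1e-3, 0.05, 0.0], [1e4, 50.0, 1.0])
    try:
        popt, pcov = optimize.curve_fit(
            _remaining_fraction, c, r, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # non-convergence
        raise RuntimeError(
            f"dose-response fit did not converge: {exc}; "
            f"data range remaining=[{r.min():.3g}, {r.max():.3g}]"
        ) from exc
    ec50, hill, ceiling = (float(v) for v in popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    stderr = {"ec50": float(perr[0]), "hill": float(perr[1]), "ceiling": float(perr[2])}
    if ceiling < 0.05:
        flags.append("flat-response: ceiling ~ 0, EC50 unidentifiable")
    if hill > 45.0:
        flags.append("step-response: slope at bound")
    resid = r - _remaining_fraction(c, *popt)
    return DoseResponseFit(
        params=DoseResponseParams(ec50=ec50, hill=hill, ceiling=ceiling),
        stderr=stderr,
        flags=tuple(flags),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
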