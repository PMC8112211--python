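"""Bliss and ZIP synergy scoring of dose-response checkerboard matrices.

Responses are inhibition fractions in [0, 1] (1 - relative viability) on a
factorial dose grid whose first row and column are the two monotherapies
(dose 0 of the partner).  Both models report a delta surface in percentage
points over the combination cells, its mean (the synergy score) and the
maximum mean over contiguous 3x3 dose windows (the most-synergistic-area
score).

Bliss: expected combined inhibition is y_A + y_B - y_A*y_B from the raw
monotherapy responses; delta is observed minus expected.

ZIP (zero interaction potency): four-parameter logistic (4PL) curves are
fitted to each monotherapy; for every combination cell the response curve
along each axis is re-fitted holding the partner fixed (a potency-shift fit
whose baseline is the partner's fitted effect), the two fitted values are
averaged, and the Bliss expectation of the fitted monotherapies is
subtracted.  Its null — data exactly Bliss-independent in the fitted
curves — gives a zero delta surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseMatrix",
    "SynergyResult",
    "bliss_delta",
    "zip_delta",
    "most_synergistic_area",
]


@dataclass
class DoseResponseMatrix:
    """Checkerboard of inhibition fractions for a drug pair.

    ``doses_a`` (rows) and ``doses_b`` (columns) are ascending concentrations
    whose first entry is 0, so ``response[:, 0]`` and ``response[0, :]`` are
    the monotherapy axes and ``response[0, 0]`` the untreated well.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or len(d) < 2:
                raise ValueError(f"{name} must be a 1-D grid with >=2 doses")
            if d[0] != 0:
                raise ValueError(f"{name} must start at dose 0 (monotherapy axis)")
            if not np.all(np.diff(d) > 0):
                raise ValueError(f"{name} must be strictly ascending")
        if self.response.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError(
                f"response shape {self.response.shape} does not match dose grids "
                f"({len(self.doses_a)}, {len(self.doses_b)})"
            )
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")

    @classmethod
    def from_viability(
        cls,
        drug_a: str,
        drug_b: str,
        doses_a,
        doses_b,
        viability: np.ndarray,
        control: float | None = None,
        replicates: int = 1,
    ) -> "DoseResponseMatrix":
        """Build from percent/relative viability: inhibition = 1 - v / control.

        ``control`` defaults to the untreated (0, 0) well.
        """
        v = np.asarray(viability, dtype=float)
        if control is None:
            control = v[0, 0]
        if control <= 0:
            raise ValueError("control viability must be positive")
        return cls(drug_a, drug_b, doses_a, doses_b, 1.0 - v / control, replicates)


@dataclass
class SynergyResult:
    model: str
    delta: np.ndarray  # percentage points, combination cells only
    synergy_score: float
    most_synergistic_area: float
    fits: dict = field(default_factory=dict)


def _validated_response(matrix: DoseResponseMatrix) -> np.ndarray:
    y = matrix.response
    if (y < -0.2).any() or (y > 1.2).any():
        raise ValueError(
            "responses outside [-0.2, 1.2]; data look like percentages or raw "
            "viability — convert to inhibition fractions first"
        )
    if (y < 0).any() or (y > 1).any():
        warnings.warn("clipping responses to [0, 1]", stacklevel=3)
        y = np.clip(y, 0.0, 1.0)
    return y


def most_synergistic_area(delta: np.ndarray, window: int = 3) -> float:
    """Maximum mean over contiguous ``window`` x ``window`` sub-blocks.

    Surfaces smaller than the window use the largest available block; ties
    resolve to the first window in row-major order (strict-improvement scan).
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty delta surface")
    wr = min(window, delta.shape[0])
    wc = min(window, delta.shape[1])
    best = -np.inf
    for i in range(delta.shape[0] - wr + 1):
        for j in range(delta.shape[1] - wc + 1):
            m = delta[i : i + wr, j : j + wc].mean()
            if m > best:
                best = m
    return float(best)


def bliss_delta(matrix: DoseResponseMatrix) -> SynergyResult:
    """Excess over Bliss independence, in percentage points per combination cell."""
    y = _validated_response(matrix)
    y_a = y[1:, 0]
    y_b = y[0, 1:]
    observed = y[1:, 1:]
    expected = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    delta = 100.0 * (observed - expected)
    return SynergyResult(
        model="bliss",
        delta=delta,
        synergy_score=float(delta.mean()),
        most_synergistic_area=most_synergistic_area(delta),
    )


def _four_pl(x: np.ndarray, ymin: float, ymax: float, ec50: float, slope: float):
    """Ascending 4PL inhibition curve; y(0) = ymin by the slope > 0 limit."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (ec50 / np.maximum(x, 1e-300)) ** slope, np.inf)
    return ymin + (ymax - ymin) / (1.0 + ratio)


def fit_monotherapy(doses: np.ndarray, response: np.ndarray) -> dict:
    """4PL fit with bounds ymin in [0, 0.3], ymax in [0.7, 1], slope, EC50 > 0.

    Falls back to monotonic linear interpolation of the observed points when
    the nonlinear fit fails to converge (fitted values then reproduce the
    observations, flagged via ``converged=False``).
    """
    nonzero = doses > 0
    if nonzero.sum() < 4:
        raise ValueError(
            f"need >=4 non-zero doses for a 4PL monotherapy fit, got {int(nonzero.sum())}"
        )
    y = np.asarray(response, dtype=float)
    half = 0.5 * (y.min() + y.max())
    above = doses[nonzero][np.argsort(np.abs(y[nonzero] - half))[0]]
    p0 = [
        float(np.clip(y.min(), 0.0, 0.3)),
        float(np.clip(y.max(), 0.7, 1.0)),
        float(max(above, 1e-6)),
        1.0,
    ]
    try:
        popt, _ = curve_fit(
            _four_pl,
            doses,
            y,
            p0=p0,
            bounds=([0.0, 0.7, 1e-12, 1e-3], [0.3, 1.0, np.inf, 20.0]),
            maxfev=20000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        return {
            "ymin": float(popt[0]),
            "ymax": float(popt[1]),
            "ec50": float(popt[2]),
            "slope": float(popt[3]),
            "converged": True,
            "fitted": _four_pl(doses, *popt),
        }
    except RuntimeError:
        warnings.warn(
            "4PL monotherapy fit did not converge; falling back to monotonic "
            "interpolation of observed responses",
            stacklevel=3,
        )
        return {
            "ymin": float(y[0]),
            "ymax": float(y[-1]),
            "ec50": float(np.median(doses[nonzero])),
            "slope": np.nan,
            "converged": False,
            "fitted": y.copy(),
        }


def _potency_shift(x: np.ndarray, emax: float, ec50: float, slope: float, y0: float):
    """Logistic rise from the partner's fixed baseline y0 toward emax."""
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (ec50 / np.maximum(x, 1e-300)) ** slope, np.inf)
    return y0 + (emax - y0) / (1.0 + ratio)


def _fit_conditional(doses: np.ndarray, y: np.ndarray, y0: float) -> np.ndarray:
    """Fitted conditional response along one axis, baseline fixed at y0."""
    half = 0.5 * (min(y.min(), y0) + y.max())
    near = doses[np.argsort(np.abs(y - half))[0]]
    p0 = [float(np.clip(y.max(), y0 + 1e-6, 1.0)), float(max(near, 1e-6)), 1.0]
    try:
        popt, _ = curve_fit(
            lambda x, emax, ec50, slope: _potency_shift(x, emax, ec50, slope, y0),
            doses,
            y,
            p0=p0,
            bounds=([0.0, 1e-12, 1e-3], [1.0, np.inf, 20.0]),
            maxfev=20000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        return _potency_shift(doses, *popt, y0)
    except RuntimeError:
        warnings.warn(
            "conditional potency-shift fit did not converge; using observed values",
            stacklevel=4,
        )
        return y.copy()


def zip_delta(matrix: DoseResponseMatrix) -> SynergyResult:
    """Zero-interaction-potency delta surface in percentage points.

    Requires >=4 non-zero doses per monotherapy axis for the 4PL fits.
    """
    y = _validated_response(matrix)
    fit_a = fit_monotherapy(matrix.doses_a, y[:, 0])
    fit_b = fit_monotherapy(matrix.doses_b, y[0, :])
    ya_fit = fit_a["fitted"][1:]
    yb_fit = fit_b["fitted"][1:]
    n_a, n_b = len(ya_fit), len(yb_fit)
    # conditional fits: along B for each row of A, and along A for each column of B
    fit_rows = np.empty((n_a, n_b))
    for i in range(n_a):
        fit_rows[i] = _fit_conditional(matrix.doses_b[1:], y[i + 1, 1:], ya_fit[i])
    fit_cols = np.empty((n_a, n_b))
    for j in range(n_b):
        fit_cols[:, j] = _fit_conditional(matrix.doses_a[1:], y[1:, j + 1], yb_fit[j])
    expected = ya_fit[:, None] + yb_fit[None, :] - ya_fit[:, None] * yb_fit[None, :]
    delta = 100.0 * ((fit_rows + fit_cols) / 2.0 - expected)
    return SynergyResult(
        model="zip",
        delta=delta,
        synergy_score=float(delta.mean()),
        most_synergistic_area=most_synergistic_area(delta),
        fits={
            "monotherapy_a": {k: fit_a[k] for k in ("ymin", "ymax", "ec50", "slope", "converged")},
            "monotherapy_b": {k: fit_b[k] for k in ("ymin", "ymax", "ec50", "slope", "converged")},
        },
    )
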