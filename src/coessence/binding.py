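"""Law-of-mass-action binding model for microscale thermophoresis (MST) titrations.

A fluorescently labeled target A is held at a fixed total concentration
``A0`` (nM) while a titrant T is serially diluted.  For a 1:1 equilibrium
A + T <-> AT with dissociation constant ``Kd``, the complex concentration is
the physical root of the mass-action quadratic::

    [AT] = 1/2 * ( (A0 + T0 + Kd) - sqrt((A0 + T0 + Kd)^2 - 4*A0*T0) )

The measured thermophoretic response is modeled as an affine function of the
fraction of target in complex, ``response = baseline + amplitude * AT/A0``.
``fit_isotherm`` estimates (Kd, amplitude, baseline) by least squares with
multi-start over log-spaced Kd initial values, and ``detect_binding``
implements the "no binding" designation for curves whose amplitude is not
resolvable above the residual noise or whose fractional-binding span across
the titration is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingModelParams",
    "TitrationSeries",
    "BindingFit",
    "fraction_bound",
    "design_titration",
    "fit_isotherm",
    "detect_binding",
]


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the 1:1 mass-action response model (concentrations in nM)."""

    A0: float
    Kd: float
    amplitude: float
    baseline: float

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if not (self.Kd > 0):  # math.inf allowed: encodes a non-binder
            raise ValueError("Kd must be positive (inf encodes a non-binder)")


@dataclass
class TitrationSeries:
    """One titration: total titrant concentrations (nM, descending) and responses."""

    T0_values: np.ndarray
    responses: np.ndarray
    n_points: int = 0
    fold: float = float("nan")
    replicate: str | int | None = None

    def __post_init__(self) -> None:
        self.T0_values = np.asarray(self.T0_values, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.T0_values.shape != self.responses.shape:
            raise ValueError("T0_values and responses must have equal length")
        if np.any(self.T0_values <= 0):
            raise ValueError("titrant concentrations must be strictly positive")
        if self.n_points == 0:
            self.n_points = self.T0_values.size


@dataclass
class BindingFit:
    """Result of fitting one titration series."""

    params: BindingModelParams
    residual_sd: float
    converged: bool
    binding_detected: bool = False
    signal_to_noise: float = float("nan")
    amplitude_over_noise: float = float("nan")
    fraction_span: float = float("nan")
    n_points: int = 0
    cost: float = float("nan")


def fraction_bound(A0: float, T0, Kd: float):
    """Complex concentration [AT] (nM) from the 1:1 mass-action quadratic.

    Parameters are total concentrations in nM.  Vectorized over ``T0``.
    Uses the numerically stable form ``2*A0*T0 / (s + sqrt(s^2 - 4*A0*T0))``
    with ``s = A0 + T0 + Kd``, which avoids cancellation at large Kd; it is
    algebraically identical to the textbook quadratic root.

    ``Kd = inf`` returns 0 (non-binder); ``Kd = 0`` gives the stoichiometric
    limit ``min(A0, T0)``.
    """
    T0 = np.asarray(T0, dtype=float)
    scalar = T0.ndim == 0
    T0 = np.atleast_1d(T0)
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    if np.any(T0 < 0):
        raise ValueError("T0 must be non-negative")
    if Kd < 0:
        raise ValueError("Kd must be non-negative")

    if math.isinf(Kd):
        at = np.zeros_like(T0)
    else:
        s = A0 + T0 + Kd
        disc = s * s - 4.0 * A0 * T0
        disc = np.maximum(disc, 0.0)  # clamp fp round-off at the stoichiometric point
        at = 2.0 * A0 * T0 / (s + np.sqrt(disc))
    return float(at[0]) if scalar else at


def design_titration(
    top_nM: float,
    n_points: int = 16,
    fold: float = 2.0,
    mix_ratio: float = 0.5,
) -> np.ndarray:
    """Final-assay titrant concentrations for a serial dilution.

    A stock at ``top_nM`` is serially diluted ``fold``-fold for ``n_points``
    steps and then mixed with labeled target (``mix_ratio`` is the volume
    fraction of titrant in the final reaction; the standard 1:1 mix gives
    0.5).  Returns concentrations in descending order.
    """
    if top_nM <= 0:
        raise ValueError("top_nM must be positive")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    i = np.arange(n_points)
    return top_nM * mix_ratio / fold**i


def _model(T0: np.ndarray, A0: float, log10_kd: float, amplitude: float, baseline: float) -> np.ndarray:
    # clamp the optimizer's excursions: Kd outside [1e-6, 1e12] nM is flat anyway
    kd = 10.0 ** float(np.clip(log10_kd, -6.0, 12.0))
    return baseline + amplitude * fraction_bound(A0, T0, kd) / A0


def fit_isotherm(
    series: TitrationSeries,
    A0: float = 20.0,
    n_starts: int = 5,
    tol: float = 1e-12,
    min_amplitude_over_noise: float = 5.0,
    min_fraction_span: float = 0.1,
) -> BindingFit:
    """Least-squares fit of (Kd, amplitude, baseline) to a titration series.

    Kd is optimized in log10 space.  The single-quadratic parameterization has
    local minima, so the fit is multi-started from ``n_starts`` log-spaced Kd
    values spanning [min(T0)/10, 100*max(T0)]; the lowest-cost converged start
    wins.  ``A0`` is the known assay constant (20 nM final target by default).
    """
    T0 = series.T0_values
    y = series.responses
    if T0.size < 4:
        raise ValueError("need at least 4 titration points to fit 3 parameters")

    kd_grid = np.logspace(
        math.log10(T0.min() / 10.0), math.log10(T0.max() * 100.0), n_starts
    )
    y_span = y.max() - y.min()
    best = None
    for kd0 in kd_grid:
        f0 = fraction_bound(A0, T0, kd0) / A0
        amp0 = y_span if y_span > 0 else 1.0
        amp0 = math.copysign(amp0, np.corrcoef(f0, y)[0, 1]) if np.std(f0) > 0 and np.std(y) > 0 else amp0
        x0 = np.array([math.log10(kd0), amp0, float(y.min())])
        try:
            res = least_squares(
                lambda p: _model(T0, A0, *p) - y,
                x0,
                xtol=tol,
                ftol=tol,
                gtol=tol,
                method="lm",
                max_nfev=5000,
            )
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        params = BindingModelParams(A0=A0, Kd=math.inf, amplitude=0.0, baseline=float(np.mean(y)))
        return BindingFit(params=params, residual_sd=float(np.std(y, ddof=1)), converged=False,
                          binding_detected=False, n_points=T0.size)

    log10_kd, amplitude, baseline = best.x
    # mirror the clamp applied inside the model; beyond it the curve is flat
    kd = math.inf if log10_kd > 12.0 else 10.0 ** float(max(log10_kd, -6.0))
    dof = max(T0.size - 3, 1)
    residual_sd = float(np.sqrt(2.0 * best.cost / dof))
    params = BindingModelParams(A0=A0, Kd=kd, amplitude=float(amplitude), baseline=float(baseline))
    fit = BindingFit(
        params=params,
        residual_sd=residual_sd,
        converged=True,
        n_points=T0.size,
        cost=float(best.cost),
    )
    frac = fraction_bound(A0, T0, kd) / A0
    fit.fraction_span = float(frac.max() - frac.min())
    fit.amplitude_over_noise = abs(fit.params.amplitude) / max(fit.residual_sd, 1e-12)
    fit.signal_to_noise = abs(fit.params.amplitude) * fit.fraction_span / max(fit.residual_sd, 1e-12)
    fit.binding_detected = detect_binding(fit, min_amplitude_over_noise, min_fraction_span)
    return fit


def detect_binding(
    fit: BindingFit,
    min_amplitude_over_noise: float = 5.0,
    min_fraction_span: float = 0.1,
) -> bool:
    """Binding designation: converged, amplitude resolvable above noise, and a
    non-negligible fraction-bound span across the assayed concentration range.

    Curves failing either threshold are designated "no binding" — no
    detectable fractional binding shift within the titration window.  An
    in-range binder measured at low noise passes both; a non-binder or a
    binder whose Kd lies far above the top titrant concentration fails the
    span test.
    """
    if not fit.converged:
        return False
    if fit.amplitude_over_noise < min_amplitude_over_noise:
        return False
    if not np.isfinite(fit.fraction_span) or fit.fraction_span < min_fraction_span:
        return False
    return True
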