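"""The Langmuir hybridization isotherm and its clamped inverse.

The equilibrium signal of a microarray probe exposed to target
concentration ``c`` is modelled as the hyperbolic dose-response

    I(c) = a * c / (b + c) + d

where ``a`` is the saturation intensity (above background), ``b`` the
half-saturation concentration (same units as ``c``, typically pM) and
``d`` the background intensity.  Concentration is recovered by the exact
algebraic inverse

    c_hat = b * (I - d) / (a - (I - d))

which is only defined for intensities strictly between the background
``d`` and the saturation limit ``a + d``.  Outside that window the
inverse is clamped: intensities at or above saturation are assigned an
arbitrary large concentration ``X``, intensities at or below background
an arbitrary small concentration ``Y``.  ``X`` and ``Y`` are chosen per
dataset, above the largest and below the smallest nonzero nominal
concentration respectively.

This module is purely computational: no file I/O, scalar or ndarray in,
scalar or ndarray out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, InvalidParamsError

__all__ = [
    "LangmuirParams",
    "ClampBounds",
    "langmuir_intensity",
    "invert_intensity",
]

CLAMP_NONE = "none"
CLAMP_SATURATED = "saturated_X"
CLAMP_BACKGROUND = "background_Y"


@dataclass(frozen=True)
class LangmuirParams:
    """A fitted (a, b, d) triple with fit diagnostics.

    Signs are unconstrained at the type level: fits legitimately return
    negative parameters for probes whose response is not hyperbolic, and
    the training-set filter relies on observing them.  Positivity is the
    business of :func:`langcal.fitting.is_langmuir_like`.

    Attributes
    ----------
    a : float
        Saturation intensity above background (intensity units).
    b : float
        Half-saturation concentration (concentration units).
    d : float
        Background intensity (intensity units).
    converged : bool
        Whether the optimizer reported success.
    residual_ss : float
        Sum of squared residuals of the fit (intensity^2 units).
    n_points : int
        Number of (concentration, intensity) pairs used; >= 3 for any
        fitted instance, 0 for hand-constructed parameter sets.
    """

    a: float
    b: float
    d: float
    converged: bool = True
    residual_ss: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "b", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"parameter {name!r} must be finite, got {v!r}")
        if self.residual_ss < 0:
            raise InvalidInputError("residual_ss must be >= 0")
        if self.n_points != 0 and self.n_points < 3:
            raise InvalidInputError("a fitted instance needs n_points >= 3")

    @property
    def saturation_intensity(self) -> float:
        """The intensity asymptote a + d approached as c -> infinity."""
        return self.a + self.d

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "d": self.d,
            "converged": self.converged,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "LangmuirParams":
        return cls(
            a=float(data["a"]),
            b=float(data["b"]),
            d=float(data["d"]),
            converged=bool(data.get("converged", True)),
            residual_ss=float(data.get("residual_ss", 0.0)),
            n_points=int(data.get("n_points", 0)),
        )

    @classmethod
    def from_json(cls, text: str) -> "LangmuirParams":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ClampBounds:
    """The arbitrary concentrations assigned outside the invertible window.

    ``X`` replaces predictions for intensities at or above the saturation
    limit a + d; ``Y`` replaces predictions for intensities at or below
    the background d.  Both are dataset-level choices: X above the largest
    nominal concentration, Y below the smallest nonzero one.
    """

    X: float
    Y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.X) and math.isfinite(self.Y)):
            raise InvalidInputError("clamp bounds must be finite")
        if not self.X > self.Y > 0:
            raise InvalidInputError(
                f"clamp bounds require X > Y > 0, got X={self.X}, Y={self.Y}"
            )

    @classmethod
    def for_concentrations(
        cls,
        concentrations,
        x_factor: float = 2.0,
        y_factor: float = 0.5,
    ) -> "ClampBounds":
        """Default bounds for a set of nominal concentrations.

        X = ``x_factor`` times the largest concentration and
        Y = ``y_factor`` times the smallest nonzero one, satisfying the
        above-the-largest / below-the-smallest constraint deterministically.
        """
        conc = np.asarray(list(concentrations), dtype=float)
        conc = conc[np.isfinite(conc)]
        nonzero = conc[conc > 0]
        if nonzero.size == 0:
            raise InvalidInputError("need at least one positive concentration")
        return cls(X=x_factor * float(conc.max()), Y=y_factor * float(nonzero.min()))

    def validate_against(self, concentrations) -> None:
        """Check X above the largest and Y below the smallest nonzero value."""
        conc = np.asarray(list(concentrations), dtype=float)
        nonzero = conc[conc > 0]
        if conc.size and not self.X > conc.max():
            raise InvalidInputError(
                f"X={self.X} must exceed the largest nominal concentration {conc.max()}"
            )
        if nonzero.size and not self.Y < nonzero.min():
            raise InvalidInputError(
                f"Y={self.Y} must be below the smallest nonzero concentration {nonzero.min()}"
            )

    def to_dict(self) -> dict:
        return {"X": self.X, "Y": self.Y}


def langmuir_intensity(c, params: LangmuirParams):
    """Forward isotherm: a*c/(b + c) + d.

    Parameters
    ----------
    c : float or array-like
        Nonnegative target concentration(s); ``b + c`` must not vanish.
    params : LangmuirParams

    Returns
    -------
    float or ndarray
        Predicted intensity, strictly increasing in ``c`` when a, b > 0
        and approaching a + d as c -> infinity.
    """
    carr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(carr)):
        raise InvalidInputError("concentration must be finite")
    if np.any(carr < 0):
        raise InvalidInputError("concentration must be >= 0")
    denom = params.b + carr
    if np.any(denom == 0):
        raise InvalidInputError("b + c must be nonzero")
    out = params.a * carr / denom + params.d
    return float(out) if np.isscalar(c) or carr.ndim == 0 else out


def _invert_array(I: np.ndarray, params: LangmuirParams, bounds: ClampBounds):
    """Vectorised clamped inverse; returns (concentrations, clamp labels)."""
    sat = I >= params.a + params.d
    bg = I <= params.d
    mid = ~(sat | bg)
    out = np.empty_like(I)
    signal = I[mid] - params.d
    out[mid] = params.b * signal / (params.a - signal)
    out[sat] = bounds.X
    out[bg] = bounds.Y
    clamp = np.full(I.shape, CLAMP_NONE, dtype=object)
    clamp[sat] = CLAMP_SATURATED
    clamp[bg] = CLAMP_BACKGROUND
    return out, clamp


def invert_intensity(I, params: LangmuirParams, bounds: ClampBounds):
    """Clamped inverse isotherm: intensity -> estimated concentration.

    For d < I < a + d the exact inverse b*(I - d)/(a - (I - d)) is
    returned; I >= a + d (at or above the saturation limit) maps to
    bounds.X, and I <= d (at or below background, including negative
    intensities) maps to bounds.Y.  Boundaries are closed on the clamped
    side because the algebraic inverse is infinite at a + d and zero at d.

    Raises
    ------
    InvalidParamsError
        If a <= 0 or b <= 0: inversion is undefined for non-Langmuir
        fits, which callers must filter out first.
    InvalidInputError
        If any intensity is non-finite.
    """
    if params.a <= 0 or params.b <= 0:
        raise InvalidParamsError(
            f"inversion requires a > 0 and b > 0, got a={params.a}, b={params.b}"
        )
    arr = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("intensity must be finite")
    out, _ = _invert_array(np.atleast_1d(arr), params, bounds)
    return float(out[0]) if arr.ndim == 0 else out.reshape(arr.shape)
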