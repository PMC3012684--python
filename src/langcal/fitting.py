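"""Nonlinear least-squares estimation of the isotherm parameters.

The global-average protocol fits one (a, b, d) triple to the pooled
(concentration, intensity) pairs of a *training set* of probes; the
fitted triple is then applied array-wide.  The per-probe mode fits each
probe independently and exists as the comparison baseline.

The loss is ordinary (unweighted) least squares on the linear intensity
scale by default, mirroring the behaviour of a plain ``nls``-style fit;
a log-scale loss is available.  Parameters are unconstrained by default:
the training-set filter depends on observing negative fitted values for
probes whose response is not hyperbolic, so clamping them away would
defeat the filter.  A constrained mode (a, b, d >= 0) exists for users
who want it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dataio import SpikeInDataset
from .exceptions import InvalidInputError, UnderdeterminedFitError
from .isotherm import LangmuirParams

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSpec",
    "FitOptions",
    "fit_global",
    "fit_per_probe",
    "is_langmuir_like",
]


@dataclass(frozen=True)
class TrainingSpec:
    """The probes whose pooled data determine the global parameters."""

    probe_ids: frozenset
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise InvalidInputError("training set must be nonempty")
        object.__setattr__(self, "probe_ids", frozenset(self.probe_ids))

    @property
    def K(self) -> int:
        return len(self.probe_ids)

    @classmethod
    def sample(cls, dataset: SpikeInDataset, K: int, seed: int) -> "TrainingSpec":
        """Draw K training probes uniformly without replacement."""
        probes = dataset.probe_ids
        if not 1 <= K <= len(probes):
            raise InvalidInputError(
                f"training size K={K} out of range 1..{len(probes)}"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(probes), size=K, replace=False)
        return cls(frozenset(probes[i] for i in chosen), seed=seed)

    def validate_against(self, dataset: SpikeInDataset) -> None:
        unknown = self.probe_ids - set(dataset.probe_ids)
        if unknown:
            raise InvalidInputError(f"training probes not in dataset: {sorted(unknown)}")


@dataclass(frozen=True)
class FitOptions:
    """Optimizer plumbing: scale, initialisation overrides, stopping rules.

    ``init_a/b/d`` override the data-driven defaults (a: intensity range,
    b: median nominal concentration, d: minimum intensity).
    """

    loss_scale: str = "linear"  # "linear" | "log"
    constrained: bool = False
    init_a: float | None = None
    init_b: float | None = None
    init_d: float | None = None
    max_iterations: int = 500
    tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.loss_scale not in ("linear", "log"):
            raise InvalidInputError("loss_scale must be 'linear' or 'log'")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise InvalidInputError("tolerance must be > 0")


def _initial_guess(c: np.ndarray, I: np.ndarray, options: FitOptions) -> np.ndarray:
    a0 = options.init_a if options.init_a is not None else float(I.max() - I.min())
    b0 = options.init_b if options.init_b is not None else float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    d0 = options.init_d if options.init_d is not None else float(I.min())
    if a0 <= 0:
        a0 = max(float(np.ptp(I)), 1.0)
    if b0 <= 0:
        b0 = 1.0
    return np.array([a0, b0, d0], dtype=float)


def fit_xy(
    c: np.ndarray,
    I: np.ndarray,
    options: FitOptions | None = None,
    full_output: bool = False,
):
    """Least-squares fit of I = a*c/(b+c) + d to paired arrays.

    Returns a :class:`LangmuirParams`; with ``full_output=True`` also the
    3x3 parameter covariance estimate (residual variance times the
    pseudo-inverse of J'J), which is NaN-filled when the fit is degenerate.
    """
    options = options or FitOptions()
    c = np.asarray(c, dtype=float)
    I = np.asarray(I, dtype=float)
    if c.shape != I.shape or c.ndim != 1:
        raise InvalidInputError("c and I must be equal-length 1-D arrays")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(I))):
        raise InvalidInputError("fit inputs must be finite")
    if c.size < 3 or np.unique(c).size < 3:
        raise UnderdeterminedFitError(
            "fitting three parameters needs >= 3 points at >= 3 distinct concentrations"
        )

    use_log = options.loss_scale == "log"
    if use_log and np.any(I <= 0):
        raise InvalidInputError("log loss requires positive intensities")

    def residuals(theta):
        a, b, d = theta
        pred = a * c / (b + c) + d
        if use_log:
            # keep the residual finite off-domain so the optimizer can recover
            pred = np.maximum(pred, 1e-12)
            return np.log(pred) - np.log(I)
        return pred - I

    x0 = _initial_guess(c, I, options)
    if options.constrained:
        bounds = (np.zeros(3), np.full(3, np.inf))
        x0 = np.maximum(x0, 1e-9)
        method = "trf"
    else:
        bounds = (-np.inf, np.inf)
        method = "lm" if c.size >= 3 else "trf"

    converged = True
    try:
        res = least_squares(
            residuals,
            x0,
            method=method,
            bounds=bounds if options.constrained else (-np.inf, np.inf),
            max_nfev=options.max_iterations * 10,
            xtol=options.tolerance,
            ftol=options.tolerance,
            gtol=options.tolerance,
        )
        theta = res.x
        converged = bool(res.success)
        jac = res.jac
    except Exception as exc:  # return the initial guess, flagged, never raise
        logger.warning("least_squares failed (%s); returning initial guess", exc)
        theta = x0
        converged = False
        jac = None

    # A rank-deficient Jacobian at the solution means the parameters are not
    # jointly identifiable from these data (constant or linear-in-c responses
    # collapse the three columns) — the situation where nls reports a
    # singular gradient.  Flag it as non-convergence.
    if converged and jac is not None:
        norms = np.linalg.norm(jac, axis=0)
        if np.any(norms <= 1e-12 * norms.max()):
            converged = False
        elif np.linalg.cond(jac / norms) > 1e8:
            converged = False

    lin_resid = theta[0] * c / (theta[1] + c) + theta[2] - I
    params = LangmuirParams(
        a=float(theta[0]),
        b=float(theta[1]),
        d=float(theta[2]),
        converged=converged,
        residual_ss=float(np.sum(lin_resid**2)),
        n_points=int(c.size),
    )
    if not full_output:
        return params
    pcov = np.full((3, 3), np.nan)
    if jac is not None and c.size > 3:
        try:
            jtj_inv = np.linalg.pinv(jac.T @ jac)
            s2 = float(np.sum(residuals(theta) ** 2)) / (c.size - 3)
            pcov = jtj_inv * s2
        except np.linalg.LinAlgError:
            pass
    return params, pcov


def fit_global(
    dataset: SpikeInDataset,
    training: TrainingSpec,
    options: FitOptions | None = None,
    full_output: bool = False,
):
    """Fit one (a, b, d) to the pooled data of the training probes.

    All (concentration, mean intensity) pairs of the training probes are
    pooled and a single triple minimises the summed squared residuals.
    Optimizer failure is reported via ``converged=False``, never by an
    exception, so batch cross-validation can proceed.
    """
    training.validate_against(dataset)
    sub = dataset.subset(training.probe_ids)
    c = sub.table["nominal_concentration"].to_numpy(dtype=float)
    I = sub.table["mean_intensity"].to_numpy(dtype=float)
    return fit_xy(c, I, options, full_output=full_output)


def fit_per_probe(
    dataset: SpikeInDataset | None,
    options: FitOptions | None = None,
) -> dict:
    """Independent per-probe fits (the probe-property-dependent baseline).

    Each probe is fitted on its own rows.  Probes with too few distinct
    concentrations or failed optimizations are returned with
    ``converged=False`` rather than aborting the batch.  An empty or
    ``None`` dataset yields an empty map.
    """
    if dataset is None:
        return {}
    out: dict = {}
    for probe, group in dataset.table.groupby("probe_id", sort=False):
        c = group["nominal_concentration"].to_numpy(dtype=float)
        I = group["mean_intensity"].to_numpy(dtype=float)
        try:
            out[probe] = fit_xy(c, I, options)
        except UnderdeterminedFitError:
            logger.warning("probe %s: underdetermined fit, flagged unconverged", probe)
            out[probe] = LangmuirParams(
                a=0.0, b=1.0, d=float(I.mean()), converged=False,
                residual_ss=float(np.sum((I - I.mean()) ** 2)), n_points=0,
            )
    return out


def is_langmuir_like(params: LangmuirParams) -> bool:
    """Training-set admission filter: all three parameters positive and
    the fit converged.

    Probes whose fitted response returns a negative value for any of a,
    b, d behave non-hyperbolically and are excluded from training; this
    operational rule avoids them without any sequence modelling.
    """
    return bool(params.converged and params.a > 0 and params.b > 0 and params.d > 0)
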