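"""Prediction, category filtering, zero-intercept regression and the
leave-K-out cross-validation harness.

Accuracy of concentration recovery is judged by regressing predicted on
nominal concentration through the origin, y = m x: the slope m measures
accuracy (1 is perfect; below/above 1 under-/over-estimation) and the
coefficient of determination uses the uncentered total sum of squares,
the convention of intercept-free linear model routines.  Spike-ins in
the "low" concentration category — where signal is indistinguishable
from background — are excluded from the regression by default.

Naming convention: "leave-K-out" holds K probes out for prediction and
trains on the remaining N - K, so leave-nine-out on ten probes trains
on a single probe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SpikeInDataset
from .exceptions import (
    InvalidInputError,
    InvalidParamsError,
    NoValidTrainingSetError,
)
from .fitting import FitOptions, TrainingSpec, fit_global, is_langmuir_like
from .isotherm import (
    CLAMP_BACKGROUND,
    CLAMP_NONE,
    CLAMP_SATURATED,
    ClampBounds,
    LangmuirParams,
    _invert_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationEstimates",
    "CategoryThresholds",
    "EvaluationResult",
    "CrossValidation",
    "predict_concentrations",
    "concentration_category",
    "zero_intercept_regression",
    "error_bar_lengths",
    "choose_training_sets",
    "leave_k_out",
]


@dataclass
class ConcentrationEstimates:
    """Predicted concentrations per (probe, condition) with clamp flags.

    ``clamp`` is ``saturated_X`` when the intensity was at or above the
    saturation limit (prediction = X), ``background_Y`` when at or below
    background (prediction = Y), else ``none``.
    """

    table: pd.DataFrame  # probe_id, condition_id, nominal_concentration,
    #                      predicted_concentration, clamp

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_clamped(self) -> int:
        return int((self.table["clamp"] != CLAMP_NONE).sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CategoryThresholds:
    """Boundaries of the low / medium / high concentration categories.

    "Low" (c <= low_max) is the range where signal is indistinguishable
    from background; "high" (c >= high_min) lies beyond the linear range
    where saturation sets in; "medium" is the linear range between them.
    There is no universal default — the boundaries are a property of each
    dataset and must be supplied by the analyst.
    """

    low_max: float
    high_min: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_max < self.high_min:
            raise InvalidInputError(
                f"need 0 <= low_max < high_min, got {self.low_max}, {self.high_min}"
            )


def concentration_category(c: float, thresholds: CategoryThresholds) -> str:
    """Classify a nominal concentration as 'low', 'medium' or 'high'."""
    if c < 0 or not math.isfinite(c):
        raise InvalidInputError("concentration must be finite and >= 0")
    if c <= thresholds.low_max:
        return "low"
    if c >= thresholds.high_min:
        return "high"
    return "medium"


@dataclass
class EvaluationResult:
    """Zero-intercept regression metrics plus per-concentration spreads.

    slope, r_squared and slope_p_value are computed on ``scale``
    ('linear' or 'log2'); per_concentration_sd maps each nominal
    concentration to the sample standard deviation of the (linear-scale)
    predictions across transcripts, the error-bar lengths of a
    calibration plot.
    """

    slope: float
    r_squared: float
    slope_p_value: float
    n_points: int
    scale: str
    per_concentration_sd: dict = field(default_factory=dict)
    training_probes: frozenset | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")
        if not (0.0 <= self.slope_p_value <= 1.0):
            raise InvalidInputError(f"p-value out of [0, 1]: {self.slope_p_value}")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "r_squared": self.r_squared,
            "slope_p_value": self.slope_p_value,
            "n_points": self.n_points,
            "scale": self.scale,
            "per_concentration_sd": {
                str(k): v for k, v in self.per_concentration_sd.items()
            },
            "training_probes": sorted(self.training_probes)
            if self.training_probes is not None
            else None,
        }


def predict_concentrations(
    dataset: SpikeInDataset,
    params: LangmuirParams,
    bounds: ClampBounds | None = None,
    exclude_probes=frozenset(),
) -> ConcentrationEstimates:
    """Invert the fitted isotherm for every (probe, condition) row.

    ``exclude_probes`` is typically the training set, so the test set
    never overlaps the probes that determined the parameters.  Raises
    ``InvalidParamsError`` for non-Langmuir parameter sets (filter with
    ``is_langmuir_like`` first).
    """
    if not is_langmuir_like(params):
        raise InvalidParamsError(
            "prediction requires a Langmuir-like converged fit "
            f"(a={params.a}, b={params.b}, d={params.d}, converged={params.converged})"
        )
    if bounds is None:
        bounds = ClampBounds.for_concentrations(
            dataset.table["nominal_concentration"]
        )
    exclude = set(exclude_probes)
    rows = dataset.table[~dataset.table["probe_id"].isin(exclude)]
    intensities = rows["mean_intensity"].to_numpy(dtype=float)
    pred, clamp = _invert_array(intensities, params, bounds)
    out = pd.DataFrame(
        {
            "probe_id": rows["probe_id"].to_numpy(),
            "condition_id": rows["condition_id"].to_numpy(),
            "nominal_concentration": rows["nominal_concentration"].to_numpy(dtype=float),
            "predicted_concentration": pred,
            "clamp": clamp,
        }
    )
    return ConcentrationEstimates(out)


def zero_intercept_regression(x, y, scale: str = "linear") -> EvaluationResult:
    """Proportional fit y = m x with uncentered R-squared.

    On the chosen scale (values are log2-transformed first when
    ``scale='log2'``, which requires x, y > 0):

        m    = sum(x*y) / sum(x^2)
        R^2  = 1 - SSE / sum(y^2)          (uncentered total SS)
        t    = m / se(m),  se(m)^2 = [SSE/(n-1)] / sum(x^2)

    and the p-value is two-sided against H0: m = 0 with n - 1 degrees of
    freedom — the conventions of a linear-model routine with the
    intercept term omitted.
    """
    if scale not in ("linear", "log2"):
        raise InvalidInputError("scale must be 'linear' or 'log2'")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D sequences")
    if xa.size < 2:
        raise InvalidInputError("regression needs at least 2 points")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise InvalidInputError("regression inputs must be finite")
    if scale == "log2":
        if np.any(xa <= 0) or np.any(ya <= 0):
            raise InvalidInputError("log2 scale requires strictly positive x and y")
        xa = np.log2(xa)
        ya = np.log2(ya)
    sxx = float(np.sum(xa * xa))
    if sxx == 0:
        raise InvalidInputError("all x are zero on the chosen scale")
    m = float(np.sum(xa * ya)) / sxx
    sse = float(np.sum((ya - m * xa) ** 2))
    syy = float(np.sum(ya * ya))
    r2 = 1.0 if syy == 0 else 1.0 - sse / syy
    r2 = min(max(r2, 0.0), 1.0)
    n = xa.size
    se2 = (sse / (n - 1)) / sxx
    if se2 <= 0:
        p = 0.0  # exact fit: the slope is infinitely many s.e. from zero
    else:
        t = m / math.sqrt(se2)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return EvaluationResult(
        slope=m, r_squared=r2, slope_p_value=p, n_points=int(n), scale=scale
    )


def error_bar_lengths(estimates: ConcentrationEstimates) -> dict:
    """Sample SD of predicted concentrations per nominal concentration.

    The error-bar lengths of a calibration plot: for each nominal
    concentration, the (n-1)-denominator standard deviation of the
    predictions across transcripts.  A concentration represented by a
    single estimate maps to 0 with a logged note, keeping downstream
    tables numeric.
    """
    if len(estimates) == 0:
        return {}
    out: dict = {}
    for conc, group in estimates.table.groupby("nominal_concentration", sort=True):
        vals = group["predicted_concentration"].to_numpy(dtype=float)
        if vals.size == 1:
            logger.info(
                "error_bar_lengths: single estimate at concentration %g, SD set to 0",
                conc,
            )
            out[float(conc)] = 0.0
        else:
            out[float(conc)] = float(np.std(vals, ddof=1))
    return out


def choose_training_sets(probe_ids, K: int, max_draws: int, seed: int) -> list:
    """Distinct K-subsets of the probe universe, exhaustive or sampled.

    If C(N, K) <= max_draws every subset is returned (deterministic
    order); otherwise max_draws distinct subsets are drawn uniformly,
    reproducibly under ``seed``, by rejection sampling.
    """
    probes = list(probe_ids)
    N = len(probes)
    if not 1 <= K <= N - 1:
        raise InvalidInputError(f"K={K} out of range 1..{N - 1} for N={N} probes")
    if max_draws < 1:
        raise InvalidInputError("max_draws must be >= 1")
    total = math.comb(N, K)
    if total <= max_draws:
        return [frozenset(c) for c in combinations(probes, K)]
    rng = np.random.default_rng(seed)
    seen: set = set()
    out: list = []
    attempts = 0
    cap = 1000 * max_draws
    while len(out) < max_draws:
        if attempts >= cap:
            raise InvalidInputError(
                f"could not draw {max_draws} distinct subsets in {cap} attempts"
            )
        attempts += 1
        pick = frozenset(probes[i] for i in rng.choice(N, size=K, replace=False))
        if pick not in seen:
            seen.add(pick)
            out.append(pick)
    return out


@dataclass
class CrossValidation:
    """Outcome of a leave-K-out pass: one regression per admitted
    training set, plus the training sets the Langmuir filter rejected."""

    results: list
    skipped_training_sets: list
    holdout: int

    @property
    def n_skipped(self) -> int:
        return len(self.skipped_training_sets)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([r.slope for r in self.results])

    @property
    def r_squared(self) -> np.ndarray:
        return np.array([r.r_squared for r in self.results])


def leave_k_out(
    dataset: SpikeInDataset,
    K: int,
    max_draws: int = 42,
    seed: int = 0,
    bounds: ClampBounds | None = None,
    thresholds: CategoryThresholds | None = None,
    scale: str = "log2",
    options: FitOptions | None = None,
    include_low: bool = False,
) -> CrossValidation:
    """Leave-K-out cross-validation of the global fit.

    For each candidate training set of size N - K (all of them, or
    ``max_draws`` sampled): fit globally on the pooled training data;
    training sets whose fit is not Langmuir-like (a nonpositive
    parameter, or no convergence) are skipped and recorded; otherwise
    the K held-out probes are predicted, rows in the low concentration
    category are dropped (unless ``include_low`` or ``thresholds`` is
    None), zero nominal concentrations are always dropped, and predicted
    vs nominal is regressed through the origin on ``scale``.

    Raises ``NoValidTrainingSetError`` if every candidate is filtered out.
    """
    N = dataset.n_probes
    if not 1 <= K <= N - 1:
        raise InvalidInputError(f"holdout K={K} out of range 1..{N - 1} for N={N}")
    train_size = N - K
    if bounds is None:
        bounds = ClampBounds.for_concentrations(dataset.table["nominal_concentration"])
    training_sets = choose_training_sets(dataset.probe_ids, train_size, max_draws, seed)
    results: list = []
    skipped: list = []
    for train in training_sets:
        params = fit_global(dataset, TrainingSpec(train, seed=seed), options)
        if not is_langmuir_like(params):
            logger.info(
                "leave_k_out: training set %s rejected (a=%.3g, b=%.3g, d=%.3g, "
                "converged=%s)", sorted(train), params.a, params.b, params.d,
                params.converged,
            )
            skipped.append(train)
            continue
        estimates = predict_concentrations(dataset, params, bounds, exclude_probes=train)
        tab = estimates.table
        keep = tab["nominal_concentration"] > 0
        if thresholds is not None and not include_low:
            keep &= tab["nominal_concentration"] > thresholds.low_max
        tab = tab[keep]
        if len(tab) < 2:
            skipped.append(train)
            continue
        res = zero_intercept_regression(
            tab["nominal_concentration"].to_numpy(),
            tab["predicted_concentration"].to_numpy(),
            scale=scale,
        )
        res.per_concentration_sd = error_bar_lengths(ConcentrationEstimates(tab))
        res.training_probes = train
        results.append(res)
    if not results:
        raise NoValidTrainingSetError(
            f"all {len(training_sets)} candidate training sets of size "
            f"{train_size} were rejected"
        )
    return CrossValidation(results=results, skipped_training_sets=skipped, holdout=K)
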