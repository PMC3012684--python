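"""Model/Results front-end over the fitting and evaluation machinery.

``GlobalLangmuirModel`` binds a spike-in dataset to a training-probe
specification; ``fit()`` returns a ``GlobalLangmuirResults`` carrying
the estimated (a, b, d), their standard errors from the least-squares
Jacobian, fit diagnostics, and methods to predict concentrations for
the held-out probes and evaluate them against the nominal truth.

    >>> model = GlobalLangmuirModel(dataset, training_probes=["p1", "p2"])
    >>> res = model.fit()
    >>> print(res.summary())
    >>> est = res.predict()
    >>> res.evaluate(scale="log2").slope
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import SpikeInDataset, average_replicates
from .evaluation import (
    CategoryThresholds,
    ConcentrationEstimates,
    EvaluationResult,
    error_bar_lengths,
    predict_concentrations,
    zero_intercept_regression,
)
from .exceptions import InvalidInputError
from .fitting import FitOptions, TrainingSpec, fit_global, is_langmuir_like
from .isotherm import ClampBounds, LangmuirParams

__all__ = ["GlobalLangmuirModel", "GlobalLangmuirResults"]


class GlobalLangmuirModel:
    """A global Langmuir isotherm bound to spike-in data and a training set.

    Parameters
    ----------
    dataset : SpikeInDataset
        Replicate-averaged intensities with nominal concentrations.
    training_probes : iterable of str, optional
        Probes whose pooled data determine (a, b, d).  Mutually
        exclusive with ``train_size``.
    train_size, seed : int, optional
        Draw ``train_size`` training probes uniformly under ``seed``.
    options : FitOptions, optional
    bounds : ClampBounds, optional
        Clamp concentrations for inversion; defaulted from the dataset.
    """

    def __init__(
        self,
        dataset: SpikeInDataset,
        training_probes=None,
        train_size: int | None = None,
        seed: int | None = None,
        options: FitOptions | None = None,
        bounds: ClampBounds | None = None,
    ) -> None:
        self.dataset = dataset
        if training_probes is not None and train_size is not None:
            raise InvalidInputError("give training_probes or train_size, not both")
        if training_probes is not None:
            self.training = TrainingSpec(frozenset(training_probes), seed=seed)
        elif train_size is not None:
            if seed is None:
                raise InvalidInputError("train_size sampling requires an explicit seed")
            self.training = TrainingSpec.sample(dataset, train_size, seed)
        else:
            raise InvalidInputError("specify training_probes or train_size")
        self.training.validate_against(dataset)
        self.options = options or FitOptions()
        self.bounds = bounds or ClampBounds.for_concentrations(
            dataset.table["nominal_concentration"]
        )

    @classmethod
    def from_tables(
        cls,
        intensity: pd.DataFrame,
        design: pd.DataFrame,
        **kwargs,
    ) -> "GlobalLangmuirModel":
        """Build from raw (un-averaged) intensity and design tables."""
        return cls(average_replicates(intensity, design), **kwargs)

    def fit(self) -> "GlobalLangmuirResults":
        params, pcov = fit_global(
            self.dataset, self.training, self.options, full_output=True
        )
        return GlobalLangmuirResults(self, params, pcov)


class GlobalLangmuirResults:
    """Fitted global isotherm: estimates, uncertainties, diagnostics."""

    param_names = ("a", "b", "d")

    def __init__(
        self,
        model: GlobalLangmuirModel,
        params: LangmuirParams,
        pcov: np.ndarray,
    ) -> None:
        self.model = model
        self.params = params
        self.pcov = pcov

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params.a, self.params.b, self.params.d])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (a, b, d) from the Jacobian at the optimum."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.pcov))

    @property
    def langmuir_like(self) -> bool:
        return is_langmuir_like(self.params)

    def predict(
        self,
        dataset: SpikeInDataset | None = None,
        exclude_training: bool = True,
    ) -> ConcentrationEstimates:
        """Invert the fitted isotherm over the (non-training) probes."""
        ds = dataset or self.model.dataset
        exclude = self.model.training.probe_ids if exclude_training else frozenset()
        return predict_concentrations(ds, self.params, self.model.bounds, exclude)

    def evaluate(
        self,
        scale: str = "log2",
        thresholds: CategoryThresholds | None = None,
        include_low: bool = False,
    ) -> EvaluationResult:
        """Zero-intercept regression of predicted vs nominal concentration."""
        est = self.predict()
        tab = est.table
        keep = tab["nominal_concentration"] > 0
        if thresholds is not None and not include_low:
            keep &= tab["nominal_concentration"] > thresholds.low_max
        tab = tab[keep]
        res = zero_intercept_regression(
            tab["nominal_concentration"].to_numpy(),
            tab["predicted_concentration"].to_numpy(),
            scale=scale,
        )
        res.per_concentration_sd = error_bar_lengths(ConcentrationEstimates(tab))
        res.training_probes = self.model.training.probe_ids
        return res

    def summary(self) -> str:
        lines = [
            "Global Langmuir isotherm fit",
            "=" * 44,
            f"{'training probes':<24}{self.params_training_label()}",
            f"{'pooled points':<24}{self.params.n_points}",
            f"{'converged':<24}{self.params.converged}",
            f"{'Langmuir-like':<24}{self.langmuir_like}",
            f"{'residual SS':<24}{self.params.residual_ss:.6g}",
            "-" * 44,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        for name, est, se in zip(self.param_names, self.theta, self.bse):
            se_txt = f"{se:.4g}" if np.isfinite(se) else "--"
            lines.append(f"{name:<8}{est:>14.6g}{se_txt:>14}")
        lines.append("-" * 44)
        lines.append(
            f"{'clamp bounds':<24}X={self.model.bounds.X:g}, Y={self.model.bounds.Y:g}"
        )
        return "\n".join(lines)

    def params_training_label(self) -> str:
        ids = sorted(self.model.training.probe_ids)
        if len(ids) <= 4:
            return ", ".join(map(str, ids))
        return f"{len(ids)} probes"

    def __repr__(self) -> str:
        return (
            f"<GlobalLangmuirResults a={self.params.a:.4g} b={self.params.b:.4g} "
            f"d={self.params.d:.4g} converged={self.params.converged}>"
        )
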