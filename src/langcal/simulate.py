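"""Synthetic Latin-square spike-in experiments with known ground truth.

The generator emulates the structure of platform control datasets: a
set of spike-in probes observed across conditions that cyclically rotate
a two-fold concentration ladder (a Latin square, so every probe sees
every concentration exactly once), per-probe heterogeneity of the
Langmuir parameters, a configurable fraction of non-hyperbolic
"contaminant" probes (linear or constant responders), and multiplicative
lognormal measurement noise applied independently per technical
replicate.

Defaults follow the best-characterised commercial control design:
42 probes over a 13-step ladder 0.125-512 pM.  Heterogeneity is
lognormal around the global parameters (keeping them positive) with one
coefficient of variation applied to a, b and d independently; noise
magnitudes are free parameters with no platform claim attached.

Randomness is fully reproducible: one stream per probe derived as
``SeedSequence([seed, probe_index])``, so enlarging the probe panel
never perturbs the draws of existing probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .dataio import SpikeInDataset, average_replicates
from .evaluation import CategoryThresholds, CrossValidation, leave_k_out
from .exceptions import ConfigError
from .isotherm import ClampBounds, LangmuirParams, langmuir_intensity

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate",
    "recovery_experiment",
    "RecoverySummary",
    "default_ladder",
]


def default_ladder() -> tuple:
    """13 two-fold steps from 0.125 to 512 (pM)."""
    return tuple(0.125 * 2.0**k for k in range(13))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a synthetic experiment.

    probe_cv is the coefficient of variation of the lognormal per-probe
    deviations of (a, b, d) around the global values; noise_sd_log the
    SD of the per-replicate multiplicative lognormal intensity noise;
    frac_nonlangmuir the fraction of probes replaced by linear or
    constant responders.
    """

    n_probes: int = 42
    concentrations: tuple = field(default_factory=default_ladder)
    n_replicates: int = 3
    global_a: float = 10000.0
    global_b: float = 100.0
    global_d: float = 200.0
    probe_cv: float = 0.2
    noise_sd_log: float = 0.2
    frac_nonlangmuir: float = 0.0
    design: str = "latin_square"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        if self.n_probes < 2:
            raise ConfigError("n_probes must be >= 2")
        if len(set(self.concentrations)) < 3:
            raise ConfigError("need >= 3 distinct concentrations")
        if any(c < 0 for c in self.concentrations):
            raise ConfigError("concentrations must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if min(self.global_a, self.global_b, self.global_d) <= 0:
            raise ConfigError("global parameters must be positive")
        if self.probe_cv < 0 or self.noise_sd_log < 0:
            raise ConfigError("variance parameters must be >= 0")
        if not 0 <= self.frac_nonlangmuir < 1:
            raise ConfigError("frac_nonlangmuir must lie in [0, 1)")
        if self.design not in ("latin_square", "full_factorial"):
            raise ConfigError("design must be 'latin_square' or 'full_factorial'")

    @property
    def global_params(self) -> LangmuirParams:
        return LangmuirParams(self.global_a, self.global_b, self.global_d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "concentrations" in data:
            data["concentrations"] = tuple(float(c) for c in data["concentrations"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["concentrations"] = list(self.concentrations)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Ground truth behind an emitted dataset.

    probe_params has one row per probe: its kind ('langmuir', 'linear'
    or 'constant') and the generating parameters; design repeats the
    emitted design table (concentration per probe x condition) so the
    truth is self-contained.
    """

    probe_params: pd.DataFrame  # probe_id, kind, a, b, d, linear_slope
    design: pd.DataFrame
    seed: int

    def params_for(self, probe_id) -> LangmuirParams:
        row = self.probe_params.set_index("probe_id").loc[probe_id]
        if row["kind"] != "langmuir":
            raise ConfigError(f"probe {probe_id} is a {row['kind']} contaminant")
        return LangmuirParams(float(row["a"]), float(row["b"]), float(row["d"]))

    @property
    def contaminant_probes(self) -> list:
        mask = self.probe_params["kind"] != "langmuir"
        return list(self.probe_params.loc[mask, "probe_id"])


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean) if size else mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _probe_label(i: int, width: int) -> str:
    return f"probe_{i:0{width}d}"


def simulate(config: SimulationConfig):
    """Generate (raw intensity table, design table, truth) for a config.

    latin_square rotates the ladder cyclically: probe i in condition j
    receives concentration ladder[(i + j) mod L] over L = len(ladder)
    conditions, so each probe covers each concentration exactly once.
    full_factorial gives every probe every concentration in every
    condition (L conditions, condition j = ladder[j] for all probes).

    The first round(frac_nonlangmuir * n_probes) probes are contaminants,
    alternating linear (slope * c + d + noise) and constant (d + noise)
    responders.  Same config (including seed) -> bit-identical tables.
    """
    ladder = np.array(config.concentrations, dtype=float)
    L = ladder.size
    n = config.n_probes
    width = len(str(n - 1))
    n_contam = int(round(config.frac_nonlangmuir * n))

    conditions = [f"cond_{j:02d}" for j in range(L)]
    raw_rows = []
    design_rows = []
    truth_rows = []
    for i in range(n):
        probe = _probe_label(i, width)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        if i < n_contam:
            kind = "linear" if i % 2 == 0 else "constant"
            a_i = b_i = np.nan
            d_i = float(_lognormal_around(rng, config.global_d, config.probe_cv))
            # linear responder spans roughly the Langmuir dynamic range
            slope = float(
                _lognormal_around(rng, config.global_a / ladder.max(), config.probe_cv)
            )
        else:
            kind = "langmuir"
            a_i = float(_lognormal_around(rng, config.global_a, config.probe_cv))
            b_i = float(_lognormal_around(rng, config.global_b, config.probe_cv))
            d_i = float(_lognormal_around(rng, config.global_d, config.probe_cv))
            slope = np.nan
        truth_rows.append(
            {"probe_id": probe, "kind": kind, "a": a_i, "b": b_i, "d": d_i,
             "linear_slope": slope}
        )
        for j, cond in enumerate(conditions):
            if config.design == "latin_square":
                c = float(ladder[(i + j) % L])
            else:
                c = float(ladder[j])
            design_rows.append(
                {"probe_id": probe, "condition_id": cond, "nominal_concentration": c}
            )
            if kind == "langmuir":
                clean = a_i * c / (b_i + c) + d_i
            elif kind == "linear":
                clean = slope * c + d_i
            else:
                clean = d_i
            for r in range(config.n_replicates):
                eps = rng.normal(0.0, config.noise_sd_log) if config.noise_sd_log else 0.0
                raw_rows.append(
                    {
                        "probe_id": probe,
                        "condition_id": cond,
                        "replicate_id": f"rep_{r:02d}",
                        "intensity": clean * float(np.exp(eps)),
                    }
                )

    raw = pd.DataFrame(raw_rows)
    design = pd.DataFrame(design_rows)
    truth = SyntheticTruth(
        probe_params=pd.DataFrame(truth_rows), design=design.copy(), seed=config.seed
    )
    return raw, design, truth


@dataclass
class RecoverySummary:
    """Distributional summary of a cross-validated recovery experiment."""

    train_size: int
    holdout: int
    slopes: np.ndarray
    r_squared: np.ndarray
    param_rel_error: np.ndarray  # max over (a, b, d) of |fit/true - 1| per result
    n_skipped: int

    @property
    def median_slope(self) -> float:
        return float(np.median(self.slopes))

    @property
    def median_r_squared(self) -> float:
        return float(np.median(self.r_squared))

    def to_dict(self) -> dict:
        return {
            "train_size": self.train_size,
            "holdout": self.holdout,
            "n_results": int(self.slopes.size),
            "n_skipped": self.n_skipped,
            "median_slope": self.median_slope,
            "median_r_squared": self.median_r_squared,
            "median_param_rel_error": float(np.median(self.param_rel_error))
            if self.param_rel_error.size
            else float("nan"),
        }


def recovery_experiment(
    config: SimulationConfig,
    holdout: int,
    max_draws: int = 42,
    thresholds: CategoryThresholds | None = None,
    scale: str = "log2",
) -> RecoverySummary:
    """Simulate, cross-validate, and summarise parameter/prediction recovery.

    Runs simulate -> average_replicates -> leave_k_out at the given
    holdout, then reports the distributions of slope, R-squared and the
    relative error of each admitted training fit against the generating
    global parameters.
    """
    from .fitting import TrainingSpec, fit_global  # local to avoid cycle at import

    raw, design, truth = simulate(config)
    dataset = average_replicates(raw, design)
    cv = leave_k_out(
        dataset,
        K=holdout,
        max_draws=max_draws,
        seed=config.seed,
        thresholds=thresholds,
        scale=scale,
    )
    true = config.global_params
    errs = []
    for res in cv.results:
        params = fit_global(dataset, TrainingSpec(res.training_probes))
        errs.append(
            max(
                abs(params.a / true.a - 1.0),
                abs(params.b / true.b - 1.0),
                abs(params.d / true.d - 1.0),
            )
        )
    return RecoverySummary(
        train_size=dataset.n_probes - holdout,
        holdout=holdout,
        slopes=cv.slopes,
        r_squared=cv.r_squared,
        param_rel_error=np.array(errs),
        n_skipped=cv.n_skipped,
    )
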