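"""Allometric power-law model, the Rule of Exponents, and scaling strategies.

The model is the classical interspecies power law

    CL = a * W**b

fitted by ordinary least squares on the log-log scale:
``log CL = log a + b * log W``.  Correction-factor variants regress the
product of clearance with a species constant (maximum life-span potential,
MLP, in years; or brain weight in grams) on body weight, and divide the
70-kg evaluation by the corresponding human constant (93.4 years, 1400 g).

The Rule of Exponents (ROE) selects among these methods from the exponent
of the simple fit.  For biologics the MLP method systematically
under-predicts and is never selected: the rule collapses to "use the
brain-weight correction when b > 1.0, otherwise simple allometry".

Human-prediction strategies:

* three-species scaling (simple / ROE / forced-MLP),
* two-species scaling (exact two-point fit, ROE never applied),
* one-species scaling with a fixed exponent,
  ``CL_human = CL_species * (W_human / W_species)**b``,
* one-species scaling averaged over several exponents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .datasets import (
    AdcSeries,
    SpeciesObservation,
    SpeciesRegistry,
    ValidationError,
    default_registry,
)

__all__ = [
    "FittingError",
    "AllometricModel",
    "AllometricResults",
    "fit_power_law",
    "fit_corrected",
    "predict_human",
    "RoeDecision",
    "roe_select",
    "HumanPrediction",
    "classify_ratio",
    "scale_three_species",
    "scale_two_species",
    "scale_one_species",
    "scale_one_species_average",
    "DEFAULT_FIXED_EXPONENTS",
    "DEFAULT_AVERAGING_EXPONENTS",
]

Method = Literal["simple", "mlp_product", "brain_weight_product"]
MoleculeClass = Literal["small_molecule", "biologic"]

#: Fixed exponents explored for one-species scaling.
DEFAULT_FIXED_EXPONENTS: tuple[float, ...] = (0.75, 0.80, 0.85, 1.0)
#: Exponent set for the one-species averaging strategy.
DEFAULT_AVERAGING_EXPONENTS: tuple[float, ...] = (0.85, 1.0, 1.1)

_CORRECTION_TO_METHOD = {"mlp": "mlp_product", "brain_weight": "brain_weight_product"}
# human denominator used when back-transforming a corrected fit
_HUMAN_DIVISOR_FIELD = {"mlp_product": "mlp_years", "brain_weight_product": "brain_weight_g"}
_SPECIES_FACTOR_FIELD = {"mlp": "mlp_years", "brain_weight": "brain_weight_g"}


class FittingError(ValueError):
    """Raised when a power-law fit is requested on unusable points."""


class AllometricModel:
    """Power-law regression model ``value = a * W**b``.

    Parameters
    ----------
    weights
        Body weights in kg, one per species; must be distinct and positive.
    values
        Positive fitted quantity (clearance, or clearance x correction
        constant) in the units implied by ``method``.
    method
        ``simple``, ``mlp_product`` or ``brain_weight_product``; determines
        how :meth:`AllometricResults.predict_human` back-transforms.
    species
        Optional species labels, carried through to the results.
    """

    def __init__(
        self,
        weights: Sequence[float],
        values: Sequence[float],
        method: Method = "simple",
        species: Sequence[str] | None = None,
    ):
        weights = np.asarray(weights, dtype=float)
        values = np.asarray(values, dtype=float)
        if weights.shape != values.shape or weights.ndim != 1:
            raise FittingError("weights and values must be 1-d and the same length")
        if weights.size < 2:
            raise FittingError("at least two species are required for a fit")
        if np.unique(weights).size != weights.size:
            raise FittingError("body weights must be distinct")
        if not (np.all(weights > 0) and np.all(values > 0)):
            raise FittingError("weights and values must be strictly positive")
        self.weights = weights
        self.values = values
        self.method: Method = method
        self.species = tuple(species) if species is not None else tuple(
            f"s{i}" for i in range(weights.size)
        )
        self._logw = np.log(weights)
        self._logv = np.log(values)

    @classmethod
    def from_series(
        cls,
        series: AdcSeries,
        constants: SpeciesRegistry | None = None,
        correction: Literal["mlp", "brain_weight"] | None = None,
        species_subset: Sequence[str] | None = None,
    ) -> "AllometricModel":
        """Build a model from a series' animal panel.

        ``correction`` multiplies each clearance by the species' MLP or
        brain weight before fitting (the correction-factor product methods).
        ``species_subset`` restricts the panel (used for two-species fits).
        """
        constants = constants or default_registry()
        animals = series.animals
        if species_subset is not None:
            animals = tuple(series.observation(s) for s in species_subset)
        weights, values, names = [], [], []
        for obs in animals:
            sc = constants[obs.species]
            factor = 1.0
            if correction is not None:
                factor = getattr(sc, _SPECIES_FACTOR_FIELD[correction])
            weights.append(sc.body_weight_kg)
            values.append(obs.clearance_ml_day * factor)
            names.append(sc.species)
        method: Method = "simple" if correction is None else _CORRECTION_TO_METHOD[correction]  # type: ignore[assignment]
        order = np.argsort(weights)
        return cls(
            [weights[i] for i in order],
            [values[i] for i in order],
            method=method,
            species=[names[i] for i in order],
        )

    def fit(self) -> "AllometricResults":
        """OLS of log(value) on log(weight); exact interpolant for n = 2."""
        exog = sm.add_constant(self._logw)
        ols = sm.OLS(self._logv, exog).fit()
        return AllometricResults(self, ols)


class AllometricResults:
    """Fitted power law: coefficient ``a``, exponent ``b``, diagnostics."""

    def __init__(self, model: AllometricModel, ols_results):
        self.model = model
        self._ols = ols_results
        intercept, slope = ols_results.params
        self.coefficient_a: float = float(math.exp(intercept))
        self.exponent_b: float = float(slope)

    # -- metadata -------------------------------------------------------
    @property
    def method(self) -> Method:
        return self.model.method

    @property
    def species_used(self) -> tuple[str, ...]:
        return self.model.species

    @property
    def n_species(self) -> int:
        return len(self.model.weights)

    @property
    def params(self) -> tuple[float, float]:
        """(a, b) on the power-law scale."""
        return (self.coefficient_a, self.exponent_b)

    # -- diagnostics ----------------------------------------------------
    @property
    def exponent_se(self) -> float:
        """Standard error of b (0/undefined for a two-point fit)."""
        return float(self._ols.bse[1]) if self.n_species > 2 else float("nan")

    @property
    def rsquared_log(self) -> float:
        return float(self._ols.rsquared) if self.n_species > 2 else 1.0

    def log_residuals(self) -> np.ndarray:
        return np.asarray(self._ols.resid)

    # -- prediction -----------------------------------------------------
    def predict(self, body_weight: float) -> float:
        """Fitted quantity (product scale for corrected methods) at W kg."""
        return self.coefficient_a * body_weight ** self.exponent_b

    def predict_human(self, constants: SpeciesRegistry | None = None) -> float:
        """Predicted human clearance in mL/day, using unrounded (a, b).

        ``a * 70**b`` for the simple method; corrected methods divide by the
        human MLP (93.4 y) or human brain weight (1400 g).
        """
        constants = constants or default_registry()
        human = constants.human
        value = self.predict(human.body_weight_kg)
        divisor_field = _HUMAN_DIVISOR_FIELD.get(self.method)
        if divisor_field is not None:
            value /= getattr(human, divisor_field)
        return value

    def summary(self) -> str:
        lines = [
            f"Allometric power-law fit ({self.method})",
            f"  species ({self.n_species}): {', '.join(self.species_used)}",
            f"  a = {self.coefficient_a:.4g}   b = {self.exponent_b:.4f}"
            + (f" (SE {self.exponent_se:.3f})" if self.n_species > 2 else ""),
            f"  R^2 (log-log) = {self.rsquared_log:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<AllometricResults {self.method} a={self.coefficient_a:.4g} "
            f"b={self.exponent_b:.4g} n={self.n_species}>"
        )


def fit_power_law(points: Sequence[tuple[float, float]]) -> AllometricResults:
    """Fit ``value = a * W**b`` to (weight, value) pairs by log-log OLS."""
    if len(points) == 0:
        raise FittingError("no points supplied")
    weights, values = zip(*points)
    return AllometricModel(weights, values).fit()


def fit_corrected(
    series: AdcSeries,
    constants: SpeciesRegistry | None = None,
    correction: Literal["mlp", "brain_weight"] = "brain_weight",
) -> AllometricResults:
    """Fit the correction-factor product (CL x MLP or CL x brain weight)."""
    if correction not in _SPECIES_FACTOR_FIELD:
        raise ValueError(f"correction must be 'mlp' or 'brain_weight', got {correction!r}")
    return AllometricModel.from_series(series, constants, correction=correction).fit()


def predict_human(
    fit: AllometricResults, constants: SpeciesRegistry | None = None
) -> float:
    """Predicted human clearance (mL/day) from a fitted power law."""
    return fit.predict_human(constants)


# ---------------------------------------------------------------------------
# Rule of Exponents
# ---------------------------------------------------------------------------

Band = Literal["low", "sa_band", "mlp_band", "brain_band", "high"]


@dataclass(frozen=True)
class RoeDecision:
    """Method choice implied by the simple-allometry exponent.

    Bands: ``low`` (< 0.56), ``sa_band`` (0.56-0.70), ``mlp_band``
    (0.71-0.99), ``brain_band`` (1.0-1.3), ``high`` (> 1.3).  For
    biologics the MLP method is never chosen; the brain-weight correction
    applies iff b > 1.0.  Out-of-band exponents are flagged via ``band``
    but trigger no invented correction.
    """

    exponent_b: float
    chosen_method: Method
    band: Band
    molecule_class: MoleculeClass

    @property
    def rationale(self) -> str:
        return (
            f"b = {self.exponent_b:.2f} ({self.band}) for a "
            f"{self.molecule_class} -> {self.chosen_method}"
        )


def _roe_band(b: float) -> Band:
    if b < 0.56:
        return "low"
    if b <= 0.70:
        return "sa_band"
    if b < 1.0:
        return "mlp_band"
    if b <= 1.3:
        return "brain_band"
    return "high"


def roe_select(b_sa: float, molecule_class: MoleculeClass = "biologic") -> RoeDecision:
    """Apply the Rule of Exponents to a simple-allometry exponent."""
    if not math.isfinite(b_sa):
        raise ValueError(f"exponent must be finite, got {b_sa!r}")
    band = _roe_band(b_sa)
    if molecule_class == "biologic":
        chosen: Method = "brain_weight_product" if b_sa > 1.0 else "simple"
    elif molecule_class == "small_molecule":
        if band == "mlp_band":
            chosen = "mlp_product"
        elif band == "brain_band":
            chosen = "brain_weight_product"
        else:  # sa_band, or out-of-band flagged via `band`
            chosen = "simple"
    else:
        raise ValueError(f"unknown molecule class {molecule_class!r}")
    return RoeDecision(
        exponent_b=b_sa, chosen_method=chosen, band=band, molecule_class=molecule_class
    )


# ---------------------------------------------------------------------------
# Human predictions
# ---------------------------------------------------------------------------


def classify_ratio(ratio: float) -> str:
    """Fold-error bucket: under (< 0.5), within ([0.5, 2.0]), over (> 2.0).

    Boundaries are inclusive on the 'within' side and applied to the
    unrounded ratio.
    """
    if ratio < 0.5:
        return "under"
    if ratio <= 2.0:
        return "within"
    return "over"


@dataclass(frozen=True)
class HumanPrediction:
    """One human clearance prediction and its evaluation against observation."""

    drug: str
    analyte: str
    strategy: str
    predicted_cl: float
    detail: Mapping[str, object] = field(default_factory=dict)
    coefficient: float | None = None
    exponent: float | None = None
    observed_cl: float | None = None
    ratio: float | None = None
    classification: str | None = None

    def __post_init__(self) -> None:
        if not self.predicted_cl > 0:
            raise ValidationError(
                f"{self.drug} ({self.strategy}): predicted clearance must be "
                f"positive, got {self.predicted_cl!r}"
            )


def _with_evaluation(prediction: HumanPrediction) -> HumanPrediction:
    """Fill ratio and fold classification when the observed CL is known."""
    if prediction.observed_cl is None:
        return prediction
    ratio = prediction.predicted_cl / prediction.observed_cl
    return HumanPrediction(
        **{
            **prediction.__dict__,
            "ratio": ratio,
            "classification": classify_ratio(ratio),
        }
    )


def scale_three_species(
    series: AdcSeries,
    constants: SpeciesRegistry | None = None,
    strategy: Literal["sa_only", "roe", "mlp_forced"] = "roe",
) -> HumanPrediction:
    """Three-species scaling: simple allometry, ROE, or forced MLP.

    ``roe`` fits simple allometry, applies the biologic Rule of Exponents,
    and refits with the brain-weight correction when selected.
    ``mlp_forced`` always applies the MLP correction (demonstrates its
    systematic under-prediction for biologics; not a recommended strategy).
    """
    constants = constants or default_registry()
    if series.n_animal_species < 3:
        raise ValidationError(
            f"{series.drug} ({series.analyte}) has only {series.n_animal_species} "
            "animal species; use scale_two_species or scale_one_species"
        )
    sa = AllometricModel.from_series(series, constants).fit()
    detail: dict[str, object] = {
        "species": series.species,
        "b_sa": sa.exponent_b,
    }
    if strategy == "sa_only":
        fit, name = sa, "three_species_sa"
    elif strategy == "mlp_forced":
        fit, name = fit_corrected(series, constants, "mlp"), "three_species_mlp"
    elif strategy == "roe":
        decision = roe_select(sa.exponent_b, "biologic")
        detail["band"] = decision.band
        detail["roe_method"] = decision.chosen_method
        if decision.chosen_method == "brain_weight_product":
            fit = fit_corrected(series, constants, "brain_weight")
        else:
            fit = sa
        name = "three_species_roe"
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    detail["method"] = fit.method
    return _with_evaluation(
        HumanPrediction(
            drug=series.drug,
            analyte=series.analyte,
            strategy=name,
            predicted_cl=fit.predict_human(constants),
            detail=detail,
            coefficient=fit.coefficient_a,
            exponent=fit.exponent_b,
            observed_cl=series.human_observed_cl,
        )
    )


def scale_two_species(
    series: AdcSeries,
    pair: tuple[str, str],
    constants: SpeciesRegistry | None = None,
) -> HumanPrediction:
    """Two-species scaling: exact two-point fit, simple allometry only.

    The Rule of Exponents is not applicable to two species and is never
    applied here.
    """
    constants = constants or default_registry()
    fit = AllometricModel.from_series(series, constants, species_subset=pair).fit()
    return _with_evaluation(
        HumanPrediction(
            drug=series.drug,
            analyte=series.analyte,
            strategy="two_species_sa",
            predicted_cl=fit.predict_human(constants),
            detail={"pair": tuple(fit.species_used), "method": "simple"},
            coefficient=fit.coefficient_a,
            exponent=fit.exponent_b,
            observed_cl=series.human_observed_cl,
        )
    )


def scale_one_species(
    observation: SpeciesObservation,
    constants: SpeciesRegistry | None = None,
    exponent: float = 1.0,
    *,
    drug: str = "",
    analyte: str = "total",
    observed_cl: float | None = None,
) -> HumanPrediction:
    """One-species scaling with a fixed exponent.

    ``CL_human = CL_species * (W_human / W_species)**exponent`` — the
    weight-ratio form; with exponent 1.0 this is linear (per-kg)
    extrapolation.
    """
    constants = constants or default_registry()
    if not exponent > 0:
        raise ValueError(f"exponent must be positive, got {exponent!r}")
    sp = constants[observation.species]
    if sp.species == "human":
        raise ValidationError("one-species scaling requires a non-human species")
    ratio_w = constants.human.body_weight_kg / sp.body_weight_kg
    predicted = observation.clearance_ml_day * ratio_w ** exponent
    return _with_evaluation(
        HumanPrediction(
            drug=drug,
            analyte=analyte,
            strategy="one_species_fixed",
            predicted_cl=predicted,
            detail={"species": sp.species, "exponent": exponent},
            exponent=exponent,
            observed_cl=observed_cl,
        )
    )


def scale_one_species_average(
    observation: SpeciesObservation,
    constants: SpeciesRegistry | None = None,
    exponents: Sequence[float] = DEFAULT_AVERAGING_EXPONENTS,
    *,
    drug: str = "",
    analyte: str = "total",
    observed_cl: float | None = None,
) -> HumanPrediction:
    """Arithmetic mean of one-species predictions over several exponents."""
    if len(exponents) == 0:
        raise ValueError("exponent list must be non-empty")
    parts = [
        scale_one_species(
            observation, constants, e, drug=drug, analyte=analyte
        ).predicted_cl
        for e in exponents
    ]
    return _with_evaluation(
        HumanPrediction(
            drug=drug,
            analyte=analyte,
            strategy="one_species_average",
            predicted_cl=float(np.mean(parts)),
            detail={
                "species": observation.species,
                "exponents": tuple(float(e) for e in exponents),
            },
            observed_cl=observed_cl,
        )
    )
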