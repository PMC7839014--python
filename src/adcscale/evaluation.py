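"""Prediction-ratio statistics, per-strategy summaries, and the full analysis.

The evaluation metric throughout is the prediction ratio
``predicted / observed`` human clearance; a prediction is "acceptable"
when the ratio lies within 0.5–2-fold (inclusive at both boundaries,
judged on the unrounded ratio).  Percent error is ``(ratio - 1) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import (
    DEFAULT_AVERAGING_EXPONENTS,
    DEFAULT_FIXED_EXPONENTS,
    HumanPrediction,
    classify_ratio,
    scale_one_species,
    scale_one_species_average,
    scale_three_species,
    scale_two_species,
)
from .datasets import AdcDataset, SpeciesRegistry, ValidationError, builtin_adc_dataset, default_registry

__all__ = [
    "evaluate",
    "StrategySummary",
    "summarize_strategy",
    "AnalysisResults",
    "run_full_analysis",
    "TWO_SPECIES_PAIRS",
]

#: Pair enumeration order for the two-species analysis.
TWO_SPECIES_PAIRS: tuple[tuple[str, str], ...] = (
    ("mouse", "monkey"),
    ("mouse", "rat"),
    ("rat", "monkey"),
)

_TABLE_COLUMNS = [
    "drug",
    "analyte",
    "strategy",
    "detail",
    "coefficient",
    "exponent",
    "predicted",
    "observed",
    "ratio",
    "classification",
]


def evaluate(prediction: HumanPrediction, observed: float) -> HumanPrediction:
    """Fill the prediction ratio and fold classification for an observation."""
    if not observed > 0:
        raise ValidationError(f"observed clearance must be positive, got {observed!r}")
    ratio = prediction.predicted_cl / observed
    return replace(
        prediction,
        observed_cl=observed,
        ratio=ratio,
        classification=classify_ratio(ratio),
    )


@dataclass(frozen=True)
class StrategySummary:
    """Fold-error bookkeeping for one prediction strategy."""

    strategy: str
    detail: str
    n_observations: int
    n_under: int
    n_within: int
    n_over: int
    pct_within: float
    ratio_min: float
    ratio_max: float

    @property
    def pct_within_rounded(self) -> int:
        """Percentage rounded half-up to an integer for display."""
        return int(np.floor(self.pct_within + 0.5))


def summarize_strategy(
    predictions: Iterable[HumanPrediction],
    strategy: str | None = None,
    detail: str = "",
) -> StrategySummary:
    """Count under / within / over classifications and the ratio range."""
    preds = list(predictions)
    if not preds:
        raise ValidationError("cannot summarise an empty prediction collection")
    if any(p.ratio is None for p in preds):
        raise ValidationError("all predictions must be evaluated (ratio present)")
    ratios = np.array([p.ratio for p in preds], dtype=float)
    classes = [p.classification for p in preds]
    n = len(preds)
    n_within = classes.count("within")
    return StrategySummary(
        strategy=strategy or preds[0].strategy,
        detail=detail,
        n_observations=n,
        n_under=classes.count("under"),
        n_within=n_within,
        n_over=classes.count("over"),
        pct_within=100.0 * n_within / n,
        ratio_min=float(ratios.min()),
        ratio_max=float(ratios.max()),
    )


def _detail_str(p: HumanPrediction) -> str:
    d = p.detail
    if "pair" in d:
        return "+".join(d["pair"])  # type: ignore[arg-type]
    if "exponents" in d:
        return f"{d['species']} E{','.join(f'{e:g}' for e in d['exponents'])}"  # type: ignore[union-attr]
    if "exponent" in d:
        return f"{d['species']} E{d['exponent']:g}"
    if "method" in d:
        return str(d["method"])
    return ""


def _rows(preds: Iterable[HumanPrediction]) -> pd.DataFrame:
    records = []
    for p in preds:
        records.append(
            (
                p.drug,
                p.analyte,
                p.strategy,
                _detail_str(p),
                p.coefficient,
                p.exponent,
                p.predicted_cl,
                p.observed_cl,
                p.ratio,
                p.classification,
            )
        )
    return pd.DataFrame(records, columns=_TABLE_COLUMNS)


@dataclass
class AnalysisResults:
    """Structured output of :func:`run_full_analysis`.

    Tidy per-prediction tables (pandas DataFrames) plus per-strategy
    summaries; ``predictions`` keeps the underlying
    :class:`~adcscale.allometry.HumanPrediction` objects keyed by strategy
    label for programmatic use.
    """

    three_species: pd.DataFrame
    two_species: pd.DataFrame
    one_species: pd.DataFrame
    mouse_average: pd.DataFrame
    summaries: pd.DataFrame
    predictions: Mapping[str, Sequence[HumanPrediction]]

    _TABLES = ("three_species", "two_species", "one_species", "mouse_average", "summaries")

    def to_csv(self, outdir: str | Path) -> list[Path]:
        """Write each table as CSV under ``outdir``; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self._TABLES:
            path = outdir / f"table_{name}.csv"
            getattr(self, name).to_csv(path, index=False, float_format="%.6g")
            written.append(path)
        return written

    def render_text(self) -> str:
        """Aligned-text rendering of all tables."""
        blocks = []
        for name in self._TABLES:
            frame = getattr(self, name)
            blocks.append(f"== {name.replace('_', ' ')} ==")
            blocks.append(frame.round(3).to_string(index=False))
            blocks.append("")
        return "\n".join(blocks)


def run_full_analysis(
    dataset: AdcDataset | None = None,
    constants: SpeciesRegistry | None = None,
    fixed_exponents: Sequence[float] = DEFAULT_FIXED_EXPONENTS,
    averaging_exponents: Sequence[float] = DEFAULT_AVERAGING_EXPONENTS,
) -> AnalysisResults:
    """Run every scaling strategy over a dataset and summarise fold errors.

    Emits (i) the three-species table (simple rows for every >=3-species
    series, brain-weight rows where the ROE selects them, forced-MLP rows),
    (ii) the two-species table over all available pairs of total-antibody
    panels, (iii) the one-species fixed-exponent table, (iv) the mouse
    averaging-strategy table, and (v) per-strategy summaries.  Ordering is
    deterministic: drug, then analyte.
    """
    constants = constants or default_registry()
    dataset = (dataset if dataset is not None else builtin_adc_dataset(constants)).sorted()
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")

    preds: dict[str, list[HumanPrediction]] = {
        "three_species_sa": [],
        "three_species_roe": [],
        "three_species_mlp": [],
    }

    three_rows: list[HumanPrediction] = []
    for series in dataset.three_species():
        sa = scale_three_species(series, constants, "sa_only")
        roe = scale_three_species(series, constants, "roe")
        mlp = scale_three_species(series, constants, "mlp_forced")
        preds["three_species_sa"].append(sa)
        preds["three_species_roe"].append(roe)
        preds["three_species_mlp"].append(mlp)
        three_rows.append(sa)
        if roe.detail.get("method") != "simple":
            three_rows.append(roe)
        three_rows.append(mlp)

    two_rows: list[HumanPrediction] = []
    totals = dataset.total_antibody()
    for pair in TWO_SPECIES_PAIRS:
        key = f"two_species_{pair[0]}_{pair[1]}"
        preds[key] = []
        for series in totals:
            if not series.has_species(*pair):
                continue
            p = scale_two_species(series, pair, constants)
            preds[key].append(p)
            two_rows.append(p)
    # restore drug-major ordering in the two-species table
    two_rows.sort(key=lambda p: (p.drug.lower(), p.analyte, _detail_str(p)))

    one_rows: list[HumanPrediction] = []
    for species in ("mouse", "rat", "monkey"):
        for exponent in fixed_exponents:
            key = f"one_species_{species}_E{exponent:g}"
            preds[key] = []
            for series in totals:
                if not series.has_species(species):
                    continue
                p = scale_one_species(
                    series.observation(species),
                    constants,
                    exponent,
                    drug=series.drug,
                    analyte=series.analyte,
                    observed_cl=series.human_observed_cl,
                )
                preds[key].append(p)
                one_rows.append(p)
    one_rows.sort(key=lambda p: (p.drug.lower(), p.analyte, _detail_str(p)))

    avg_rows: list[HumanPrediction] = []
    preds["one_species_average_mouse"] = []
    for series in totals:
        if not series.has_species("mouse"):
            continue
        p = scale_one_species_average(
            series.observation("mouse"),
            constants,
            averaging_exponents,
            drug=series.drug,
            analyte=series.analyte,
            observed_cl=series.human_observed_cl,
        )
        preds["one_species_average_mouse"].append(p)
        avg_rows.append(p)

    summaries = []
    for key, plist in preds.items():
        evaluated = [p for p in plist if p.ratio is not None]
        if not evaluated:
            continue
        s = summarize_strategy(evaluated, strategy=key)
        summaries.append(
            (
                key,
                s.n_observations,
                s.n_under,
                s.n_within,
                s.n_over,
                s.pct_within,
                s.pct_within_rounded,
                s.ratio_min,
                s.ratio_max,
            )
        )
    summary_frame = pd.DataFrame(
        summaries,
        columns=[
            "strategy",
            "n_observations",
            "n_under",
            "n_within",
            "n_over",
            "pct_within",
            "pct_within_display",
            "ratio_min",
            "ratio_max",
        ],
    )

    return AnalysisResults(
        three_species=_rows(three_rows),
        two_species=_rows(two_rows),
        one_species=_rows(one_rows),
        mouse_average=_rows(avg_rows),
        summaries=summary_frame,
        predictions=preds,
    )
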