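"""Multi-species clearance datasets and the species-constants registry.

The central containers are :class:`SpeciesRegistry` (per-species body weight,
brain weight, and maximum life-span potential) and :class:`AdcDataset`, a
validated collection of :class:`AdcSeries` — one drug x analyte panel of
animal clearance observations plus the observed human clearance.

Clearances are absolute (mL/day), never per-kg: every downstream computation
in this package operates on absolute clearance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "SpeciesConstants",
    "SpeciesRegistry",
    "SpeciesObservation",
    "AdcSeries",
    "AdcDataset",
    "load_constants",
    "load_dataset",
    "save_dataset",
    "builtin_adc_dataset",
    "HUMAN",
]

HUMAN = "human"

ANALYTES = ("total", "conjugate")

_CONSTANTS_COLUMNS = ["species", "body_weight_kg", "brain_weight_g", "mlp_years"]
_DATASET_COLUMNS = ["drug", "analyte", "species", "clearance_ml_per_day"]


class ValidationError(ValueError):
    """Raised when a dataset or registry violates its invariants."""


@dataclass(frozen=True)
class SpeciesConstants:
    """Physiological constants for one species.

    body_weight_kg
        Reference body weight W (kg) used in all power-law fits.
    brain_weight_g
        Brain weight (g); multiplicative correction factor for the
        brain-weight method.
    mlp_years
        Maximum life-span potential (years); correction factor for the
        MLP method.
    """

    species: str
    body_weight_kg: float
    brain_weight_g: float
    mlp_years: float

    def __post_init__(self) -> None:
        for name in ("body_weight_kg", "brain_weight_g", "mlp_years"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(
                    f"species {self.species!r}: {name} must be strictly "
                    f"positive, got {value!r}"
                )


class SpeciesRegistry:
    """Lookup table of :class:`SpeciesConstants`, keyed case-insensitively."""

    def __init__(self, entries: Iterable[SpeciesConstants]):
        self._entries: dict[str, SpeciesConstants] = {}
        for entry in entries:
            key = entry.species.strip().lower()
            if key in self._entries:
                raise ValidationError(f"duplicate species {entry.species!r} in registry")
            self._entries[key] = replace(entry, species=key)
        if not self._entries:
            raise ValidationError("species registry is empty")

    def __contains__(self, species: str) -> bool:
        return species.strip().lower() in self._entries

    def __iter__(self) -> Iterator[SpeciesConstants]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, species: str) -> SpeciesConstants:
        key = species.strip().lower()
        try:
            return self._entries[key]
        except KeyError:
            known = ", ".join(sorted(self._entries))
            raise ValidationError(
                f"unknown species {species!r}; registry contains: {known}"
            ) from None

    @property
    def human(self) -> SpeciesConstants:
        return self[HUMAN]

    def body_weight(self, species: str) -> float:
        return self[species].body_weight_kg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.species, c.body_weight_kg, c.brain_weight_g, c.mlp_years)
                for c in self
            ],
            columns=_CONSTANTS_COLUMNS,
        )


def default_registry() -> SpeciesRegistry:
    """The four-species registry (mouse, rat, cynomolgus monkey, human).

    Body weights 0.02 / 0.25 / 3.5 / 70 kg, brain weights 0.36 / 1.8 / 63 /
    1400 g, MLP 3 / 4.4 / 18 / 93.4 years.
    """
    return load_constants(None)


def _read_bundled(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("adcscale.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_constants(source: str | Path | None = None) -> SpeciesRegistry:
    """Load a species-constants registry from CSV, or the built-in default.

    The CSV must carry the header
    ``species,body_weight_kg,brain_weight_g,mlp_years``.
    """
    if source is None or source == "builtin":
        frame = _read_bundled("species_constants.csv")
    else:
        frame = pd.read_csv(source)
    missing = [c for c in _CONSTANTS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"constants file missing column(s): {', '.join(missing)}")
    entries = []
    for idx, row in frame.iterrows():
        try:
            entries.append(
                SpeciesConstants(
                    species=str(row["species"]),
                    body_weight_kg=float(row["body_weight_kg"]),
                    brain_weight_g=float(row["brain_weight_g"]),
                    mlp_years=float(row["mlp_years"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"constants row {idx} ({row['species']!r}): {exc}")
    return SpeciesRegistry(entries)


@dataclass(frozen=True)
class SpeciesObservation:
    """One animal (or human) clearance measurement, absolute mL/day."""

    species: str
    clearance_ml_day: float

    def __post_init__(self) -> None:
        if not self.clearance_ml_day > 0:
            raise ValidationError(
                f"{self.species}: clearance must be strictly positive "
                f"(log-transform must be defined), got {self.clearance_ml_day!r}"
            )


@dataclass(frozen=True)
class AdcSeries:
    """One drug x analyte panel: animal observations + observed human CL.

    The observed human clearance is deliberately kept off the ``animals``
    collection so fitting code can never include humans in a fit.
    """

    drug: str
    analyte: str
    animals: tuple[SpeciesObservation, ...]
    human_observed_cl: float | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"{self.drug}: analyte must be one of {ANALYTES}, got {self.analyte!r}"
            )
        if not self.animals:
            raise ValidationError(f"{self.drug} ({self.analyte}): no animal observations")
        seen: set[str] = set()
        for obs in self.animals:
            key = obs.species.strip().lower()
            if key == HUMAN:
                raise ValidationError(
                    f"{self.drug} ({self.analyte}): human must not appear among "
                    "animal observations"
                )
            if key in seen:
                raise ValidationError(
                    f"{self.drug} ({self.analyte}): duplicate species {obs.species!r}"
                )
            seen.add(key)
        if self.human_observed_cl is not None and not self.human_observed_cl > 0:
            raise ValidationError(
                f"{self.drug} ({self.analyte}): observed human clearance must be "
                f"positive, got {self.human_observed_cl!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug, self.analyte)

    @property
    def n_animal_species(self) -> int:
        return len(self.animals)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(obs.species for obs in self.animals)

    def observation(self, species: str) -> SpeciesObservation:
        key = species.strip().lower()
        for obs in self.animals:
            if obs.species.strip().lower() == key:
                return obs
        raise ValidationError(
            f"{self.drug} ({self.analyte}): species {species!r} not in series "
            f"(has {', '.join(self.species)})"
        )

    def has_species(self, *species: str) -> bool:
        present = {s.strip().lower() for s in self.species}
        return all(s.strip().lower() in present for s in species)


class AdcDataset:
    """Ordered, validated collection of :class:`AdcSeries`."""

    def __init__(self, series: Iterable[AdcSeries]):
        self._series: list[AdcSeries] = list(series)
        keys = [s.key for s in self._series]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValidationError(f"duplicate (drug, analyte) series: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self._series)

    def __iter__(self) -> Iterator[AdcSeries]:
        return iter(self._series)

    def __getitem__(self, key: tuple[str, str] | str) -> AdcSeries:
        if isinstance(key, str):
            matches = [s for s in self._series if s.drug.lower() == key.lower()]
            if not matches:
                available = ", ".join(sorted({s.drug for s in self._series}))
                raise KeyError(f"unknown drug {key!r}; available: {available}")
            if len(matches) > 1:
                raise KeyError(
                    f"drug {key!r} has multiple analytes "
                    f"({', '.join(s.analyte for s in matches)}); pass (drug, analyte)"
                )
            return matches[0]
        drug, analyte = key
        for s in self._series:
            if s.drug.lower() == drug.lower() and s.analyte == analyte:
                return s
        raise KeyError(f"no series ({drug!r}, {analyte!r})")

    def sorted(self) -> "AdcDataset":
        return AdcDataset(sorted(self._series, key=lambda s: (s.drug.lower(), s.analyte)))

    def three_species(self) -> "AdcDataset":
        """Subset with at least three animal species (ROE-eligible)."""
        return AdcDataset(s for s in self._series if s.n_animal_species >= 3)

    def total_antibody(self) -> "AdcDataset":
        return AdcDataset(s for s in self._series if s.analyte == "total")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self._series:
            for obs in s.animals:
                rows.append((s.drug, s.analyte, obs.species, obs.clearance_ml_day))
            if s.human_observed_cl is not None:
                rows.append((s.drug, s.analyte, HUMAN, s.human_observed_cl))
        return pd.DataFrame(rows, columns=_DATASET_COLUMNS)


def _series_from_frame(
    frame: pd.DataFrame, constants: SpeciesRegistry
) -> list[AdcSeries]:
    missing = [c for c in _DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"dataset missing column(s): {', '.join(missing)}")
    unknown = sorted(
        {
            str(sp)
            for sp in frame["species"]
            if str(sp).strip().lower() not in constants
        }
    )
    if unknown:
        raise ValidationError(
            f"unresolvable species in dataset: {', '.join(unknown)} "
            f"(registry has: {', '.join(sorted(c.species for c in constants))})"
        )
    series: list[AdcSeries] = []
    for (drug, analyte), block in frame.groupby(["drug", "analyte"], sort=False):
        species_seen = [str(s).strip().lower() for s in block["species"]]
        dupes = sorted({s for s in species_seen if species_seen.count(s) > 1})
        if dupes:
            raise ValidationError(
                f"{drug} ({analyte}): duplicate species row(s): {', '.join(dupes)}"
            )
        human_cl = None
        animals = []
        for _, row in block.iterrows():
            sp = str(row["species"]).strip().lower()
            cl = float(row["clearance_ml_per_day"])
            if cl <= 0:
                raise ValidationError(
                    f"{drug} ({analyte}, {sp}): non-positive clearance {cl!r}"
                )
            if sp == HUMAN:
                human_cl = cl
            else:
                animals.append(SpeciesObservation(species=sp, clearance_ml_day=cl))
        # normalise species order by ascending body weight
        animals.sort(key=lambda o: constants.body_weight(o.species))
        series.append(
            AdcSeries(
                drug=str(drug),
                analyte=str(analyte),
                animals=tuple(animals),
                human_observed_cl=human_cl,
            )
        )
    return series


def load_dataset(
    path: str | Path, constants: SpeciesRegistry | None = None
) -> AdcDataset:
    """Load an ADC clearance dataset from tidy CSV.

    Expected header: ``drug,analyte,species,clearance_ml_per_day``; human
    rows carry the observed human clearance for the series.
    """
    constants = constants or default_registry()
    frame = pd.read_csv(path)
    return AdcDataset(_series_from_frame(frame, constants))


def save_dataset(dataset: AdcDataset, path: str | Path) -> None:
    """Write a dataset back to the tidy CSV interchange format."""
    dataset.to_frame().to_csv(path, index=False)


def builtin_adc_dataset(constants: SpeciesRegistry | None = None) -> AdcDataset:
    """The bundled 13-series ADC clearance dataset.

    Ten series carry mouse/rat/monkey panels (seven total-antibody, three
    conjugate); DMOT4039A, Pinatuzumab vedotin and ADC1 have mouse and
    monkey only. All clearances are absolute mL/day at reference body
    weights 0.02, 0.25, 3.5 and 70 kg.
    """
    constants = constants or default_registry()
    return AdcDataset(_series_from_frame(_read_bundled("adc_clearance.csv"), constants))
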