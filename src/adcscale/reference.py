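"""Published reference values and the reproduction/discrepancy report.

This package re-derives every number of the published interspecies-scaling
analysis it implements from the bundled clearance dataset.  The printed
values of that analysis are recorded here, cell by cell, so the pipeline
can report per-cell agreement.  A minority of printed cells are internally
inconsistent with the published input data (they imply slightly different
animal clearances than the input table lists); those cells are flagged in
``KNOWN_DISCREPANCIES``, reported with status ``documented_discrepancy``,
and excluded from the assertion oracle.  See ``docs/discrepancies.md``.

Cell naming: ``<method-or-pair-or-species>.<quantity>`` — e.g.
``simple.exponent``, ``mouse-monkey.predicted``, ``mouse.E0.85``.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .allometry import (
    fit_corrected,
    scale_one_species,
    scale_one_species_average,
    scale_three_species,
    scale_two_species,
)
from .datasets import AdcDataset, SpeciesRegistry, builtin_adc_dataset, default_registry

__all__ = ["KNOWN_DISCREPANCIES", "reference_report"]

# --- three-species scaling: {(drug, analyte): {method: (a, b, predicted, ratio)}}
TABLE_THREE_SPECIES: Mapping[tuple[str, str], Mapping[str, tuple]] = {
    ("DSTP3086S", "total"): {
        "simple": (11.7, 1.06, 1052, 1.83),
        "brain_weight": (155.7, 2.06, 709, 1.23),
    },
    ("T-DM1", "total"): {"simple": (5.37, 0.89, 236, 0.69)},
    ("T-DM1", "conjugate"): {"simple": (14.3, 0.91, 683, 1.14)},
    ("DNIB0600A", "total"): {
        "simple": (13.7, 1.07, 1313, 1.54),
        "brain_weight": (182.5, 2.08, 886, 1.04),
    },
    ("Brentuximab vedotin", "total"): {"simple": (13, 0.90, 595, 0.80)},
    ("Thiomab", "total"): {
        "simple": (6.5, 1.03, 517, 2.58),
        "brain_weight": (86.9, 2.03, 345, 1.73),
    },
    ("Thiomab", "conjugate"): {"simple": (18.3, 0.95, 1027, 1.35)},
    ("Polatuzumab vedotin", "total"): {
        "simple": (8.91, 1.06, 795, 0.78),
        "brain_weight": (119, 2.06, 537, 0.53),
    },
    ("Anti-5T4", "total"): {"simple": (9.9, 0.82, 323, 0.90)},
    ("Anti-5T4", "conjugate"): {"simple": (17.3, 0.85, 640, 0.91)},
}

# --- forced-MLP predictions: {(drug, analyte): (predicted, ratio)}
TABLE_MLP: Mapping[tuple[str, str], tuple] = {
    ("Brentuximab vedotin", "total"): (274, 0.37),
    ("T-DM1", "total"): (111, 0.32),
    ("T-DM1", "conjugate"): (319, 0.53),
    ("Thiomab", "conjugate"): (478, 0.63),
    ("Anti-5T4", "total"): (151, 0.42),
    ("Anti-5T4", "conjugate"): (288, 0.41),
}

# --- two-species scaling (total antibody): {drug: {pair: (a, b, predicted)}}
TABLE_TWO_SPECIES: Mapping[str, Mapping[tuple[str, str], tuple]] = {
    "DNIB0600A": {
        ("mouse", "monkey"): (12.1, 1.08, 1190),
        ("mouse", "rat"): (21.8, 1.23, 3981),
        ("rat", "monkey"): (14.5, 0.93, 753),
    },
    "DMOT4039A": {("mouse", "monkey"): (21.3, 1.21, 3640)},
    "Polatuzumab vedotin": {
        ("mouse", "monkey"): (6.6, 1.04, 543),
        ("mouse", "rat"): (28.8, 1.42, 12007),
        ("rat", "monkey"): (10.3, 0.68, 185),
    },
    "Pinatuzumab vedotin": {("mouse", "monkey"): (8.46, 1.08, 832)},
    "ADC1": {("mouse", "monkey"): (9.38, 1.09, 962)},
    "Brentuximab vedotin": {
        ("mouse", "monkey"): (16.6, 0.89, 728),
        ("mouse", "rat"): (5.1, 0.59, 63),
        ("rat", "monkey"): (11.6, 1.18, 1745),
    },
    "DSTP3086S": {
        ("mouse", "monkey"): (12.4, 1.09, 1277),
        ("mouse", "rat"): (9.3, 0.98, 598),
        ("rat", "monkey"): (11.4, 1.13, 1386),
    },
    "T-DM1": {
        ("mouse", "monkey"): (5.3, 0.89, 231),
        ("mouse", "rat"): (5.4, 0.87, 219),
        ("rat", "monkey"): (5.8, 0.92, 291),
    },
    "Thiomab": {
        ("mouse", "monkey"): (5.6, 1.03, 445),
        ("mouse", "rat"): (11.6, 1.21, 1982),
        ("rat", "monkey"): (7, 0.85, 259),
    },
    "Anti-5T4": {
        ("mouse", "monkey"): (9.7, 0.82, 316),
        ("mouse", "rat"): (10.7, 0.85, 388),
        ("rat", "monkey"): (10, 0.80, 299),
    },
}

# --- one-species fixed exponents (total antibody):
#     {drug: {species: (E0.75, E0.80, E0.85, E1.0)}}
ONE_SPECIES_EXPONENTS = (0.75, 0.80, 0.85, 1.0)
TABLE_ONE_SPECIES: Mapping[str, Mapping[str, tuple]] = {
    "DNIB0600A": {
        "mouse": (82, 123, 185, 630),
        "rat": (272, 361, 479, 1114),
        "monkey": (440, 511, 594, 931),
    },
    "DMOT4039A": {"mouse": (86, 130, 196, 665), "monkey": (914, 1061, 1233, 1932)},
    "DSTP3086S": {
        "mouse": (90, 135, 204, 693),
        "rat": (163, 215, 286, 665),
        "monkey": (444, 515, 598, 938),
    },
    "T-DM1": {
        "mouse": (73, 109, 165, 560),
        "rat": (111, 147, 195, 455),
        "monkey": (152, 177, 205, 322),
    },
    "Polatuzumab vedotin": {
        "mouse": (46, 70, 105, 356),
        "rat": (185, 245, 325, 756),
        "monkey": (199, 231, 268, 420),
    },
    "Pinatuzumab vedotin": {"mouse": (56, 83, 126, 427), "monkey": (311, 361, 420, 658)},
    "ADC1": {"mouse": (60, 90, 136, 462), "monkey": (348, 404, 469, 735)},
    "Brentuximab vedotin": {
        "mouse": (55, 82, 123, 420),
        "rat": (154, 204, 271, 630),
        "monkey": (483, 561, 652, 1022),
    },
    "Thiomab": {
        "mouse": (44, 66, 99, 338),
        "rat": (147, 195, 259, 602),
        "monkey": (193, 224, 260, 407),
    },
    "Anti-5T4": {
        "mouse": (177, 266, 400, 1361),
        "rat": (226, 299, 397, 924),
        "monkey": (256, 297, 345, 541),
    },
}

# --- mouse averaging strategy: {drug: printed average prediction}
TABLE_MOUSE_AVERAGE: Mapping[str, float] = {
    "DNIB0600A": 726,
    "DMOT4039A": 766,
    "DSTP3086S": 799,
    "T-DM1": 645,
    "Polatuzumab vedotin": 411,
    "Pinatuzumab vedotin": 492,
    "ADC1": 532,
    "Brentuximab vedotin": 484,
    "Thiomab": 390,
    "Anti-5T4": 1618,
}


def _row_cells(table: str, drug: str, species: str) -> set[tuple[str, str, str, str]]:
    return {
        (table, drug, "total", f"{species}.E{e:g}") for e in ONE_SPECIES_EXPONENTS
    }


#: Printed cells that do not reproduce from the published input data.
#: They imply slightly different animal clearances (or transposed rows)
#: than the input table lists; computed values follow the input table.
KNOWN_DISCREPANCIES: set[tuple[str, str, str, str]] = (
    {
        ("three_species", "Polatuzumab vedotin", "total", f"simple.{q}")
        for q in ("exponent", "predicted", "ratio")
    }
    | {
        ("three_species", "Polatuzumab vedotin", "total", f"brain_weight.{q}")
        for q in ("exponent", "predicted", "ratio")
    }
    | {
        ("three_species", "Anti-5T4", "conjugate", f"simple.{q}")
        for q in ("exponent", "predicted", "ratio")
    }
    # rows transposed relative to the input data
    | {
        ("two_species", "T-DM1", "total", f"mouse-rat.{q}")
        for q in ("coefficient", "exponent", "predicted")
    }
    | {
        ("two_species", "T-DM1", "total", f"rat-monkey.{q}")
        for q in ("coefficient", "exponent", "predicted")
    }
    | {
        ("two_species", "DSTP3086S", "total", f"mouse-monkey.{q}")
        for q in ("exponent", "predicted")
    }
    | {
        ("two_species", "Pinatuzumab vedotin", "total", f"mouse-monkey.{q}")
        for q in ("exponent", "predicted")
    }
    | {("two_species", "Brentuximab vedotin", "total", "mouse-monkey.predicted")}
    # printed prediction derives from the rounded (a, b) = (5.1, 0.59); the
    # unrounded two-point fit gives 64.5 (b sits on the 0.595 rounding edge)
    | {("two_species", "Brentuximab vedotin", "total", "mouse-rat.predicted")}
    # computed coefficient 9.21 vs printed 9.3 — off in the last printed digit
    | {("two_species", "DSTP3086S", "total", "mouse-rat.coefficient")}
    | _row_cells("one_species", "Brentuximab vedotin", "mouse")
    | _row_cells("one_species", "Polatuzumab vedotin", "mouse")
    | _row_cells("one_species", "Polatuzumab vedotin", "rat")
    | _row_cells("one_species", "Polatuzumab vedotin", "monkey")
    | _row_cells("one_species", "DSTP3086S", "mouse")
    | _row_cells("one_species", "Pinatuzumab vedotin", "mouse")
    | _row_cells("one_species", "ADC1", "mouse")
    | _row_cells("one_species", "Thiomab", "mouse")
    # implies mouse CL 0.3889 rather than the input table's 0.39 (~0.3%)
    | _row_cells("one_species", "Anti-5T4", "mouse")
    # the printed averaging column mixes exponent sets; see discrepancies doc
    | {("mouse_average", drug, "total", "average") for drug in TABLE_MOUSE_AVERAGE}
)

# per-quantity comparison rule: printed values carry rounded precision, so
# exponents get an absolute half-ulp-scale band and the rest relative bands
_PREDICTED_RELTOL = {
    "three_species": 0.015,
    "mlp": 0.01,
    "two_species": 0.02,
    "one_species": 0.01,
    "mouse_average": 0.01,
}


def _agrees(table: str, quantity: str, printed: float, computed: float) -> bool:
    if quantity == "exponent":
        return abs(computed - printed) <= 0.006
    if quantity == "coefficient":
        return abs(computed - printed) <= max(0.01 * printed, 0.05)
    if quantity == "ratio":
        return abs(computed - printed) <= 0.02
    return abs(computed - printed) <= _PREDICTED_RELTOL[table] * printed


def reference_report(
    dataset: AdcDataset | None = None, constants: SpeciesRegistry | None = None
) -> pd.DataFrame:
    """Recompute every printed cell and report per-cell agreement.

    Columns: table, drug, analyte, cell, printed, computed, rel_error,
    status (``asserted`` or ``documented_discrepancy``), agrees.
    """
    constants = constants or default_registry()
    dataset = dataset if dataset is not None else builtin_adc_dataset(constants)
    rows: list[tuple] = []

    def emit(table: str, drug: str, analyte: str, cell: str, printed, computed) -> None:
        quantity = cell.rsplit(".", 1)[-1] if "." in cell else cell
        if quantity.startswith("E") or quantity == "average":
            quantity = "predicted"
        status = (
            "documented_discrepancy"
            if (table, drug, analyte, cell) in KNOWN_DISCREPANCIES
            else "asserted"
        )
        rows.append(
            (
                table,
                drug,
                analyte,
                cell,
                float(printed),
                float(computed),
                (computed - printed) / printed,
                status,
                _agrees(table, quantity, float(printed), float(computed)),
            )
        )

    for (drug, analyte), methods in TABLE_THREE_SPECIES.items():
        series = dataset[(drug, analyte)]
        sa = scale_three_species(series, constants, "sa_only")
        for method, (a, b, predicted, ratio) in methods.items():
            if method == "simple":
                fit_a, fit_b, pred, r = sa.coefficient, sa.exponent, sa.predicted_cl, sa.ratio
            else:
                fit = fit_corrected(series, constants, "brain_weight")
                fit_a, fit_b = fit.coefficient_a, fit.exponent_b
                pred = fit.predict_human(constants)
                r = pred / series.human_observed_cl
            emit("three_species", drug, analyte, f"{method}.coefficient", a, fit_a)
            emit("three_species", drug, analyte, f"{method}.exponent", b, fit_b)
            emit("three_species", drug, analyte, f"{method}.predicted", predicted, pred)
            emit("three_species", drug, analyte, f"{method}.ratio", ratio, r)

    for (drug, analyte), (predicted, ratio) in TABLE_MLP.items():
        p = scale_three_species(dataset[(drug, analyte)], constants, "mlp_forced")
        emit("mlp", drug, analyte, "mlp.predicted", predicted, p.predicted_cl)
        emit("mlp", drug, analyte, "mlp.ratio", ratio, p.ratio)

    for drug, pairs in TABLE_TWO_SPECIES.items():
        series = dataset[(drug, "total")]
        for pair, (a, b, predicted) in pairs.items():
            p = scale_two_species(series, pair, constants)
            tag = "-".join(pair)
            emit("two_species", drug, "total", f"{tag}.coefficient", a, p.coefficient)
            emit("two_species", drug, "total", f"{tag}.exponent", b, p.exponent)
            emit("two_species", drug, "total", f"{tag}.predicted", predicted, p.predicted_cl)

    for drug, species_rows in TABLE_ONE_SPECIES.items():
        series = dataset[(drug, "total")]
        for species, printed_row in species_rows.items():
            obs = series.observation(species)
            for e, printed in zip(ONE_SPECIES_EXPONENTS, printed_row):
                p = scale_one_species(obs, constants, e, drug=drug)
                emit("one_species", drug, "total", f"{species}.E{e:g}", printed, p.predicted_cl)

    for drug, printed in TABLE_MOUSE_AVERAGE.items():
        series = dataset[(drug, "total")]
        p = scale_one_species_average(series.observation("mouse"), constants, drug=drug)
        emit("mouse_average", drug, "total", "average", printed, p.predicted_cl)

    return pd.DataFrame(
        rows,
        columns=[
            "table",
            "drug",
            "analyte",
            "cell",
            "printed",
            "computed",
            "rel_error",
            "status",
            "agrees",
        ],
    )
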