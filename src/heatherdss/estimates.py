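"""Expert-elicited variable estimate tables.

Every model input is an expert estimate: a 90% confidence interval (the
5th and 95th percentiles of all values the expert considers plausible)
together with a distribution family that says how the interval is to be
turned into a sampling distribution.  Three families are supported:

``posnorm``
    normal distribution truncated below at zero (non-negative quantities
    such as costs, prices and plant counts),
``tnorm``
    normal distribution truncated to the 0-100 range (percentages), and
``const``
    a point mass (known quantities such as the simulated time horizon).

The canonical input set for the heather monitoring model ships as a
built-in fixture (:func:`builtin_table1`); arbitrary tables with the same
structure can be read from and written to UTF-8 CSV files with header
``variable,unit,distribution,lower,upper,description``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "DISTRIBUTIONS",
    "STRATEGY_CODES",
    "STRATEGY_LABELS",
    "HEATHER_MANIFEST",
    "CSV_HEADER",
    "EstimateFormatError",
    "EstimateValidationError",
    "VariableEstimate",
    "EstimateTable",
    "builtin_table1",
    "parse_estimate_table",
    "write_estimate_table",
]

DISTRIBUTIONS = ("posnorm", "tnorm", "const")

#: Monitoring strategy codes: current visual regime (B), intensified
#: visual monitoring (I) and hyperspectral sensor monitoring (S).
STRATEGY_CODES = ("B", "I", "S")
STRATEGY_LABELS = {"B": "Baseline", "I": "Improved", "S": "Sensor"}

CSV_HEADER = ("variable", "unit", "distribution", "lower", "upper", "description")
_REQUIRED_COLUMNS = frozenset({"variable", "distribution", "lower", "upper"})


class EstimateFormatError(ValueError):
    """A file could not be understood as an estimate table."""


class EstimateValidationError(ValueError):
    """An estimate (or a table of estimates) violates an invariant."""


@dataclass(frozen=True)
class VariableEstimate:
    """One elicited model input.

    Parameters
    ----------
    name : str
        Variable identifier.  Names ending in ``_B``, ``_I`` or ``_S``
        belong to one monitoring strategy; all other names are shared.
    unit : str
        Unit of the quantity (``€``, ``%``, ``digit``, ``years``, ``ha``).
    distribution : str
        One of :data:`DISTRIBUTIONS`.
    lower, upper : float
        5th and 95th percentile of the elicited 90% confidence interval.
    description : str
        Free-text description.
    """

    name: str
    unit: str
    distribution: str
    lower: float
    upper: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise EstimateValidationError(
                f"{self.name}: unknown distribution {self.distribution!r} "
                f"(expected one of {DISTRIBUTIONS})"
            )
        if not (self.lower <= self.upper):
            raise EstimateValidationError(
                f"{self.name}: lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.distribution == "const" and self.lower != self.upper:
            raise EstimateValidationError(
                f"{self.name}: constant with unequal bounds ({self.lower}, {self.upper})"
            )
        if self.unit == "%" and not (0.0 <= self.lower and self.upper <= 100.0):
            raise EstimateValidationError(
                f"{self.name}: percent variable outside [0, 100] "
                f"({self.lower}, {self.upper})"
            )
        if self.distribution == "posnorm" and self.lower < 0:
            raise EstimateValidationError(
                f"{self.name}: posnorm lower bound must be non-negative, got {self.lower}"
            )

    @property
    def strategy(self) -> str | None:
        """Strategy code for suffixed names, ``None`` for shared variables."""
        if len(self.name) > 2 and self.name[-2] == "_" and self.name[-1] in STRATEGY_CODES:
            return self.name[-1]
        return None

    @property
    def is_constant(self) -> bool:
        return self.distribution == "const"

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _coerce_degenerate(estimate: VariableEstimate) -> VariableEstimate:
    """Coerce a zero-width stochastic interval to a point mass.

    A 90% CI with identical bounds defines a point mass regardless of the
    declared family (e.g. a posnorm listed with bounds 0, 0).
    """
    if estimate.distribution != "const" and estimate.lower == estimate.upper:
        logger.warning(
            "%s: zero-width %s interval coerced to a constant at %g",
            estimate.name,
            estimate.distribution,
            estimate.lower,
        )
        return replace(estimate, distribution="const")
    return estimate


class EstimateTable(Mapping[str, VariableEstimate]):
    """An ordered, validated collection of :class:`VariableEstimate` entries."""

    def __init__(
        self,
        estimates: Iterable[VariableEstimate],
        *,
        coerce_degenerate: bool = True,
    ) -> None:
        entries: dict[str, VariableEstimate] = {}
        for est in estimates:
            if est.name in entries:
                raise EstimateValidationError(f"duplicate variable name {est.name!r}")
            entries[est.name] = _coerce_degenerate(est) if coerce_degenerate else est
        self._entries = entries

    def __getitem__(self, name: str) -> VariableEstimate:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"EstimateTable({len(self)} variables)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EstimateTable):
            return NotImplemented
        return list(self._entries.items()) == list(other._entries.items())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def shared_names(self) -> tuple[str, ...]:
        return tuple(n for n, e in self._entries.items() if e.strategy is None)

    def strategy_names(self, code: str) -> tuple[str, ...]:
        if code not in STRATEGY_CODES:
            raise ValueError(f"unknown strategy code {code!r}")
        return tuple(n for n, e in self._entries.items() if e.strategy == code)

    def validate_complete(self, manifest: Iterable[str] = None) -> None:
        """Check that every variable the cash-flow model needs is present.

        Extra variables are allowed (and ignored by the heather model).
        """
        required = tuple(manifest) if manifest is not None else HEATHER_MANIFEST
        missing = [name for name in required if name not in self._entries]
        if missing:
            raise EstimateValidationError(
                "estimate table is missing required variables: " + ", ".join(missing)
            )

    def to_frame(self):
        """Return the table as a :class:`pandas.DataFrame` (one row per variable)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "variable": e.name,
                    "unit": e.unit,
                    "distribution": e.distribution,
                    "lower": e.lower,
                    "upper": e.upper,
                    "description": e.description,
                }
                for e in self._entries.values()
            ]
        )


# --- Table 1 fixture -------------------------------------------------------

# (name, unit, distribution, lower, upper, description)
_TABLE1_ROWS: tuple[tuple[str, str, str, float, float, str], ...] = (
    ("discount_rate", "digit", "posnorm", 1, 5, "discount rate"),
    ("var_CV", "%", "tnorm", 5, 15, "desired coefficient of variation"),
    ("n_years", "years", "const", 10, 10, "years of production"),
    ("production_area", "ha", "const", 8, 8, "total area of the nursery field"),
    ("chance_high_risk", "%", "tnorm", 40, 60,
     "chance of a year presenting high-risk conditions"),
    ("initial_investment_B", "€", "posnorm", 100, 200,
     "initial investment costs to enable Baseline"),
    ("initial_investment_I", "€", "posnorm", 200, 500,
     "initial investment costs to enable Improved"),
    ("initial_investment_S", "€", "posnorm", 18000, 100000,
     "initial investment costs to enable Sensor"),
    ("additional_investment_B", "€", "posnorm", 50, 100,
     "additional costs to enable Baseline"),
    ("additional_investment_I", "€", "posnorm", 50, 100,
     "additional costs to enable Improved"),
    ("additional_investment_S", "€", "posnorm", 100, 500,
     "additional costs to enable Sensor"),
    ("labor_costs_B", "€", "posnorm", 100, 1500,
     "monetary value reflecting the time spent by a person involved in "
     "maintaining Baseline"),
    ("labor_costs_I", "€", "posnorm", 500, 3500,
     "monetary value reflecting the time spent by a person involved in "
     "maintaining Improved"),
    ("labor_costs_S", "€", "posnorm", 500, 5000,
     "monetary value reflecting the time spent by a person involved in "
     "maintaining Sensor"),
    ("post_processing_costs_B", "€", "const", 0, 0,
     "costs of data post processing for Baseline"),
    ("post_processing_costs_I", "€", "posnorm", 0, 0,
     "costs of data post processing for Improved"),
    ("post_processing_costs_S", "€", "posnorm", 100, 500,
     "costs of data post processing for Sensor"),
    ("sample_number_B", "digit", "posnorm", 2, 3, "number of samples for Baseline"),
    ("sample_number_I", "digit", "posnorm", 2, 15, "number of samples for Improved"),
    ("sample_number_S", "digit", "posnorm", 2, 6, "number of samples for Sensor"),
    ("lab_costs_per_sample", "€", "posnorm", 15, 70, "laboratory costs per sample"),
    ("plant_value_of_discarded_plant", "€", "posnorm", 0.25, 0.6,
     "value of discarded plant"),
    ("plant_value_of_A1_quality", "€", "posnorm", 0.6, 0.9,
     "value of marketable plant with high quality"),
    ("number_of_saved_high_quality_plants_B", "digit", "posnorm", 500, 6000,
     "number of high quality plants saved by Baseline"),
    ("number_of_saved_high_quality_plants_I", "digit", "posnorm", 2000, 18000,
     "number of high quality plants saved by Improved"),
    ("number_of_saved_high_quality_plants_S", "digit", "posnorm", 500, 10000,
     "number of high quality plants saved by Sensor"),
    ("adjustment_sample_size_B", "%", "tnorm", 10, 50,
     "adjustment in sample size for Baseline"),
    ("adjustment_sample_size_I", "%", "tnorm", 10, 30,
     "adjustment in sample size for Improved"),
    ("adjustment_sample_size_S", "%", "tnorm", 10, 30,
     "adjustment in sample size for Sensor"),
    ("resource_savings_B", "€", "posnorm", 100, 500, "resource savings for Baseline"),
    ("resource_savings_I", "€", "posnorm", 500, 1000, "resource savings for Improved"),
    ("resource_savings_S", "€", "posnorm", 500, 1000, "resource savings for Sensor"),
)

#: Frozen manifest of the variable names the heather cash-flow model requires.
HEATHER_MANIFEST: tuple[str, ...] = tuple(row[0] for row in _TABLE1_ROWS)


def builtin_table1() -> EstimateTable:
    """The canonical expert-elicited input set for the heather model.

    32 variables: discount rate, interannual coefficient of variation,
    horizon, area, chance of a high-risk year, three plant/lab prices,
    and eight per-strategy triples (investments, maintenance, labor,
    post-processing, sample numbers, sample-size adjustments, saved
    plants, resource savings).
    """
    return EstimateTable(
        VariableEstimate(name, unit, dist, float(lo), float(hi), desc)
        for name, unit, dist, lo, hi, desc in _TABLE1_ROWS
    )


# --- CSV I/O ---------------------------------------------------------------

_GROUPED_NUMBER = re.compile(r"^-?\d{1,3}(,\d{3})+(\.\d*)?$")


def _parse_number(text: str, variable: str, column: str) -> float:
    """Parse a bound, stripping thousands separators ("18,000").

    Comma decimal separators ("3,5") are rejected: they are ambiguous with
    grouped integers and the canonical format uses a point.
    """
    raw = text.strip()
    if _GROUPED_NUMBER.match(raw):
        raw = raw.replace(",", "")
    elif "," in raw:
        raise EstimateFormatError(
            f"{variable}: {column}={text!r} uses a comma decimal separator; "
            "use '.' for decimals and ',' only as a thousands separator"
        )
    try:
        return float(raw)
    except ValueError as exc:
        raise EstimateFormatError(
            f"{variable}: could not parse {column}={text!r} as a number"
        ) from exc


def parse_estimate_table(
    source: str | Path | IO[str],
    *,
    delimiter: str = ",",
) -> EstimateTable:
    """Read an estimate table from a CSV file (or open text stream).

    The header must contain at least ``variable``, ``distribution``,
    ``lower`` and ``upper``; ``unit`` and ``description`` are optional.
    """
    if hasattr(source, "read"):
        return _parse_stream(source, delimiter)  # type: ignore[arg-type]
    with open(source, "r", encoding="utf-8", newline="") as handle:
        return _parse_stream(handle, delimiter)


def _parse_stream(handle: IO[str], delimiter: str) -> EstimateTable:
    reader = csv.DictReader(handle, delimiter=delimiter)
    if reader.fieldnames is None:
        raise EstimateFormatError("empty file: no header row")
    fields = {name.strip().lower(): name for name in reader.fieldnames}
    missing = _REQUIRED_COLUMNS - set(fields)
    if missing:
        raise EstimateFormatError(
            "missing required columns: " + ", ".join(sorted(missing))
        )

    estimates = []
    for row in reader:
        name = (row[fields["variable"]] or "").strip()
        if not name:
            continue
        dist = (row[fields["distribution"]] or "").strip()
        estimates.append(
            VariableEstimate(
                name=name,
                unit=(row.get(fields.get("unit", ""), "") or "").strip(),
                distribution=dist,
                lower=_parse_number(row[fields["lower"]], name, "lower"),
                upper=_parse_number(row[fields["upper"]], name, "upper"),
                description=(row.get(fields.get("description", ""), "") or "").strip(),
            )
        )
    return EstimateTable(estimates)


def write_estimate_table(table: EstimateTable, dest: str | Path | IO[str]) -> None:
    """Write a table to UTF-8 CSV such that ``parse(write(t))`` equals ``t``."""
    if hasattr(dest, "write"):
        _write_stream(table, dest)  # type: ignore[arg-type]
        return
    with open(dest, "w", encoding="utf-8", newline="") as handle:
        _write_stream(table, handle)


def _write_stream(table: EstimateTable, handle: IO[str]) -> None:
    writer = csv.writer(handle)
    writer.writerow(CSV_HEADER)
    for est in table.values():
        writer.writerow(
            [est.name, est.unit, est.distribution,
             repr(est.lower), repr(est.upper), est.description]
        )
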