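"""Induction-phenotype metrics and strain comparison tables.

From a kinetic fit, four phenotype metrics are derived:

- activation time (onset ``x``),
- steady-state expression level (``alpha/delta``),
- time to half-steady-state (``x + ln2/delta``),
- time from activation to half-steady-state (``ln2/delta``).

Two comparison views are provided: each strain's metrics as a percentage of
a reference strain's (``100 * strain / reference``), and the percent change
of each metric between a first induction and a reinduction
(``100 * (secondary - primary) / primary``).  Reported values are rounded to
one decimal, half away from zero, matching the convention of printed strain
tables; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .kinetics import KineticFit

__all__ = [
    "METRICS",
    "PhenotypeRow",
    "ComparisonTable",
    "derive_phenotypes",
    "relative_to_reference",
    "percent_change",
    "round_half_away",
]

#: Metric attribute names on PhenotypeRow, in report order.
METRICS = ("activation_time", "steady_state_level", "time_to_half", "activation_to_half")


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (printed-table convention)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


@dataclass(frozen=True)
class PhenotypeRow:
    """One strain/condition's derived induction phenotypes."""

    strain: str
    condition: str  # "primary" | "secondary"
    activation_time: float
    steady_state_level: float
    time_to_half: float
    activation_to_half: float

    def __post_init__(self) -> None:
        if self.condition not in ("primary", "secondary"):
            raise ValueError("condition must be 'primary' or 'secondary'")
        for m in METRICS:
            if getattr(self, m) < 0:
                raise ValueError(f"{m} must be non-negative")
        # consistency up to the 0.1 rounding of printed tables
        if abs(self.time_to_half - self.activation_time - self.activation_to_half) > 0.1 + 1e-9:
            raise ValueError("time_to_half must equal activation_time + activation_to_half")


@dataclass
class ComparisonTable:
    """Rows of (strain, metric, percent value) in one comparison mode."""

    rows: list  # of (strain, metric, value)
    reference_strain: str
    mode: str  # "relative_to_reference" | "percent_change"
    notes: list = field(default_factory=list)

    def value(self, strain: str, metric: str) -> float:
        for s, m, v in self.rows:
            if s == strain and m == metric:
                return v
        raise KeyError((strain, metric))


def derive_phenotypes(fit: KineticFit, strain: str, condition: str) -> PhenotypeRow:
    """Turn a kinetic fit into the four phenotype metrics."""
    x, alpha, delta = fit.params.as_tuple()
    if delta <= 0:
        raise ValueError("phenotypes require degradation_rate > 0")
    if alpha <= 0:
        raise ValueError("phenotypes undefined for production_rate == 0")
    half = math.log(2.0) / delta
    return PhenotypeRow(
        strain=strain,
        condition=condition,
        activation_time=x,
        steady_state_level=alpha / delta,
        time_to_half=x + half,
        activation_to_half=half,
    )


def relative_to_reference(rows: list[PhenotypeRow], reference: str) -> ComparisonTable:
    """Each metric as a percent of the reference strain's value.

    Rows are matched to the reference within the same condition, so a table
    holding both first-induction and reinduction rows compares like with
    like.  Always computes ``100 * strain / reference``.
    """
    ref_by_cond = {r.condition: r for r in rows if r.strain == reference}
    if not ref_by_cond:
        raise ValueError(f"reference strain {reference!r} not among rows")
    out = []
    for row in rows:
        ref = ref_by_cond.get(row.condition)
        if ref is None:
            raise ValueError(f"no {row.condition} reference row for {reference!r}")
        for m in METRICS:
            denom = getattr(ref, m)
            num = getattr(row, m)
            if denom == 0:
                # reinduction onsets are all indistinguishable from zero, and
                # the printed comparison reports 100.0 for them; only a zero
                # reference against a nonzero strain value is unresolvable
                if num == 0:
                    out.append((row.strain, m, 100.0))
                    continue
                raise ValueError(f"reference metric {m} is zero")
            out.append((row.strain, m, round_half_away(100.0 * num / denom)))
    return ComparisonTable(
        rows=out,
        reference_strain=reference,
        mode="relative_to_reference",
        notes=["values are 100*strain/reference in every column"],
    )


def percent_change(primary: PhenotypeRow, secondary: PhenotypeRow) -> ComparisonTable:
    """Percent change of each metric from first induction to reinduction."""
    if primary.strain != secondary.strain:
        raise ValueError("percent_change compares conditions of one strain")
    out = []
    for m in METRICS:
        base = getattr(primary, m)
        if base == 0:
            raise ValueError(f"primary metric {m} is zero")
        out.append(
            (primary.strain, m, round_half_away(100.0 * (getattr(secondary, m) - base) / base))
        )
    return ComparisonTable(rows=out, reference_strain=primary.strain, mode="percent_change")
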