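"""Double-mutant-cycle thermodynamics.

A double-mutant cycle compares the stability change of a double mutant with
the sum of its constituent single mutants, all relative to a common reference
(wild type) at a reference temperature (298 K by default):

    dddG_f = ddG_f(double) - [ddG_f(single 1) + ddG_f(single 2)]

A non-zero coupling energy dddG_f indicates thermodynamic epistasis between
the two substitutions. Standard errors combine in quadrature, treating the
records as independent Gaussians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import IncompatibleRecordsError, InsufficientOverlapError, InvalidParameterError


@dataclass(frozen=True)
class StabilityRecord:
    """A variant's dG_f (or ddG_f) at a reference temperature, kJ/mol."""

    variant_label: str
    dg: float
    se: float = 0.0
    source: str = "free-fit"
    reference_temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InvalidParameterError("standard error must be >= 0")


@dataclass(frozen=True)
class CycleResult:
    """The four-corner double-mutant cycle summary."""

    ddg_single_1: StabilityRecord
    ddg_single_2: StabilityRecord
    ddg_double: StabilityRecord
    dddg: float
    dddg_se: float


def _check_compatible(records: Sequence[StabilityRecord]) -> None:
    sources = {r.source for r in records}
    temps = {r.reference_temperature for r in records}
    if len(sources) > 1 or len(temps) > 1:
        raise IncompatibleRecordsError(
            f"records mix sources {sorted(sources)} / reference temperatures {sorted(temps)}"
        )


def ddg(variant: StabilityRecord, reference: StabilityRecord) -> StabilityRecord:
    """Stability change relative to a reference: ddG = dG(variant) - dG(reference).

    Errors add in quadrature. Both records must share source and reference
    temperature.
    """
    _check_compatible([variant, reference])
    return StabilityRecord(
        variant_label=variant.variant_label,
        dg=variant.dg - reference.dg,
        se=math.hypot(variant.se, reference.se),
        source=variant.source,
        reference_temperature=variant.reference_temperature,
    )


def coupling_energy(
    ddg1: StabilityRecord, ddg2: StabilityRecord, ddg12: StabilityRecord
) -> CycleResult:
    """Coupling energy dddG_f = ddG(double) - [ddG(single1) + ddG(single2)].

    Symmetric in the two single-mutant arguments; the standard error is the
    quadrature sum of the three record errors.
    """
    _check_compatible([ddg1, ddg2, ddg12])
    dddg = ddg12.dg - (ddg1.dg + ddg2.dg)
    dddg_se = math.sqrt(ddg1.se**2 + ddg2.se**2 + ddg12.se**2)
    return CycleResult(ddg1, ddg2, ddg12, dddg, dddg_se)


def cycle_from_corners(
    dg_reference: StabilityRecord,
    dg_single_1: StabilityRecord,
    dg_single_2: StabilityRecord,
    dg_double: StabilityRecord,
) -> CycleResult:
    """Build the cycle from the four absolute dG_f corners.

    Equivalent to differencing against the reference first; path independence
    holds exactly: dddG = dG12 - dG1 - dG2 + dG_ref.
    """
    return coupling_energy(
        ddg(dg_single_1, dg_reference),
        ddg(dg_single_2, dg_reference),
        ddg(dg_double, dg_reference),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement between experimental and predicted stability changes."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    unmatched_experimental: tuple[str, ...]
    unmatched_predicted: tuple[str, ...]


def compare_predictions(
    experimental: Sequence[StabilityRecord],
    predicted: Sequence[StabilityRecord],
) -> ComparisonResult:
    """Pearson correlation (and fitted line) between matched ddG tables.

    Records are matched by variant label; at least three matches are
    required. Unmatched labels on either side are reported, not an error.
    Prediction tables in arbitrary units (e.g. sequence-model scores) are
    handled identically -- Pearson r is scale-free.
    """
    exp_map = {r.variant_label: r.dg for r in experimental}
    pred_map = {r.variant_label: r.dg for r in predicted}
    common = [k for k in exp_map if k in pred_map]
    if len(common) < 3:
        raise InsufficientOverlapError(
            f"only {len(common)} matched variants; need >= 3"
        )
    x = np.array([exp_map[k] for k in common])
    y = np.array([pred_map[k] for k in common])
    r, p = stats.pearsonr(x, y)
    line = stats.linregress(x, y)
    return ComparisonResult(
        r=float(r),
        p_value=float(p),
        slope=float(line.slope),
        intercept=float(line.intercept),
        n=len(common),
        unmatched_experimental=tuple(k for k in exp_map if k not in pred_map),
        unmatched_predicted=tuple(k for k in pred_map if k not in exp_map),
    )


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
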