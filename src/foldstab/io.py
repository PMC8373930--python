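"""Tidy CSV input/output and report tables.

The canonical dataset dialect is long-form CSV with header columns
``variant,replicate,denaturant_M,temperature_C,signal`` -- one observation
per row, temperatures in degC on disk (instrument convention) and Kelvin in
memory. Stability-record tables use ``variant_label,dg,se,source``; external
prediction tables (FoldX, Rosetta, sequence models) are ingested in the same
shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cycles import CycleResult, StabilityRecord, round_half_away
from .dataset import UnfoldingDataset, UnfoldingSeries
from .exceptions import DataParseError
from .fitting import FitResult, derived_quantity

DATASET_COLUMNS = ["variant", "replicate", "denaturant_M", "temperature_C", "signal"]
_KEY_COLUMNS = ["variant", "replicate", "denaturant_M", "temperature_C"]

PathLike = Union[str, Path]


def _lines(index: pd.Index) -> str:
    """Data-file line numbers (header is line 1) for an offending index."""
    return ", ".join(str(i + 2) for i in list(index)[:10])


def read_dataset(path: PathLike) -> list[UnfoldingDataset]:
    """Read a tidy melting-curve CSV into datasets grouped by (variant, replicate)."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DataParseError(f"{path}: missing column(s) {', '.join(missing)}")
    numeric = df[["replicate", "denaturant_M", "temperature_C", "signal"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().any(axis=1) & df[
        ["replicate", "denaturant_M", "temperature_C", "signal"]
    ].notna().any(axis=1)
    bad |= df[DATASET_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise DataParseError(
            f"{path}: non-numeric or missing cells at line(s) {_lines(df.index[bad])}"
        )
    df[numeric.columns] = numeric
    dupes = df.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dupes.any():
        raise DataParseError(
            f"{path}: duplicate (variant,replicate,denaturant,temperature) keys "
            f"at line(s) {_lines(df.index[dupes])}"
        )

    datasets = []
    for (variant, replicate), g in df.groupby(["variant", "replicate"], sort=True):
        series = []
        for denaturant, sg in g.groupby("denaturant_M", sort=True):
            sg = sg.sort_values("temperature_C")
            series.append(
                UnfoldingSeries(
                    denaturant=float(denaturant),
                    temperature=sg["temperature_C"].to_numpy() + 273.15,
                    signal=sg["signal"].to_numpy(),
                )
            )
        datasets.append(UnfoldingDataset(str(variant), series, int(replicate)))
    return datasets


def write_dataset(datasets: Sequence[UnfoldingDataset], path: PathLike) -> None:
    """Write datasets in the canonical tidy CSV dialect (degC on disk)."""
    frames = []
    for ds in datasets:
        for s in ds.series:
            frames.append(
                pd.DataFrame(
                    {
                        "variant": ds.variant_label,
                        "replicate": ds.replicate_id,
                        "denaturant_M": s.denaturant,
                        "temperature_C": s.temperature - 273.15,
                        "signal": s.signal,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stability_records(path: PathLike) -> list[StabilityRecord]:
    """Read a stability table CSV: variant_label,dg,se[,source]."""
    df = pd.read_csv(path)
    required = ["variant_label", "dg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataParseError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            StabilityRecord(
                variant_label=str(row["variant_label"]),
                dg=float(row["dg"]),
                se=float(row["se"]) if "se" in df.columns and pd.notna(row.get("se")) else 0.0,
                source=str(row["source"]) if "source" in df.columns else "external-prediction",
            )
        )
    return records


def format_value(value: float, se: Optional[float], ndigits: int) -> str:
    """'352.3 +/- 0.2'-style formatting, half-away-from-zero rounding."""
    v = round_half_away(value, ndigits)
    text = f"{v:.{ndigits}f}" if ndigits > 0 else f"{v:.0f}"
    if se is None or not np.isfinite(se):
        return text
    s = round_half_away(se, ndigits)
    stext = f"{s:.{ndigits}f}" if ndigits > 0 else f"{s:.0f}"
    return f"{text} ± {stext}"


@dataclass
class Report:
    """Formatted parameter table plus an optional coupling-energy block."""

    parameters: pd.DataFrame
    cycles: Optional[pd.DataFrame] = None

    def to_text(self) -> str:
        parts = [self.parameters.to_string(index=False)]
        if self.cycles is not None:
            parts += ["", self.cycles.to_string(index=False)]
        return "\n".join(parts)


_COLUMN_PRECISION = [
    ("t_m", "T_m (K)", 1),
    ("dh_m", "dH_m (kJ/mol)", 0),
    ("dcp", "dC_p (kJ/mol/K)", 1),
    ("m_value", "m (kJ/mol/M)", 1),
]


def report_table(
    fits: Sequence[FitResult],
    cycles: Sequence[CycleResult] = (),
    reference_temperature: float = 298.0,
) -> Report:
    """One row per variant with 'value ± SE' formatting, least stable first.

    Derived columns dG_f and [D]50% at the reference temperature carry
    delta-method errors from each fit's covariance. Passing cycle results
    adds a coupling-energy block; an empty cycle list omits it.
    """
    rows = []
    for fit in fits:
        dg, dg_se = derived_quantity(fit, "dg", temperature=reference_temperature)
        d50, d50_se = derived_quantity(fit, "d50", temperature=reference_temperature)
        row = {"variant": fit.variant_label, "_dg": dg}
        for attr, col, nd in _COLUMN_PRECISION:
            row[col] = format_value(
                getattr(fit.thermo, attr), fit.standard_errors.get(attr), nd
            )
        row["dG_f (kJ/mol)"] = format_value(dg, dg_se, 1)
        row["[D]50% (M)"] = format_value(d50, d50_se, 1)
        row["converged"] = fit.converged
        rows.append(row)
    params = (
        pd.DataFrame(rows).sort_values("_dg", ascending=False).drop(columns="_dg")
    )
    cycles_df = None
    if cycles:
        cycles_df = pd.DataFrame(
            {
                "single_1": c.ddg_single_1.variant_label,
                "single_2": c.ddg_single_2.variant_label,
                "double": c.ddg_double.variant_label,
                "dddG (kJ/mol)": format_value(c.dddg, c.dddg_se, 1),
            }
            for c in cycles
        )
    return Report(parameters=params.reset_index(drop=True), cycles=cycles_df)
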