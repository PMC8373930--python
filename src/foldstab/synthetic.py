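"""Seeded synthetic unfolding experiments and the packaged CI2 reference table.

The generator emulates the measurement design used for CI2 nanoDSF melts:
a 15-95 degC temperature ramp read at each of 6-16 GuHCl concentrations
(default 13 levels evenly spaced over 0-5 M), sigmoidal two-state transitions
riding on affine baselines, with additive i.i.d. Gaussian noise. The forward
model is the same :func:`foldstab.observation.predicted_signal` used by the
global fitter, so simulator and fitter cannot drift apart.

The packaged reference table carries the published thermodynamic parameters
(T_m, dH_m, dC_p, m, and derived dG_f, [D]50%, common-m ddG_f with standard
errors) for 26 purified CI2 variants, so every downstream stage is testable
without downloads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import UnfoldingDataset, UnfoldingSeries
from .exceptions import DesignError, VariantLookupError
from .observation import BaselineParams, predicted_signal
from .thermo import Condition, ThermoParams

#: Default truth baselines: well separated, realistically sloped transition.
DEFAULT_BASELINES = BaselineParams(
    native_intercept=1000.0,
    native_t_slope=-2.0,
    native_d_slope=0.0,
    unfolded_intercept=600.0,
    unfolded_t_slope=-1.0,
    unfolded_d_slope=20.0,
)

_DEFAULT_LEVELS = tuple(np.linspace(0.0, 5.0, 13))


@dataclass(frozen=True)
class ExperimentDesign:
    """Measurement design for one synthetic unfolding experiment.

    Defaults mirror the published design: 13 GuHCl levels evenly spaced over
    0-5 M, a 15-95 degC ramp read every 0.5 degC, and additive Gaussian noise
    with sigma = 1% of the mid-range transition amplitude
    (``noise_relative=True`` interprets ``noise_sd`` as that fraction;
    otherwise it is in absolute signal units).
    """

    denaturant_levels: Sequence[float] = _DEFAULT_LEVELS
    temperature_start: float = 15.0  # degC
    temperature_stop: float = 95.0  # degC
    temperature_step: float = 0.5  # degC
    noise_sd: float = 0.01
    noise_relative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.denaturant_levels)) < 5:
            raise DesignError("need >= 5 distinct denaturant levels")
        if min(self.denaturant_levels) < 0:
            raise DesignError("denaturant levels must be >= 0 M")
        if self.temperature_step <= 0:
            raise DesignError("temperature step must be > 0")
        if self.temperature_stop <= self.temperature_start:
            raise DesignError("temperature_stop must exceed temperature_start")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")

    def temperature_grid(self) -> np.ndarray:
        """Temperature grid in Kelvin (inclusive of both endpoints)."""
        t_c = np.arange(
            self.temperature_start,
            self.temperature_stop + self.temperature_step / 2,
            self.temperature_step,
        )
        return t_c + 273.15


def transition_amplitude(
    baselines: BaselineParams, design: ExperimentDesign
) -> float:
    """|B_N - B_U| at the middle of the temperature ramp and denaturant grid."""
    t_mid = float(np.mean(design.temperature_grid()))
    d_mid = float(np.median(np.asarray(design.denaturant_levels)))
    cond = Condition(t_mid, d_mid)
    return float(abs(baselines.native(cond) - baselines.unfolded(cond)))


def _noise_sigma(baselines: BaselineParams, design: ExperimentDesign) -> float:
    if design.noise_relative:
        return design.noise_sd * transition_amplitude(baselines, design)
    return design.noise_sd


def simulate_dataset(
    thermo: ThermoParams,
    baselines: BaselineParams = DEFAULT_BASELINES,
    design: ExperimentDesign = ExperimentDesign(),
    variant_label: str = "synthetic",
    replicate_id: int = 0,
    seed_sequence: Optional[np.random.SeedSequence] = None,
) -> UnfoldingDataset:
    """Simulate one variant's full 2D unfolding experiment.

    One series per denaturant level; each series draws noise from an
    independent substream spawned from the design seed (or the supplied
    ``seed_sequence``), so the same (truth, design, seed) is bit-identical
    and different series are statistically independent.
    """
    ss = seed_sequence or np.random.SeedSequence(design.seed)
    sigma = _noise_sigma(baselines, design)
    temps = design.temperature_grid()
    series = []
    children = ss.spawn(len(design.denaturant_levels))
    for d, child in zip(design.denaturant_levels, children):
        cond = Condition(temps, float(d))
        clean = predicted_signal(thermo, baselines, cond)
        if sigma > 0:
            noisy = clean + np.random.default_rng(child).normal(0.0, sigma, temps.shape)
        else:
            noisy = np.asarray(clean, dtype=float)
        series.append(UnfoldingSeries(float(d), temps.copy(), noisy))
    return UnfoldingDataset(variant_label, series, replicate_id)


def simulate_cycle(
    truths: Mapping[str, ThermoParams],
    baselines: BaselineParams = DEFAULT_BASELINES,
    design: ExperimentDesign = ExperimentDesign(),
) -> list[UnfoldingDataset]:
    """Simulate the four corners of a double-mutant cycle.

    ``truths`` maps four distinct labels (reference, two singles, double) to
    their true parameters. Each dataset gets an independent noise stream
    derived deterministically from the master design seed.
    """
    if len(truths) != 4:
        raise DesignError(f"a double-mutant cycle has 4 corners, got {len(truths)}")
    master = np.random.SeedSequence(design.seed)
    children = master.spawn(len(truths))
    return [
        simulate_dataset(
            params, baselines, design, variant_label=label, seed_sequence=child
        )
        for (label, params), child in zip(truths.items(), children)
    ]


# ---------------------------------------------------------------------------
# Packaged reference parameters for the 26 characterised CI2 variants.
# ---------------------------------------------------------------------------

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def canonical_label(label: str) -> str:
    """Normalise a variant label: 'wt', 'L49I, I57V' -> 'wild-type', 'L49I/I57V'.

    Multi-mutant labels are split on commas/slashes and sorted by residue
    number.
    """
    s = label.strip()
    if s.lower().replace(" ", "-").replace("_", "-") in {"wild-type", "wt", "wildtype"}:
        return "wild-type"
    parts = [p.strip() for p in re.split(r"[,/]", s) if p.strip()]
    keyed = []
    for p in parts:
        m = _MUTATION_RE.match(p)
        if not m:
            raise VariantLookupError(f"malformed mutation token {p!r} in {label!r}")
        keyed.append((int(m.group(2)), p))
    return "/".join(p for _, p in sorted(keyed))


@lru_cache(maxsize=1)
def load_reference_table() -> pd.DataFrame:
    """Published thermodynamic parameters for the 26 CI2 variants (indexed by label)."""
    with resources.files("foldstab.data").joinpath("ci2_reference_params.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("variant")


def reference_record(variant_label: str) -> pd.Series:
    """Full published row (parameters, derived quantities, standard errors)."""
    table = load_reference_table()
    label = canonical_label(variant_label)
    if label not in table.index:
        raise VariantLookupError(f"variant {variant_label!r} not in reference table")
    return table.loc[label]


def reference_params(variant_label: str) -> ThermoParams:
    """Published (T_m, dH_m, dC_p, m) of a variant as :class:`ThermoParams`."""
    rec = reference_record(variant_label)
    return ThermoParams(
        t_m=float(rec["t_m"]),
        dh_m=float(rec["dh_m"]),
        dcp=float(rec["dcp"]),
        m_value=float(rec["m"]),
    )
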