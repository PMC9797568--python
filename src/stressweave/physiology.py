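"""Chemostat physiology: specific rates, yields, and condition comparisons.

At steady state in a chemostat the growth rate equals the dilution rate D,
so specific consumption/production rates follow from a mass balance over
the vessel: q = D * (feed - residual) / X, converted from g to mmol with
the compound's molar mass. Consumption is reported negative by convention.
Yields are grams of biomass (Y_XS) or ethanol (Y_EthS) formed per gram of
glucose consumed. Condition comparisons report percent change and log2
fold change of any parameter between a control and a treated culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError

#: Molar masses (g/mol) for the compounds quantified by HPLC / off-gas
#: analysis in glucose-limited anaerobic cultivations. Overridable by
#: passing an explicit ``molar_mass`` to :func:`specific_rate`.
MOLAR_MASSES: dict[str, float] = {
    "glucose": 180.16,
    "ethanol": 46.07,
    "glycerol": 92.09,
    "co2": 44.01,
    "lactate": 90.08,
    "pyruvate": 88.06,
    "acetate": 60.05,
}


@dataclass
class ChemostatRecord:
    """Physiology of one cultivation condition.

    Rates ``q`` are mmol gDW^-1 h^-1 (negative = consumption), ``D`` and
    ``mu`` h^-1, biomass ``X`` g DW L^-1, yields g per g glucose.
    """

    condition: str
    D: float
    mu: float
    X: float
    q: dict[str, float] = field(default_factory=dict)
    Y_XS: float | None = None
    Y_EthS: float | None = None
    feed_conc: dict[str, float] = field(default_factory=dict)
    residual_conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ParameterError(f"dilution rate must be positive, got {self.D}")
        if self.X <= 0:
            raise ParameterError(f"biomass must be positive, got {self.X}")
        for compound, conc in self.residual_conc.items():
            if conc < 0:
                raise ParameterError(f"negative residual concentration for {compound}")
        for name, y in (("Y_XS", self.Y_XS), ("Y_EthS", self.Y_EthS)):
            if y is not None and not 0 < y < 1.1:
                raise ParameterError(f"{name}={y} outside (0, 1.1)")


def specific_rate(
    D: float,
    feed_conc: float,
    residual_conc: float,
    X: float,
    molar_mass: float,
    consumption: bool = True,
) -> float:
    """Steady-state specific rate q in mmol gDW^-1 h^-1.

    q = +/- 1000 * D * (feed - residual) / (molar_mass * X); consumed
    compounds are returned negative.
    """
    if X <= 0:
        raise ZeroDivisionError("biomass X must be positive")
    if molar_mass <= 0:
        raise ParameterError("molar mass must be positive")
    if feed_conc < 0 or residual_conc < 0:
        raise ParameterError("concentrations must be non-negative")
    if consumption and feed_conc < residual_conc:
        raise ParameterError("feed below residual for a consumed compound")
    q = 1000.0 * D * (feed_conc - residual_conc) / (molar_mass * X)
    return -q if consumption else q


def yields(
    D: float,
    X: float,
    feed_glucose: float,
    residual_glucose: float,
    ethanol_conc: float,
) -> tuple[float, float]:
    """Biomass and ethanol yields on consumed glucose (g/g)."""
    consumed = feed_glucose - residual_glucose
    if consumed <= 0:
        raise ZeroDivisionError("no glucose consumed; yields undefined")
    return X / consumed, ethanol_conc / consumed


def percent_change(control: float, treated: float) -> float:
    """Relative change of *treated* vs *control*, in percent (unrounded)."""
    if control == 0:
        raise ZeroDivisionError("percent change undefined for zero control")
    return 100.0 * (treated - control) / control


def log2_fold_change(control: float, treated: float) -> float:
    """log2(treated / control); both values must be strictly positive."""
    if control <= 0 or treated <= 0:
        raise ParameterError("log2 fold change requires positive values")
    return math.log2(treated / control)


def compare_conditions(table: pd.DataFrame) -> pd.DataFrame:
    """Derive percent and log2 changes for each parameter of two conditions.

    *table* needs columns ``parameter``, ``control``, ``treated``. Percent
    change is rounded to the nearest integer for reporting; log2 fold
    change is emitted only where both values are strictly positive (rates
    with a sign convention are compared on magnitude).

    Returns one row per parameter with columns ``parameter``, ``control``,
    ``treated``, ``percent_change``, ``log2_fold_change``.
    """
    required = {"parameter", "control", "treated"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"comparison table missing columns: {sorted(missing)}")
    rows = []
    for rec in table.itertuples(index=False):
        c, t = float(rec.control), float(rec.treated)
        pct = round(percent_change(c, t)) if c != 0 else float("nan")
        lfc = (
            log2_fold_change(abs(c), abs(t))
            if c != 0 and t != 0 and (c > 0) == (t > 0)
            else float("nan")
        )
        rows.append(
            {
                "parameter": rec.parameter,
                "control": c,
                "treated": t,
                "percent_change": pct,
                "log2_fold_change": lfc,
            }
        )
    return pd.DataFrame(rows)
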