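"""Substrate composition accounting under ash conservation.

Mineral ash is not consumed during composting, so the rise in the ash
fraction of total dry solids measures how much total mass was lost:

    solids_loss = 1 - ash_initial / ash_final

Final component measurements reported per kg of *final* dry solids are
converted back to the initial-mass basis with the same factor, after which a
component's percent loss is just ``100 * (initial - final) / initial``.
Pooled losses over several components (e.g. the structural sugars) are
mass-weighted: total mass lost over total initial mass, not the mean of the
row percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass
class AshPair:
    """Initial and final ash content as fractions of total dry solids."""

    ash_initial: float
    ash_final: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ash_initial < 1.0 or not 0.0 < self.ash_final < 1.0:
            raise ValueError("ash fractions must be in (0,1)")
        if self.ash_final < self.ash_initial:
            raise ValueError(
                "final ash fraction below initial: inconsistent with a "
                "mass-losing process under ash conservation"
            )


@dataclass
class ComponentRow:
    """One substrate component on the initial-mass basis (g/kg initial mix)."""

    name: str
    initial: float
    final_adjusted: float

    def __post_init__(self) -> None:
        if self.initial < 0 or self.final_adjusted < 0:
            raise ValueError("component masses must be >= 0")


def solids_loss(ash: AshPair) -> float:
    """Total dry-solids loss fraction implied by ash conservation."""
    if ash.ash_final <= 0:
        raise ValueError("final ash fraction must be positive")
    return 1.0 - ash.ash_initial / ash.ash_final


def adjust_final(final_measured: float, ash: AshPair) -> float:
    """Convert g per kg *final* solids to g per kg *initial* mix."""
    return final_measured * ash.ash_initial / ash.ash_final


def component_loss_percent(row: ComponentRow) -> float:
    """Percent loss of one component; negative values flag apparent gains."""
    if row.initial <= 0:
        raise ValueError(
            f"component {row.name!r} has zero initial mass: loss undefined"
        )
    return 100.0 * (row.initial - row.final_adjusted) / row.initial


def pooled_loss_percent(rows: Sequence[ComponentRow]) -> float:
    """Mass-weighted pooled percent loss over several components."""
    if not rows:
        raise ValueError("no components supplied")
    total_initial = sum(r.initial for r in rows)
    if total_initial <= 0:
        raise ValueError("pooled initial mass is zero")
    total_final = sum(r.final_adjusted for r in rows)
    return 100.0 * (total_initial - total_final) / total_initial


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def loss_table(
    rows: Sequence[ComponentRow], ash: AshPair | None = None
) -> pd.DataFrame:
    """Per-component loss report with rounded and unrounded columns."""
    out = []
    for r in rows:
        loss = component_loss_percent(r)
        out.append(
            {
                "name": r.name,
                "initial_g_per_kg": r.initial,
                "final_adjusted_g_per_kg": r.final_adjusted,
                "loss_percent": loss,
                "loss_percent_rounded": round_half_up(loss),
            }
        )
    df = pd.DataFrame(out)
    if ash is not None:
        df.attrs["solids_loss"] = solids_loss(ash)
    return df


def read_composition_csv(
    path: str | Path, ash: AshPair | None = None
) -> list[ComponentRow]:
    """Load components from CSV, converting measured finals if needed.

    Accepts either a ``final_adjusted_g_per_kg`` column, or a
    ``final_measured_g_per_kg`` column plus an ``ash`` pair for conversion.
    """
    df = pd.read_csv(path)
    rows = []
    for rec in df.itertuples():
        if hasattr(rec, "final_adjusted_g_per_kg") and not pd.isna(
            rec.final_adjusted_g_per_kg
        ):
            final = float(rec.final_adjusted_g_per_kg)
        elif hasattr(rec, "final_measured_g_per_kg"):
            if ash is None:
                raise ValueError(
                    "measured finals need an ash pair for basis conversion"
                )
            final = adjust_final(float(rec.final_measured_g_per_kg), ash)
        else:
            raise ValueError("no final composition column found")
        rows.append(ComponentRow(rec.name, float(rec.initial_g_per_kg), final))
    return rows
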