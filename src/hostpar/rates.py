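"""Host-survival (HS) and parasitism-rate (PR) response variables.

Both rates standardize a parasitoid-exposed vial's emergence by the mean
number of adult flies reared for the same host species under the same
heat-timing treatment *without* parasitoids (the control denominator):

    HS = flies / denominator        PR = wasps / denominator

so a decline in HS is attributable to parasitoids, not to heat, and PR
measures wasp yield against the hosts actually available under that
thermal regime. Either ratio can exceed 1 by sampling noise (more flies in
a parasitoid vial than the control mean); values are capped at 1 per vial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .design import NO_PARASITOID, DesignCell, VialRecord, select
from .errors import DegenerateEstimateError, ValidationError

#: Denominators built from fewer control vials than this are flagged.
MIN_CONTROL_VIALS = 3


@dataclass(frozen=True)
class RateRecord:
    """HS/PR for one parasitoid-exposed vial."""

    cell: DesignCell
    replicate_id: str
    flies: int
    wasps: int
    denominator: float
    hs: float
    pr: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def control_denominator(dataset: Sequence[VialRecord], host: str,
                        heat_timing: str) -> float:
    """Mean fly emergence in the matching no-parasitoid vials."""
    controls = select(dataset, host=host, parasitoid=NO_PARASITOID,
                      heat_timing=heat_timing)
    if not controls:
        raise ValidationError(
            f"no no-parasitoid control vials for host={host!r}, "
            f"heat_timing={heat_timing!r}")
    mean = sum(v.flies for v in controls) / len(controls)
    if mean <= 0:
        raise DegenerateEstimateError(
            f"control fly emergence is zero for host={host!r}, "
            f"heat_timing={heat_timing!r}: HS/PR undefined")
    return mean


def host_survival(flies: int, denominator: float) -> float:
    """``min(flies / denominator, 1)``."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if flies < 0:
        raise ValidationError("flies must be non-negative")
    return min(flies / denominator, 1.0)


def parasitism_rate(wasps: int, denominator: float) -> float:
    """``min(wasps / denominator, 1)``."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if wasps < 0:
        raise ValidationError("wasps must be non-negative")
    return min(wasps / denominator, 1.0)


def summarize_rates(dataset: Sequence[VialRecord]) -> list[RateRecord]:
    """One RateRecord per parasitoid-exposed vial, in dataset order.

    Denominators are matched on (host, heat_timing) and shared across
    parasitoid species. No-parasitoid vials are consumed as controls only.
    Flags: ``few_controls(n=...)`` when the denominator came from fewer
    than three control vials.
    """
    denominators: dict[tuple[str, str], tuple[float, int]] = {}
    records: list[RateRecord] = []
    for v in dataset:
        if not v.cell.has_parasitoid:
            continue
        key = (v.cell.host, v.cell.heat_timing)
        if key not in denominators:
            denom = control_denominator(dataset, *key)
            n_controls = len(select(dataset, host=key[0],
                                    parasitoid=NO_PARASITOID,
                                    heat_timing=key[1]))
            denominators[key] = (denom, n_controls)
        denom, n_controls = denominators[key]
        flags: list[str] = []
        if n_controls < MIN_CONTROL_VIALS:
            flags.append(f"few_controls(n={n_controls})")
        records.append(RateRecord(
            cell=v.cell, replicate_id=v.replicate_id,
            flies=v.flies, wasps=v.wasps, denominator=denom,
            hs=host_survival(v.flies, denom),
            pr=parasitism_rate(v.wasps, denom),
            flags=tuple(flags)))
    return records


def rates_to_frame(records: Sequence[RateRecord]) -> pd.DataFrame:
    """Flat rate table matching the CSV interface."""
    rows = [{
        "host": r.cell.host, "parasitoid": r.cell.parasitoid,
        "heat_timing": r.cell.heat_timing, "replicate": r.replicate_id,
        "flies": r.flies, "wasps": r.wasps, "denominator": r.denominator,
        "hs": r.hs, "pr": r.pr, "flags": ";".join(r.flags),
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "host", "parasitoid", "heat_timing", "replicate", "flies", "wasps",
        "denominator", "hs", "pr", "flags"])
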