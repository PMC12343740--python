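"""Factorial design model and vial-count table I/O.

The experiments this package targets cross three factors in laboratory
microcosms: host species, parasitoid treatment (one of several wasp species
or a no-parasitoid control), and the timing of a 24-h extreme-heat pulse
relative to the parasitoid foraging window (ambient control, or heat
before / during / after the attack). Every treatment combination is
replicated as glass vials seeded with a fixed number of host eggs; the
response recorded per vial is the total number of adult flies and adult
wasps that eventually emerge.

This module defines the design data model (:class:`DesignConstants`,
:class:`DesignCell`, :class:`VialRecord`), the canonical CSV interchange
format, and validation. Heat-timing categories, not calendar days, are the
stable keys throughout the package: the exposure day ``tau`` attached to a
timing level is metadata carried by :class:`DesignConstants`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Label for the no-parasitoid control level of the parasitoid factor.
NO_PARASITOID = "none"
#: Label for the no-heat control level of the heat-timing factor.
AMBIENT = "ambient"

#: Canonical CSV header, in order.
VIAL_COLUMNS = ("host", "parasitoid", "heat_timing", "replicate",
                "eggs", "flies", "wasps")

DEFAULT_HEAT_DAYS: dict[str, int | None] = {
    AMBIENT: None, "before": 1, "during": 3, "after": 7,
}


@dataclass(frozen=True)
class DesignConstants:
    """Design quantities shared by every vial.

    Parameters
    ----------
    eggs_per_vial : int
        Host eggs seeded into each vial (H0).
    end_day : float
        Day on which emergence totals are taken (T); late stragglers are
        folded into this end-of-experiment total.
    wasp_count : int
        Number of foraging female wasps per parasitoid vial (P).
    attack_day : float
        Day the wasps are introduced (start of the 24-h foraging window).
    heat_days : mapping
        Heat-timing level -> exposure day ``tau`` (``None`` for the ambient,
        no-heat control).
    replicates_per_cell : int
        Replicate vials per treatment combination.
    """

    eggs_per_vial: int = 50
    end_day: float = 8.0
    wasp_count: int = 3
    attack_day: float = 3.0
    heat_days: Mapping[str, int | None] = field(
        default_factory=lambda: dict(DEFAULT_HEAT_DAYS))
    replicates_per_cell: int = 6

    def __post_init__(self) -> None:
        if self.eggs_per_vial <= 0:
            raise ValidationError("eggs_per_vial must be positive")
        if self.wasp_count < 0:
            raise ValidationError("wasp_count must be non-negative")
        if not 0 < self.attack_day < self.end_day:
            raise ValidationError(
                f"attack_day must lie strictly inside (0, end_day); got "
                f"attack_day={self.attack_day}, end_day={self.end_day}")
        if self.replicates_per_cell < 1:
            raise ValidationError("replicates_per_cell must be >= 1")
        for level, tau in self.heat_days.items():
            if tau is None:
                continue
            if not 0 < tau <= self.end_day:
                raise ValidationError(
                    f"heat day for level {level!r} must be in (0, end_day] "
                    f"or None; got {tau!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "DesignConstants":
        """Build constants from a (possibly partial) plain mapping."""
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(
                f"unknown design-constant keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "heat_days" in kwargs:
            kwargs["heat_days"] = {
                str(k): (None if v in (None, "none") else int(v))
                for k, v in kwargs["heat_days"].items()}
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConstants":
        """Read constants from a JSON or YAML config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValidationError(f"{path}: expected a mapping at top level")
        return cls.from_mapping(data)

    def timing_levels(self) -> tuple[str, ...]:
        return tuple(self.heat_days)


@dataclass(frozen=True, order=True)
class DesignCell:
    """One treatment combination: host x parasitoid x heat timing."""

    host: str
    parasitoid: str
    heat_timing: str

    def __post_init__(self) -> None:
        for name in ("host", "parasitoid", "heat_timing"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value:
                raise ValidationError(f"{name} must be a non-empty string")

    @property
    def has_parasitoid(self) -> bool:
        return self.parasitoid != NO_PARASITOID

    @property
    def heated(self) -> bool:
        return self.heat_timing != AMBIENT


@dataclass(frozen=True)
class VialRecord:
    """Observed (or simulated) emergence counts for one replicate vial."""

    cell: DesignCell
    replicate_id: str
    eggs: int
    flies: int
    wasps: int

    def __post_init__(self) -> None:
        for name in ("eggs", "flies", "wasps"):
            value = getattr(self, name)
            # counts of emerged adults are inherently integral; reject
            # fractional values instead of rounding
            if isinstance(value, bool) or not isinstance(value, (int,)):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
        if self.eggs <= 0:
            raise ValidationError("eggs must be positive")
        if self.flies < 0 or self.wasps < 0:
            raise ValidationError("emergence counts must be non-negative")
        if self.flies + self.wasps > self.eggs:
            raise ValidationError(
                f"flies + wasps = {self.flies + self.wasps} exceeds "
                f"eggs = {self.eggs}")
        if not self.cell.has_parasitoid and self.wasps > 0:
            raise ValidationError(
                "wasps recorded in a no-parasitoid control vial")


def enumerate_design(constants: DesignConstants,
                     host_levels: Sequence[str],
                     parasitoid_levels: Sequence[str],
                     timing_levels: Sequence[str]) -> list[DesignCell]:
    """Cartesian product of factor levels, in (host, parasitoid, timing) order.

    The returned order is deterministic: hosts vary slowest, timing fastest.
    """
    for name, levels in (("host", host_levels),
                         ("parasitoid", parasitoid_levels),
                         ("heat_timing", timing_levels)):
        if not levels:
            raise ValidationError(f"{name} levels must be non-empty")
        if len(set(levels)) != len(levels):
            raise ValidationError(f"duplicate {name} levels: {list(levels)}")
    return [DesignCell(h, p, t)
            for h in host_levels
            for p in parasitoid_levels
            for t in timing_levels]


def _as_count(text: object, name: str) -> int:
    try:
        value = float(text)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} is not a number: {text!r}") from None
    if not value.is_integer():
        raise ValidationError(f"{name} must be an integer count, got {text!r}")
    return int(value)


def read_vials(path: str | Path) -> list[VialRecord]:
    """Read a vial-count table from CSV.

    Expects the canonical header ``host,parasitoid,heat_timing,replicate,
    eggs,flies,wasps``. Row order is preserved. A malformed row raises a
    :class:`ValidationError` naming the (1-based) data row.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(VIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        logger.warning("%s: header-only file, no vial records", path)
        return []
    records: list[VialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            cell = DesignCell(row.host, row.parasitoid, row.heat_timing)
            records.append(VialRecord(
                cell=cell,
                replicate_id=str(row.replicate),
                eggs=_as_count(row.eggs, "eggs"),
                flies=_as_count(row.flies, "flies"),
                wasps=_as_count(row.wasps, "wasps"),
            ))
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from None
    return records


def vials_to_frame(records: Iterable[VialRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the canonical columns."""
    rows = [
        {"host": r.cell.host, "parasitoid": r.cell.parasitoid,
         "heat_timing": r.cell.heat_timing, "replicate": r.replicate_id,
         "eggs": r.eggs, "flies": r.flies, "wasps": r.wasps}
        for r in records]
    return pd.DataFrame(rows, columns=list(VIAL_COLUMNS))


def write_vials(records: Sequence[VialRecord], path: str | Path) -> None:
    """Write records as canonical CSV; ``read_vials`` round-trips exactly."""
    vials_to_frame(records).to_csv(path, index=False)


def select(records: Iterable[VialRecord], *,
           host: str | None = None,
           parasitoid: str | None = None,
           heat_timing: str | None = None) -> list[VialRecord]:
    """Filter vial records on any subset of the three design factors."""
    out = []
    for r in records:
        if host is not None and r.cell.host != host:
            continue
        if parasitoid is not None and r.cell.parasitoid != parasitoid:
            continue
        if heat_timing is not None and r.cell.heat_timing != heat_timing:
            continue
        out.append(r)
    return out
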