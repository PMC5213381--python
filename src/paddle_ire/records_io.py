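"""Ablation-site records: data model, CSV schemas, validation, derived quantities.

Schema
------
``sites.csv`` — one row per application site:

    pig_id,group,thickness_mm,peak_voltages_v,peak_currents_a,arcing

``group`` is one of ``50J``, ``100J``, ``4x50J``; the pulse columns hold
semicolon-joined per-pulse values (1 value for the single-energy groups,
4 for the serial group); ``arcing`` is ``true``/``false``.

``sections.csv`` — one row per histology section:

    pig_id,group,section_index,necrotic_halfwidth_mm,transition_halfwidth_mm,contains_vital_inside,spans_between_paddles

Half-widths are radial extents (mm) of the complete-necrosis and
transition zones along the mid-plane; ``spans_between_paddles`` records
whether non-viable parenchyma bridges the tissue from paddle to paddle
(the success criterion).  Sections attach to sites by ``(pig_id, group)``.

Files are UTF-8, comma-separated, dot-decimal.  ``write_sites`` emits a
canonical form (sites sorted by pig then group, floats in shortest ``%g``
form) that round-trips byte-for-byte through ``read_sites``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

from .errors import DomainError, SchemaError, ValidationError

__all__ = [
    "Group",
    "GROUP_ORDER",
    "EXPECTED_PULSES",
    "HistologySection",
    "AblationSite",
    "read_sites",
    "write_sites",
    "electric_field",
    "site_resistance",
    "summary_peak_current",
]


class Group(str, Enum):
    """Treatment group: delivered energy per application site."""

    SINGLE_50J = "50J"
    SINGLE_100J = "100J"
    SERIAL_4X50J = "4x50J"


GROUP_ORDER: tuple[Group, ...] = (Group.SINGLE_50J, Group.SINGLE_100J, Group.SERIAL_4X50J)

#: pulses per application: one for the single-energy groups, four serial 50 J pulses
EXPECTED_PULSES = {Group.SINGLE_50J: 1, Group.SINGLE_100J: 1, Group.SERIAL_4X50J: 4}

_THICKNESS_SANITY_MM = (1.0, 30.0)


@dataclass(frozen=True)
class HistologySection:
    """One H&E section scored along the mid-plane.

    ``necrotic_halfwidth`` is the radial extent of complete necrosis,
    ``transition_halfwidth`` the outer extent of the transition zone
    (alternating vital/necrotic cells with neutrophil influx).
    """

    necrotic_halfwidth: float
    transition_halfwidth: float
    contains_vital_inside: bool = False
    spans_between_paddles: bool = False

    def __post_init__(self):
        if self.necrotic_halfwidth < 0:
            raise ValidationError(
                f"necrotic_halfwidth must be >= 0, got {self.necrotic_halfwidth}"
            )
        if self.transition_halfwidth < self.necrotic_halfwidth:
            raise ValidationError(
                "transition_halfwidth must be >= necrotic_halfwidth "
                f"({self.transition_halfwidth} < {self.necrotic_halfwidth})"
            )


@dataclass(frozen=True)
class AblationSite:
    """One application site: group, geometry, recorded pulses, histology."""

    pig_id: str
    group: Group
    thickness: float  # mm, measured with a caliper between the paddles
    peak_voltages: tuple[float, ...]  # V, one per pulse
    peak_currents: tuple[float, ...]  # A, one per pulse
    arcing: bool = False
    sections: tuple[HistologySection, ...] = ()

    def __post_init__(self):
        expected = EXPECTED_PULSES[self.group]
        if len(self.peak_currents) != expected:
            raise ValidationError(
                f"group {self.group.value} requires {expected} pulse(s), "
                f"got {len(self.peak_currents)} peak currents"
            )
        if len(self.peak_voltages) != expected:
            raise ValidationError(
                f"group {self.group.value} requires {expected} pulse(s), "
                f"got {len(self.peak_voltages)} peak voltages"
            )
        lo, hi = _THICKNESS_SANITY_MM
        if not (lo <= self.thickness <= hi):
            raise ValidationError(
                f"thickness {self.thickness} mm outside sanity window [{lo}, {hi}] mm"
            )
        if any(v <= 0 for v in self.peak_voltages):
            raise ValidationError(f"peak voltages must be positive, got {self.peak_voltages}")
        if any(i <= 0 for i in self.peak_currents):
            raise ValidationError(f"peak currents must be positive, got {self.peak_currents}")

    def with_sections(self, sections: tuple[HistologySection, ...]) -> "AblationSite":
        return replace(self, sections=sections)


# ---------------------------------------------------------------------------
# CSV parsing
# ---------------------------------------------------------------------------

_SITES_HEADER = [
    "pig_id",
    "group",
    "thickness_mm",
    "peak_voltages_v",
    "peak_currents_a",
    "arcing",
]
_SECTIONS_HEADER = [
    "pig_id",
    "group",
    "section_index",
    "necrotic_halfwidth_mm",
    "transition_halfwidth_mm",
    "contains_vital_inside",
    "spans_between_paddles",
]


def _parse_group(raw: str, row: int) -> Group:
    try:
        return Group(raw)
    except ValueError:
        raise SchemaError(
            f"unknown group {raw!r}; expected one of {[g.value for g in Group]}",
            row=row,
            column="group",
        ) from None


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(f"not a number: {raw!r}", row=row, column=column) from None


def _parse_bool(raw: str, row: int, column: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1"):
        return True
    if low in ("false", "0"):
        return False
    raise SchemaError(f"not a boolean: {raw!r}", row=row, column=column)


def _parse_pulse_list(raw: str, row: int, column: str) -> tuple[float, ...]:
    parts = [p for p in raw.split(";") if p.strip() != ""]
    if not parts:
        raise SchemaError("empty pulse list", row=row, column=column)
    return tuple(_parse_float(p, row, column) for p in parts)


def _check_header(actual: list[str] | None, expected: list[str], path: Path) -> None:
    if actual != expected:
        raise SchemaError(f"{path}: header {actual!r} does not match schema {expected!r}", row=1)


def read_sites(
    sites_path: str | Path, sections_path: str | Path | None = None
) -> list[AblationSite]:
    """Parse and validate a cohort.

    Raises :class:`SchemaError` for malformed cells (with row/column) and
    :class:`ValidationError` for records violating domain invariants.
    When ``sections_path`` is given, sections are attached to sites by
    ``(pig_id, group)``; a section with no matching site is an error.
    """
    sites_path = Path(sites_path)
    sites: list[AblationSite] = []
    order: dict[tuple[str, str], int] = {}
    with open(sites_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), _SITES_HEADER, sites_path)
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(_SITES_HEADER):
                raise SchemaError(
                    f"expected {len(_SITES_HEADER)} columns, got {len(row)}", row=rownum
                )
            rec = dict(zip(_SITES_HEADER, row))
            group = _parse_group(rec["group"], rownum)
            key = (rec["pig_id"], group.value)
            if key in order:
                raise ValidationError(
                    f"duplicate site for pig {rec['pig_id']!r} group {group.value} "
                    f"(rows {order[key]} and {rownum})"
                )
            try:
                site = AblationSite(
                    pig_id=rec["pig_id"],
                    group=group,
                    thickness=_parse_float(rec["thickness_mm"], rownum, "thickness_mm"),
                    peak_voltages=_parse_pulse_list(rec["peak_voltages_v"], rownum, "peak_voltages_v"),
                    peak_currents=_parse_pulse_list(rec["peak_currents_a"], rownum, "peak_currents_a"),
                    arcing=_parse_bool(rec["arcing"], rownum, "arcing"),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
            order[key] = rownum
            sites.append(site)

    if sections_path is None:
        return sites

    sections_path = Path(sections_path)
    by_key: dict[tuple[str, str], list[HistologySection]] = {k: [] for k in order}
    with open(sections_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), _SECTIONS_HEADER, sections_path)
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(_SECTIONS_HEADER):
                raise SchemaError(
                    f"expected {len(_SECTIONS_HEADER)} columns, got {len(row)}", row=rownum
                )
            rec = dict(zip(_SECTIONS_HEADER, row))
            group = _parse_group(rec["group"], rownum)
            key = (rec["pig_id"], group.value)
            if key not in by_key:
                raise ValidationError(
                    f"row {rownum}: section for unknown site "
                    f"(pig {rec['pig_id']!r}, group {group.value})"
                )
            try:
                section = HistologySection(
                    necrotic_halfwidth=_parse_float(
                        rec["necrotic_halfwidth_mm"], rownum, "necrotic_halfwidth_mm"
                    ),
                    transition_halfwidth=_parse_float(
                        rec["transition_halfwidth_mm"], rownum, "transition_halfwidth_mm"
                    ),
                    contains_vital_inside=_parse_bool(
                        rec["contains_vital_inside"], rownum, "contains_vital_inside"
                    ),
                    spans_between_paddles=_parse_bool(
                        rec["spans_between_paddles"], rownum, "spans_between_paddles"
                    ),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
            by_key[key].append(section)

    return [s.with_sections(tuple(by_key[(s.pig_id, s.group.value)])) for s in sites]


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_sites(
    sites: list[AblationSite],
    sites_path: str | Path,
    sections_path: str | Path | None = None,
) -> None:
    """Write a cohort in canonical form (sorted by pig id, then group order)."""
    group_rank = {g: i for i, g in enumerate(GROUP_ORDER)}
    ordered = sorted(sites, key=lambda s: (s.pig_id, group_rank[s.group]))
    with open(sites_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SITES_HEADER)
        for s in ordered:
            writer.writerow(
                [
                    s.pig_id,
                    s.group.value,
                    _fmt(s.thickness),
                    ";".join(_fmt(v) for v in s.peak_voltages),
                    ";".join(_fmt(i) for i in s.peak_currents),
                    "true" if s.arcing else "false",
                ]
            )
    if sections_path is None:
        return
    with open(sections_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SECTIONS_HEADER)
        for s in ordered:
            for k, sec in enumerate(s.sections):
                writer.writerow(
                    [
                        s.pig_id,
                        s.group.value,
                        str(k),
                        _fmt(sec.necrotic_halfwidth),
                        _fmt(sec.transition_halfwidth),
                        "true" if sec.contains_vital_inside else "false",
                        "true" if sec.spans_between_paddles else "false",
                    ]
                )


# ---------------------------------------------------------------------------
# Derived per-site quantities (descriptive only)
# ---------------------------------------------------------------------------

def electric_field(site: AblationSite) -> float:
    """Descriptive field strength (V/cm): max peak voltage / thickness.

    Electrode-tissue polarisation makes the voltage gradient inside the
    tissue smaller than applied voltage / distance, so this number is a
    labelling convention, not a dosimetric quantity; current density is
    the physically meaningful dose here.
    """
    if site.thickness <= 0:
        raise DomainError("thickness must be > 0")
    v_per_mm = max(site.peak_voltages) / site.thickness
    return v_per_mm * 10.0  # V/mm -> V/cm


def site_resistance(site: AblationSite) -> tuple[float, ...]:
    """Per-pulse peak resistance V/I (ohm); descriptive."""
    if any(i <= 0 for i in site.peak_currents):
        raise DomainError("peak currents must be > 0")
    return tuple(v / i for v, i in zip(site.peak_voltages, site.peak_currents))


def summary_peak_current(site: AblationSite, mode: str = "mean") -> float:
    """Collapse per-pulse peak currents to one value per site.

    For the serial group the study does not say how four pulses combine;
    the default averages them (consistent with one mean per group in the
    summary table); ``max`` and ``last`` are available.
    """
    if mode == "mean":
        return sum(site.peak_currents) / len(site.peak_currents)
    if mode == "max":
        return max(site.peak_currents)
    if mode == "last":
        return site.peak_currents[-1]
    raise DomainError(f"unknown summary mode {mode!r}")
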