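"""Declarative 384-well plate layouts: wells -> treatments and controls.

A layout maps each used well to a sample id, treatment, concentration (nM)
or timepoint (minutes), vehicle group (DMSO or EtOH solvent controls) and
replicate index, plus a concentration factor for enriched extracts (200x
for solid-phase-extracted water samples). Layouts round-trip through YAML
and validate against the 384-well geometry (wells A01–P24).
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError

WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")
VEHICLE_GROUPS = ("DMSO", "EtOH", "none")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 384-well id, e.g. (0, 0) -> 'A01'."""
    if not (0 <= row < 16 and 0 <= col < 24):
        raise ValueError(f"(row={row}, col={col}) outside 384-well plate")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def is_valid_well(well: str) -> bool:
    return bool(WELL_RE.match(well))


@dataclass
class WellSpec:
    well: str
    sample: str
    treatment: str = ""
    concentration: float | None = None
    timepoint: float | None = None
    vehicle_group: str = "none"
    is_vehicle: bool = False
    replicate: int = 1
    concentration_factor: float = 1.0


@dataclass
class LayoutReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class PlateLayout:
    plate: str
    wells: list[WellSpec]
    fields_per_well: int = 8

    def well_map(self) -> dict[str, WellSpec]:
        return {w.well: w for w in self.wells}

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.sample)
        return list(seen)

    def validate(self) -> LayoutReport:
        """Report-only check of well ids, vehicle wiring and replication."""
        rep = LayoutReport()
        seen_wells: set[str] = set()
        vehicle_groups_present = {
            w.vehicle_group for w in self.wells if w.is_vehicle
        }
        per_sample: dict[str, int] = {}
        if self.fields_per_well < 1:
            rep.violations.append("fields_per_well must be >= 1")
        if not self.wells:
            rep.violations.append("layout has no wells")
        for w in self.wells:
            if not is_valid_well(w.well):
                rep.violations.append(f"invalid well id {w.well!r} (expect A01-P24)")
            if w.well in seen_wells:
                rep.violations.append(f"well {w.well!r} assigned twice")
            seen_wells.add(w.well)
            if w.vehicle_group not in VEHICLE_GROUPS:
                rep.violations.append(
                    f"well {w.well!r}: unknown vehicle group {w.vehicle_group!r}"
                )
            if not w.is_vehicle and w.vehicle_group == "none":
                rep.violations.append(
                    f"well {w.well!r} ({w.sample}): non-vehicle sample must name "
                    "a vehicle group"
                )
            elif not w.is_vehicle and w.vehicle_group not in vehicle_groups_present:
                rep.violations.append(
                    f"well {w.well!r} ({w.sample}): vehicle group "
                    f"{w.vehicle_group!r} has no vehicle wells in this layout"
                )
            if w.concentration is not None and w.concentration < 0:
                rep.violations.append(f"well {w.well!r}: negative concentration")
            if w.concentration_factor < 1:
                rep.violations.append(
                    f"well {w.well!r}: concentration_factor must be >= 1"
                )
            per_sample[w.sample] = per_sample.get(w.sample, 0) + 1
        for sample, n in per_sample.items():
            if n < 4:
                rep.warnings.append(
                    f"sample {sample!r} has {n} replicate wells; the design norm "
                    "is at least 4"
                )
        return rep

    def to_dict(self) -> dict:
        return {
            "plate": self.plate,
            "fields_per_well": self.fields_per_well,
            "wells": [asdict(w) for w in self.wells],
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        try:
            wells = [WellSpec(**w) for w in d["wells"]]
            return cls(
                plate=d.get("plate", "PLATE"),
                wells=wells,
                fields_per_well=int(d.get("fields_per_well", 8)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed layout: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_layout(layout: PlateLayout) -> LayoutReport:
    """Module-level alias for :meth:`PlateLayout.validate`."""
    return layout.validate()


def _assign_wells(n: int, start: int = 0) -> list[str]:
    return [well_name(i // 24, i % 24) for i in range(start, start + n)]


def dose_series_layout(
    doses,
    wells_per_dose: int = 4,
    fields_per_well: int = 8,
    plate: str = "DOSE",
    treatment: str = "P4",
    vehicle_group: str = "EtOH",
    concentration_factor: float = 1.0,
) -> PlateLayout:
    """Layout for a dose-response run: a vehicle group (0 nM) plus one
    replicate-well group per positive dose."""
    doses = [float(d) for d in doses]
    if 0.0 not in doses:
        doses = [0.0] + doses
    doses = sorted(set(doses))
    wells: list[WellSpec] = []
    names = iter(_assign_wells(len(doses) * wells_per_dose))
    for dose in doses:
        vehicle = dose == 0.0
        sample = vehicle_group if vehicle else f"{treatment}_{dose:g}nM"
        for rep in range(1, wells_per_dose + 1):
            wells.append(
                WellSpec(
                    well=next(names),
                    sample=sample,
                    treatment=vehicle_group if vehicle else treatment,
                    concentration=dose,
                    vehicle_group=vehicle_group,
                    is_vehicle=vehicle,
                    replicate=rep,
                    concentration_factor=concentration_factor,
                )
            )
    return PlateLayout(plate=plate, wells=wells, fields_per_well=fields_per_well)


def time_series_layout(
    timepoints,
    wells_per_timepoint: int = 4,
    fields_per_well: int = 8,
    plate: str = "TIME",
    treatment: str = "P4",
    vehicle_group: str = "EtOH",
) -> PlateLayout:
    """Layout for a time-course: t = 0 wells are the vehicle group."""
    tps = sorted(set(float(t) for t in timepoints) | {0.0})
    wells: list[WellSpec] = []
    names = iter(_assign_wells(len(tps) * wells_per_timepoint))
    for t in tps:
        vehicle = t == 0.0
        sample = vehicle_group if vehicle else f"{treatment}_t{t:g}min"
        for rep in range(1, wells_per_timepoint + 1):
            wells.append(
                WellSpec(
                    well=next(names),
                    sample=sample,
                    treatment=vehicle_group if vehicle else treatment,
                    timepoint=t,
                    vehicle_group=vehicle_group,
                    is_vehicle=vehicle,
                    replicate=rep,
                )
            )
    return PlateLayout(plate=plate, wells=wells, fields_per_well=fields_per_well)
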