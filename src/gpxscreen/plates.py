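"""Plate-centric domain types and tabular I/O.

Wells are addressed by row-letter + zero-padded column labels ("A01" ...
"AF48" on a 1536-well plate). Rows and columns are 1-based. Concentrations
are stored in molar throughout; display helpers convert to uM/nM.

The long-format plate table CSV is the interchange format every other stage
consumes: one row per (plate, well, channel, time) read, with plate-level
metadata (format, assay) repeated on each row.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    DataError,
    PlateFormatError,
    PlateIntegrityError,
    ValidationError,
)

__all__ = [
    "PlateFormat",
    "Assay",
    "Channel",
    "WellRole",
    "Read",
    "WellRecord",
    "PlateRecord",
    "DoseSeries",
    "CompoundRecord",
    "build_dose_series",
    "read_plate_table",
    "write_plate_table",
    "well_label",
    "label_to_row_col",
    "format_concentration",
]


class PlateFormat(str, enum.Enum):
    w1536 = "w1536"
    w384 = "w384"
    w96 = "w96"

    @property
    def n_rows(self) -> int:
        return {"w1536": 32, "w384": 16, "w96": 8}[self.value]

    @property
    def n_columns(self) -> int:
        return {"w1536": 48, "w384": 24, "w96": 12}[self.value]

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_columns


class Assay(str, enum.Enum):
    """The seven assay formats of the screening panel.

    gpx1/gpx2/gpx4 are GR-coupled NADPH-consumption assays; gr_counter is
    the coupling-enzyme counter-screen; txnrd1 the selenite-reduction
    counter-screen; mbbr_* the monobromobimane orthogonal endpoint assays.
    """

    gpx1 = "gpx1"
    gpx2 = "gpx2"
    gpx4 = "gpx4"
    gr_counter = "gr_counter"
    txnrd1 = "txnrd1"
    mbbr_gpx1 = "mbbr_gpx1"
    mbbr_gpx4 = "mbbr_gpx4"

    @property
    def channel(self) -> "Channel":
        if self in (Assay.mbbr_gpx1, Assay.mbbr_gpx4):
            return Channel.mbbr_394_490
        return Channel.nadph_340_450


class Channel(str, enum.Enum):
    nadph_340_450 = "nadph_340_450"
    mbbr_394_490 = "mbbr_394_490"


class WellRole(str, enum.Enum):
    sample = "sample"
    pos_control = "pos_control"
    neg_control = "neg_control"
    control_titration = "control_titration"
    empty = "empty"


_ROLES_WITH_CONCENTRATION = {WellRole.sample, WellRole.control_titration}


def _row_letters(row: int) -> str:
    """1-based row index -> A..Z, AA, AB, ... (plate-reader convention)."""
    if row < 1:
        raise ValidationError(f"row index must be >= 1, got {row}")
    letters = ""
    n = row
    while n > 0:
        n, rem = divmod(n - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def _letters_to_row(letters: str) -> int:
    n = 0
    for ch in letters:
        if not "A" <= ch <= "Z":
            raise ValidationError(f"invalid row letters {letters!r}")
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n


def well_label(row: int, column: int, fmt: PlateFormat) -> str:
    """Label for 1-based (row, column) on the given plate format."""
    if not (1 <= row <= fmt.n_rows and 1 <= column <= fmt.n_columns):
        raise ValidationError(
            f"({row}, {column}) outside {fmt.value} geometry "
            f"({fmt.n_rows} x {fmt.n_columns})"
        )
    return f"{_row_letters(row)}{column:02d}"


def label_to_row_col(label: str, fmt: PlateFormat) -> tuple[int, int]:
    """Inverse of :func:`well_label`; validates against plate geometry."""
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    if i == 0 or i == len(label):
        raise ValidationError(f"malformed well label {label!r}")
    row = _letters_to_row(label[:i])
    try:
        column = int(label[i:])
    except ValueError as exc:
        raise ValidationError(f"malformed well label {label!r}") from exc
    if not (1 <= row <= fmt.n_rows and 1 <= column <= fmt.n_columns):
        raise PlateIntegrityError(
            f"well {label!r} outside {fmt.value} geometry"
        )
    return row, column


def format_concentration(molar: float) -> str:
    """Human-readable concentration with 3 significant digits (uM/nM/pM)."""
    if molar >= 1e-6:
        return f"{molar * 1e6:.3g} uM"
    if molar >= 1e-9:
        return f"{molar * 1e9:.3g} nM"
    return f"{molar * 1e12:.3g} pM"


@dataclass(frozen=True)
class Read:
    channel: Channel
    time_s: float
    rfu: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rfu) or self.rfu < 0:
            raise ValidationError(f"rfu must be finite and >= 0, got {self.rfu}")
        if self.time_s < 0:
            raise ValidationError(f"time must be >= 0, got {self.time_s}")


@dataclass
class WellRecord:
    plate_id: str
    well: str
    row: int
    column: int
    role: WellRole
    compound_id: str | None = None
    concentration: float | None = None  # molar
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.role = WellRole(self.role)
        if self.role in _ROLES_WITH_CONCENTRATION:
            if self.concentration is None or self.concentration <= 0:
                raise ValidationError(
                    f"well {self.well}: role {self.role.value} requires a "
                    f"positive concentration"
                )
        elif self.concentration is not None:
            raise ValidationError(
                f"well {self.well}: role {self.role.value} must not carry a "
                f"concentration"
            )
        self.reads.sort(key=lambda r: (r.channel.value, r.time_s))

    def reads_on(self, channel: Channel) -> list[Read]:
        return [r for r in self.reads if r.channel == channel]

    def read_at(self, channel: Channel, time_s: float) -> Read:
        for r in self.reads_on(channel):
            if math.isclose(r.time_s, time_s, abs_tol=1e-9):
                return r
        raise DataError(
            f"well {self.plate_id}/{self.well}: no {channel.value} read at "
            f"t={time_s} s"
        )


# Minimum control counts enforced when validating a plate, by format.
DEFAULT_MIN_CONTROLS = {
    PlateFormat.w1536: (64, 64),
    PlateFormat.w384: (8, 8),
    PlateFormat.w96: (8, 8),
}


@dataclass
class PlateRecord:
    plate_id: str
    format: PlateFormat
    assay: Assay
    wells: list[WellRecord] = field(default_factory=list)
    read_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.format = PlateFormat(self.format)
        self.assay = Assay(self.assay)
        self.read_times = tuple(self.read_times)

    def validate(self, min_controls: tuple[int, int] | None = None) -> None:
        """Check geometry, label uniqueness and control counts.

        ``min_controls`` is (min_pos, min_neg); ``None`` uses the format
        default (64/64 for 1536-well), ``(0, 0)`` disables the check.
        """
        if len(self.wells) > self.format.capacity:
            raise PlateIntegrityError(
                f"plate {self.plate_id}: {len(self.wells)} wells exceed "
                f"{self.format.value} capacity {self.format.capacity}"
            )
        seen: set[str] = set()
        for w in self.wells:
            if w.well in seen:
                raise PlateIntegrityError(
                    f"plate {self.plate_id}: duplicate well {w.well}"
                )
            seen.add(w.well)
            row, col = label_to_row_col(w.well, self.format)
            if (row, col) != (w.row, w.column):
                raise PlateIntegrityError(
                    f"plate {self.plate_id}: well {w.well} label disagrees "
                    f"with (row={w.row}, column={w.column})"
                )
        if min_controls is None:
            min_controls = DEFAULT_MIN_CONTROLS[self.format]
        min_pos, min_neg = min_controls
        n_pos = sum(1 for w in self.wells if w.role == WellRole.pos_control)
        n_neg = sum(1 for w in self.wells if w.role == WellRole.neg_control)
        if n_pos < min_pos or n_neg < min_neg:
            raise PlateIntegrityError(
                f"plate {self.plate_id}: {n_pos} pos / {n_neg} neg control "
                f"wells, need >= {min_pos}/{min_neg}"
            )

    def wells_by_role(self, role: WellRole) -> list[WellRecord]:
        return [w for w in self.wells if w.role == role]

    def well(self, label: str) -> WellRecord:
        for w in self.wells:
            if w.well == label:
                return w
        raise DataError(f"plate {self.plate_id}: no well {label}")


@dataclass(frozen=True)
class DoseSeries:
    """Descending geometric concentration series (molar)."""

    concentrations: tuple[float, ...]
    fold: float

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) < 2:
            raise ValidationError("dose series needs >= 2 points")
        if self.fold <= 1:
            raise ValidationError(f"dilution fold must be > 1, got {self.fold}")
        for hi, lo in zip(c, c[1:]):
            if lo <= 0 or abs(hi / lo - self.fold) > 1e-9 * self.fold:
                raise ValidationError(
                    "concentrations are not a descending geometric series "
                    f"with fold {self.fold}"
                )

    @property
    def n_points(self) -> int:
        return len(self.concentrations)

    @property
    def top(self) -> float:
        return self.concentrations[0]

    @property
    def bottom(self) -> float:
        return self.concentrations[-1]


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str = ""
    library: str = ""
    annotations: tuple[str, ...] = ()


def build_dose_series(
    top_concentration: float, n_points: int, fold: float
) -> DoseSeries:
    """Intra-plate 1:fold dilution series from a top concentration.

    The screening default is an 1:3 series from 49.8 uM: 7 points reach
    68.3 nM, 11 points reach ~842 pM.
    """
    if top_concentration <= 0:
        raise ValidationError("top concentration must be > 0")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    concs = tuple(top_concentration / fold**i for i in range(n_points))
    return DoseSeries(concentrations=concs, fold=float(fold))


PLATE_TABLE_COLUMNS = [
    "plate",
    "format",
    "assay",
    "well",
    "role",
    "compound",
    "concentration_molar",
    "channel",
    "time_s",
    "rfu",
]


def write_plate_table(plates: Iterable[PlateRecord], path) -> None:
    """Write plates as a long-format CSV, one row per read.

    Output is deterministic: rows sorted by (plate, well, channel, time),
    fixed column order, fixed float formatting.
    """
    rows = []
    for plate in plates:
        for w in sorted(plate.wells, key=lambda w: (w.row, w.column)):
            for r in w.reads:
                rows.append(
                    (
                        plate.plate_id,
                        plate.format.value,
                        plate.assay.value,
                        w.well,
                        w.role.value,
                        w.compound_id or "",
                        "" if w.concentration is None else repr(w.concentration),
                        r.channel.value,
                        repr(float(r.time_s)),
                        repr(float(r.rfu)),
                    )
                )
    rows.sort(key=lambda r: (r[0], r[3], r[7], float(r[8])))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PLATE_TABLE_COLUMNS)
        writer.writerows(rows)


def read_plate_table(
    path, min_controls: tuple[int, int] | None = None
) -> list[PlateRecord]:
    """Read a long-format plate table CSV back into validated PlateRecords.

    Malformed rows are reported with their 1-based line number; duplicate
    (plate, well, channel, time) reads raise an integrity error.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PlateFormatError(f"{path}: empty file, no header")
        missing = [c for c in PLATE_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise PlateFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        plates: dict[str, PlateRecord] = {}
        wells: dict[tuple[str, str], WellRecord] = {}
        seen_reads: set[tuple[str, str, str, float]] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                plate_id = row["plate"]
                fmt = PlateFormat(row["format"])
                assay = Assay(row["assay"])
                label = row["well"]
                role = WellRole(row["role"])
                compound = row["compound"] or None
                conc = (
                    float(row["concentration_molar"])
                    if row["concentration_molar"]
                    else None
                )
                channel = Channel(row["channel"])
                time_s = float(row["time_s"])
                rfu = float(row["rfu"])
            except (KeyError, ValueError) as exc:
                raise PlateFormatError(f"{path}:{lineno}: malformed row: {exc}")
            key = (plate_id, label, channel.value, time_s)
            if key in seen_reads:
                raise PlateIntegrityError(
                    f"{path}:{lineno}: duplicate read {key}"
                )
            seen_reads.add(key)
            if plate_id not in plates:
                plates[plate_id] = PlateRecord(
                    plate_id=plate_id, format=fmt, assay=assay
                )
            plate = plates[plate_id]
            if (plate.format, plate.assay) != (fmt, assay):
                raise PlateIntegrityError(
                    f"{path}:{lineno}: plate {plate_id} changes format/assay"
                )
            wkey = (plate_id, label)
            if wkey not in wells:
                try:
                    r, c = label_to_row_col(label, fmt)
                except ValidationError as exc:
                    raise PlateIntegrityError(f"{path}:{lineno}: {exc}")
                wells[wkey] = WellRecord(
                    plate_id=plate_id,
                    well=label,
                    row=r,
                    column=c,
                    role=role,
                    compound_id=compound,
                    concentration=conc,
                )
                plate.wells.append(wells[wkey])
            wells[wkey].reads.append(Read(channel=channel, time_s=time_s, rfu=rfu))
    result = list(plates.values())
    for plate in result:
        for w in plate.wells:
            w.reads.sort(key=lambda r: (r.channel.value, r.time_s))
        times = sorted({r.time_s for w in plate.wells for r in w.reads})
        plate.read_times = tuple(times)
        plate.validate(min_controls=min_controls)
    return result
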