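"""Domain types and I/O for 1536-well screening campaigns.

A campaign is a set of 32x48 plates read on two channels: a GFP reporter
channel (488 nm) tracking rod-photoreceptor rescue and a DAPI channel
(405 nm) tracking viability.  Each well carries a layout annotation: the
cell-line context (WT reporter-positive control, RD16 disease line, or the
reporter-negative PARENTAL counter-screen line), its treatment (a compound
at a nominal molar concentration, or DMSO vehicle), and a mask flag set by
quality control.

On-disk dialect (all plain CSV):

* intensity table  ``plate_id,row,col,gfp,dapi``
* layout table     ``plate_id,row,col,cell_line,treatment,compound_id,concentration_molar,masked``
* plate metadata   ``plate_id,assay_kind,replicate`` (optional; inferred when absent)
* compound map     ``compound_id,name,stock_molar``

Coordinates are 0-based (row 0..31, col 0..47).  A1-style labels
(rows ``A``..``AF``, columns 1..48) are also accepted on input and
normalized; when the row label is alphabetic the column is read 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateWellError, PlateParseError, ScreenError

N_ROWS = 32
N_COLS = 48

WELL_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "cell_line",
    "treatment",
    "compound_id",
    "concentration_molar",
    "gfp",
    "dapi",
    "masked",
]


class CellLine(str, Enum):
    WT = "WT"
    RD16 = "RD16"
    PARENTAL = "PARENTAL"


class Treatment(str, Enum):
    COMPOUND = "COMPOUND"
    DMSO = "DMSO"


class AssayKind(str, Enum):
    """What a plate measures: the disease assay (RD16 + compounds), the
    autofluorescence counter-screen (reporter-negative parental cells), or a
    dedicated positive-control plate (WT)."""

    DISEASE_ASSAY = "DISEASE_ASSAY"
    COUNTER_SCREEN = "COUNTER_SCREEN"
    POSITIVE_CONTROL = "POSITIVE_CONTROL"


@dataclass(frozen=True)
class WellRecord:
    """One well: raw two-channel intensities plus layout annotation."""

    plate_id: str
    row: int
    col: int
    cell_line: CellLine
    treatment: Treatment
    compound_id: str | None
    concentration: float | None  # mol/L, nominal assay concentration
    gfp: float
    dapi: float
    masked: bool = False

    def __post_init__(self):
        if not (0 <= self.row < N_ROWS):
            raise ValueError(f"row {self.row} outside [0, {N_ROWS})")
        if not (0 <= self.col < N_COLS):
            raise ValueError(f"col {self.col} outside [0, {N_COLS})")
        is_dmso = self.treatment == Treatment.DMSO
        if is_dmso != (self.compound_id is None) or is_dmso != (
            self.concentration is None
        ):
            raise ValueError(
                "treatment=DMSO must coincide with null compound_id and "
                "null concentration"
            )
        if self.concentration is not None and not self.concentration > 0:
            raise ValueError("concentration must be > 0")
        if self.gfp < 0 or self.dapi < 0:
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class PlateInfo:
    assay_kind: AssayKind
    replicate_index: int = 0

    def __post_init__(self):
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound with its dilution series (mol/L, strictly decreasing)."""

    compound_id: str
    name: str = ""
    stock_concentration: float = 10e-3  # 10 mM DMSO stock
    series: tuple[float, ...] = ()

    def __post_init__(self):
        if any(c <= 0 for c in self.series):
            raise ValueError("series concentrations must be > 0")
        if any(a <= b for a, b in zip(self.series, self.series[1:])):
            raise ValueError("series must be strictly decreasing")


@dataclass
class PlateSet:
    """A screening campaign: well table plus per-plate metadata.

    ``wells`` is a DataFrame with columns :data:`WELL_COLUMNS`; DMSO wells
    carry ``compound_id=None`` and ``concentration_molar=NaN``.
    """

    wells: pd.DataFrame
    plate_info: dict[str, PlateInfo] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[WellRecord], plate_info: dict[str, PlateInfo]
    ) -> "PlateSet":
        rows = [
            (
                r.plate_id,
                r.row,
                r.col,
                r.cell_line.value,
                r.treatment.value,
                r.compound_id,
                math.nan if r.concentration is None else r.concentration,
                float(r.gfp),
                float(r.dapi),
                bool(r.masked),
            )
            for r in records
        ]
        df = pd.DataFrame(rows, columns=WELL_COLUMNS)
        ps = cls(wells=df, plate_info=dict(plate_info))
        ps.validate()
        return ps

    def iter_records(self) -> Iterable[WellRecord]:
        for t in self.wells.itertuples(index=False):
            yield WellRecord(
                plate_id=t.plate_id,
                row=int(t.row),
                col=int(t.col),
                cell_line=CellLine(t.cell_line),
                treatment=Treatment(t.treatment),
                compound_id=None if t.compound_id is None else str(t.compound_id),
                concentration=None
                if pd.isna(t.concentration_molar)
                else float(t.concentration_molar),
                gfp=float(t.gfp),
                dapi=float(t.dapi),
                masked=bool(t.masked),
            )

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    def plate(self, plate_id: str) -> pd.DataFrame:
        return self.wells[self.wells["plate_id"] == plate_id]

    def validate(self) -> None:
        df = self.wells
        if list(df.columns) != WELL_COLUMNS:
            raise ScreenError(f"well table must have columns {WELL_COLUMNS}")
        if df.duplicated(subset=["plate_id", "row", "col"]).any():
            dup = df[df.duplicated(subset=["plate_id", "row", "col"], keep=False)]
            key = dup.iloc[0]
            raise DuplicateWellError(
                f"duplicate well ({key.plate_id}, {key.row}, {key.col})"
            )
        if ((df["row"] < 0) | (df["row"] >= N_ROWS)).any():
            raise ScreenError("row outside plate geometry")
        if ((df["col"] < 0) | (df["col"] >= N_COLS)).any():
            raise ScreenError("col outside plate geometry")
        if ((df["gfp"] < 0) | (df["dapi"] < 0)).any():
            raise ScreenError("negative intensity")
        dmso = df["treatment"] == Treatment.DMSO.value
        if (dmso != df["compound_id"].isna()).any() or (
            dmso != df["concentration_molar"].isna()
        ).any():
            raise ScreenError(
                "DMSO wells must have null compound_id and concentration, "
                "compound wells must have both"
            )
        for pid in df["plate_id"].unique():
            if pid not in self.plate_info:
                raise ScreenError(f"plate {pid!r} missing from plate_info")

    def copy(self) -> "PlateSet":
        return PlateSet(wells=self.wells.copy(), plate_info=dict(self.plate_info))

    def equals(self, other: "PlateSet") -> bool:
        """Field-for-field equality, insensitive to row order."""
        if self.plate_info != other.plate_info:
            return False

        def canon(df: pd.DataFrame) -> pd.DataFrame:
            out = df.sort_values(["plate_id", "row", "col"]).reset_index(drop=True)
            return out.astype(
                {
                    "row": int,
                    "col": int,
                    "concentration_molar": float,
                    "gfp": float,
                    "dapi": float,
                    "masked": bool,
                }
            )

        a, b = canon(self.wells), canon(other.wells)
        if len(a) != len(b):
            return False
        return a.equals(b)


# ---------------------------------------------------------------------------
# coordinate parsing

def _row_label(row: int) -> str:
    # A..Z, then AA..AF for rows 26..31
    if row < 26:
        return chr(ord("A") + row)
    return "A" + chr(ord("A") + row - 26)


def parse_row(text: str) -> int:
    """Parse a row as a 0-based integer or an A1-style letter label."""
    s = text.strip()
    if s.lstrip("-").isdigit():
        return int(s)
    label = s.upper()
    if label and all("A" <= c <= "Z" for c in label):
        idx = 0
        for c in label:
            idx = idx * 26 + (ord(c) - ord("A") + 1)
        return idx - 1
    raise ValueError(f"unparseable row {text!r}")


def parse_coords(row_text: str, col_text: str) -> tuple[int, int]:
    """Normalize (row, col) strings to 0-based integers.

    Numeric rows are 0-based with 0-based columns; alphabetic row labels
    imply 1-based columns (the A1 convention of plate-reader exports).
    """
    alpha = not row_text.strip().lstrip("-").isdigit()
    row = parse_row(row_text)
    col = int(col_text)
    if alpha:
        col -= 1
    return row, col


# ---------------------------------------------------------------------------
# dilution series

def dilution_series(stock: float, factor: float, n_points: int) -> list[float]:
    """Serial dilution concentrations ``[stock, stock/factor, ...]`` (mol/L).

    Mirrors the screening libraries' preparation: a 10 mM DMSO stock diluted
    1:``factor`` for ``n_points`` concentrations (e.g. the confirmatory
    11-point 1:3 series).
    """
    if stock <= 0:
        raise ValueError("stock must be > 0")
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return [stock / factor**i for i in range(n_points)]


# ---------------------------------------------------------------------------
# readers / writers

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(text: str, path, line, field) -> bool:
    s = text.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise PlateParseError(path, line, field, f"not a boolean: {text!r}")


def _read_csv_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [(i + 1, row) for i, row in enumerate(reader) if row]
    if not rows:
        raise PlateParseError(path, 1, "header", "empty file")
    header = [h.strip() for h in rows[0][1]]
    return header, rows[1:]


def read_plate_table(
    path: str | Path,
    layout: str | Path,
    plate_meta: str | Path | None = None,
) -> PlateSet:
    """Join an intensity table to its layout into a :class:`PlateSet`.

    Layout wells without a matching intensity row are kept with
    ``masked=True`` and zero intensities; intensity rows without a layout
    entry are an error.  ``plate_meta`` optionally supplies per-plate assay
    kind and replicate index; otherwise both are inferred from the plate's
    cell-line composition (replicate 0).
    """
    ipath, lpath = Path(path), Path(layout)

    header, rows = _read_csv_rows(ipath)
    expected = ["plate_id", "row", "col", "gfp", "dapi"]
    if header != expected:
        raise PlateParseError(ipath, 1, "header", f"expected {expected}, got {header}")
    intensities: dict[tuple[str, int, int], tuple[float, float]] = {}
    for line_no, row in rows:
        if len(row) != 5:
            raise PlateParseError(ipath, line_no, "row", "wrong field count")
        pid = row[0].strip()
        try:
            r, c = parse_coords(row[1], row[2])
        except ValueError as e:
            raise PlateParseError(ipath, line_no, "row/col", str(e)) from e
        if not (0 <= r < N_ROWS):
            raise PlateParseError(ipath, line_no, "row", f"row {r} outside [0,{N_ROWS})")
        if not (0 <= c < N_COLS):
            raise PlateParseError(ipath, line_no, "col", f"col {c} outside [0,{N_COLS})")
        try:
            gfp, dapi = float(row[3]), float(row[4])
        except ValueError as e:
            raise PlateParseError(ipath, line_no, "gfp/dapi", str(e)) from e
        if gfp < 0:
            raise PlateParseError(ipath, line_no, "gfp", "negative intensity")
        if dapi < 0:
            raise PlateParseError(ipath, line_no, "dapi", "negative intensity")
        key = (pid, r, c)
        if key in intensities:
            raise DuplicateWellError(f"{ipath}: duplicate well {key}")
        intensities[key] = (gfp, dapi)

    header, rows = _read_csv_rows(lpath)
    expected = [
        "plate_id",
        "row",
        "col",
        "cell_line",
        "treatment",
        "compound_id",
        "concentration_molar",
        "masked",
    ]
    if header != expected:
        raise PlateParseError(lpath, 1, "header", f"expected {expected}, got {header}")

    recs: list[tuple] = []
    seen: set[tuple[str, int, int]] = set()
    for line_no, row in rows:
        if len(row) != 8:
            raise PlateParseError(lpath, line_no, "row", "wrong field count")
        pid = row[0].strip()
        try:
            r, c = parse_coords(row[1], row[2])
        except ValueError as e:
            raise PlateParseError(lpath, line_no, "row/col", str(e)) from e
        if not (0 <= r < N_ROWS) or not (0 <= c < N_COLS):
            raise PlateParseError(lpath, line_no, "row/col", "outside plate geometry")
        try:
            cell_line = CellLine(row[3].strip())
        except ValueError as e:
            raise PlateParseError(lpath, line_no, "cell_line", str(e)) from e
        try:
            treatment = Treatment(row[4].strip())
        except ValueError as e:
            raise PlateParseError(lpath, line_no, "treatment", str(e)) from e
        compound_id = row[5].strip() or None
        conc_text = row[6].strip()
        conc = math.nan
        if conc_text:
            try:
                conc = float(conc_text)
            except ValueError as e:
                raise PlateParseError(lpath, line_no, "concentration_molar", str(e)) from e
            if conc <= 0:
                raise PlateParseError(
                    lpath, line_no, "concentration_molar", "must be > 0"
                )
        is_dmso = treatment == Treatment.DMSO
        if is_dmso != (compound_id is None) or is_dmso != math.isnan(conc):
            raise PlateParseError(
                lpath,
                line_no,
                "treatment",
                "DMSO wells must have empty compound_id/concentration and "
                "compound wells must have both",
            )
        masked = _parse_bool(row[7], lpath, line_no, "masked")
        key = (pid, r, c)
        if key in seen:
            raise DuplicateWellError(f"{lpath}: duplicate well {key}")
        seen.add(key)
        if key in intensities:
            gfp, dapi = intensities.pop(key)
        else:
            gfp, dapi, masked = 0.0, 0.0, True
        recs.append(
            (pid, r, c, cell_line.value, treatment.value, compound_id, conc, gfp, dapi, masked)
        )

    if intensities:
        key = next(iter(intensities))
        raise PlateParseError(
            ipath, 0, "plate_id/row/col", f"intensity row {key} has no layout entry"
        )

    wells = pd.DataFrame(recs, columns=WELL_COLUMNS)

    if plate_meta is not None:
        plate_info = _read_plate_meta(plate_meta)
    else:
        plate_info = {}
        for pid in wells["plate_id"].unique():
            lines = set(wells.loc[wells["plate_id"] == pid, "cell_line"])
            if CellLine.PARENTAL.value in lines:
                kind = AssayKind.COUNTER_SCREEN
            elif CellLine.RD16.value in lines:
                kind = AssayKind.DISEASE_ASSAY
            else:
                kind = AssayKind.POSITIVE_CONTROL
            plate_info[pid] = PlateInfo(assay_kind=kind, replicate_index=0)

    ps = PlateSet(wells=wells, plate_info=plate_info)
    ps.validate()
    return ps


def _read_plate_meta(path) -> dict[str, PlateInfo]:
    header, rows = _read_csv_rows(path)
    expected = ["plate_id", "assay_kind", "replicate"]
    if header != expected:
        raise PlateParseError(path, 1, "header", f"expected {expected}, got {header}")
    info: dict[str, PlateInfo] = {}
    for line_no, row in rows:
        pid = row[0].strip()
        if pid in info:
            raise DuplicateWellError(f"{path}: duplicate plate {pid}")
        try:
            kind = AssayKind(row[1].strip())
        except ValueError as e:
            raise PlateParseError(path, line_no, "assay_kind", str(e)) from e
        try:
            rep = int(row[2])
        except ValueError as e:
            raise PlateParseError(path, line_no, "replicate", str(e)) from e
        info[pid] = PlateInfo(assay_kind=kind, replicate_index=rep)
    return info


def write_plate_table(plates: PlateSet, outdir: str | Path) -> dict[str, Path]:
    """Serialize a PlateSet into its CSV dialect under ``outdir``.

    Writes ``plates.csv`` (intensities), ``layout.csv``, and
    ``plate_info.csv``; the round trip through :func:`read_plate_table` is
    lossless for every field including mask flags.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plates.validate()
    df = plates.wells.sort_values(["plate_id", "row", "col"])

    ipath = outdir / "plates.csv"
    lpath = outdir / "layout.csv"
    mpath = outdir / "plate_info.csv"

    inten = df[["plate_id", "row", "col", "gfp", "dapi"]]
    inten.to_csv(ipath, index=False)

    layout = df[
        [
            "plate_id",
            "row",
            "col",
            "cell_line",
            "treatment",
            "compound_id",
            "concentration_molar",
            "masked",
        ]
    ].copy()
    layout["masked"] = np.where(layout["masked"], "true", "false")
    layout.to_csv(lpath, index=False)

    with open(mpath, "w") as fh:
        fh.write("plate_id,assay_kind,replicate\n")
        for pid in sorted(plates.plate_info):
            info = plates.plate_info[pid]
            fh.write(f"{pid},{info.assay_kind.value},{info.replicate_index}\n")

    return {"plates": ipath, "layout": lpath, "plate_info": mpath}


def read_compound_map(path: str | Path) -> dict[str, CompoundRecord]:
    header, rows = _read_csv_rows(path)
    expected = ["compound_id", "name", "stock_molar"]
    if header != expected:
        raise PlateParseError(path, 1, "header", f"expected {expected}, got {header}")
    out: dict[str, CompoundRecord] = {}
    for line_no, row in rows:
        cid = row[0].strip()
        if cid in out:
            raise DuplicateWellError(f"{path}: duplicate compound {cid}")
        try:
            stock = float(row[2])
        except ValueError as e:
            raise PlateParseError(path, line_no, "stock_molar", str(e)) from e
        out[cid] = CompoundRecord(compound_id=cid, name=row[1].strip(), stock_concentration=stock)
    return out


def write_compound_map(compounds: Sequence[CompoundRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("compound_id,name,stock_molar\n")
        for c in compounds:
            fh.write(f"{c.compound_id},{c.name},{c.stock_concentration!r}\n")
    return path
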