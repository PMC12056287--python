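"""Data model and file I/O for per-cell tissue maps.

The pipeline's universal currency is the :class:`CellTable`: one row per
segmented cell with sample id, x/y coordinates in micrometres, one 0/1
positivity flag per marker of a :class:`MarkerPanel`, and optional 0-255
staining intensities.  Tables travel as tab-separated UTF-8 text with "."
decimals — the lowest-friction interchange with segmentation exports.
Lines starting with ``#`` are provenance comments and are skipped on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, ValidationError

__all__ = [
    "CANONICAL_MARKERS",
    "REGION_LABELS",
    "MarkerPanel",
    "RegionGeometry",
    "CellTable",
    "core_area",
    "read_cell_table",
    "write_cell_table",
    "read_region_geometry",
    "write_region_geometry",
]

#: The canonical 20-marker panel: lineage markers (CD3/CD8/CD4, the subset
#: transcription factors, CD56, CD11c), functional markers (TIM-3, PD-1,
#: CTLA-4, GranzymeB, Ki67, HLA-DR, CD27, CD45RA) and structural markers
#: (panCK for tumor epithelium, CD31 for endothelium).  "RORgt" is the
#: ASCII spelling of RORγT used in file headers.
CANONICAL_MARKERS: tuple[str, ...] = (
    "CD3", "CD8", "CD4", "FOXP3", "T-bet", "GATA3", "RORgt", "BCL6",
    "CD27", "CD56", "CD11c", "TIM-3", "PD-1", "CTLA-4", "panCK", "Ki67",
    "CD31", "GranzymeB", "HLA-DR", "CD45RA",
)

#: Tissue-compartment labels: tumor center, invasive-margin bands on the
#: stromal and tumoral side of the borderline, tissue beyond the margin on
#: the stromal side, and unassigned.
REGION_LABELS: tuple[str, ...] = ("CT", "IM_STROMA", "IM_TUMOR", "OUTSIDE", "UNASSIGNED")

MANDATORY_COLUMNS: tuple[str, ...] = ("cell_id", "sample_id", "x_um", "y_um")

INTENSITY_SUFFIX = "_int"


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered, unique set of marker identifiers."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValidationError("marker panel must not be empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate marker names in panel: {dupes}")

    @classmethod
    def default(cls) -> "MarkerPanel":
        return cls(CANONICAL_MARKERS)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, marker: str) -> bool:
        return marker in self.names

    def index(self, marker: str) -> int:
        return self.names.index(marker)


@dataclass(frozen=True)
class RegionGeometry:
    """Tumor-stroma borderline of a large section.

    ``borderline`` is an open polyline of (x, y) vertices in μm.  ``tumor_side``
    declares which side of the (directed) polyline is tumor: "left" means the
    tumor lies to the left when walking the vertices in order.  The invasive
    margin is the band of half-width ``margin_width_um`` either side of the
    borderline.
    """

    borderline: np.ndarray
    tumor_side: str = "left"
    margin_width_um: float = 360.0

    def __post_init__(self) -> None:
        verts = np.asarray(self.borderline, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise GeometryError("borderline must be an (n, 2) array of vertices")
        if verts.shape[0] < 2:
            raise GeometryError("borderline needs at least 2 vertices")
        if not np.isfinite(verts).all():
            raise GeometryError("borderline vertices must be finite")
        if np.allclose(verts, verts[0]):
            raise GeometryError("degenerate borderline: all vertices identical")
        object.__setattr__(self, "borderline", verts)
        if self.tumor_side not in ("left", "right"):
            raise GeometryError(f"tumor_side must be 'left' or 'right', got {self.tumor_side!r}")
        if not self.margin_width_um > 0:
            raise GeometryError("margin_width_um must be > 0")


@dataclass
class CellTable:
    """A validated per-cell table plus its panel and optional tissue context.

    ``cells`` columns: ``cell_id``, ``sample_id``, ``x_um``, ``y_um``, one 0/1
    column per panel marker, optionally ``<marker>_int`` intensities in
    [0, 255] and a ``region`` label column.
    """

    panel: MarkerPanel
    cells: pd.DataFrame
    area_mm2: float | None = None
    geometry: RegionGeometry | None = None

    def __post_init__(self) -> None:
        self.cells = self.cells.reset_index(drop=True)
        _validate_cells(self.cells, self.panel)
        if self.area_mm2 is not None and not self.area_mm2 > 0:
            raise ValidationError(f"area_mm2 must be > 0, got {self.area_mm2}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) float array of cell centre coordinates in μm."""
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def positivity(self, marker: str) -> np.ndarray:
        if marker not in self.panel:
            raise ValidationError(f"marker {marker!r} not in panel")
        return self.cells[marker].to_numpy(dtype=bool)

    def positivity_matrix(self) -> pd.DataFrame:
        return self.cells[list(self.panel.names)].astype(bool)

    def has_intensities(self) -> bool:
        return any(f"{m}{INTENSITY_SUFFIX}" in self.cells.columns for m in self.panel)

    def subset(self, mask: np.ndarray) -> "CellTable":
        return replace(self, cells=self.cells.loc[np.asarray(mask)].reset_index(drop=True))


def _validate_cells(df: pd.DataFrame, panel: MarkerPanel) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    for marker in panel:
        if marker not in df.columns:
            raise FormatError(f"missing positivity column for panel marker {marker!r}")
    if len(df) == 0:
        return
    coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        row = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise ValidationError(f"non-finite coordinate at row {row}")
    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(f"duplicate cell_id within sample at row {row}")
    for marker in panel:
        vals = df[marker].to_numpy()
        ok = np.isin(vals, (0, 1, True, False))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise ValidationError(
                f"non-binary positivity value {vals[row]!r} in column {marker!r} at row {row}"
            )
        icol = f"{marker}{INTENSITY_SUFFIX}"
        if icol in df.columns:
            ivals = df[icol].to_numpy(dtype=float)
            bad = ~((ivals >= 0) & (ivals <= 255))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"intensity outside [0, 255] in column {icol!r} at row {row}"
                )
    if "region" in df.columns:
        vals = df["region"].to_numpy()
        ok = np.isin(vals, REGION_LABELS)
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise ValidationError(f"unknown region label {vals[row]!r} at row {row}")


def core_area(diameter_mm: float) -> float:
    """Area in mm² of a circular tissue core of the given diameter in mm.

    The standard tissue-microarray spot is 0.6 mm across, i.e. ≈0.2827 mm².
    """
    if not diameter_mm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_mm}")
    return math.pi * (diameter_mm / 2.0) ** 2


# -- file I/O -----------------------------------------------------------------


def read_cell_table(
    path: str | Path,
    panel: MarkerPanel | None = None,
    area_mm2: float | None = None,
    geometry: RegionGeometry | None = None,
) -> CellTable:
    """Read a tab-separated cell table (``#`` lines are comments).

    Expected header: ``cell_id  sample_id  x_um  y_um`` then one 0/1 column
    per panel marker, optionally ``<marker>_int`` intensity columns and a
    ``region`` column.  Row order is preserved.
    """
    panel = panel or MarkerPanel.default()
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#",
            dtype={"cell_id": str, "sample_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    keep = [c for c in df.columns if c in MANDATORY_COLUMNS or c == "region"
            or c in panel.names or (c.endswith(INTENSITY_SUFFIX) and c[: -len(INTENSITY_SUFFIX)] in panel.names)]
    df = df[keep]
    for marker in panel:
        if marker in df.columns and len(df):
            vals = df[marker]
            if not vals.isin((0, 1)).all():
                row = int(np.flatnonzero(~vals.isin((0, 1)).to_numpy())[0])
                raise ValidationError(
                    f"non-binary positivity value {vals.iloc[row]!r} in column {marker!r} at row {row}"
                )
            df[marker] = vals.astype(np.int8)
    return CellTable(panel=panel, cells=df, area_mm2=area_mm2, geometry=geometry)


def write_cell_table(
    table: CellTable,
    path: str | Path,
    header_lines: Sequence[str] | Iterable[str] = (),
) -> None:
    """Write a cell table as tab-separated UTF-8 text.

    ``header_lines`` are emitted first, each prefixed with ``# `` (used by the
    CLI for provenance: version, seed, parameters).  Output is bit-stable for
    a fixed input; floats are written with full precision so a read/write
    round trip is the identity.
    """
    path = Path(path)
    df = table.cells.copy()
    for marker in table.panel:
        df[marker] = df[marker].astype(np.int8)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        # %.17g guarantees an exact float round trip
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.17g")


def write_region_geometry(geometry: RegionGeometry, path: str | Path) -> None:
    """Write a borderline as a two-column vertex list with a one-line header."""
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# tumor_side={geometry.tumor_side} margin_width_um={float(geometry.margin_width_um)!r}\n"
        )
        fh.write("x_um\ty_um\n")
        for x, y in geometry.borderline:
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def read_region_geometry(path: str | Path) -> RegionGeometry:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise FormatError(f"geometry file {path} lacks the tumor-side header line")
    fields = dict(
        tok.split("=", 1) for tok in first.lstrip("# ").split() if "=" in tok
    )
    if "tumor_side" not in fields:
        raise FormatError(f"geometry header must declare tumor_side: {first!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if "x_um" not in df.columns or "y_um" not in df.columns:
        raise FormatError("geometry file must have x_um and y_um columns")
    return RegionGeometry(
        borderline=df[["x_um", "y_um"]].to_numpy(dtype=float),
        tumor_side=fields["tumor_side"],
        margin_width_um=float(fields.get("margin_width_um", 360.0)),
    )
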