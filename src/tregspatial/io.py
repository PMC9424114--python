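"""Readers, writers and the shared data model.

The pipeline starts from per-cell tables exported by image-analysis software
(one row per segmented cell: sample id, x/y position, tissue-region label and
a mean fluorescence intensity per marker channel), tissue masks, and a
clinical table.  Everything downstream consumes the canonical containers
defined here.

Coordinate convention: Cartesian micrometres, origin at the image top-left,
y increasing downward (raster order).  Pixel-space inputs are converted on
read via ``pixel_scale_um`` (default 0.5 µm/px).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

log = logging.getLogger("tregspatial")

REGIONS = ("epithelial", "stromal", "unassigned")
NA_TOKENS = {"", "NA", "NaN", "nan"}

DEFAULT_PIXEL_SCALE_UM = 0.5


# ---------------------------------------------------------------------------
# tissue outlines


@dataclass(frozen=True)
class TissueOutline:
    """Tissue region as one or more simple polygons (µm), holes allowed."""

    geometry: MultiPolygon

    def __post_init__(self):
        geom = self.geometry
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
        if not isinstance(geom, MultiPolygon):
            raise TypeError(f"expected (Multi)Polygon, got {type(geom).__name__}")
        geom = shapely.make_valid(geom) if not geom.is_valid else geom
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
        object.__setattr__(self, "geometry", geom)
        if self.area_um2 <= 0:
            raise ValueError("tissue outline has non-positive area")

    @property
    def area_um2(self) -> float:
        return float(self.geometry.area)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    def contains_points(self, x, y, tolerance: float = 1e-6) -> np.ndarray:
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.dwithin(pts, self.geometry, tolerance)

    @classmethod
    def disc(cls, diameter_mm: float, n_vertices: int = 256) -> "TissueOutline":
        """Circular core outline of the given diameter, centred at (r, r)."""
        r = diameter_mm * 1000.0 / 2.0
        ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        ring = np.column_stack([r + r * np.cos(ang), r + r * np.sin(ang)])
        return cls(MultiPolygon([Polygon(ring)]))


# ---------------------------------------------------------------------------
# per-cell tables


@dataclass
class SampleCellTable:
    """All segmented cells of one tissue core.

    ``cells`` has columns ``x``, ``y`` (µm), ``region`` (epithelial /
    stromal / unassigned) and one float column per marker; the index is the
    cell id.
    """

    sample_id: str
    cells: pd.DataFrame
    series_id: str = "1"
    core_diameter_mm: float = 1.0
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    outline: TissueOutline | None = None

    def __post_init__(self):
        if self.core_diameter_mm <= 0:
            raise ValueError("core_diameter_mm must be positive")
        for col in ("x", "y"):
            if col not in self.cells.columns:
                raise ValueError(f"cell table lacks mandatory column '{col}'")
            if not np.isfinite(self.cells[col].to_numpy(float)).all():
                raise ValueError(f"non-finite values in coordinate column '{col}'")
        if "region" not in self.cells.columns:
            self.cells = self.cells.assign(region="unassigned")
        bad = ~self.cells["region"].isin(REGIONS)
        if bad.any():
            raise ValueError(
                f"invalid region label(s): {sorted(self.cells.loc[bad, 'region'].unique())}"
            )
        for m in self.markers:
            vals = self.cells[m].to_numpy(float)
            if (vals < 0).any():
                row = int(np.argmax(vals < 0))
                raise ValueError(f"negative intensity for marker '{m}' at row {row}")

    @property
    def markers(self) -> list[str]:
        return [c for c in self.cells.columns if c not in ("x", "y", "region")]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def intensity(self, marker: str) -> np.ndarray:
        if marker not in self.markers:
            raise KeyError(f"marker '{marker}' not present in sample {self.sample_id}")
        return self.cells[marker].to_numpy(float)

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(float)


@dataclass(frozen=True)
class CellTableDialect:
    """Schema mapping from a source export to the canonical cell table.

    The shipped default expects canonical names already; real exports remap
    their own column names here.  ``coordinate_units`` is ``"um"`` or
    ``"px"`` (pixels are converted with ``pixel_scale_um``).
    """

    sample_col: str = "sample_id"
    x_col: str = "x"
    y_col: str = "y"
    region_col: str | None = "region"
    series_col: str | None = "series_id"
    marker_cols: Mapping[str, str] = field(
        default_factory=lambda: {m: m for m in ("CD3", "CD4", "CD8", "CD25", "FOXP3")}
    )
    coordinate_units: str = "um"
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    region_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "epithelial": "epithelial",
            "tumor": "epithelial",
            "stroma": "stromal",
            "stromal": "stromal",
        }
    )


def read_cell_table(
    path,
    dialect: CellTableDialect | None = None,
    core_diameter_mm: float = 1.0,
) -> list[SampleCellTable]:
    """Read a delimited per-cell export into one table per sample.

    Delimiter is auto-detected (TSV/CSV).  Row order within a sample is
    preserved; unmapped columns are ignored with a warning.
    """
    dialect = dialect or CellTableDialect()
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)

    mandatory = [dialect.sample_col, dialect.x_col, dialect.y_col]
    mandatory += list(dialect.marker_cols.values())
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column '{col}' in {path}")

    used = set(mandatory) | {dialect.region_col, dialect.series_col}
    unmapped = [c for c in df.columns if c not in used]
    if unmapped:
        log.warning("ignoring unmapped columns: %s", unmapped)

    scale = dialect.pixel_scale_um if dialect.coordinate_units == "px" else 1.0

    def _num(col, kind):
        try:
            return pd.to_numeric(df[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric {kind} in column '{col}': {exc}") from None

    out = pd.DataFrame(
        {
            "x": _num(dialect.x_col, "coordinate") * scale,
            "y": _num(dialect.y_col, "coordinate") * scale,
        }
    )
    if dialect.region_col and dialect.region_col in df.columns:
        reg = df[dialect.region_col].fillna("unassigned")
        out["region"] = [
            dialect.region_map.get(r, r if r in REGIONS else "unassigned") for r in reg
        ]
    else:
        out["region"] = "unassigned"
    for marker, src in dialect.marker_cols.items():
        vals = _num(src, "intensity")
        neg = np.flatnonzero(vals < 0)
        if neg.size:
            raise ValueError(
                f"negative intensity in column '{src}' at row {int(neg[0])}"
            )
        out[marker] = vals

    sample_ids = df[dialect.sample_col].astype(str)
    series = (
        df[dialect.series_col].astype(str)
        if dialect.series_col and dialect.series_col in df.columns
        else pd.Series("1", index=df.index)
    )
    tables = []
    for sid in sample_ids.unique():
        mask = (sample_ids == sid).to_numpy()
        cells = out.loc[mask].reset_index(drop=True)
        cells = cells[["x", "y", "region"] + list(dialect.marker_cols)]
        tables.append(
            SampleCellTable(
                sample_id=sid,
                series_id=str(series[mask].iloc[0]),
                core_diameter_mm=core_diameter_mm,
                pixel_scale_um=dialect.pixel_scale_um,
                cells=cells,
            )
        )
    return tables


def write_cell_table(tables: Sequence[SampleCellTable], path) -> None:
    """Write sample cell tables to one canonical TSV (round-trips with
    :func:`read_cell_table` under the default dialect)."""
    frames = []
    for t in tables:
        f = t.cells.copy()
        f.insert(0, "sample_id", t.sample_id)
        f.insert(1, "series_id", t.series_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.8g", na_rep="NA"
    )


# ---------------------------------------------------------------------------
# tissue masks


def _contours_to_multipolygon(contours_xy: list[np.ndarray]) -> MultiPolygon:
    """Assemble closed contours into polygons with holes by containment depth."""
    polys = [Polygon(c) for c in contours_xy if len(c) >= 4]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    polys = [p for p in polys if not p.is_empty and p.area > 0]
    order = np.argsort([-p.area for p in polys])
    shells: list[tuple[Polygon, list]] = []  # (shell, holes)
    depths = {}
    for i in order:
        p = polys[i]
        depth = sum(
            1 for j in order if j != i and polys[j].area > p.area and polys[j].contains(p)
        )
        depths[i] = depth
        if depth % 2 == 0:
            shells.append((p, []))
        else:
            # hole: attach to the smallest even-depth polygon containing it
            parents = [
                (s.area, k)
                for k, (s, _) in enumerate(shells)
                if s.contains(p)
            ]
            if parents:
                _, k = min(parents)
                shells[k][1].append(p.exterior)
    result = [Polygon(s.exterior, holes) for s, holes in shells]
    return MultiPolygon(result)


def read_tissue_mask(path, pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM) -> TissueOutline:
    """Trace a tissue outline from a binary raster (foreground = tissue) or a
    WKT polygon text file.

    Raster contours are traced with marching squares at the 0.5 iso-level, so
    for rectilinear masks the polygon area equals the foreground pixel count
    times ``pixel_scale_um**2``.
    """
    path = Path(path)
    if path.suffix.lower() in (".wkt", ".txt"):
        geom = shapely.wkt.loads(path.read_text())
        return TissueOutline(geom if isinstance(geom, MultiPolygon) else MultiPolygon([geom]))
    try:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path))
    except Exception as exc:  # unreadable raster
        raise ValueError(f"unreadable raster mask {path}: {exc}") from exc
    if img.ndim == 3:
        img = img[..., 0]
    fg = img > 0
    if not fg.any():
        raise ValueError(f"no tissue foreground in mask {path}")
    padded = np.pad(fg.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    # (row, col) in padded space -> (x, y) in µm
    xy = [
        np.column_stack([(c[:, 1] - 1.0) * pixel_scale_um, (c[:, 0] - 1.0) * pixel_scale_um])
        for c in contours
    ]
    return TissueOutline(_contours_to_multipolygon(xy))


def write_tissue_mask(outline: TissueOutline, path) -> None:
    Path(path).write_text(outline.geometry.wkt + "\n")


def write_outlines(tables: Sequence[SampleCellTable], path) -> None:
    """Per-sample tissue outlines as a two-column TSV (sample_id, WKT)."""
    with open(path, "w") as fh:
        fh.write("sample_id\twkt\n")
        for t in tables:
            if t.outline is not None:
                fh.write(f"{t.sample_id}\t{t.outline.geometry.wkt}\n")


def read_outlines(path) -> dict[str, TissueOutline]:
    out = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in df.iterrows():
        geom = shapely.wkt.loads(row["wkt"])
        if not isinstance(geom, MultiPolygon):
            geom = MultiPolygon([geom])
        out[row["sample_id"]] = TissueOutline(geom)
    return out


# ---------------------------------------------------------------------------
# clinical tables


STAGES = ("I", "II", "III", "IV")
SEXES = ("female", "male")
PT_VALUES = ("1", "2", "3", "4")
PN_VALUES = ("0", "1", "2")
R_VALUES = ("R0", "R1", "R2")
LOCATIONS = ("right", "left", "rectum", "synchronous")
MSI_VALUES = ("MSI", "MSS")
MUT_VALUES = ("wt", "mut")


@dataclass
class ClinicalRecord:
    """One patient: covariates and raw follow-up fields (months)."""

    patient_id: str
    age: float
    sex: str
    tnm_stage: str
    pT: str
    pN: str
    r_status: str
    location: str
    msi: str | None
    braf: str | None
    kras: str | None
    adjuvant_chemo: bool
    preop_radio: bool
    synchronous_primary: bool
    followup_months: float
    relapse_months: float | None = None
    death_months: float | None = None
    cohort: str = "1"

    def __post_init__(self):
        checks = [
            ("sex", self.sex, SEXES),
            ("tnm_stage", self.tnm_stage, STAGES),
            ("pT", self.pT, PT_VALUES),
            ("pN", self.pN, PN_VALUES),
            ("r_status", self.r_status, R_VALUES),
            ("location", self.location, LOCATIONS),
        ]
        for name, val, allowed in checks:
            if val not in allowed:
                raise ValueError(f"invalid {name} value '{val}' (allowed: {allowed})")
        for name, val, allowed in [
            ("msi", self.msi, MSI_VALUES),
            ("braf", self.braf, MUT_VALUES),
            ("kras", self.kras, MUT_VALUES),
        ]:
            if val is not None and val not in allowed:
                raise ValueError(f"invalid {name} value '{val}' (allowed: {allowed} or NA)")
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")


_CLINICAL_COLS = [
    "patient_id", "age", "sex", "tnm_stage", "pT", "pN", "r_status", "location",
    "msi", "braf", "kras", "adjuvant_chemo", "preop_radio", "synchronous_primary",
    "followup_months", "relapse_months", "death_months", "cohort",
]

_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False,
                "yes": True, "no": False}


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in _CLINICAL_COLS[:-1]:
        if col not in df.columns:
            raise ValueError(f"missing mandatory clinical column '{col}'")
    records = []
    for i, row in df.iterrows():
        def _opt(col):
            v = row.get(col, "")
            return None if v in NA_TOKENS else v

        def _optf(col):
            v = _opt(col)
            return None if v is None else float(v)

        def _bool(col):
            v = str(row[col]).strip().lower()
            if v not in _BOOL_TOKENS:
                raise ValueError(f"row {i}: invalid boolean '{row[col]}' in '{col}'")
            return _BOOL_TOKENS[v]

        try:
            records.append(
                ClinicalRecord(
                    patient_id=row["patient_id"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    tnm_stage=row["tnm_stage"],
                    pT=row["pT"],
                    pN=row["pN"],
                    r_status=row["r_status"],
                    location=row["location"],
                    msi=_opt("msi"),
                    braf=_opt("braf"),
                    kras=_opt("kras"),
                    adjuvant_chemo=_bool("adjuvant_chemo"),
                    preop_radio=_bool("preop_radio"),
                    synchronous_primary=_bool("synchronous_primary"),
                    followup_months=float(row["followup_months"]),
                    relapse_months=_optf("relapse_months"),
                    death_months=_optf("death_months"),
                    cohort=row.get("cohort", "1") or "1",
                )
            )
        except ValueError as exc:
            raise ValueError(f"clinical table row {i}: {exc}") from None
    return records


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_CLINICAL_COLS)


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    df = clinical_to_frame(records).copy()
    for col in ("adjuvant_chemo", "preop_radio", "synchronous_primary"):
        df[col] = df[col].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# generic score output


def write_sample_scores(frame: pd.DataFrame, path) -> None:
    """Write any per-sample result table as TSV with a stable column order,
    a header, and >= 6 significant digits on floats."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def read_sample_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
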