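"""Readers and writers for the pipeline's plain-text formats.

Formats:

* contour CSV — long format with columns ``contour_id, point_index, x_um,
  y_um`` plus an optional ``orientation`` column; a leading directive line
  ``# coordinates: y_down`` declares image-pixel coordinates, which are
  flipped to y-up at read time.
* measures CSV — ``line_id, replicate, height_um, radius_um``.
* cross CSV — the R/qtl "csv" dialect: header row with phenotype then marker
  names, second row with chromosome ids (blank for phenotypes), third row
  with cM positions, then one row per line with phenotype values and genotype
  letters A/H/B (missing "-").
* run manifest — JSON recording command, config snapshot, seed, input
  checksums, outputs and package version, so any run is reproducible from the
  manifest alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import Contour
from .geometry import SamMeasures
from .qtl import (
    CrossPopulation,
    GeneticMap,
    GENO_LETTERS,
    LETTER_GENO,
    QtlScanResult,
)

__all__ = [
    "read_contours",
    "write_contours",
    "read_measures",
    "write_measures",
    "read_cross",
    "write_cross",
    "write_scan",
    "write_intervals",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def read_contours(path) -> list[Contour]:
    """Read contours from long-format CSV; flips y when the file declares y-down."""
    path = Path(path)
    y_down = False
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            y_down = "y_down" in first.replace(" ", "").lower()
            header_line = 1
        else:
            header_line = 0
    if path.stat().st_size == 0 or (header_line == 1 and not path.read_text().strip("#").strip()):
        warnings.warn(f"{path} is empty; no contours read", stacklevel=2)
        return []
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; no contours read", stacklevel=2)
        return []
    required = {"contour_id", "point_index", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x_um", "y_um"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if bad.size:
            line = int(bad[0]) + header_line + 2  # 1-based, after header
            raise ValueError(f"{path}: malformed value in column {col} at line {line}")

    contours = []
    for cid, sub in df.groupby("contour_id", sort=False):
        order = sub["point_index"].to_numpy()
        if np.any(np.diff(order) <= 0):
            raise ValueError(f"{path}: non-monotone point_index in contour {cid!r}")
        pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        if y_down:
            pts[:, 1] = -pts[:, 1]
        orientation = "unknown"
        if "orientation" in sub.columns:
            orientation = str(sub["orientation"].iloc[0])
        contours.append(Contour(points=pts, contour_id=str(cid), orientation=orientation))
    return contours


def write_contours(path, contours: list[Contour], coordinates: str = "y_up") -> None:
    """Write contours to the long-format CSV dialect (full float precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# coordinates: {coordinates}\n")
        w = csv.writer(fh)
        w.writerow(["contour_id", "point_index", "x_um", "y_um", "orientation"])
        for c in contours:
            pts = c.points if coordinates == "y_up" else c.points * [1.0, -1.0]
            for i, (x, y) in enumerate(pts):
                w.writerow([c.contour_id, i, repr(float(x)), repr(float(y)), c.orientation])


# ---------------------------------------------------------------------------
# primary measures
# ---------------------------------------------------------------------------

def read_measures(path) -> list[SamMeasures]:
    """Read a primary-measures table (line_id, replicate, height_um, radius_um)."""
    df = pd.read_csv(path)
    required = {"line_id", "replicate", "height_um", "radius_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SamMeasures(str(r.line_id), str(r.replicate), float(r.height_um), float(r.radius_um))
        for r in df.itertuples()
    ]


def write_measures(path, measures: list[SamMeasures]) -> None:
    pd.DataFrame(
        [(m.line_id, m.replicate, m.height, m.radius) for m in measures],
        columns=["line_id", "replicate", "height_um", "radius_um"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# R/qtl-style cross files
# ---------------------------------------------------------------------------

def write_cross(path, cross: CrossPopulation) -> None:
    """Write a cross in the R/qtl csv dialect (phenotypes first, then genotypes)."""
    path = Path(path)
    pheno_cols = list(cross.phenotypes.columns)
    marker_names, chrom_row, pos_row = [], [], []
    for ch in cross.map.chromosomes:
        for name, pos in zip(cross.map.marker_names[ch], cross.map.positions[ch]):
            marker_names.append(name)
            chrom_row.append(ch)
            pos_row.append(repr(float(pos)))
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([*pheno_cols, "id", *marker_names])
        w.writerow([""] * (len(pheno_cols) + 1) + chrom_row)
        w.writerow([""] * (len(pheno_cols) + 1) + pos_row)
        for i, line_id in enumerate(cross.phenotypes.index):
            phenos = [repr(float(v)) if np.isfinite(v) else "-"
                      for v in cross.phenotypes.loc[line_id, pheno_cols]]
            genos = [GENO_LETTERS[int(g)] for g in cross.genotypes[i]]
            w.writerow([*phenos, str(line_id), *genos])


def read_cross(path) -> CrossPopulation:
    """Read an R/qtl-dialect cross CSV; genotype letters A/H/B, '-' missing."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: cross file needs 3 header rows plus data")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    if not (len(header) == len(chrom_row) == len(pos_row)):
        raise ValueError(
            f"{path}: header rows disagree in length "
            f"({len(header)}, {len(chrom_row)}, {len(pos_row)})"
        )
    # phenotype columns are those with a blank chromosome entry
    n_pheno = 0
    while n_pheno < len(chrom_row) and chrom_row[n_pheno] == "":
        n_pheno += 1
    pheno_cols = header[:n_pheno]
    marker_names_flat = header[n_pheno:]
    chroms_flat = chrom_row[n_pheno:]
    pos_flat = [float(p) for p in pos_row[n_pheno:]]
    if not marker_names_flat:
        raise ValueError(f"{path}: no marker columns found")

    chromosomes: list[str] = []
    marker_names: dict[str, list[str]] = {}
    positions: dict[str, list[float]] = {}
    for name, ch, pos in zip(marker_names_flat, chroms_flat, pos_flat):
        if ch not in marker_names:
            chromosomes.append(ch)
            marker_names[ch] = []
            positions[ch] = []
        marker_names[ch].append(name)
        positions[ch].append(pos)

    id_col = pheno_cols.index("id") if "id" in pheno_cols else None
    pheno_data: list[list[float]] = []
    line_ids: list[str] = []
    geno_rows = []
    for ln, row in enumerate(rows[3:], start=4):
        if not row:
            continue
        if len(row) != len(header):
            raise ValueError(f"{path}: line {ln} has {len(row)} fields, expected {len(header)}")
        phenos = row[:n_pheno]
        if id_col is not None:
            line_ids.append(phenos[id_col])
        else:
            line_ids.append(str(len(line_ids) + 1))
        pheno_data.append(
            [float(v) if v not in ("-", "", "NA") else np.nan
             for j, v in enumerate(phenos) if j != id_col]
        )
        geno = []
        for k, letter in enumerate(row[n_pheno:]):
            if letter not in LETTER_GENO:
                raise ValueError(
                    f"{path}: unknown genotype {letter!r} at line {ln}, "
                    f"marker {marker_names_flat[k]!r}"
                )
            geno.append(LETTER_GENO[letter])
        geno_rows.append(geno)

    gmap = GeneticMap(
        chromosomes=chromosomes,
        marker_names=marker_names,
        positions={ch: np.asarray(p) for ch, p in positions.items()},
    )
    pheno_df = pd.DataFrame(
        pheno_data,
        columns=[c for j, c in enumerate(pheno_cols) if j != id_col],
        index=pd.Index(line_ids, name="line_id"),
    )
    return CrossPopulation(map=gmap, genotypes=np.asarray(geno_rows, dtype=np.int8),
                           phenotypes=pheno_df)


# ---------------------------------------------------------------------------
# scan outputs
# ---------------------------------------------------------------------------

def write_scan(path, scan: QtlScanResult) -> None:
    """Scan table as TSV (chr, pos_cM, marker, lod)."""
    scan.table[["chr", "pos_cM", "marker", "lod"]].to_csv(path, sep="\t", index=False)


def write_intervals(path, scans: list[QtlScanResult]) -> None:
    """All Bayes intervals of the given scans as one TSV."""
    rows = [
        (s.trait, iv.chromosome, iv.lower, iv.peak, iv.upper, iv.coverage)
        for s in scans
        for iv in s.intervals
    ]
    pd.DataFrame(
        rows, columns=["trait", "chr", "lower_cM", "peak_cM", "upper_cM", "coverage"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written by every CLI run."""

    command: str
    seed: int | None
    config: dict = dc_field(default_factory=dict)
    inputs: dict[str, str] = dc_field(default_factory=dict)
    outputs: list[str] = dc_field(default_factory=list)
    started: str = ""
    finished: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def write(self, path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
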