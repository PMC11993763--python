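"""Readers and writers for the file formats the pipeline touches.

Conventions used throughout the package:

* Coordinates are decimal degrees on the WGS84 sphere.
* Grids use a lower-left origin; row 0 of the in-memory array is the
  *southernmost* row.  ESRI ASCII files store the top row first, so arrays
  are flipped on read/write.
* SNP positions are 1-based (VCF convention); gene intervals are 0-based
  half-open (BED convention).
* The missing-genotype sentinel is ``MISSING`` (a reserved negative code);
  every downstream statistic handles it with pairwise/complete-case logic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("lineagescape")

#: Reserved sentinel for a missing diploid genotype call.
MISSING: int = -9

#: Names of the 19 standard bioclimatic summary variables.
BIOCLIM_VARS: tuple[str, ...] = tuple(f"BIO{i}" for i in range(1, 20))

#: 2.5 arc-minutes in decimal degrees.
ARCMIN_2_5: float = 2.5 / 60.0


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class EmptyResultError(ValueError):
    """A filter or query removed every record."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for ``n_samples`` individuals.

    ``calls`` is an ``n_samples x n_snps`` integer array of alternate-allele
    counts (0, 1, 2) with :data:`MISSING` for no-calls.
    """

    samples: list[str]
    snps: list[tuple[str, int, str]]  # (chrom, 1-based pos, id)
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes {bad}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        last: dict[str, int] = {}
        for chrom, pos, _ in self.snps:
            if chrom in last and pos <= last[chrom]:
                raise ValueError(
                    f"positions not strictly increasing on {chrom} at {pos}"
                )
            last[chrom] = pos

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s[2] for s in self.snps]

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the SNP columns in ``index`` (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in index],
            calls=self.calls[:, index],
        )


@dataclass
class OccurrenceSet:
    """Georeferenced presence records, optionally pooled to a grid."""

    records: pd.DataFrame  # columns: lon, lat, season, group
    grid_resolution: float | None = None  # arc-minutes, set after pooling

    def __post_init__(self) -> None:
        need = {"lon", "lat", "season", "group"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns {sorted(missing)}")
        lon = self.records["lon"].to_numpy(float)
        lat = self.records["lat"].to_numpy(float)
        bad = np.flatnonzero((np.abs(lon) > 180) | (np.abs(lat) > 90))
        if bad.size:
            raise ValueError(
                f"coordinates out of range in rows {bad.tolist()[:20]}"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ClimateGrid:
    """A stack of co-registered raster layers for one climate scenario.

    All layers share origin, resolution and shape.  Nodata cells are stored
    as NaN and must coincide across layers.
    """

    origin: tuple[float, float]  # (lon, lat) of the lower-left corner
    resolution: float  # degrees per cell
    shape: tuple[int, int]  # (n_rows, n_cols); row 0 = southernmost
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    scenario: str = "current"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != tuple(self.shape):
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid shape {self.shape}"
                )
            self.layers[name] = arr

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != tuple(self.shape):
            raise ValueError(f"layer shape {values.shape} != {self.shape}")
        self.layers[name] = values

    def finite_mask(self) -> np.ndarray:
        """Boolean mask of cells finite in every layer."""
        mask = np.ones(self.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-center coordinates, shape = grid shape."""
        rows = np.arange(self.shape[0])
        cols = np.arange(self.shape[1])
        lat = self.origin[1] + (rows + 0.5) * self.resolution
        lon = self.origin[0] + (cols + 0.5) * self.resolution
        return np.meshgrid(lon, lat)

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing the given coordinates."""
        col = np.floor((np.asarray(lon) - self.origin[0]) / self.resolution).astype(int)
        row = np.floor((np.asarray(lat) - self.origin[1]) / self.resolution).astype(int)
        return row, col

    def copy(self, scenario: str | None = None) -> "ClimateGrid":
        return ClimateGrid(
            origin=self.origin,
            resolution=self.resolution,
            shape=self.shape,
            layers={k: v.copy() for k, v in self.layers.items()},
            scenario=scenario if scenario is not None else self.scenario,
            nodata=self.nodata,
        )


@dataclass
class GeneIntervalTable:
    """Gene intervals in BED convention (0-based, half-open)."""

    intervals: list[tuple[str, int, int, str]]  # (chrom, start, end, gene_id)

    def __post_init__(self) -> None:
        for chrom, start, end, gid in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end} ({gid})")
        self.intervals = sorted(self.intervals, key=lambda t: (t[0], t[1], t[2]))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, min_maf: float = 0.05,
             max_missing: float = 0.2) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a 0/1/2 genotype matrix.

    Sites with minor-allele frequency below ``min_maf`` (computed on
    non-missing calls) or with a missing-call fraction above ``max_missing``
    are removed.  Raises :class:`EmptyResultError` if no site survives.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    snps: list[tuple[str, int, str]] = []
    cols: list[np.ndarray] = []
    n_seen = n_maf = n_miss = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        n_seen += 1
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        codes = np.full(n, MISSING, dtype=np.int16)
        codes[gt == 0] = 0
        codes[gt == 1] = 1
        codes[gt == 3] = 2
        obs = codes != MISSING
        n_obs = int(obs.sum())
        if n_obs == 0 or (n - n_obs) / n > max_missing:
            n_miss += 1
            continue
        p = codes[obs].sum() / (2 * n_obs)
        if min(p, 1 - p) < min_maf:
            n_maf += 1
            continue
        vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        snps.append((var.CHROM, var.POS, vid))
        cols.append(codes)
    logger.info(
        "read_vcf: %d biallelic SNPs scanned, %d failed MAF>=%.3g, "
        "%d failed missingness<=%.3g, %d retained",
        n_seen, n_maf, min_maf, n_miss, max_missing, len(snps),
    )
    if not snps:
        raise EmptyResultError(f"no sites in {path} survive the filters")
    calls = np.stack(cols, axis=1)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(c for c, _, _ in g.snps)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, (chrom, pos, vid) in enumerate(g.snps):
            row = "\t".join(gt_str[int(c)] for c in g.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tG\t.\t.\t.\tGT\t{row}\n")


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_HDR_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, layer_name: str = "layer",
                    scenario: str = "current") -> ClimateGrid:
    """Read one ESRI ASCII grid file into a single-layer :class:`ClimateGrid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HDR_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        for key in _HDR_KEYS:
            if key not in header:
                raise FormatError(f"{path}: missing header field {key!r}")
        nodata = header.get("nodata_value", -9999.0)
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: data shape {data.shape} != header ({nrows}, {ncols})"
        )
    values = np.flipud(data).copy()  # file stores north first; row 0 = south
    values[values == nodata] = np.nan
    grid = ClimateGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        resolution=header["cellsize"],
        shape=(nrows, ncols),
        scenario=scenario,
        nodata=nodata,
    )
    grid.add_layer(layer_name, values)
    return grid


def write_ascii_grid(grid: ClimateGrid, layer: str, path: str | Path) -> None:
    """Write one layer of a :class:`ClimateGrid` as an ESRI ASCII file.

    Finite values round-trip bit-identically (written with ``repr``
    precision); NaN cells are written as the nodata sentinel.
    """
    arr = grid.layers[layer]
    out = np.flipud(arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {grid.origin[1]!r}\n")
        fh.write(f"cellsize {grid.resolution!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in out:
            fh.write(" ".join(
                repr(grid.nodata) if not np.isfinite(v) else repr(float(v))
                for v in row
            ) + "\n")


def read_grid_stack(directory: str | Path, layer_names: list[str],
                    scenario: str = "current") -> ClimateGrid:
    """Read ``<directory>/<name>.asc`` for each name into one grid stack."""
    directory = Path(directory)
    grid: ClimateGrid | None = None
    for name in layer_names:
        g = read_ascii_grid(directory / f"{name}.asc", name, scenario)
        if grid is None:
            grid = g
        else:
            if (g.origin != grid.origin or g.resolution != grid.resolution
                    or g.shape != grid.shape):
                raise FormatError(f"layer {name} georeference mismatch")
            grid.add_layer(name, g.layers[name])
    assert grid is not None
    return grid


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a CSV of occurrence records (lon, lat, season, group)."""
    df = pd.read_csv(path)
    if df.empty and set(df.columns) >= {"lon", "lat", "season", "group"}:
        return OccurrenceSet(records=df)
    if df.empty:
        return OccurrenceSet(records=pd.DataFrame(
            columns=["lon", "lat", "season", "group"]))
    return OccurrenceSet(records=df)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.records.to_csv(path, index=False)


def pool_to_grid(occ: OccurrenceSet, resolution_arcmin: float = 2.5,
                 origin: tuple[float, float] = (-180.0, -90.0)) -> OccurrenceSet:
    """Pool occurrences to one record per (grid cell, season, group).

    Cell assignment is ``floor((coord - origin) / cellsize)``; the pooled
    record carries the cell-center coordinates.
    """
    if len(occ) == 0:
        return OccurrenceSet(records=occ.records.copy(),
                             grid_resolution=resolution_arcmin)
    cell = resolution_arcmin / 60.0
    df = occ.records.copy()
    df["_col"] = np.floor((df["lon"].to_numpy(float) - origin[0]) / cell).astype(int)
    df["_row"] = np.floor((df["lat"].to_numpy(float) - origin[1]) / cell).astype(int)
    pooled = (
        df.groupby(["_row", "_col", "season", "group"], as_index=False)
        .first()
    )
    pooled["lon"] = origin[0] + (pooled["_col"] + 0.5) * cell
    pooled["lat"] = origin[1] + (pooled["_row"] + 0.5) * cell
    pooled = pooled.drop(columns=["_row", "_col"]).reset_index(drop=True)
    logger.info("pool_to_grid: %d records pooled to %d cells", len(df), len(pooled))
    return OccurrenceSet(records=pooled[occ.records.columns.tolist()],
                         grid_resolution=resolution_arcmin)


# ---------------------------------------------------------------------------
# Gene intervals / SNP annotation
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GeneIntervalTable:
    """Read gene intervals from a BED file (first 4 columns used)."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i + 1}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"feature{i}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return GeneIntervalTable(intervals=rows)


def write_bed(genes: GeneIntervalTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, gid in genes.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{gid}\n")


def annotate_snps(snps: list[tuple[str, int, str]],
                  genes: GeneIntervalTable) -> pd.DataFrame:
    """Assign each SNP the gene interval(s) containing it.

    A SNP at 1-based position ``p`` hits the 0-based half-open interval
    ``[s, e)`` iff ``s <= p - 1 < e``.  Overlapping hits are all reported
    (semicolon-joined) and flagged ambiguous.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, gid in genes.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gid)
    out = []
    n_nochrom = 0
    for chrom, pos, sid in snps:
        tree = trees.get(chrom)
        if tree is None:
            n_nochrom += 1
            out.append((sid, chrom, pos, None, False))
            continue
        hits = sorted(iv.data for iv in tree.at(pos - 1))
        gene = ";".join(hits) if hits else None
        out.append((sid, chrom, pos, gene, len(hits) > 1))
    if n_nochrom:
        logger.info("annotate_snps: %d SNPs on chromosomes absent from the "
                    "interval table", n_nochrom)
    return pd.DataFrame(out, columns=["snp_id", "chrom", "pos", "gene_id",
                                      "ambiguous"])


# ---------------------------------------------------------------------------
# Locality table
# ---------------------------------------------------------------------------

def read_localities(path: str | Path) -> pd.DataFrame:
    """Read a locality table: deme, lon, lat, lineage, BIO1..BIO19."""
    df = pd.read_csv(path)
    need = {"deme", "lon", "lat", "lineage"} | set(BIOCLIM_VARS)
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"locality table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Default configuration: every pipeline threshold has a key here.
DEFAULT_CONFIG: dict[str, object] = {
    "seed": 0,
    "min_maf": 0.05,            # minimum allele frequency filter
    "max_missing": 0.2,         # per-site missing-call fraction
    "min_deme_size": 3,         # demes below this are dropped from PhiST/RDA
    "n_climate_pcs": 3,         # climate PCs retained as RDA predictors
    "rda_sd_mult": 3.0,         # +-k s.d. loading cutoff for candidates
    "outlier_fdr": 0.05,        # BH q-value threshold for both scans
    "outlier_trim": 0.05,       # per-tail trim for the FST chi-square null
    "n_perm": 9999,             # Mantel / MRM / RDA-ANOVA permutations
    "equivalency_n_perm": 1000, # niche equivalency permutations
    "sign_test_B": 1000,        # habitat sign-test bootstrap resamples
    "density_grid_R": 100,      # environmental-space density grid size
    "buffer_km": 1500.0,        # availability buffer around occurrences
    "grid_resolution_arcmin": 2.5,
    "n_offset_predictors": 5,   # variables kept for the enriched RDA
    "offset_corr_threshold": 0.7,
    "range_threshold": 0.5,     # suitability cutoff for binary ranges
    "confound_filter": True,
    "pca_scale": True,          # scale genotypes by sqrt(p(1-p)) in PCA
}


def read_config(path: str | Path) -> dict[str, object]:
    """Parse a flat ``key = value`` config file over the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{i + 1}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            cfg[key] = _coerce(raw)
    return cfg


def _coerce(raw: str) -> object:
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
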