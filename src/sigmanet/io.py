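"""Genotype and coordinate I/O, preprocessing, and the binary dataset store.

The network consumes a genotype matrix of minor-allele counts together with a
table of planar sample coordinates.  This module reads those from standard
formats (VCF + delimited text), polarizes genotypes to the minor allele,
projects latitude/longitude onto a local flat plane, and provides the
fixed-layout binary container used to stream training datasets.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptyInputError,
    InsufficientSNPsError,
    InvalidParameterError,
    SigmanetError,
    StoreIntegrityError,
    StoreVersionError,
    UnsupportedPloidyError,
)

logger = logging.getLogger(__name__)

#: mean Earth radius, kilometres (IUGG)
EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Minor-allele-count matrix with genomic positions.

    Unphased: one row per individual, entries in {0, 1, 2}.
    Phased: two adjacent haplotype rows per individual, entries in {0, 1}.
    Columns (SNPs) are ordered by genomic position.
    """

    counts: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    phased: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.counts.ndim != 2:
            raise InvalidParameterError("counts must be 2-D (samples x SNPs)")
        if self.counts.shape[1] != len(self.positions):
            raise InvalidParameterError("positions length must equal SNP count")
        maxval = 1 if self.phased else 2
        if self.counts.size and (self.counts.min() < 0 or self.counts.max() > maxval):
            raise InvalidParameterError(
                f"entries must lie in [0, {maxval}] for phased={self.phased}"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise InvalidParameterError("positions must be strictly increasing")
        rows_per_ind = 2 if self.phased else 1
        if self.counts.shape[0] != rows_per_ind * len(self.sample_ids):
            raise AlignmentError(
                f"{self.counts.shape[0]} genotype rows for {len(self.sample_ids)} "
                f"samples (phased={self.phased})"
            )

    @property
    def n(self) -> int:
        """Number of individuals."""
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        """Number of SNPs."""
        return self.counts.shape[1]

    def rows_for(self, i: int) -> np.ndarray:
        """Genotype rows of individual ``i``: shape (1, m) unphased, (2, m) phased."""
        if self.phased:
            return self.counts[2 * i : 2 * i + 2]
        return self.counts[i : i + 1]


@dataclass
class LocationsTable:
    """Planar sample coordinates, aligned row-for-row with a GenotypeMatrix."""

    sample_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    raw_lat: np.ndarray | None = None
    raw_long: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.sample_ids) == len(self.x) == len(self.y)):
            raise AlignmentError("sample_ids, x and y must have equal length")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of planar coordinates."""
        return np.column_stack([self.x, self.y])

    def subset(self, idx) -> "LocationsTable":
        idx = np.asarray(idx)
        return LocationsTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            x=self.x[idx],
            y=self.y[idx],
            raw_lat=None if self.raw_lat is None else np.asarray(self.raw_lat)[idx],
            raw_long=None if self.raw_long is None else np.asarray(self.raw_long)[idx],
        )


# ---------------------------------------------------------------------------
# VCF / locations ingestion
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, phased: bool = False, max_missing: float = 0.1) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a minor-allele-count matrix.

    Multiallelic or non-SNP records are skipped with a warning.  Sites with a
    missing-genotype fraction above ``max_missing`` are dropped; remaining
    missing entries are imputed to the per-site mean count rounded to the
    nearest integer (the network requires dense input).  Polarization: the
    allele with frequency < 0.5 is counted; at exactly 0.5 the ALT allele is
    counted (REF stays the reference allele).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    if n == 0:
        raise EmptyInputError(f"no samples in {path}")

    cols: list[np.ndarray] = []
    positions: list[int] = []
    n_skipped_multi = 0
    n_skipped_missing = 0
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped_multi += 1
            continue
        # genotypes: list of [allele0, allele1, phased_flag] per sample
        gts = np.array([g[:2] for g in var.genotypes], dtype=np.int32)
        if gts.shape != (n, 2):
            raise UnsupportedPloidyError(
                f"site {var.CHROM}:{var.POS} is not diploid for all samples"
            )
        missing = (gts < 0).any(axis=1)
        if missing.mean() > max_missing:
            n_skipped_missing += 1
            continue

        if phased:
            hap = gts.astype(np.float64).reshape(-1)  # 2n haplotype entries
            hap[np.repeat(missing, 2)] = np.nan
            alt_freq = np.nanmean(hap)
            if alt_freq > 0.5:
                hap = 1.0 - hap  # count REF instead
            fill = np.nanmean(hap)
            if np.isnan(hap).any():
                n_imputed += int(np.isnan(hap).sum())
                hap[np.isnan(hap)] = round(fill)
            col = hap
        else:
            dos = gts.clip(min=0).sum(axis=1).astype(np.float64)
            dos[missing] = np.nan
            alt_freq = np.nanmean(dos) / 2.0
            if alt_freq > 0.5:
                dos = 2.0 - dos
            fill = np.nanmean(dos)
            if np.isnan(dos).any():
                n_imputed += int(np.isnan(dos).sum())
                dos[np.isnan(dos)] = round(fill)
            col = dos
        cols.append(col.astype(np.int8))
        positions.append(var.POS)

    if n_skipped_multi:
        logger.warning("skipped %d multiallelic/non-SNP records", n_skipped_multi)
    if n_skipped_missing:
        logger.warning("skipped %d sites with missingness > %.0f%%",
                       n_skipped_missing, 100 * max_missing)
    if n_imputed:
        logger.warning("imputed %d missing genotype entries", n_imputed)
    if not cols:
        raise EmptyInputError(f"no biallelic SNPs in {path}")

    counts = np.column_stack(cols)
    return GenotypeMatrix(counts=counts, positions=np.array(positions),
                          sample_ids=sample_ids, phased=phased)


def read_locations(path: str | Path, vcf_sample_ids: list[str] | None = None) -> LocationsTable:
    """Read a delimited table of per-sample coordinates.

    Expects two numeric columns (x/longitude then y/latitude order as written)
    plus an optional identifier column.  With identifiers present and
    ``vcf_sample_ids`` given, rows are reordered to VCF sample order; without
    identifiers, row order is taken as-is and the row count must match.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    # locate the id column (non-numeric), if any
    numeric = [pd.to_numeric(df[c], errors="coerce").notna().all() for c in df.columns]
    id_cols = [c for c, isnum in zip(df.columns, numeric) if not isnum]
    num_cols = [c for c, isnum in zip(df.columns, numeric) if isnum]
    if len(num_cols) < 2:
        raise SigmanetError(f"{path}: need two numeric coordinate columns")
    if len(id_cols) > 1:
        raise SigmanetError(f"{path}: more than one non-numeric column")

    if id_cols:
        ids = df[id_cols[0]].astype(str).tolist()
    else:
        ids = [str(i) for i in range(len(df))]

    xs = pd.to_numeric(df[num_cols[0]]).to_numpy(dtype=float)
    ys = pd.to_numeric(df[num_cols[1]]).to_numpy(dtype=float)

    if vcf_sample_ids is not None:
        if len(df) != len(vcf_sample_ids):
            raise AlignmentError(
                f"{len(df)} coordinate rows for {len(vcf_sample_ids)} VCF samples"
            )
        if id_cols:
            order = {s: i for i, s in enumerate(ids)}
            missing = [s for s in vcf_sample_ids if s not in order]
            if missing:
                raise AlignmentError(f"coordinate table lacks samples: {missing}")
            perm = [order[s] for s in vcf_sample_ids]
            ids = list(vcf_sample_ids)
            xs, ys = xs[perm], ys[perm]
    return LocationsTable(sample_ids=ids, x=xs, y=ys)


def project_coordinates(lat, long, reference: tuple[float, float]) -> tuple:
    """Project latitude/longitude (degrees) onto a local flat plane.

    Equirectangular projection about the reference point ``(lat0, long0)``:
    ``x = R cos(lat0) (long - long0)``, ``y = R (lat - lat0)`` with angles in
    radians and R the mean Earth radius, so outputs are kilometres.  Accurate
    to well under 1% for clusters narrower than ~100 km at mid-latitudes,
    which covers the spatial scale of dispersal studies.
    """
    lat = np.asarray(lat, dtype=float)
    long = np.asarray(long, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise InvalidParameterError("latitude outside [-90, 90]")
    lat0, long0 = reference
    if abs(lat0) > 90:
        raise InvalidParameterError("reference latitude outside [-90, 90]")
    x = EARTH_RADIUS_KM * math.cos(math.radians(lat0)) * np.radians(long - long0)
    y = EARTH_RADIUS_KM * np.radians(lat - lat0)
    return x, y


def project_locations(ids, lat, long, reference=None) -> LocationsTable:
    """Project a set of lat/long samples; default reference is the centroid."""
    lat = np.asarray(lat, dtype=float)
    long = np.asarray(long, dtype=float)
    if reference is None:
        reference = (float(lat.mean()), float(long.mean()))
    x, y = project_coordinates(lat, long, reference)
    return LocationsTable(sample_ids=list(ids), x=x, y=y, raw_lat=lat, raw_long=long)


# ---------------------------------------------------------------------------
# Matrix utilities
# ---------------------------------------------------------------------------


def subsample_snps(g: GenotypeMatrix, m_target: int, rng_seed: int) -> GenotypeMatrix:
    """Uniform column subsample without replacement, genomic order preserved."""
    if m_target > g.m:
        raise InsufficientSNPsError(f"requested {m_target} SNPs but only {g.m} available")
    if m_target < 0:
        raise InvalidParameterError("m_target must be >= 0")
    rng = np.random.default_rng(rng_seed)
    keep = np.sort(rng.choice(g.m, size=m_target, replace=False))
    return GenotypeMatrix(
        counts=g.counts[:, keep],
        positions=g.positions[keep],
        sample_ids=list(g.sample_ids),
        phased=g.phased,
    )


def filter_mac(g: GenotypeMatrix, min_mac: int) -> GenotypeMatrix:
    """Drop SNP columns whose minor-allele count falls below ``min_mac``.

    With small samples a large share of segregating sites are singletons,
    which carry almost no information about pairwise relatedness; filtering
    them concentrates the information content of a fixed-size SNP panel.
    """
    if min_mac <= 0:
        return g
    # summing rows gives the minor-allele count in both encodings
    mac = g.counts.sum(axis=0, dtype=np.int64)
    keep = mac >= min_mac
    return GenotypeMatrix(counts=g.counts[:, keep], positions=g.positions[keep],
                         sample_ids=list(g.sample_ids), phased=g.phased)


def pair_distance(loc: LocationsTable, i: int, j: int) -> float:
    """Euclidean distance between samples i and j on the planar coordinates."""
    n = loc.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"sample index out of range (n={n})")
    return float(math.hypot(loc.x[i] - loc.x[j], loc.y[i] - loc.y[j]))


def pairwise_distances(loc: LocationsTable, pairs) -> np.ndarray:
    """Vector of Euclidean distances for an iterable of (i, j) pairs."""
    pairs = np.asarray(list(pairs))
    dx = loc.x[pairs[:, 0]] - loc.x[pairs[:, 1]]
    dy = loc.y[pairs[:, 0]] - loc.y[pairs[:, 1]]
    return np.hypot(dx, dy)


# ---------------------------------------------------------------------------
# Binary dataset store
# ---------------------------------------------------------------------------

_MAGIC = b"SGMASTORE\x00"
_VERSION = 1
# header: magic(10s) version(<I) n(<I) m(<I) count(<I) phased(B) pad(5x)
_HEADER = struct.Struct("<10sIIIIB5x")


@dataclass
class DatasetStore:
    """On-disk container of (genotypes, locations, sigma) training records.

    Layout (all little-endian): a fixed header (magic, format version, n, m,
    record count, phased flag) followed by ``count`` fixed-width records.
    Each record is: sigma_true (f8), sigma_f (f8), genotype counts
    (rows*m int8 row-major, rows = n or 2n), coordinates (n*2 f8).
    Fixed width makes the store seekable and the round trip lossless.
    """

    path: Path
    n: int
    m: int
    count: int
    phased: bool

    @property
    def rows(self) -> int:
        return 2 * self.n if self.phased else self.n

    @property
    def record_nbytes(self) -> int:
        return 16 + self.rows * self.m + self.n * 2 * 8

    def record(self, k: int) -> tuple[GenotypeMatrix, LocationsTable, float, float]:
        """Read record ``k``: (genotypes, locations, sigma_true, sigma_f)."""
        if not (0 <= k < self.count):
            raise IndexError(f"record {k} out of range (count={self.count})")
        with open(self.path, "rb") as f:
            f.seek(_HEADER.size + k * self.record_nbytes)
            buf = f.read(self.record_nbytes)
        if len(buf) != self.record_nbytes:
            raise StoreIntegrityError("truncated record", offset=_HEADER.size + k * self.record_nbytes)
        sigma_true, sigma_f = struct.unpack_from("<dd", buf, 0)
        off = 16
        counts = np.frombuffer(buf, dtype=np.int8, count=self.rows * self.m, offset=off)
        counts = counts.reshape(self.rows, self.m).copy()
        off += self.rows * self.m
        coords = np.frombuffer(buf, dtype="<f8", count=self.n * 2, offset=off).reshape(self.n, 2)
        ids = [str(i) for i in range(self.n)]
        g = GenotypeMatrix(counts=counts, positions=np.arange(1, self.m + 1),
                           sample_ids=ids, phased=self.phased)
        loc = LocationsTable(sample_ids=ids, x=coords[:, 0].copy(), y=coords[:, 1].copy())
        return g, loc, sigma_true, sigma_f

    def __len__(self) -> int:
        return self.count

    def __iter__(self):
        for k in range(self.count):
            yield self.record(k)

    def sigmas(self) -> np.ndarray:
        """True effective sigma of every record (fast header-strided read)."""
        out = np.empty(self.count)
        with open(self.path, "rb") as f:
            for k in range(self.count):
                f.seek(_HEADER.size + k * self.record_nbytes)
                out[k] = struct.unpack("<d", f.read(8))[0]
        return out


def write_store(records, path: str | Path, phased: bool = False) -> DatasetStore:
    """Write an iterable of (GenotypeMatrix, LocationsTable, sigma_true, sigma_f)
    records (homogeneous n and m) to a binary store at ``path``."""
    path = Path(path)
    records = list(records)
    n = m = 0
    if records:
        g0 = records[0][0]
        n, m = g0.n, g0.m
        phased = g0.phased
    with open(path, "wb") as f:
        f.write(_HEADER.pack(_MAGIC, _VERSION, n, m, len(records), int(phased)))
        for rec in records:
            g, loc, sigma_true = rec[0], rec[1], float(rec[2])
            sigma_f = float(rec[3]) if len(rec) > 3 else float("nan")
            if g.n != n or g.m != m or g.phased != phased:
                raise InvalidParameterError(
                    f"inhomogeneous record: n={g.n}, m={g.m}, phased={g.phased} "
                    f"(store has n={n}, m={m}, phased={phased})"
                )
            if loc.n != g.n:
                raise AlignmentError("locations row count != genotype sample count")
            f.write(struct.pack("<dd", sigma_true, sigma_f))
            f.write(np.ascontiguousarray(g.counts, dtype=np.int8).tobytes())
            f.write(np.ascontiguousarray(loc.coords, dtype="<f8").tobytes())
    return read_store(path)


def read_store(path: str | Path) -> DatasetStore:
    """Open a binary dataset store, validating header and file size."""
    path = Path(path)
    size = path.stat().st_size
    if size < _HEADER.size:
        raise StoreIntegrityError("file smaller than header", offset=size)
    with open(path, "rb") as f:
        magic, version, n, m, count, phased = _HEADER.unpack(f.read(_HEADER.size))
    if magic != _MAGIC:
        raise StoreIntegrityError("bad magic bytes", offset=0)
    if version != _VERSION:
        raise StoreVersionError(f"store version {version}, expected {_VERSION}")
    store = DatasetStore(path=path, n=n, m=m, count=count, phased=bool(phased))
    expected = _HEADER.size + count * store.record_nbytes
    if size != expected:
        raise StoreIntegrityError(
            f"file size {size} != expected {expected}", offset=min(size, expected)
        )
    return store
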