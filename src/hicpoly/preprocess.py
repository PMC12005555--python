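"""Contact-map I/O and preprocessing.

Reads dense contact matrices, extracts fixed-size genomic regions,
normalizes maps, computes genomic-distance normalized maps, compartment
PC1 vectors, contact-probability scaling curves, and the 2x coarsening
used by the graph neural network.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ContactMap",
    "NormalizedMap",
    "ScalingCurve",
    "load_contact_map",
    "save_contact_map",
    "extract_regions",
    "normalize_map",
    "distance_normalize",
    "compartment_pc1",
    "coarsen_2x",
    "contact_scaling",
]

_SYM_ATOL = 1e-9
_BINARY_MAGIC = b"HPCM"

#: default region size in megabases (512 bins at 50 kb)
DEFAULT_REGION_MB = 25.6
#: target mean contact probability for the first off-diagonal
OFFDIAG_TARGET = 0.1


@dataclass
class ContactMap:
    """Symmetric nonnegative contact matrix with genomic metadata.

    Parameters
    ----------
    values
        ``m x m`` symmetric matrix of nonnegative contact counts or
        probabilities.
    resolution_bp
        Bin size in base pairs (50000 by default).
    chrom
        Chromosome label.
    start_bp
        Genomic coordinate of the first bin.
    is_normalized
        True once :func:`normalize_map` has been applied.
    """

    values: np.ndarray
    resolution_bp: int = 50_000
    chrom: str = "chr?"
    start_bp: int = 0
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"contact map must be square, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("contact map entries must be nonnegative")
        if not np.allclose(self.values, self.values.T, atol=_SYM_ATOL, rtol=0):
            raise ValueError("contact map must be symmetric (atol 1e-9)")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def copy_with(self, values: np.ndarray, **kw) -> "ContactMap":
        return replace(self, values=values, **kw)


@dataclass
class NormalizedMap:
    """Genomic-distance normalized contact map (observed over expected).

    Each entry of the parent map is divided by the mean of its diagonal;
    diagonals with zero mean are left at 0.
    """

    values: np.ndarray
    resolution_bp: int = 50_000
    chrom: str = "chr?"
    start_bp: int = 0

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass
class ScalingCurve:
    """Contact probability as a function of genomic separation (in bins)."""

    probabilities: np.ndarray
    resolution_bp: int = 50_000

    def to_tsv(self, path: str | Path) -> None:
        sep_bp = np.arange(len(self.probabilities)) * self.resolution_bp
        np.savetxt(
            path,
            np.column_stack([sep_bp, self.probabilities]),
            delimiter="\t",
            header="separation_bp\tmean_contact",
            comments="",
        )


# ---------------------------------------------------------------------------
# I/O


def _symmetrize_checked(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    if np.any(values < 0):
        raise ValueError("matrix has negative entries")
    scale = max(np.abs(values).max(), 1.0)
    asym = np.abs(values - values.T).max() / scale
    if asym > 1e-6:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds relative tolerance 1e-6")
    return 0.5 * (values + values.T)


def load_contact_map(path: str | Path, format: str = "dense_text") -> ContactMap:
    """Read a contact map from disk.

    ``dense_text`` is a whitespace-delimited square matrix (one row per
    line); ``dense_binary`` is the small binary container written by
    :func:`save_contact_map`; ``hic_container`` dispatches to ``cooler``
    when available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_text":
        values = np.loadtxt(path, dtype=float, ndmin=2)
        return ContactMap(_symmetrize_checked(values))
    if format == "dense_binary":
        return _read_binary(path)
    if format == "hic_container":
        return _read_cooler(path)
    raise ValueError(f"unknown contact-map format: {format!r}")


def save_contact_map(cmap: ContactMap, path: str | Path, format: str = "dense_text") -> None:
    path = Path(path)
    if format == "dense_text":
        np.savetxt(path, cmap.values, fmt="%.17g")
    elif format == "dense_binary":
        _write_binary(cmap, path)
    else:
        raise ValueError(f"unknown contact-map format: {format!r}")


def _write_binary(cmap: ContactMap, path: Path) -> None:
    chrom = cmap.chrom.encode()
    with open(path, "wb") as fh:
        fh.write(_BINARY_MAGIC)
        fh.write(struct.pack("<iqqi", cmap.m, cmap.resolution_bp, cmap.start_bp, len(chrom)))
        fh.write(chrom)
        fh.write(struct.pack("<?", cmap.is_normalized))
        fh.write(np.ascontiguousarray(cmap.values, dtype="<f8").tobytes())


def _read_binary(path: Path) -> ContactMap:
    with open(path, "rb") as fh:
        if fh.read(4) != _BINARY_MAGIC:
            raise ValueError(f"{path} is not a dense_binary contact map")
        m, resolution_bp, start_bp, clen = struct.unpack("<iqqi", fh.read(24))
        chrom = fh.read(clen).decode()
        (is_normalized,) = struct.unpack("<?", fh.read(1))
        values = np.frombuffer(fh.read(8 * m * m), dtype="<f8").reshape(m, m).copy()
    return ContactMap(
        _symmetrize_checked(values),
        resolution_bp=resolution_bp,
        chrom=chrom,
        start_bp=start_bp,
        is_normalized=is_normalized,
    )


def _read_cooler(path: Path) -> ContactMap:  # pragma: no cover - optional dependency
    try:
        import cooler
    except ImportError as exc:
        raise ImportError(
            "reading multi-resolution Hi-C containers requires the 'cooler' package"
        ) from exc
    clr = cooler.Cooler(str(path))
    values = clr.matrix(balance=False)[:]
    values = np.nan_to_num(np.asarray(values, dtype=float))
    chrom = clr.chromnames[0] if clr.chromnames else "chr?"
    return ContactMap(
        _symmetrize_checked(values), resolution_bp=int(clr.binsize), chrom=chrom
    )


# ---------------------------------------------------------------------------
# Region extraction and normalization


def extract_regions(chrom_map: ContactMap, region_mb: float = DEFAULT_REGION_MB) -> list[ContactMap]:
    """Partition a chromosomal map into consecutive fixed-size regions.

    Tiles non-overlapping windows of ``region_mb`` megabases starting at
    position 0; windows whose main diagonal contains a zero (centromeres,
    telomeres, unmappable bins) are discarded, as is a trailing partial
    window.
    """
    bins_per_region = int(round(region_mb * 1e6 / chrom_map.resolution_bp))
    if bins_per_region < 1:
        raise ValueError("region smaller than one bin")
    m = chrom_map.m
    diag = np.diag(chrom_map.values)
    regions: list[ContactMap] = []
    for start in range(0, m - bins_per_region + 1, bins_per_region):
        stop = start + bins_per_region
        if np.any(diag[start:stop] <= 0):
            continue
        sub = chrom_map.values[start:stop, start:stop].copy()
        regions.append(
            chrom_map.copy_with(
                sub, start_bp=chrom_map.start_bp + start * chrom_map.resolution_bp
            )
        )
    return regions


def normalize_map(H: ContactMap) -> ContactMap:
    """Scale so the first off-diagonal mean is 0.1, then set the diagonal to 1."""
    vals = H.values
    off = np.diagonal(vals, offset=1)
    mu = off.mean() if off.size else 0.0
    if mu <= 0:
        raise ValueError("first off-diagonal mean is zero; cannot normalize")
    out = vals * (OFFDIAG_TARGET / mu)
    np.fill_diagonal(out, 1.0)
    return H.copy_with(out, is_normalized=True)


def _diagonal_means(values: np.ndarray) -> np.ndarray:
    m = values.shape[0]
    return np.array([np.diagonal(values, offset=d).mean() for d in range(m)])


def distance_normalize(H: ContactMap | NormalizedMap) -> NormalizedMap:
    """Divide each entry by the mean of its diagonal (observed / expected).

    Diagonals with zero mean map to 0 so downstream eigendecompositions
    stay well-defined.
    """
    vals = np.asarray(H.values, dtype=float)
    m = vals.shape[0]
    means = _diagonal_means(vals)
    i, j = np.indices((m, m))
    denom = means[np.abs(i - j)]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, vals / np.where(denom > 0, denom, 1.0), 0.0)
    return NormalizedMap(
        out,
        resolution_bp=H.resolution_bp,
        chrom=getattr(H, "chrom", "chr?"),
        start_bp=getattr(H, "start_bp", 0),
    )


def compartment_pc1(Hn: NormalizedMap | ContactMap) -> np.ndarray:
    """First principal component score vector of the distance-normalized map.

    Computed on the column-mean-centered matrix via SVD; the returned
    vector is the first right-singular vector scaled by its singular
    value, with sign fixed so the largest-magnitude entry is positive.
    A constant (degenerate) input yields a zero vector with a warning.
    """
    vals = np.asarray(Hn.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite entries in normalized map")
    centered = vals - vals.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0, atol=1e-12):
        warnings.warn("degenerate (constant) map: PC1 direction undefined, returning zeros")
        return np.zeros(vals.shape[0])
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0] * s[0]
    peak = np.argmax(np.abs(pc1))
    if pc1[peak] < 0:
        pc1 = -pc1
    return pc1


def coarsen_2x(H50: ContactMap) -> ContactMap:
    """Coarsen by summing 2x2 blocks (50 kb -> 100 kb); conserves total mass."""
    m = H50.m
    if m % 2:
        raise ValueError(f"coarsen_2x requires even bin count, got m={m}")
    v = H50.values.reshape(m // 2, 2, m // 2, 2).sum(axis=(1, 3))
    return H50.copy_with(v, resolution_bp=H50.resolution_bp * 2)


def contact_scaling(H: ContactMap) -> ScalingCurve:
    """Mean contact frequency per genomic separation (one value per diagonal)."""
    return ScalingCurve(_diagonal_means(H.values), resolution_bp=H.resolution_bp)


def write_vector_tsv(vec: np.ndarray, path: str | Path, resolution_bp: int = 50_000) -> None:
    """Write a per-bin vector (e.g. PC1) as two-column TSV."""
    pos = np.arange(len(vec)) * resolution_bp
    np.savetxt(path, np.column_stack([pos, vec]), delimiter="\t", header="pos_bp\tvalue", comments="")
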