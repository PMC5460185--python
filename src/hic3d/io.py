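"""Readers, writers and the internal data model for matrices, tracks, segments and conformations.

On-disk formats (all plain text except the optional HDF5 matrix container):

* dense TSV contact matrix — tab-separated floats, no header, row ``i`` is bin ``i``;
* cooler-style matrix — HDF5 with ``bins/{chrom,start,end}`` and
  ``pixels/{bin1_id,bin2_id,count}`` datasets (upper triangle, including diagonal);
* bedGraph tracks and BED segment lists — native 0-based half-open coordinates;
* conformation table — whitespace table with columns ``model  bin  x  y  z`` (μm)
  preceded by ``#chrom=...``, ``#bin_size=...`` metadata lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from hic3d.errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class BinTable:
    """Contiguous, non-overlapping fixed-size bins on one chromosome.

    Bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)`` in 0-based
    half-open coordinates.
    """

    chrom: str
    bin_size: int
    n_bins: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if self.n_bins < 2:
            raise ValidationError(f"need at least 2 bins, got {self.n_bins}")

    @property
    def total_bp(self) -> int:
        return self.bin_size * self.n_bins

    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def ends(self) -> np.ndarray:
        return self.starts() + self.bin_size

    def bin_of(self, pos: int) -> int:
        """Bin index containing base-pair position ``pos`` (0-based)."""
        if not 0 <= pos < self.total_bp:
            raise ValidationError(f"position {pos} outside [0, {self.total_bp})")
        return pos // self.bin_size


class ContactMatrix:
    """Symmetric, non-negative binned contact-frequency matrix.

    ``C`` may be a dense ndarray or a scipy sparse matrix (used for large
    block-diagonal synthetic cohorts); analysis code that needs dense data
    should go through :meth:`dense` or :meth:`submatrix`.
    """

    def __init__(self, bins: BinTable, C, *, validate: bool = True):
        self.bins = bins
        issparse = sp.issparse(C)
        if not issparse:
            C = np.asarray(C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise FormatError(f"contact matrix must be square, got shape {C.shape}")
        if C.shape[0] != bins.n_bins:
            raise ValidationError(
                f"matrix size {C.shape[0]} does not match bin table ({bins.n_bins} bins)"
            )
        if validate:
            if issparse:
                if C.count_nonzero() and C.min() < 0:
                    raise ValidationError("contact matrix contains negative entries")
                asym = abs(C - C.T)
                if asym.count_nonzero() and asym.max() > SYMMETRY_RTOL * max(1.0, abs(C).max()):
                    logger.warning("asymmetric contact matrix: symmetrizing by averaging")
                    warnings.warn("asymmetric contact matrix symmetrized by averaging")
                C = (C + C.T) * 0.5
                C = sp.csr_matrix(C)
            else:
                if np.any(C < 0):
                    raise ValidationError("contact matrix contains negative entries")
                if not np.all(np.isfinite(C)):
                    raise ValidationError("contact matrix contains non-finite entries")
                scale = max(1.0, float(np.abs(C).max()))
                if np.max(np.abs(C - C.T)) > SYMMETRY_RTOL * scale:
                    logger.warning("asymmetric contact matrix: symmetrizing by averaging")
                    warnings.warn("asymmetric contact matrix symmetrized by averaging")
                C = (C + C.T) * 0.5
        self.C = C

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.C)

    def dense(self) -> np.ndarray:
        return self.C.toarray() if self.is_sparse else self.C

    def submatrix(self, i0: int, i1: int) -> np.ndarray:
        """Dense block ``C[i0:i1, i0:i1]``."""
        block = self.C[i0:i1, i0:i1]
        return block.toarray() if self.is_sparse else np.asarray(block)


@dataclass
class GenomeTrack:
    """Per-bin real values with a missing-value mask (``mask[i]`` True = missing)."""

    bins: BinTable
    values: np.ndarray
    name: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bins.n_bins,):
            raise ValidationError(
                f"track length {self.values.shape} != n_bins {self.bins.n_bins}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask length does not match values")

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask


@dataclass
class SegmentList:
    """Genomic intervals ``(chrom, start, end, label)``, 0-based half-open."""

    chroms: list
    starts: np.ndarray
    ends: np.ndarray
    labels: list

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        n = len(self.starts)
        if not (len(self.chroms) == len(self.ends) == len(self.labels) == n):
            raise ValidationError("segment list fields have unequal lengths")
        if np.any(self.starts >= self.ends):
            bad = int(np.argmax(self.starts >= self.ends))
            raise ValidationError(
                f"segment {bad} has start >= end ({self.starts[bad]} >= {self.ends[bad]})"
            )
        self._check_overlap()

    def _check_overlap(self):
        for chrom in set(self.chroms):
            idx = [i for i, c in enumerate(self.chroms) if c == chrom]
            order = sorted(idx, key=lambda i: self.starts[i])
            for a, b in zip(order, order[1:]):
                if self.ends[a] > self.starts[b]:
                    raise ValidationError(
                        f"overlapping segments on {chrom}: "
                        f"[{self.starts[a]},{self.ends[a]}) and [{self.starts[b]},{self.ends[b]})"
                    )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for i in range(len(self)):
            yield self.chroms[i], int(self.starts[i]), int(self.ends[i]), self.labels[i]

    def total_length(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def subset(self, indices) -> "SegmentList":
        indices = list(indices)
        return SegmentList(
            [self.chroms[i] for i in indices],
            self.starts[indices],
            self.ends[indices],
            [self.labels[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# Contact matrices


def read_contact_matrix(path, fmt: str = "dense-tsv", *, chrom: str = "chr",
                        bin_size: int | None = None) -> ContactMatrix:
    """Read a per-chromosome contact matrix.

    ``fmt`` is ``"dense-tsv"`` (requires ``bin_size``) or ``"cooler"``
    (requires ``chrom`` to be present in the file's bin table).
    """
    if fmt == "dense-tsv":
        if bin_size is None:
            raise ValueError("bin_size is required for dense-tsv input")
        C = np.loadtxt(path, delimiter="\t", ndmin=2)
        if C.shape[0] != C.shape[1]:
            raise FormatError(f"non-square matrix in {path}: shape {C.shape}")
        bins = BinTable(chrom, int(bin_size), C.shape[0])
        return ContactMatrix(bins, C)
    if fmt == "cooler":
        return _read_cooler(path, chrom)
    raise ValueError(f"unknown contact matrix format: {fmt!r}")


def write_contact_matrix(matrix: ContactMatrix, path, fmt: str = "dense-tsv") -> None:
    if fmt == "dense-tsv":
        np.savetxt(path, matrix.dense(), delimiter="\t", fmt="%.17g")
        return
    if fmt == "cooler":
        _write_cooler(matrix, path)
        return
    raise ValueError(f"unknown contact matrix format: {fmt!r}")


def _read_cooler(path, chrom: str) -> ContactMatrix:
    import h5py

    with h5py.File(path, "r") as h5:
        chroms = [c.decode() if isinstance(c, bytes) else str(c) for c in h5["bins/chrom"][:]]
        sel = np.array([c == chrom for c in chroms])
        if not sel.any():
            raise KeyError(f"chromosome {chrom!r} not found in {path}")
        starts = h5["bins/start"][:][sel]
        ends = h5["bins/end"][:][sel]
        offset = int(np.argmax(sel))
        n = int(sel.sum())
        bin_size = int(ends[0] - starts[0])
        b1 = h5["pixels/bin1_id"][:]
        b2 = h5["pixels/bin2_id"][:]
        count = h5["pixels/count"][:].astype(float)
    keep = sel[np.minimum(b1, len(sel) - 1)] & sel[np.minimum(b2, len(sel) - 1)]
    b1, b2, count = b1[keep] - offset, b2[keep] - offset, count[keep]
    C = np.zeros((n, n))
    C[b1, b2] = count
    C[b2, b1] = count
    bins = BinTable(chrom, bin_size, n)
    return ContactMatrix(bins, C)


def _write_cooler(matrix: ContactMatrix, path) -> None:
    import h5py

    bins = matrix.bins
    C = matrix.dense()
    iu, ju = np.triu_indices(bins.n_bins)
    nz = C[iu, ju] != 0
    with h5py.File(path, "w") as h5:
        g = h5.create_group("bins")
        g.create_dataset("chrom", data=np.array([bins.chrom] * bins.n_bins, dtype="S32"))
        g.create_dataset("start", data=bins.starts())
        g.create_dataset("end", data=bins.ends())
        p = h5.create_group("pixels")
        p.create_dataset("bin1_id", data=iu[nz])
        p.create_dataset("bin2_id", data=ju[nz])
        p.create_dataset("count", data=C[iu, ju][nz])


# ---------------------------------------------------------------------------
# Tracks


def read_track(path, bins: BinTable, name: str = "") -> GenomeTrack:
    """Bin a bedGraph file: length-weighted interval means per bin; uncovered bins masked."""
    weight = np.zeros(bins.n_bins)
    wsum = np.zeros(bins.n_bins)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"expected 4 bedGraph columns, got {len(parts)}", lineno)
            chrom, start_s, end_s, value_s = parts[:4]
            if chrom != bins.chrom:
                continue
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", lineno)
            start = max(start, 0)
            end = min(end, bins.total_bp)
            if start >= end:
                continue
            first = start // bins.bin_size
            last = (end - 1) // bins.bin_size
            for b in range(first, last + 1):
                lo = max(start, b * bins.bin_size)
                hi = min(end, (b + 1) * bins.bin_size)
                weight[b] += hi - lo
                wsum[b] += value * (hi - lo)
    covered = weight > 0
    values = np.full(bins.n_bins, np.nan)
    values[covered] = wsum[covered] / weight[covered]
    return GenomeTrack(bins, values, name=name or str(path), mask=~covered)


def write_track(track: GenomeTrack, path) -> None:
    starts, ends = track.bins.starts(), track.bins.ends()
    with open(path, "w") as fh:
        for i in range(track.bins.n_bins):
            if track.mask[i]:
                continue
            fh.write(f"{track.bins.chrom}\t{starts[i]}\t{ends[i]}\t{track.values[i]:.17g}\n")


def smooth_track(track: GenomeTrack, window_bp: int) -> GenomeTrack:
    """Centered moving average over unmasked bins within ``window_bp``."""
    bin_size = track.bins.bin_size
    if window_bp < bin_size:
        raise ValueError(f"window {window_bp} smaller than bin size {bin_size}")
    if window_bp % bin_size != 0:
        raise ValueError(f"window {window_bp} not a multiple of bin size {bin_size}")
    w = window_bp // bin_size
    half = w // 2
    n = track.bins.n_bins
    vals = np.where(track.mask, 0.0, track.values)
    cnt = (~track.mask).astype(float)
    # cumulative sums give exact windowed means at edges too
    cv = np.concatenate([[0.0], np.cumsum(vals)])
    cc = np.concatenate([[0.0], np.cumsum(cnt)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    num = cv[hi] - cv[lo]
    den = cc[hi] - cc[lo]
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return GenomeTrack(track.bins, out, name=track.name, mask=~ok)


# ---------------------------------------------------------------------------
# Segments (BED)


def read_segments(path) -> SegmentList:
    chroms, starts, ends, labels = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"expected >= 3 BED columns, got {len(parts)}", lineno)
            try:
                chroms.append(parts[0])
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            labels.append(parts[3] if len(parts) > 3 else "")
    return SegmentList(chroms, np.array(starts, dtype=np.int64),
                       np.array(ends, dtype=np.int64), labels)


def write_segments(segments: SegmentList, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# Conformations


def write_conformations(ensemble, path) -> None:
    """Write a non-empty list of conformations as a plain-text table."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValidationError("cannot write an empty ensemble")
    bins = ensemble[0].bins
    with open(path, "w") as fh:
        fh.write(f"#chrom={bins.chrom}\n#bin_size={bins.bin_size}\n#n_bins={bins.n_bins}\n")
        fh.write("#model\tbin\tx\ty\tz\n")
        for m, conf in enumerate(ensemble):
            if conf.bins.n_bins != bins.n_bins:
                raise ValidationError("conformations in one ensemble must share a bin table")
            for b in range(bins.n_bins):
                x, y, z = conf.coords[b]
                fh.write(f"{m}\t{b}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


def read_conformations(path):
    from hic3d.optimizer import Conformation  # deferred: optimizer imports this module

    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValidationError(
                    f"line {lineno}: expected 5 columns (model bin x y z), got {len(parts)}"
                )
            rows.append((int(parts[0]), int(parts[1]),
                         float(parts[2]), float(parts[3]), float(parts[4])))
    for key in ("chrom", "bin_size", "n_bins"):
        if key not in meta:
            raise FormatError(f"missing #{key}= metadata line in {path}")
    bins = BinTable(meta["chrom"], int(meta["bin_size"]), int(meta["n_bins"]))
    if not rows:
        raise ValidationError(f"no coordinate rows in {path}")
    n_models = max(r[0] for r in rows) + 1
    coords = np.full((n_models, bins.n_bins, 3), np.nan)
    for m, b, x, y, z in rows:
        coords[m, b] = (x, y, z)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("conformation table has missing (model, bin) rows")
    return [Conformation(coords[m], bins) for m in range(n_models)]
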