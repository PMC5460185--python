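"""A/B compartment calling and degree-of-compartmentalization profiling.

The matrix is normalized by the observed/expected method (each entry divided
by its diagonal mean), turned into a bin-bin Pearson correlation matrix, and
split two ways spectrally (2-means on the leading eigenvector of the
centered correlation matrix). Labels are oriented by a user-supplied track —
the eigenvector sign alone is arbitrary. The per-bin degree of
compartmentalization is the log ratio of mean normalized contacts with A
bins versus B bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hic3d.errors import DegenerateInputError, ValidationError
from hic3d.io import BinTable, ContactMatrix, GenomeTrack, SegmentList, smooth_track
from hic3d.stats import masked_pearson

logger = logging.getLogger(__name__)

LABEL_A, LABEL_B, UNASSIGNED = "A", "B", "."


@dataclass
class CompartmentProfile:
    bins: BinTable
    labels: np.ndarray  # per-bin "A" / "B" / "." strings
    degree: np.ndarray | None = None
    orientation_track: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.bins.n_bins,):
            raise ValidationError("label length does not match bin table")
        bad = set(self.labels) - {LABEL_A, LABEL_B, UNASSIGNED}
        if bad:
            raise ValidationError(f"unknown compartment labels: {bad}")

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    def mask_for(self, label: str) -> np.ndarray:
        return self.labels == label


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    """Divide each entry by the mean of its diagonal; zero-mean diagonals → NaN."""
    C = matrix.dense()
    n = matrix.n_bins
    OE = np.full((n, n), np.nan)
    for k in range(n):
        mean_k = np.diagonal(C, k).mean()
        if mean_k > 0:
            idx = np.arange(n - k)
            OE[idx, idx + k] = C[idx, idx + k] / mean_k
            OE[idx + k, idx] = OE[idx, idx + k]
    return OE


def correlation_matrix(oe: np.ndarray) -> np.ndarray:
    """Pearson correlation of O/E rows; constant or empty rows are masked (NaN)."""
    n = oe.shape[0]
    valid_col = ~np.all(np.isnan(oe), axis=0)
    X = oe[:, valid_col]
    # rows with NaNs (masked diagonals) are handled pairwise
    R = np.full((n, n), np.nan)
    finite = np.isfinite(X)
    if finite.all() and X.shape[1] >= 3:
        sd = X.std(axis=1)
        ok = sd > 0
        if ok.any():
            sub = np.corrcoef(X[ok])
            R[np.ix_(ok, ok)] = sub
        np.fill_diagonal(R, np.where(ok, 1.0, np.nan))
        return R
    for i in range(n):
        for j in range(i, n):
            both = finite[i] & finite[j]
            if both.sum() < 3:
                continue
            xi, xj = X[i, both], X[j, both]
            sx, sy = xi.std(), xj.std()
            if sx == 0 or sy == 0:
                continue
            R[i, j] = R[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    np.fill_diagonal(R, np.where(np.isfinite(np.diagonal(R)), 1.0, np.nan))
    return R


def call_compartments(corr: np.ndarray, orientation: GenomeTrack,
                      bins: BinTable | None = None) -> CompartmentProfile:
    """Two-way spectral split of the correlation matrix, oriented by a track.

    Leading eigenvector of the centered correlation matrix, 2-means on its
    entries; the cluster with the higher mean orientation value becomes A.
    """
    bins = bins or orientation.bins
    n = corr.shape[0]
    if n != bins.n_bins:
        raise ValidationError("correlation matrix and orientation track sizes differ")
    valid = np.isfinite(np.diagonal(corr))
    labels = np.array([UNASSIGNED] * n, dtype=object)
    R = corr[np.ix_(valid, valid)]
    R = np.where(np.isfinite(R), R, 0.0)
    m = R.shape[0]
    if m < 2:
        raise DegenerateInputError("fewer than 2 usable bins")
    Rc = R - R.mean(axis=0, keepdims=True)
    Rc -= Rc.mean(axis=1, keepdims=True)
    w, V = np.linalg.eigh((Rc + Rc.T) / 2)
    ev = V[:, np.argmax(w)]
    degenerate = w.max() < 1e-10 * max(1.0, float(np.abs(R).max()))
    split = None if degenerate else _two_means_1d(ev)
    if split is None:
        logger.warning("degenerate spectral split: all bins fall on one side")
        labels[valid] = LABEL_A
        return CompartmentProfile(bins, labels, orientation_track=orientation.name)
    side = split  # boolean over valid bins
    track_vals = np.where(orientation.mask, np.nan, orientation.values)[valid]
    mean1 = np.nanmean(track_vals[side]) if side.any() else np.nan
    mean0 = np.nanmean(track_vals[~side]) if (~side).any() else np.nan
    if np.isnan(mean1) or np.isnan(mean0) or mean1 == mean0:
        raise ValidationError(
            "orientation track cannot break the A/B tie; supply explicit labels"
        )
    a_side = side if mean1 > mean0 else ~side
    lab = np.where(a_side, LABEL_A, LABEL_B).astype(object)
    labels[valid] = lab
    return CompartmentProfile(bins, labels, orientation_track=orientation.name)


def _two_means_1d(x: np.ndarray) -> np.ndarray | None:
    """Exact 2-means on a 1-D array (scan over sorted split points)."""
    order = np.argsort(x)
    xs = x[order]
    n = len(xs)
    if xs[0] == xs[-1]:
        return None
    csum = np.cumsum(xs)
    total = csum[-1]
    ks = np.arange(1, n)
    left_mean = csum[:-1] / ks
    right_mean = (total - csum[:-1]) / (n - ks)
    # within-cluster sum of squares up to constants: maximize between-cluster term
    between = ks * left_mean**2 + (n - ks) * right_mean**2
    k = int(np.argmax(between))
    side = np.zeros(n, dtype=bool)
    side[order[k + 1:]] = True
    if side.all() or not side.any():
        return None
    return side


def degree_of_compartmentalization(matrix: ContactMatrix,
                                   profile: CompartmentProfile,
                                   eps_factor: float = 1e-6) -> GenomeTrack:
    """Per-bin log ratio of mean O/E contact with A bins vs B bins (self excluded).

    A small pseudocount (``eps_factor`` × overall mean O/E) keeps the log
    finite when a bin has no contacts with one class.
    """
    OE = observed_over_expected(matrix)
    in_a = profile.mask_for(LABEL_A)
    in_b = profile.mask_for(LABEL_B)
    if not in_a.any() or not in_b.any():
        raise ValidationError("profile must contain both A and B bins")
    n = matrix.n_bins
    eps = eps_factor * np.nanmean(OE)
    degree = np.full(n, np.nan)
    for i in range(n):
        row = OE[i].copy()
        row[i] = np.nan  # exclude self
        a_vals = row[in_a]
        b_vals = row[in_b]
        a_mean = np.nanmean(a_vals) if np.any(np.isfinite(a_vals)) else np.nan
        b_mean = np.nanmean(b_vals) if np.any(np.isfinite(b_vals)) else np.nan
        if np.isnan(a_mean) or np.isnan(b_mean):
            continue
        degree[i] = np.log((a_mean + eps) / (b_mean + eps))
    mask = ~np.isfinite(degree) | ~profile.assigned
    return GenomeTrack(profile.bins, degree, name="degree_of_compartmentalization",
                       mask=mask)


def track_correlation(degree: GenomeTrack, feature: GenomeTrack,
                      window_bp: int | None = None) -> float:
    """Pearson r between the degree profile and a (smoothed) feature track."""
    if degree.bins.n_bins != feature.bins.n_bins:
        raise ValidationError("tracks are on different bin tables")
    if window_bp is not None and window_bp > feature.bins.bin_size:
        feature = smooth_track(feature, window_bp)
    mask = degree.mask | feature.mask
    return masked_pearson(degree.values, feature.values, mask)


def overlap_fraction(segments: SegmentList, profile: CompartmentProfile,
                     label: str) -> float:
    """Fraction of total segment length that overlaps bins carrying ``label``."""
    total = segments.total_length()
    if total == 0:
        raise ValidationError("segments have zero total length")
    bs = profile.bins.bin_size
    hit = 0
    for chrom, start, end, _ in segments:
        if chrom != profile.bins.chrom:
            continue
        start = max(start, 0)
        end = min(end, profile.bins.total_bp)
        if start >= end:
            continue
        first, last = start // bs, (end - 1) // bs
        for b in range(first, last + 1):
            if profile.labels[b] != label:
                continue
            hit += min(end, (b + 1) * bs) - max(start, b * bs)
    return hit / total
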