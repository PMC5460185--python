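"""Two-type classification of chromatin segments from intra-segment Hi-C patterns.

Each segment is summarized by the log variance of its contact frequencies at
log-spaced genomic separations. Long segments are split into two sets by
k-means to seed labels, and a linear discriminant classifier is trained with
a held-out split and k-fold cross-validation, then applied to all segments
above a minimum length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold

from hic3d.errors import ValidationError
from hic3d.io import ContactMatrix, SegmentList

MIN_TRAIN_BP = 500_000
MIN_CLASSIFY_BP = 300_000
TYPE_A, TYPE_B, UNASSIGNED = "A", "B", "unassigned"


@dataclass
class VarianceFeatureVector:
    segment_id: int
    values: np.ndarray  # log(eps + population variance) per distance bin
    mask: np.ndarray  # True where the distance bin had < 2 intra-segment entries
    edges_bp: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.edges_bp = np.asarray(self.edges_bp, dtype=float)
        if len(self.values) != len(self.edges_bp) - 1:
            raise ValidationError("feature length does not match distance-bin edges")


@dataclass
class SegmentTypeModel:
    """Trained two-class LDA over log-variance contact features."""

    coef: np.ndarray
    intercept: float
    classes: list
    edges_bp: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    kmeans_sizes: dict
    train_idx: np.ndarray
    test_idx: np.ndarray
    cv_loss: float
    test_error: float
    seed: int
    _estimator: LinearDiscriminantAnalysis | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (0.0 <= self.cv_loss <= 1.0 and 0.0 <= self.test_error <= 1.0):
            raise ValidationError("cv_loss and test_error must lie in [0, 1]")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.coef):
            raise ValidationError(
                f"feature length {X.shape[1]} != model expectation {len(self.coef)}"
            )
        Z = (X - self.feature_mean) / self.feature_std
        score = Z @ self.coef + self.intercept
        return np.where(score > 0, self.classes[1], self.classes[0])

    def to_json(self) -> str:
        return json.dumps({
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "classes": list(self.classes),
            "edges_bp": self.edges_bp.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "kmeans_sizes": {str(k): int(v) for k, v in self.kmeans_sizes.items()},
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "cv_loss": self.cv_loss,
            "test_error": self.test_error,
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SegmentTypeModel":
        d = json.loads(text)
        return cls(np.array(d["coef"]), d["intercept"], d["classes"],
                   np.array(d["edges_bp"]), np.array(d["feature_mean"]),
                   np.array(d["feature_std"]), d["kmeans_sizes"],
                   np.array(d["train_idx"]), np.array(d["test_idx"]),
                   d["cv_loss"], d["test_error"], d["seed"])


def default_distance_bins(bin_size: int, max_sep_bp: int,
                          bins_per_decade: int = 4) -> np.ndarray:
    """Log-spaced separation-bin edges from 2 bins up to ``max_sep_bp``."""
    lo = 2 * bin_size
    if max_sep_bp <= lo:
        raise ValidationError("maximum separation must exceed 2 bins")
    n_edges = max(2, int(np.ceil(np.log10(max_sep_bp / lo) * bins_per_decade)) + 1)
    edges = np.geomspace(lo, max_sep_bp, n_edges)
    edges[-1] *= 1 + 1e-12
    return edges


def variance_eps(matrix: ContactMatrix) -> float:
    """Pseudocount for log-variance features: 1e-8 × (global mean contact)²."""
    C = matrix.C
    total = C.sum() if matrix.is_sparse else C.sum()
    mean = float(total) / (matrix.n_bins**2)
    return 1e-8 * mean**2


def variance_features(matrix: ContactMatrix, start_bin: int, end_bin: int,
                      edges_bp: np.ndarray, eps: float,
                      segment_id: int = 0) -> VarianceFeatureVector:
    """Log population variance of intra-segment contacts per separation bin."""
    if end_bin - start_bin < 2:
        raise ValidationError("segment must span at least 2 bins")
    bs = matrix.bins.bin_size
    block = matrix.submatrix(start_bin, end_bin)
    m = block.shape[0]
    n_feat = len(edges_bp) - 1
    values = np.full(n_feat, np.log(eps))
    mask = np.ones(n_feat, dtype=bool)
    seps = np.arange(1, m) * bs
    which = np.digitize(seps, edges_bp) - 1
    for b in range(n_feat):
        ks = np.nonzero(which == b)[0] + 1
        if len(ks) == 0:
            continue
        entries = np.concatenate([np.diagonal(block, k) for k in ks])
        if len(entries) < 2:
            continue
        values[b] = np.log(eps + entries.var())  # population variance (ddof=0)
        mask[b] = False
    return VarianceFeatureVector(segment_id, values, mask, edges_bp)


def features_for_segments(matrix: ContactMatrix, segments: SegmentList,
                          edges_bp: np.ndarray | None = None
                          ) -> list[VarianceFeatureVector]:
    """Feature vectors for every segment, on one shared distance-bin grid."""
    bs = matrix.bins.bin_size
    if edges_bp is None:
        max_len = int((segments.ends - segments.starts).max())
        edges_bp = default_distance_bins(bs, max_len)
    eps = variance_eps(matrix)
    out = []
    for idx, (chrom, start, end, _) in enumerate(segments):
        if chrom != matrix.bins.chrom:
            raise ValidationError(f"segment {idx} on {chrom}, matrix on {matrix.bins.chrom}")
        out.append(variance_features(matrix, start // bs, end // bs, edges_bp,
                                     eps, segment_id=idx))
    return out


def feature_matrix(features: list[VarianceFeatureVector]) -> np.ndarray:
    X = np.stack([f.values for f in features])
    edges0 = features[0].edges_bp
    for f in features[1:]:
        if len(f.edges_bp) != len(edges0) or not np.allclose(f.edges_bp, edges0):
            raise ValidationError("feature vectors use different distance-bin grids")
    return X


def seed_labels_kmeans(features: list[VarianceFeatureVector], lengths_bp: np.ndarray,
                       min_length_bp: int = MIN_TRAIN_BP, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """k-means (k=2) on long segments' features; returns (long indices, labels).

    The cluster with the larger mean feature magnitude — more intra-segment
    structure — is labeled type A.
    """
    lengths_bp = np.asarray(lengths_bp)
    long_idx = np.nonzero(lengths_bp >= min_length_bp)[0]
    if len(long_idx) < 2:
        raise ValidationError("need at least 2 segments above the training length")
    X = feature_matrix([features[i] for i in long_idx])
    # drop distance bins masked in >5% of segments (their log-eps fill values
    # would dominate the euclidean metric), then z-score the rest
    mask_frac = np.stack([features[i].mask for i in long_idx]).mean(axis=0)
    cols = mask_frac <= 0.05
    if not cols.any():
        cols = mask_frac == mask_frac.min()
    Xk = X[:, cols]
    sd = Xk.std(axis=0)
    Xk = (Xk - Xk.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(Xk)
    mean0 = X[raw == 0][:, cols].mean()
    mean1 = X[raw == 1][:, cols].mean()
    a_cluster = 0 if mean0 >= mean1 else 1
    labels = np.where(raw == a_cluster, TYPE_A, TYPE_B)
    return long_idx, labels


def train_lda(features: list[VarianceFeatureVector], labels: np.ndarray,
              test_fraction: float = 0.2, cv_folds: int = 5,
              seed: int = 0) -> SegmentTypeModel:
    """Fit a two-class LDA with a seeded held-out split and k-fold CV.

    Features are standardized with training-set statistics; the discriminant
    uses shrinkage toward the diagonal for stability with short feature
    vectors.
    """
    X = feature_matrix(features)
    y = np.asarray(labels)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    if len(set(y[train_idx])) < 2:
        raise ValidationError("training split contains a single class")

    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    def fit(idx):
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        est.fit(Z[idx], y[idx])
        return est

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_errors = []
    for tr, va in kf.split(train_idx):
        tr_idx, va_idx = train_idx[tr], train_idx[va]
        if len(set(y[tr_idx])) < 2:
            fold_errors.append(np.mean(y[va_idx] != y[tr_idx][0]))
            continue
        est = fit(tr_idx)
        fold_errors.append(float(np.mean(est.predict(Z[va_idx]) != y[va_idx])))
    cv_loss = float(np.mean(fold_errors))

    est = fit(train_idx)
    if len(test_idx):
        test_error = float(np.mean(est.predict(Z[test_idx]) != y[test_idx]))
    else:
        test_error = 0.0
    coef = est.coef_.ravel()
    intercept = float(est.intercept_[0])
    est_classes = list(est.classes_)
    return SegmentTypeModel(coef, intercept, est_classes, features[0].edges_bp,
                            mu, sd, {c: int((y == c).sum()) for c in classes},
                            train_idx, test_idx, cv_loss, test_error, seed,
                            _estimator=est)


def classify_segments(model: SegmentTypeModel,
                      features: list[VarianceFeatureVector],
                      segments: SegmentList,
                      min_classify_bp: int = MIN_CLASSIFY_BP) -> SegmentList:
    """Apply the trained discriminant; short segments stay unassigned."""
    X = feature_matrix(features)
    pred = model.predict(X)
    lengths = segments.ends - segments.starts
    labels = [pred[i] if lengths[i] >= min_classify_bp else UNASSIGNED
              for i in range(len(segments))]
    return SegmentList(list(segments.chroms), segments.starts.copy(),
                       segments.ends.copy(), labels)


def type_composition(types: SegmentList, reference) -> pd.DataFrame:
    """Length-weighted contingency table of segment types vs a reference classing.

    ``reference`` is either a :class:`SegmentList` (labels per interval) or a
    :class:`CompartmentProfile` (labels per bin). Rows are segment types,
    columns reference classes, entries overlapping base pairs; row fractions
    are appended as ``frac_<class>`` columns.
    """
    from hic3d.compartments import CompartmentProfile

    if len(types) == 0:
        raise ValidationError("empty type segment list")
    table: dict[str, dict[str, int]] = {}

    def add(t, r, bp):
        table.setdefault(t, {}).setdefault(r, 0)
        table[t][r] += bp

    if isinstance(reference, CompartmentProfile):
        bs = reference.bins.bin_size
        for chrom, start, end, t in types:
            if chrom != reference.bins.chrom:
                continue
            start = max(start, 0)
            end = min(end, reference.bins.total_bp)
            for b in range(start // bs, (end - 1) // bs + 1):
                bp = min(end, (b + 1) * bs) - max(start, b * bs)
                add(t, str(reference.labels[b]), bp)
    elif isinstance(reference, SegmentList):
        if len(reference) == 0:
            raise ValidationError("empty reference segment list")
        for chrom, start, end, t in types:
            for rchrom, rstart, rend, rlabel in reference:
                if rchrom != chrom:
                    continue
                bp = min(end, rend) - max(start, rstart)
                if bp > 0:
                    add(t, rlabel, bp)
    else:
        raise TypeError("reference must be a SegmentList or CompartmentProfile")

    df = pd.DataFrame(table).T.fillna(0).astype(int)
    df = df.sort_index()
    row_sums = df.sum(axis=1)
    for col in list(df.columns):
        df[f"frac_{col}"] = df[col] / row_sums
    return df
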