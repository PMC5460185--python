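"""Seed-deterministic synthetic data: ground-truth polymer structures,
distance-decay contact matrices with Poisson counting noise, planted
two-compartment plaid patterns, two-type domain cohorts and correlated
feature tracks. Every pipeline stage is testable against these generators
without any external data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from hic3d.compartments import LABEL_A, LABEL_B, CompartmentProfile
from hic3d.errors import ValidationError
from hic3d.io import BinTable, ContactMatrix, GenomeTrack, SegmentList
from hic3d.optimizer import Conformation
from hic3d.restraints import DecayCurve, ScalingModel


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generators (see module docstring)."""

    n_bins: int = 400
    bin_size: int = 50_000
    block_bins: int = 50  # alternating A/B compartment block length
    alpha: float = 2.0  # within-compartment O/E enrichment (> 1)
    decay_exponent: float = 1.0  # contact ∝ separation^-exponent
    depth: float = 400.0  # expected contact at one-bin separation
    radial_bias: float = 0.35  # A-toward-center step bias in make_structure
    n_subsquares: tuple = (2, 4)  # nested enriched squares per type-A segment
    square_enrichment: float = 3.0
    length_mean_a: float = 588_000.0  # type-A segment length draw (bp)
    length_mean_b: float = 744_000.0
    length_sd: float = 150_000.0
    depth_jitter_sd: float = 0.1  # lognormal per-segment depth variation
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 1:
            raise ValidationError("alpha must exceed 1")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.n_bins % self.block_bins != 0:
            raise ValidationError("compartment blocks must tile the chromosome")

    def block_labels(self) -> np.ndarray:
        """Alternating A/B labels, one per bin."""
        n_blocks = self.n_bins // self.block_bins
        per_block = [LABEL_A if b % 2 == 0 else LABEL_B for b in range(n_blocks)]
        return np.repeat(np.array(per_block, dtype=object), self.block_bins)


def reference_decay_curve(spec: SyntheticSpec, model: ScalingModel) -> DecayCurve:
    """The generator's exact contact-vs-separation law, tabulated per diagonal.

    Pure power law, so log-log interpolation through it is exact.
    """
    l = np.arange(1, spec.n_bins, dtype=float) * spec.bin_size
    C = spec.depth * (l / spec.bin_size) ** (-spec.decay_exponent)
    return DecayCurve(l, C)


def _hilbert_axes(h: int, order: int, dims: int = 3) -> list[int]:
    """Skilling transform: Hilbert index → grid coordinates (unit steps)."""
    nbits = dims * order
    X = [0] * dims
    for i in range(nbits):
        bit = (h >> (nbits - 1 - i)) & 1
        X[i % dims] = (X[i % dims] << 1) | bit
    N = 2 << (order - 1)
    t = X[dims - 1] >> 1
    for i in range(dims - 1, 0, -1):
        X[i] ^= X[i - 1]
    X[0] ^= t
    Q = 2
    while Q != N:
        P = Q - 1
        for i in range(dims - 1, -1, -1):
            if X[i] & Q:
                X[0] ^= P
            else:
                t = (X[0] ^ X[i]) & P
                X[0] ^= t
                X[i] ^= t
        Q <<= 1
    return X


def make_structure(spec: SyntheticSpec, seed: int | None = None,
                   model: ScalingModel | None = None,
                   jitter_frac: float = 0.15) -> Conformation:
    """Crumpled-globule-like ground-truth polymer with radial A/B segregation.

    Beads follow a jittered 3D space-filling (Hilbert) path whose pairwise
    distances scale as the cube root of genomic separation — the same
    exponent the restraint conversion assumes, so restraints built from this
    structure's contacts are mutually consistent. A-bead radii are contracted
    and B-bead radii expanded by ``radial_bias`` (skipped when only one
    compartment is present). Bond lengths stay within ~±3 ``jitter_frac`` of
    the scaling-law distance at one bin.
    """
    model = model or ScalingModel()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = spec.block_labels()
    bias = spec.radial_bias if len(set(labels)) > 1 else 0.0
    step = model.distance(spec.bin_size)
    order = 1
    while 8**order < spec.n_bins:
        order += 1
    grid = np.array([_hilbert_axes(h, order) for h in range(spec.n_bins)], dtype=float)
    coords = (grid - grid.mean(axis=0)) * step
    coords += rng.normal(0.0, jitter_frac * step, size=coords.shape)
    if bias:
        r = np.linalg.norm(coords, axis=1)
        scale = np.where(labels == LABEL_A, 1.0 - 0.5 * bias, 1.0 + 0.5 * bias)
        coords *= scale[:, None]
    bins = BinTable("chrS", spec.bin_size, spec.n_bins)
    return Conformation(coords, bins, seed=spec.seed if seed is None else seed)


def structure_to_hic(conf: Conformation, model: ScalingModel, spec: SyntheticSpec,
                     seed: int | None = None, noiseless: bool = False) -> ContactMatrix:
    """Forward model: pairwise distance → effective separation → expected contact.

    The effective genomic separation inverts the scaling law,
    ``l_eff = L (d / 2R)³``; the expected contact follows the generator's
    power-law decay. Counts are Poisson unless ``noiseless``.
    """
    n = conf.n_beads
    iu, ju = np.triu_indices(n, k=1)
    d = conf.pairwise_distances(iu, ju)
    l_eff = model.L_bp * (d / model.d_max) ** 3
    l_eff = np.maximum(l_eff, 0.5 * conf.bins.bin_size)  # cap the near-contact blowup
    expected = spec.depth * (l_eff / conf.bins.bin_size) ** (-spec.decay_exponent)
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        counts = rng.poisson(expected).astype(float)
    C = np.zeros((n, n))
    C[iu, ju] = counts
    C[ju, iu] = counts
    return ContactMatrix(conf.bins, C, validate=False)


def make_plaid_matrix(spec: SyntheticSpec, seed: int | None = None,
                      noiseless: bool = False
                      ) -> tuple[ContactMatrix, CompartmentProfile]:
    """Distance-decay matrix with a planted two-compartment plaid pattern.

    Same-compartment pairs are enriched ×α, cross-compartment pairs depleted
    ×(1/α); Poisson sampling adds counting noise.
    """
    labels = spec.block_labels()
    n = spec.n_bins
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    decay = spec.depth * np.maximum(sep, 0.5) ** (-spec.decay_exponent)
    same = (labels[:, None] == labels[None, :])
    expected = decay * np.where(same, spec.alpha, 1.0 / spec.alpha)
    if noiseless:
        C = expected.copy()
    else:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        iu, ju = np.triu_indices(n)
        counts = rng.poisson(expected[iu, ju]).astype(float)
        C = np.zeros((n, n))
        C[iu, ju] = counts
        C[ju, iu] = counts
    bins = BinTable("chrS", spec.bin_size, n)
    profile = CompartmentProfile(bins, labels, orientation_track="planted")
    return ContactMatrix(bins, C, validate=False), profile


def make_typed_segments(spec: SyntheticSpec, n_segments: int,
                        seed: int | None = None, min_length_bp: int = 0
                        ) -> tuple[ContactMatrix, SegmentList]:
    """Cohort of concatenated segments of two intra-segment pattern types.

    Type A segments carry distance decay plus 2-4 nested enriched diagonal
    squares (localized interaction domains); type B segments contact nearly
    uniformly. Per-segment sequencing depth is jittered lognormally. The
    matrix is block-diagonal and stored sparse.
    """
    if n_segments < 4:
        raise ValidationError("need at least 4 segments")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    bs = spec.bin_size
    blocks, chroms, starts, ends, labels = [], [], [], [], []
    pos = 0
    for s in range(n_segments):
        is_a = rng.random() < 0.5
        mean = spec.length_mean_a if is_a else spec.length_mean_b
        length = rng.normal(mean, spec.length_sd)
        length = max(length, max(min_length_bp, 2 * bs))
        m = int(round(length / bs))
        m = max(m, max(2, int(np.ceil(min_length_bp / bs))))
        depth = spec.depth * np.exp(rng.normal(0.0, spec.depth_jitter_sd))
        sep = np.abs(np.subtract.outer(np.arange(m), np.arange(m))).astype(float)
        if is_a:
            expected = depth * np.maximum(sep, 0.5) ** (-spec.decay_exponent)
            lo, hi = spec.n_subsquares
            count = int(rng.integers(lo, hi + 1))
            # square sizes are fixed fractions of the segment so every type-A
            # segment enriches the same separation range; positions are random
            for frac in np.linspace(0.55, 0.25, count):
                size = max(2, int(round(frac * m)))
                start = rng.integers(0, max(1, m - size + 1))
                expected[start:start + size, start:start + size] *= spec.square_enrichment
                inner = max(2, size // 2)  # nested inner square
                istart = start + rng.integers(0, size - inner + 1)
                expected[istart:istart + inner, istart:istart + inner] *= \
                    spec.square_enrichment
        else:
            level = depth * (m / 2.0) ** (-spec.decay_exponent)
            expected = np.full((m, m), level)
        iu, ju = np.triu_indices(m)
        counts = rng.poisson(expected[iu, ju]).astype(float)
        block = np.zeros((m, m))
        block[iu, ju] = counts
        block[ju, iu] = counts
        blocks.append(sp.csr_matrix(block))
        chroms.append("chrS")
        starts.append(pos * bs)
        ends.append((pos + m) * bs)
        labels.append("A" if is_a else "B")
        pos += m
    C = sp.block_diag(blocks, format="csr")
    bins = BinTable("chrS", bs, pos)
    matrix = ContactMatrix(bins, C, validate=False)
    segments = SegmentList(chroms, np.array(starts), np.array(ends), labels)
    return matrix, segments


def make_correlated_track(profile: CompartmentProfile, effect: float,
                          noise_sd: float, seed: int = 0,
                          name: str = "synthetic_feature") -> GenomeTrack:
    """Gaussian track with mean +effect on A bins and −effect on B bins."""
    rng = np.random.default_rng(seed)
    n = profile.bins.n_bins
    mean = np.zeros(n)
    mean[profile.mask_for(LABEL_A)] = effect
    mean[profile.mask_for(LABEL_B)] = -effect
    values = mean + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else mean
    return GenomeTrack(profile.bins, values, name=name, mask=~profile.assigned)
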