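"""Conversion of a contact matrix into pairwise distance restraints.

The pipeline: a power-law scaling model gives the expected spatial distance
for a genomic separation; the empirical contact-vs-separation decay curve is
tabulated from the matrix (per-diagonal up to a cutoff, log-spaced beyond,
made monotone in log-log space); contact frequencies are then mapped to
distances by linear interpolation on the double-logarithm plot. Long-range
entries are block-smoothed beforehand to tame low signal-to-noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from hic3d.errors import DegenerateInputError, ValidationError
from hic3d.io import BinTable, ContactMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalingModel:
    """d(l) = 2R (l / L)^(1/3): spatial distance expected for genomic separation l.

    R is the nuclear radius (μm), L the total genome length (bp). The cube-root
    exponent reflects space-filling packing of the genome inside the nucleus.
    """

    R_um: float = 10.0
    L_bp: float = 6.0e9

    EXPONENT = 1.0 / 3.0

    def __post_init__(self):
        if self.R_um <= 0:
            raise ValidationError(f"R must be positive, got {self.R_um}")
        if self.L_bp <= 0:
            raise ValidationError(f"L must be positive, got {self.L_bp}")

    def distance(self, l_bp):
        """Expected distance (μm) at genomic separation ``l_bp`` (> 0)."""
        l_bp = np.asarray(l_bp, dtype=float)
        if np.any(l_bp <= 0):
            raise ValueError("genomic separation must be positive")
        return 2.0 * self.R_um * (l_bp / self.L_bp) ** self.EXPONENT

    @property
    def d_max(self) -> float:
        """Nuclear diameter 2R, the ceiling for any restraint distance."""
        return 2.0 * self.R_um


def expected_distance(l_bp, model: ScalingModel):
    """Functional alias for :meth:`ScalingModel.distance`."""
    return model.distance(l_bp)


@dataclass
class DecayCurve:
    """Mean contact frequency tabulated against genomic separation.

    ``l`` strictly increasing (bp); ``C`` strictly positive and, after
    :meth:`enforce_monotone`, strictly decreasing.
    """

    l: np.ndarray
    C: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.l = np.asarray(self.l, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.counts is None:
            self.counts = np.ones_like(self.l)
        if len(self.l) < 2:
            raise DegenerateInputError("decay curve needs at least 2 support points")
        if np.any(np.diff(self.l) <= 0):
            raise ValidationError("decay curve separations must be strictly increasing")
        if np.any(self.C <= 0):
            raise ValidationError("decay curve contact values must be positive")

    def enforce_monotone(self) -> "DecayCurve":
        """Non-increasing fit in log-log space (isotonic), ties collapsed.

        Real decay curves wiggle; interpolation needs a monotone table.
        """
        logC = np.log(self.C)
        iso = IsotonicRegression(increasing=False)
        fit = iso.fit_transform(np.log(self.l), logC, sample_weight=self.counts)
        # collapse runs of equal fitted values into single knots (geometric-mean l)
        l_out, c_out, n_out = [], [], []
        i = 0
        while i < len(fit):
            j = i
            while j + 1 < len(fit) and fit[j + 1] == fit[i]:
                j += 1
            w = self.counts[i:j + 1]
            l_out.append(np.exp(np.average(np.log(self.l[i:j + 1]), weights=w)))
            c_out.append(np.exp(fit[i]))
            n_out.append(w.sum())
            i = j + 1
        if len(l_out) < 2:
            raise DegenerateInputError("decay curve collapsed to a single knot")
        return DecayCurve(np.array(l_out), np.array(c_out), np.array(n_out))


def decay_curve(matrix: ContactMatrix, *, cutoff_bp: float = 2.0e6,
                bins_per_decade: int = 10, monotone: bool = True) -> DecayCurve:
    """Tabulate mean contact vs genomic separation.

    Per-diagonal means up to ``cutoff_bp``; count-weighted log-spaced distance
    bins (``bins_per_decade``) beyond, where single diagonals are noisy.
    All-zero diagonals are dropped.
    """
    C = matrix.dense()
    n = matrix.n_bins
    bs = matrix.bins.bin_size
    diag_mean = np.empty(n - 1)
    diag_cnt = np.empty(n - 1)
    for k in range(1, n):
        d = np.diagonal(C, k)
        diag_mean[k - 1] = d.mean()
        diag_cnt[k - 1] = d.size
    seps = np.arange(1, n, dtype=float) * bs

    near = seps <= cutoff_bp
    ls, cs, ns = [], [], []
    for k in np.nonzero(near)[0]:
        if diag_mean[k] > 0:
            ls.append(seps[k])
            cs.append(diag_mean[k])
            ns.append(diag_cnt[k])
    far = ~near
    if far.any():
        lmax = seps[-1]
        n_edges = max(2, int(np.ceil(np.log10(lmax / cutoff_bp) * bins_per_decade)) + 1)
        edges = np.geomspace(cutoff_bp, lmax, n_edges)
        edges[-1] = lmax * (1 + 1e-12)
        which = np.digitize(seps[far], edges) - 1
        for b in range(n_edges - 1):
            sel = which == b
            if not sel.any():
                continue
            w = diag_cnt[far][sel]
            m = np.average(diag_mean[far][sel], weights=w)
            if m <= 0:
                continue
            ls.append(np.exp(np.average(np.log(seps[far][sel]), weights=w)))
            cs.append(m)
            ns.append(w.sum())
    if not ls:
        raise DegenerateInputError("all off-diagonal contacts are zero")
    order = np.argsort(ls)
    curve = DecayCurve(np.array(ls)[order], np.array(cs)[order], np.array(ns)[order])
    return curve.enforce_monotone() if monotone else curve


def _log_interp(x, xp_desc, fp, lo_clip, hi_clip):
    """Linear interpolation in log space with log-linear extrapolation, clipped.

    ``xp_desc`` is strictly decreasing; output clipped to [lo_clip, hi_clip].
    """
    lx = np.log(x)
    lxp = np.log(xp_desc)[::-1]
    lfp = np.log(fp)[::-1]
    out = np.interp(lx, lxp, lfp)
    # extrapolate with the terminal segment slopes
    if len(lxp) >= 2:
        lo = lx < lxp[0]
        hi = lx > lxp[-1]
        if np.any(lo):
            s = (lfp[1] - lfp[0]) / (lxp[1] - lxp[0])
            out = np.where(lo, lfp[0] + s * (lx - lxp[0]), out)
        if np.any(hi):
            s = (lfp[-1] - lfp[-2]) / (lxp[-1] - lxp[-2])
            out = np.where(hi, lfp[-1] + s * (lx - lxp[-1]), out)
    return np.clip(np.exp(out), lo_clip, hi_clip)


def contact_to_distance(c, curve: DecayCurve, model: ScalingModel):
    """Map contact frequency to spatial distance (μm) via log-log interpolation.

    Exact at the curve's knots: ``c == C_k`` returns ``d(l_k)``. Out-of-range
    contacts extrapolate log-linearly, clamped to ``[d(l_min), 2R]``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("contact frequency must be positive")
    d_knots = model.distance(curve.l)
    return _log_interp(c, curve.C, d_knots, d_knots[0], model.d_max)


def distance_to_contact(d, curve: DecayCurve, model: ScalingModel):
    """Inverse of :func:`contact_to_distance`: distance (μm) to contact frequency.

    Distances outside the curve's span clamp to the terminal contact values.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    d_knots = model.distance(curve.l)  # increasing; curve.C decreasing along it
    out = np.interp(np.log(d), np.log(d_knots), np.log(curve.C))
    return np.clip(np.exp(out), curve.C.min(), curve.C.max())


def smooth_long_range(matrix: ContactMatrix, genomic_cutoff: float = 2.0e6,
                      block_bp: float = 2.0e5) -> ContactMatrix:
    """Replace far-from-diagonal entries by their aligned block means.

    Pairs separated by more than ``genomic_cutoff`` are averaged within
    aligned ``block_bp`` × ``block_bp`` blocks; nearer pairs pass through
    unchanged. Idempotent, symmetry- and block-mass-preserving.
    """
    bs = matrix.bins.bin_size
    if block_bp < bs:
        raise ValueError(f"block ({block_bp}) smaller than one bin ({bs})")
    if block_bp % bs != 0:
        raise ValueError(f"block ({block_bp}) not a multiple of bin size ({bs})")
    if genomic_cutoff < block_bp:
        raise ValueError("genomic_cutoff must be >= block_bp")
    C = matrix.dense().copy()
    n = matrix.n_bins
    r = int(block_bp // bs)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]) * bs
    far = sep > genomic_cutoff
    if far.any():
        blk = idx // r
        nb = int(blk[-1]) + 1
        flat_blk = blk[:, None] * nb + blk[None, :]
        sums = np.bincount(flat_blk[far], weights=C[far], minlength=nb * nb)
        cnts = np.bincount(flat_blk[far], minlength=nb * nb)
        means = np.divide(sums, cnts, out=np.zeros_like(sums), where=cnts > 0)
        C[far] = means[flat_blk[far]]
    return ContactMatrix(matrix.bins, C, validate=False)


@dataclass
class RestraintSet:
    """Pairwise distance targets plus bonded equilibrium distances.

    ``i < j`` index bead pairs; ``target`` in μm; ``weight`` is the priority
    weight 1/target² (short restraints dominate); ``d_eq[k]`` is the bond
    length between beads k and k+1.
    """

    i: np.ndarray
    j: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    d_eq: np.ndarray
    bins: BinTable

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.target = np.asarray(self.target, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.d_eq = np.asarray(self.d_eq, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.target) == len(self.weight)):
            raise ValidationError("restraint arrays have unequal lengths")
        if np.any(self.i >= self.j):
            raise ValidationError("restraints must have i < j")
        if np.any(self.target <= 0):
            raise ValidationError("restraint targets must be positive")
        if np.any(~np.isfinite(self.weight)) or np.any(self.weight <= 0):
            raise ValidationError("restraint weights must be finite and positive")
        if len(self.d_eq) != self.bins.n_bins - 1:
            raise ValidationError("need one d_eq per consecutive bead pair")
        if np.any(self.d_eq <= 0):
            raise ValidationError("bond equilibrium distances must be positive")

    @property
    def n_restraints(self) -> int:
        return len(self.i)

    @property
    def n_beads(self) -> int:
        return self.bins.n_bins

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#chrom={self.bins.chrom}\n#bin_size={self.bins.bin_size}\n")
            fh.write(f"#n_bins={self.bins.n_bins}\n")
            fh.write("#d_eq=" + ",".join(f"{d:.17g}" for d in self.d_eq) + "\n")
            fh.write("#i\tj\ttarget_um\tweight\n")
            for i, j, t, w in zip(self.i, self.j, self.target, self.weight):
                fh.write(f"{i}\t{j}\t{t:.17g}\t{w:.17g}\n")

    @classmethod
    def load(cls, path) -> "RestraintSet":
        meta, rows = {}, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "=" in line:
                        k, _, v = line[1:].partition("=")
                        meta[k.strip()] = v.strip()
                    continue
                a, b, t, w = line.split("\t")
                rows.append((int(a), int(b), float(t), float(w)))
        bins = BinTable(meta["chrom"], int(meta["bin_size"]), int(meta["n_bins"]))
        d_eq = np.array([float(x) for x in meta["d_eq"].split(",")])
        if rows:
            i, j, t, w = (np.array(x) for x in zip(*rows))
        else:
            i = j = np.empty(0, dtype=np.int64)
            t = w = np.empty(0)
        return cls(i, j, t, w, d_eq, bins)


def build_restraints(matrix: ContactMatrix, model: ScalingModel, *,
                     min_contact: float = 0.0,
                     curve: DecayCurve | None = None) -> RestraintSet:
    """One distance restraint per pair with contact above ``min_contact``.

    ``matrix`` should already be long-range smoothed. Bond equilibrium
    distances come from the first off-diagonal through the same mapping;
    zero-contact consecutive pairs fall back to the scaling-law distance at
    one bin size (chain continuity must never break).
    """
    if curve is None:
        curve = decay_curve(matrix)
    C = matrix.dense()
    n = matrix.n_bins
    iu, ju = np.triu_indices(n, k=1)
    vals = C[iu, ju]
    keep = vals > max(min_contact, 0.0)
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    target = contact_to_distance(vals, curve, model) if len(vals) else np.empty(0)
    weight = 1.0 / target**2 if len(vals) else np.empty(0)

    adj = np.diagonal(C, 1).copy()
    d_eq = np.empty(n - 1)
    pos = adj > 0
    if pos.any():
        d_eq[pos] = contact_to_distance(adj[pos], curve, model)
    if (~pos).any():
        logger.warning("%d consecutive pairs with zero contact: using scaling-law bond length",
                       int((~pos).sum()))
        d_eq[~pos] = model.distance(matrix.bins.bin_size)
    return RestraintSet(iu, ju, target, weight, d_eq, matrix.bins)
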