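"""Velocity-assisted gradient optimization of bead-spring conformations.

Two potentials drive the optimization: a harmonic bond term between
consecutive beads, and an asymmetric restraint term per restrained pair —
quadratic above the target distance, logarithmic-wall below it (zero value
and slope at the target, divergent toward zero separation). Positions follow
an overdamped descent with an adaptive timestep inversely proportional to
the maximum force; random velocity kicks are injected periodically to escape
local traps and are annealed away over the final stretch of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hic3d.errors import Hic3dError, ValidationError
from hic3d.io import BinTable
from hic3d.restraints import RestraintSet

logger = logging.getLogger(__name__)

_D_GUARD_FRAC = 1e-6  # distances below this fraction of the target are clamped


class OptimizationDivergence(Hic3dError):
    """Raised when the restraint energy rises persistently during a run."""


@dataclass
class Conformation:
    """Per-bead 3D coordinates (μm) for one chromosome model."""

    coords: np.ndarray
    bins: BinTable
    seed: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.bins.n_bins, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} != ({self.bins.n_bins}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("conformation has non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return self.bins.n_bins

    def radius_of_gyration(self) -> float:
        centered = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((centered**2).sum(axis=1).mean()))

    def pairwise_distances(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        diff = self.coords[i] - self.coords[j]
        return np.sqrt((diff**2).sum(axis=1))

    def distance_matrix(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coords))


@dataclass
class OptimizerParams:
    """Knobs of the optimization scheme.

    ``step_scale`` is the largest per-step displacement the gradient term may
    produce (μm); ``None`` means 0.1 × mean bond length, resolved at run
    time. ``kick_scale`` multiplies the violation-adaptive amplitude of the
    periodic random velocity kicks (kicks vanish as restraints are met).
    """

    k_bond: float = 50.0
    k_restraint: float = 1.0
    n_steps: int = 80_000
    velocity_resample_interval: int = 100
    kick_scale: float = 0.05
    kick_friction: float = 0.9
    step_scale: float | None = None
    max_displacement: float | None = None
    dt_min: float = 1e-9
    dt_max: float | None = None  # None: 1 / (max per-bead pair stiffness)
    checkpoint_interval: int | None = None
    quench_fraction: float = 0.05  # final fraction of steps run without kicks
    use_numba: bool = True

    def __post_init__(self):
        if self.k_bond <= 0 or self.k_restraint <= 0:
            raise ValidationError("stiffness scales must be positive")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.velocity_resample_interval < 1:
            raise ValidationError("velocity_resample_interval must be >= 1")


@dataclass
class OptimizationResult:
    conformation: Conformation
    checkpoint_steps: np.ndarray
    checkpoint_violation: np.ndarray  # total weighted restraint energy
    initial_violation: float
    final_violation: float
    n_steps: int
    late_drift_rms: float = np.nan  # RMS coordinate change over the final 5%


# ---------------------------------------------------------------------------
# Potentials (scalar/vectorized reference forms)


def bond_energy(d, d_eq, k_b):
    """½ k_b (d − d_eq)²; minimum 0 at d = d_eq."""
    d = np.asarray(d, dtype=float)
    return 0.5 * k_b * (d - d_eq) ** 2


def restraint_energy(d, d_bar, k1, k2):
    """Asymmetric restraint potential.

    Quadratic ``k1 (d − d̄)²`` for d ≥ d̄; soft wall
    ``k2 (d − d̄·ln(d/d̄) − d̄)`` for d < d̄ — zero value and slope at d̄,
    divergent toward d = 0 (clamped at a numerical guard).
    """
    d = np.asarray(d, dtype=float)
    d_bar = np.asarray(d_bar, dtype=float)
    d_eff = np.maximum(d, _D_GUARD_FRAC * d_bar)
    upper = k1 * (d - d_bar) ** 2
    lower = k2 * (d_eff - d_bar * np.log(d_eff / d_bar) - d_bar)
    return np.where(d >= d_bar, upper, lower)


def _restraint_dEdd(d, d_bar, k1, k2):
    d_eff = np.maximum(d, _D_GUARD_FRAC * d_bar)
    return np.where(d >= d_bar, 2.0 * k1 * (d - d_bar), k2 * (1.0 - d_bar / d_eff))


# ---------------------------------------------------------------------------
# Pair bookkeeping and gradients


class _PairSystem:
    """Precomputed flat pair arrays: bonds first, then restraints."""

    def __init__(self, restraints: RestraintSet, params: OptimizerParams):
        n = restraints.n_beads
        bi = np.arange(n - 1, dtype=np.int64)
        self.pi = np.concatenate([bi, restraints.i])
        self.pj = np.concatenate([bi + 1, restraints.j])
        self.ref = np.concatenate([restraints.d_eq, restraints.target])
        self.n_bonds = n - 1
        self.n_beads = n
        self.k_bond = params.k_bond
        # per-restraint stiffness: global scale × priority weight
        self.kw = np.concatenate([
            np.zeros(self.n_bonds),
            params.k_restraint * restraints.weight,
        ])
        self.is_bond = np.zeros(len(self.pi), dtype=bool)
        self.is_bond[: self.n_bonds] = True

    def pair_distances(self, coords: np.ndarray) -> np.ndarray:
        diff = coords[self.pi] - coords[self.pj]
        return np.sqrt((diff**2).sum(axis=1))

    def energy_terms(self, coords: np.ndarray) -> tuple[float, float]:
        """(bond energy, restraint violation energy)."""
        d = self.pair_distances(coords)
        e_bond = float(bond_energy(d[: self.n_bonds], self.ref[: self.n_bonds],
                                   self.k_bond).sum())
        e_res = float(restraint_energy(d[self.n_bonds:], self.ref[self.n_bonds:],
                                       self.kw[self.n_bonds:],
                                       self.kw[self.n_bonds:]).sum())
        return e_bond, e_res

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        if _numba_grad is not None and getattr(self, "_use_numba", True):
            return _numba_grad(coords, self.pi, self.pj, self.ref, self.kw,
                               self.is_bond, self.k_bond)
        return self._gradient_numpy(coords)

    def _gradient_numpy(self, coords: np.ndarray) -> np.ndarray:
        diff = coords[self.pi] - coords[self.pj]
        d = np.sqrt((diff**2).sum(axis=1))
        d_safe = np.maximum(d, 1e-12)
        dEdd = np.empty_like(d)
        nb = self.n_bonds
        dEdd[:nb] = self.k_bond * (d[:nb] - self.ref[:nb])
        dEdd[nb:] = _restraint_dEdd(d[nb:], self.ref[nb:], self.kw[nb:], self.kw[nb:])
        fpair = (dEdd / d_safe)[:, None] * diff
        grad = np.zeros_like(coords)
        n = self.n_beads
        for ax in range(3):
            grad[:, ax] += np.bincount(self.pi, weights=fpair[:, ax], minlength=n)
            grad[:, ax] -= np.bincount(self.pj, weights=fpair[:, ax], minlength=n)
        if not np.all(np.isfinite(grad)):
            bad = int(np.argmax(~np.isfinite(fpair).all(axis=1)))
            raise Hic3dError(
                f"non-finite force on pair ({self.pi[bad]}, {self.pj[bad]})"
            )
        return grad


try:  # optional compiled kernel; results match the numpy path to rounding
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _numba_grad_kernel(coords, pi, pj, ref, kw, is_bond, k_bond, grad):
        for p in range(pi.shape[0]):
            i, j = pi[p], pj[p]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d = (dx * dx + dy * dy + dz * dz) ** 0.5
            r = ref[p]
            if is_bond[p]:
                dEdd = k_bond * (d - r)
            elif d >= r:
                dEdd = 2.0 * kw[p] * (d - r)
            else:
                d_eff = d if d > _D_GUARD_FRAC * r else _D_GUARD_FRAC * r
                dEdd = kw[p] * (1.0 - r / d_eff)
            scale = dEdd / (d if d > 1e-12 else 1e-12)
            fx, fy, fz = scale * dx, scale * dy, scale * dz
            grad[i, 0] += fx
            grad[i, 1] += fy
            grad[i, 2] += fz
            grad[j, 0] -= fx
            grad[j, 1] -= fy
            grad[j, 2] -= fz

    def _numba_grad(coords, pi, pj, ref, kw, is_bond, k_bond):
        grad = np.zeros_like(coords)
        _numba_grad_kernel(coords, pi, pj, ref, kw, is_bond, k_bond, grad)
        if not np.all(np.isfinite(grad)):
            raise Hic3dError("non-finite force encountered")
        return grad

except Exception:  # pragma: no cover - numba genuinely absent
    _numba_grad = None


def total_gradient(conf: Conformation, restraints: RestraintSet,
                   params: OptimizerParams | None = None) -> np.ndarray:
    """Analytic gradient of the total energy w.r.t. every bead coordinate."""
    params = params or OptimizerParams()
    system = _PairSystem(restraints, params)
    system._use_numba = params.use_numba
    return system.gradient(conf.coords)


def total_energy(conf: Conformation, restraints: RestraintSet,
                 params: OptimizerParams | None = None) -> float:
    params = params or OptimizerParams()
    system = _PairSystem(restraints, params)
    return sum(system.energy_terms(conf.coords))


def adaptive_step(forces: np.ndarray, step_scale: float,
                  dt_min: float = 1e-9, dt_max: float = 1e3) -> float:
    """Timestep inversely proportional to the max per-bead force magnitude."""
    fmax = float(np.sqrt((np.asarray(forces) ** 2).sum(axis=-1)).max()) \
        if np.asarray(forces).size else 0.0
    if fmax == 0.0:
        return dt_max
    return float(np.clip(step_scale / fmax, dt_min, dt_max))


# ---------------------------------------------------------------------------
# Initial structures


def random_coil(bins: BinTable, step_um: float, radius_um: float,
                seed: int) -> Conformation:
    """Gaussian-direction random walk with fixed step, reflected into a sphere."""
    rng = np.random.default_rng(seed)
    n = bins.n_bins
    coords = np.zeros((n, 3))
    for k in range(1, n):
        step = rng.normal(size=3)
        step *= step_um / np.linalg.norm(step)
        nxt = coords[k - 1] + step
        r = np.linalg.norm(nxt)
        if r > radius_um:  # fold back inside the confining sphere
            nxt *= (2 * radius_um - r) / r
        coords[k] = nxt
    return Conformation(coords, bins, seed=seed)


# ---------------------------------------------------------------------------
# Main optimization loop


def optimize(initial: Conformation, restraints: RestraintSet,
             params: OptimizerParams | None = None, seed: int = 0) -> OptimizationResult:
    """Minimize bond + restraint energy from ``initial`` by kick-assisted descent.

    Deterministic for a fixed seed. Velocity kicks scale with the current
    violation level (an exactly satisfied conformation is a fixed point) and
    are switched off over the final ``quench_fraction`` of steps.
    """
    params = params or OptimizerParams()
    if restraints.n_beads != initial.n_beads:
        raise ValidationError("restraint set size does not match conformation")
    system = _PairSystem(restraints, params)
    system._use_numba = params.use_numba
    rng = np.random.default_rng(seed)

    mean_deq = float(restraints.d_eq.mean())
    step_scale = params.step_scale if params.step_scale is not None else 0.1 * mean_deq
    max_disp = (params.max_displacement if params.max_displacement is not None
                else 0.5 * mean_deq)
    dt_max = params.dt_max
    if dt_max is None:
        # stability bound for the late plain-descent phase: dt below the
        # inverse of the stiffest per-bead curvature (Gershgorin-style)
        stiff = np.concatenate([np.full(system.n_bonds, params.k_bond),
                                2.0 * system.kw[system.n_bonds:]])
        row = np.bincount(system.pi, weights=stiff, minlength=system.n_beads)
        row += np.bincount(system.pj, weights=stiff, minlength=system.n_beads)
        dt_max = 1.0 / max(float(row.max()), 1e-12)
    ckpt = params.checkpoint_interval or max(1, params.n_steps // 50)
    n_res = max(1, restraints.n_restraints)
    quench_start = params.n_steps - int(np.ceil(params.quench_fraction * params.n_steps))

    x = initial.coords.copy()
    v = np.zeros_like(x)
    _, e0 = system.energy_terms(x)
    best_x, best_e = x.copy(), e0
    steps_log, viol_log = [0], [e0]
    bad_streak = 0

    quench_snapshot = x.copy() if quench_start == 0 else None
    for step in range(params.n_steps):
        if step == quench_start:
            quench_snapshot = x.copy()
        kicking = step < quench_start
        if kicking and step % params.velocity_resample_interval == 0:
            _, e_res = system.energy_terms(x)
            sigma = params.kick_scale * mean_deq * np.sqrt(e_res / n_res)
            v = rng.normal(0.0, 1.0, size=x.shape) * sigma
        grad = system.gradient(x)
        dt = adaptive_step(-grad, step_scale, params.dt_min, dt_max)
        disp = v - dt * grad
        norms = np.sqrt((disp**2).sum(axis=1))
        over = norms > max_disp
        if over.any():
            disp[over] *= (max_disp / norms[over])[:, None]
        x += disp
        v *= params.kick_friction

        if (step + 1) % ckpt == 0 or step + 1 == params.n_steps:
            _, e_res = system.energy_terms(x)
            steps_log.append(step + 1)
            viol_log.append(e_res)
            if e_res < best_e:
                best_e, best_x = e_res, x.copy()
            bad_streak = bad_streak + 1 if e_res > 5.0 * max(e0, 1e-300) else 0
            if bad_streak >= 5 and e0 > 0:
                raise OptimizationDivergence(
                    f"restraint energy rose to {e_res:.3g} (initial {e0:.3g}) "
                    f"for {bad_streak} consecutive checkpoints at step {step + 1}"
                )

    _, e_final = system.energy_terms(x)
    drift = np.nan
    if quench_snapshot is not None:
        drift = float(np.sqrt(((x - quench_snapshot) ** 2).sum(axis=1).mean()))
    if e_final > e0:  # guarantee the no-worse-than-start contract
        x, e_final = best_x, best_e
    conf = Conformation(x, initial.bins, seed=seed)
    return OptimizationResult(conf, np.array(steps_log), np.array(viol_log),
                              e0, e_final, params.n_steps, late_drift_rms=drift)


def generate_ensemble(restraints: RestraintSet, params: OptimizerParams | None = None,
                      n_models: int = 10, base_seed: int = 0,
                      coil_radius_um: float | None = None) -> list[Conformation]:
    """Optimize ``n_models`` conformations from independent random coils.

    Model ``k`` uses seed ``base_seed + k`` for both its coil and its run, so
    results are reproducible and order-independent. Diverged models are
    dropped with a warning; more than 20% failures is an error.
    """
    if n_models < 1:
        raise ValidationError("n_models must be >= 1")
    params = params or OptimizerParams()
    if coil_radius_um is None:
        from hic3d.restraints import ScalingModel

        coil_radius_um = ScalingModel().distance(restraints.bins.total_bp)
    mean_deq = float(restraints.d_eq.mean())
    models: list[Conformation] = []
    failures = 0
    for k in range(n_models):
        seed = base_seed + k
        coil = random_coil(restraints.bins, mean_deq, coil_radius_um, seed)
        try:
            result = optimize(coil, restraints, params, seed=seed)
        except OptimizationDivergence as exc:
            logger.warning("model %d (seed %d) diverged: %s", k, seed, exc)
            failures += 1
            continue
        models.append(result.conformation)
    if failures > 0.2 * n_models:
        raise Hic3dError(f"{failures}/{n_models} models diverged")
    return models
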