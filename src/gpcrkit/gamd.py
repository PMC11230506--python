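"""Gaussian-accelerated Langevin dynamics.

The boost potential is harmonic below a threshold energy E:

    dV(V) = 1/2 k (E - V)^2   for V < E,   0 otherwise,

with E and k chosen automatically from running potential statistics so that
(i) boosting preserves the energy ordering, (ii) it smooths the surface and
(iii) the boost SD stays below a user limit sigma0 so that second-order
cumulant reweighting remains accurate.  Two independent boosts may be applied
("dual" mode): one to the soft conformational term (the dihedral-term
analogue) and one to the total potential.

Dynamics use the BAOAB splitting of Langevin dynamics, which gives accurate
configurational sampling near the stability limit.  The boost enters as a
force rescaling: modified force = lambda * F with lambda = 1 - k (E - V).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB, KCAL_PER_MOL_TO_AMU_A2_PS2
from .potentials import PotentialModel

__all__ = [
    "PotentialStats",
    "BoostParams",
    "GaMDProtocol",
    "GaMDTrajectory",
    "RunningStats",
    "update_stats",
    "boost_energy",
    "boost_force_scale",
    "select_boost_params",
    "run_stage",
    "run_protocol",
    "count_well_crossings",
]


# ---------------------------------------------------------------------------
# potential statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PotentialStats:
    """Running min/max/mean/SD of a potential-energy stream (kcal/mol).

    ``sigma_v`` is the population SD (divide by n), matching a running-moment
    implementation.
    """

    vmax: float
    vmin: float
    vavg: float
    sigma_v: float
    count: int

    def __post_init__(self):
        if self.count >= 1:
            if not (self.vmin <= self.vavg <= self.vmax):
                raise ValueError("require vmin <= vavg <= vmax")
            if self.sigma_v < 0:
                raise ValueError("sigma_v must be >= 0")


class RunningStats:
    """Welford accumulator producing a `PotentialStats` snapshot."""

    def __init__(self):
        self.n = 0
        self._mean = 0.0
        self._m2 = 0.0
        self._vmin = np.inf
        self._vmax = -np.inf

    def add(self, v: float) -> None:
        self.n += 1
        d = v - self._mean
        self._mean += d / self.n
        self._m2 += d * (v - self._mean)
        if v < self._vmin:
            self._vmin = v
        if v > self._vmax:
            self._vmax = v

    def add_many(self, vs) -> None:
        for v in np.asarray(vs, dtype=float).ravel():
            self.add(float(v))

    def snapshot(self) -> PotentialStats:
        if self.n < 1:
            raise ValueError("no samples accumulated")
        return PotentialStats(self._vmax, self._vmin, self._mean,
                              float(np.sqrt(self._m2 / self.n)), self.n)


def update_stats(stats: PotentialStats | None, v: float) -> PotentialStats:
    """Pure-functional single-value update of running potential statistics."""
    if stats is None:
        return PotentialStats(v, v, v, 0.0, 1)
    n = stats.count + 1
    mean = stats.vavg + (v - stats.vavg) / n
    # recover m2 from population SD, then Welford-update
    m2 = stats.sigma_v**2 * stats.count + (v - stats.vavg) * (v - mean)
    return PotentialStats(max(stats.vmax, v), min(stats.vmin, v), mean,
                          float(np.sqrt(max(m2, 0.0) / n)), n)


# ---------------------------------------------------------------------------
# boost parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoostParams:
    """Acceleration parameters for one boosted energy term.

    E (kcal/mol) is the threshold energy, k (mol/kcal) the harmonic force
    constant, and k0 = k * (Vmax - Vmin) the dimensionless strength in (0, 1].
    """

    e: float
    k: float
    k0: float
    bound: str = "lower"          # "lower" or "upper"
    term: str = "total"           # "total" or "soft" (dihedral analogue)

    def __post_init__(self):
        if not (0.0 < self.k0 <= 1.0):
            raise ValueError("require 0 < k0 <= 1")
        if self.bound not in ("lower", "upper"):
            raise ValueError("bound must be 'lower' or 'upper'")


def boost_energy(v: float, params: BoostParams) -> float:
    """Harmonic boost dV = 1/2 k (E - V)^2 below threshold, 0 at/above it."""
    if v >= params.e:
        return 0.0
    d = params.e - v
    return 0.5 * params.k * d * d


def boost_force_scale(v: float, params: BoostParams) -> float:
    """Force rescaling lambda = 1 - k (E - V) for V < E, else 1."""
    if v >= params.e:
        return 1.0
    return 1.0 - params.k * (params.e - v)


def select_boost_params(stats: PotentialStats, sigma0: float,
                        bound: str = "lower", term: str = "total") -> BoostParams:
    """Choose (E, k, k0) from potential statistics.

    Lower bound: E = Vmax and k0 = min(1, (sigma0/sigmaV) * (Vmax-Vmin)/(Vmax-Vavg)).
    Upper bound: k0'' = (1 - sigma0/sigmaV) * (Vmax-Vmin)/(Vavg-Vmin) with
    E = Vmin + 1/k, accepted iff 0 < k0'' <= 1; otherwise falls back to the
    lower-bound formula.  Always k = k0 / (Vmax - Vmin).
    """
    if stats.count < 2:
        raise ValueError("need at least 2 samples to select boost parameters")
    spread = stats.vmax - stats.vmin
    if spread <= 0:
        raise ValueError("degenerate statistics: Vmax == Vmin")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")

    if stats.sigma_v == 0.0:
        import warnings

        warnings.warn("sigma_V is zero; capping k0 at 1", stacklevel=2)
        k0 = 1.0
        chosen = "lower"
    elif bound == "upper":
        k0pp = (1.0 - sigma0 / stats.sigma_v) * spread / max(stats.vavg - stats.vmin, 1e-300)
        if 0.0 < k0pp <= 1.0:
            k0 = k0pp
            chosen = "upper"
        else:
            k0 = min(1.0, (sigma0 / stats.sigma_v) * spread / max(stats.vmax - stats.vavg, 1e-300))
            chosen = "lower"
    elif bound == "lower":
        k0 = min(1.0, (sigma0 / stats.sigma_v) * spread / max(stats.vmax - stats.vavg, 1e-300))
        chosen = "lower"
    else:
        raise ValueError("bound must be 'lower' or 'upper'")

    k = k0 / spread
    e = stats.vmax if chosen == "lower" else stats.vmin + 1.0 / k
    return BoostParams(e=e, k=k, k0=k0, bound=chosen, term=term)


def predicted_boost_sd(params: BoostParams, stats: PotentialStats) -> float:
    """Linearized boost SD, k * (E - Vavg) * sigma_V (kcal/mol)."""
    return params.k * (params.e - stats.vavg) * stats.sigma_v


# ---------------------------------------------------------------------------
# protocol / trajectory containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaMDProtocol:
    """Staged cMD -> boosted equilibration -> production protocol.

    Stage lengths are in integration steps.  ``stats_cadence`` is the
    parameter re-selection interval during equilibration (statistics
    themselves accumulate every step, cumulatively across stages).
    ``mode`` selects no boost, a single total-potential boost, or the dual
    soft+total boost.
    """

    dt: float = 0.01                       # ps
    friction: float = 1.0                  # ps^-1
    temperature: float = DEFAULT_TEMPERATURE
    n_cmd: int = 10_000
    n_equil: int = 20_000
    n_production: int = 50_000
    stats_cadence: int = 10_000
    sigma0_total: float = 6.0              # kcal/mol
    sigma0_soft: float = 6.0
    mode: str = "single"                   # "none" | "single" | "dual"
    bound: str = "lower"
    replicas: int = 1
    save_every: int = 10

    def __post_init__(self):
        if min(self.n_cmd, self.n_equil, self.n_production) < 0:
            raise ValueError("stage lengths must be >= 0")
        if self.stats_cadence < 1:
            raise ValueError("stats cadence must be >= 1")
        if self.sigma0_total <= 0 or self.sigma0_soft <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.mode not in ("none", "single", "dual"):
            raise ValueError("mode must be none|single|dual")


@dataclass
class TrajectoryFragment:
    """Frames saved from one stage (or one production replica)."""

    times: np.ndarray                      # ps
    coords: np.ndarray                     # (n_frames, ndim)
    v_soft: np.ndarray
    v_total: np.ndarray
    dv_soft: np.ndarray
    dv_total: np.ndarray
    stage: str = ""
    replica: int = 0

    @property
    def dv(self) -> np.ndarray:
        """Total boost per frame (soft + total boosts), for reweighting."""
        return self.dv_soft + self.dv_total

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class GaMDTrajectory:
    """Full protocol output: stage fragments plus final boost parameters."""

    cmd: TrajectoryFragment | None
    equil: TrajectoryFragment | None
    production: list[TrajectoryFragment]
    protocol: GaMDProtocol
    final_params: dict[str, BoostParams | None]
    final_stats: dict[str, PotentialStats | None] = field(default_factory=dict)

    def combined_production(self) -> TrajectoryFragment:
        """All production replicas concatenated for joint analysis."""
        frs = self.production
        if not frs:
            raise ValueError("no production frames")
        return TrajectoryFragment(
            times=np.concatenate([f.times for f in frs]),
            coords=np.concatenate([f.coords for f in frs]),
            v_soft=np.concatenate([f.v_soft for f in frs]),
            v_total=np.concatenate([f.v_total for f in frs]),
            dv_soft=np.concatenate([f.dv_soft for f in frs]),
            dv_total=np.concatenate([f.dv_total for f in frs]),
            stage="production",
            replica=-1,
        )


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def _draw_velocities(model: PotentialModel, temperature: float, rng) -> np.ndarray:
    sd = np.sqrt(KB * temperature * KCAL_PER_MOL_TO_AMU_A2_PS2 / model.masses)
    return sd * rng.standard_normal(model.ndim)


def run_stage(model: PotentialModel, x: np.ndarray, v: np.ndarray,
              params: dict[str, BoostParams | None] | None, nsteps: int,
              protocol: GaMDProtocol, rng,
              stats_soft: RunningStats | None = None,
              stats_total: RunningStats | None = None,
              reselect_every: int | None = None,
              stage_name: str = "cmd", replica: int = 0,
              ) -> tuple[TrajectoryFragment, np.ndarray, np.ndarray, dict]:
    """Integrate ``nsteps`` of BAOAB Langevin dynamics with optional boost.

    ``params`` maps ``{"soft": BoostParams|None, "total": BoostParams|None}``;
    ``None`` (or all-None) is conventional MD.  If ``reselect_every`` is set,
    parameters are re-selected from the cumulative statistics at that cadence
    (equilibration stage).  Returns the saved fragment, final (x, v) and the
    final parameter dict.

    Stability: ``dt`` must resolve the stiffest mode; the caller is expected
    to keep dt * omega_max < ~0.5 (checked crudely against non-finite energy,
    which aborts with the offending frame index).
    """
    x = np.array(x, dtype=float)
    v = np.array(v, dtype=float)
    dt = protocol.dt
    kbt_dyn = KB * protocol.temperature * KCAL_PER_MOL_TO_AMU_A2_PS2
    c1 = np.exp(-protocol.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kbt_dyn / model.masses)
    inv_m = KCAL_PER_MOL_TO_AMU_A2_PS2 / model.masses

    params = dict(params or {})
    p_soft = params.get("soft")
    p_total = params.get("total")

    n_save = nsteps // protocol.save_every
    out_t = np.empty(n_save)
    out_x = np.empty((n_save, model.ndim))
    out_vs = np.empty(n_save)
    out_vt = np.empty(n_save)
    out_dvs = np.empty(n_save)
    out_dvt = np.empty(n_save)

    noise = rng.standard_normal((nsteps, model.ndim))

    vs, vr, fsoft, frest = model.energy_force(x)
    vtot = vs + vr
    isave = 0
    for step in range(nsteps):
        # effective force with boost rescaling
        if p_total is not None or p_soft is not None:
            lam_t = boost_force_scale(vtot, p_total) if p_total is not None else 1.0
            f = lam_t * (fsoft + frest)
            if p_soft is not None:
                f = f + (boost_force_scale(vs, p_soft) - 1.0) * fsoft
        else:
            f = fsoft + frest

        v += 0.5 * dt * f * inv_m
        x += 0.5 * dt * v
        v = c1 * v + c2 * noise[step]
        x += 0.5 * dt * v
        vs, vr, fsoft, frest = model.energy_force(x)
        vtot = vs + vr
        if not np.isfinite(vtot):
            raise FloatingPointError(
                f"non-finite energy at step {step} of stage '{stage_name}'")
        if p_total is not None or p_soft is not None:
            lam_t = boost_force_scale(vtot, p_total) if p_total is not None else 1.0
            f = lam_t * (fsoft + frest)
            if p_soft is not None:
                f = f + (boost_force_scale(vs, p_soft) - 1.0) * fsoft
        else:
            f = fsoft + frest
        v += 0.5 * dt * f * inv_m

        if stats_total is not None:
            stats_total.add(vtot)
        if stats_soft is not None:
            stats_soft.add(vs)

        if reselect_every and (step + 1) % reselect_every == 0:
            if p_total is not None and stats_total is not None:
                p_total = select_boost_params(stats_total.snapshot(),
                                              protocol.sigma0_total,
                                              protocol.bound, term="total")
            if p_soft is not None and stats_soft is not None:
                p_soft = select_boost_params(stats_soft.snapshot(),
                                             protocol.sigma0_soft,
                                             protocol.bound, term="soft")

        if (step + 1) % protocol.save_every == 0:
            out_t[isave] = (step + 1) * dt
            out_x[isave] = x
            out_vs[isave] = vs
            out_vt[isave] = vtot
            out_dvs[isave] = boost_energy(vs, p_soft) if p_soft is not None else 0.0
            out_dvt[isave] = boost_energy(vtot, p_total) if p_total is not None else 0.0
            isave += 1

    frag = TrajectoryFragment(out_t, out_x, out_vs, out_vt, out_dvs, out_dvt,
                              stage=stage_name, replica=replica)
    return frag, x, v, {"soft": p_soft, "total": p_total}


def run_protocol(model: PotentialModel, protocol: GaMDProtocol,
                 seed: int = 0) -> GaMDTrajectory:
    """Run the staged protocol: cMD statistics collection, boosted
    equilibration with cumulative parameter re-selection, then fixed-parameter
    production replicas differing only in their velocity seeds.

    ``mode="none"`` reduces exactly to conventional Langevin dynamics (one
    continuous unboosted run with the same noise stream).
    """
    ss = np.random.SeedSequence(seed)
    child_main, *child_reps = ss.spawn(1 + max(protocol.replicas, 1))
    rng = np.random.default_rng(child_main)

    x = model.default_start.copy()
    v = _draw_velocities(model, protocol.temperature, rng)

    if protocol.mode == "none":
        total = protocol.n_cmd + protocol.n_equil + protocol.n_production
        frag, x, v, _ = run_stage(model, x, v, None, total, protocol, rng,
                                  stage_name="cmd")
        return GaMDTrajectory(cmd=frag, equil=None, production=[frag],
                              protocol=protocol,
                              final_params={"soft": None, "total": None},
                              final_stats={"soft": None, "total": None})

    if protocol.n_cmd == 0:
        raise ValueError("boosted protocol requires a non-empty cMD stage for statistics")

    want_soft = protocol.mode == "dual"
    stats_total = RunningStats()
    stats_soft = RunningStats() if want_soft else None

    cmd_frag, x, v, _ = run_stage(model, x, v, None, protocol.n_cmd, protocol, rng,
                                  stats_soft=stats_soft, stats_total=stats_total,
                                  stage_name="cmd")

    params = {
        "total": select_boost_params(stats_total.snapshot(), protocol.sigma0_total,
                                     protocol.bound, term="total"),
        "soft": (select_boost_params(stats_soft.snapshot(), protocol.sigma0_soft,
                                     protocol.bound, term="soft")
                 if want_soft else None),
    }

    equil_frag = None
    if protocol.n_equil > 0:
        equil_frag, x, v, params = run_stage(
            model, x, v, params, protocol.n_equil, protocol, rng,
            stats_soft=stats_soft, stats_total=stats_total,
            reselect_every=protocol.stats_cadence, stage_name="equil")

    production = []
    for irep in range(max(protocol.replicas, 1)):
        rep_rng = np.random.default_rng(child_reps[irep])
        v_rep = _draw_velocities(model, protocol.temperature, rep_rng)
        frag, _, _, _ = run_stage(model, x.copy(), v_rep, params,
                                  protocol.n_production, protocol, rep_rng,
                                  stage_name="production", replica=irep)
        production.append(frag)

    return GaMDTrajectory(cmd=cmd_frag, equil=equil_frag, production=production,
                          protocol=protocol, final_params=params,
                          final_stats={"total": stats_total.snapshot(),
                                       "soft": (stats_soft.snapshot()
                                                if stats_soft is not None else None)})


# ---------------------------------------------------------------------------
# analysis helper
# ---------------------------------------------------------------------------


def count_well_crossings(x: np.ndarray, b: float, frac: float = 0.5) -> int:
    """Count transitions between the wells at -b and +b of a double well.

    Uses hysteresis: a crossing is registered only when the coordinate passes
    from below ``-frac*b`` to above ``+frac*b`` or vice versa.
    """
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = -frac * b, frac * b
    state = 0
    crossings = 0
    for q in x:
        if q <= lo:
            if state == 1:
                crossings += 1
            state = -1
        elif q >= hi:
            if state == -1:
                crossings += 1
            state = 1
    return crossings
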