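"""Two-site nucleotide binding/exchange kinetics.

Formalizes the two-step binding picture for a receptor-coupled G protein:
a nucleotide first binds a peripheral low-affinity site (site 1), then
relocates to the canonical binding pocket (site 2) once the G protein's
helical domain opens enough to admit it.  In the intermediate-state complex
that relocation is restricted; the ``access2`` scalar in [0, 1] gates every flux
through the site-2 gate — entry (ktrans) and release (koff2) pass the same
sterically restricted opening (1 = freely accessible, fully activated-like;
small = intermediate-like).  Hydrolysis is irreversible and occurs at
site 2 only.

Scheme (mass action, one nucleotide per protein):

    P + N  <->[kon1/koff1]  P.N(site1)  ->[access2*ktrans]  P.N(site2)
    P.N(site2) ->[access2*koff2] P + N   P.N(site2) ->[khyd] P + N_hydrolyzed

Both a labeled (fluorescent) and an unlabeled nucleotide pool compete for
the same sites; the observed signal is the total site-bound labeled
nucleotide (unit fluorescence gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit
from scipy.stats import f as f_dist

__all__ = [
    "TwoSiteModel",
    "AssayProtocol",
    "KineticTrace",
    "FitResult",
    "simulate_assay",
    "make_binding_trace",
    "fit_association",
    "fit_two_site",
    "exchange_summary",
    "equilibrium_occupancies",
]

# species order in the state vector
_SPECIES = ("L", "U", "P", "P1L", "P1U", "P2L", "P2U", "HL", "HU")


@dataclass(frozen=True)
class TwoSiteModel:
    """Rate constants (s^-1; kon1 in M^-1 s^-1) and starting concentrations (M)."""

    kon1: float
    koff1: float
    ktrans: float = 0.0
    koff2: float = 0.0
    khyd: float = 0.0
    access2: float = 1.0
    protein: float = 0.0
    labeled: float = 0.0
    unlabeled: float = 0.0

    def __post_init__(self):
        for name in ("kon1", "koff1", "ktrans", "koff2", "khyd"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if not 0.0 <= self.access2 <= 1.0:
            raise ValueError("access2 must lie in [0, 1]")
        if min(self.protein, self.labeled, self.unlabeled) < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class AssayProtocol:
    """Timed additions and a sampling grid.

    ``events``: sequence of (time s, species, concentration M) additions,
    species one of "labeled", "unlabeled", "protein".  ``duration``: total
    time (s).  ``n_samples``: points on the uniform sampling grid.
    """

    duration: float
    n_samples: int = 500
    events: tuple = ()

    def __post_init__(self):
        evs = tuple((float(t), str(sp), float(c)) for t, sp, c in self.events)
        if any(c < 0 for _, _, c in evs):
            raise ValueError("event concentrations must be >= 0")
        if list(evs) != sorted(evs, key=lambda e: e[0]):
            raise ValueError("events must be time-ordered")
        object.__setattr__(self, "events", evs)
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_samples)


@dataclass
class KineticTrace:
    """Sampled signal (total site-bound labeled nucleotide) vs time."""

    times: np.ndarray
    signal: np.ndarray
    noise_sd: float = 0.0
    ground_truth: dict = field(default_factory=dict)
    species: np.ndarray | None = None   # (n_samples, 9) full state, noiseless runs


def _rhs(t, y, m: TwoSiteModel):
    L, U, P, P1L, P1U, P2L, P2U, HL, HU = y
    g = m.access2 * m.ktrans
    off2 = m.access2 * m.koff2      # the gate restricts passage both ways
    bindL = m.kon1 * P * L
    bindU = m.kon1 * P * U
    dP1L = bindL - (m.koff1 + g) * P1L
    dP1U = bindU - (m.koff1 + g) * P1U
    dP2L = g * P1L - (off2 + m.khyd) * P2L
    dP2U = g * P1U - (off2 + m.khyd) * P2U
    dL = -bindL + m.koff1 * P1L + off2 * P2L
    dU = -bindU + m.koff1 * P1U + off2 * P2U
    dHL = m.khyd * P2L
    dHU = m.khyd * P2U
    dP = -bindL - bindU + m.koff1 * (P1L + P1U) + (off2 + m.khyd) * (P2L + P2U)
    return [dL, dU, dP, dP1L, dP1U, dP2L, dP2U, dHL, dHU]


def simulate_assay(model: TwoSiteModel, protocol: AssayProtocol) -> KineticTrace:
    """Integrate the mass-action scheme over the protocol (noiseless).

    Events add free species instantaneously.  Each nucleotide pool
    (free + site1 + site2 + hydrolyzed) is conserved between events to
    ~1e-10 relative (tight LSODA tolerances); stiff-integration failures
    surface with the integrator's diagnostics.
    """
    y = np.zeros(9)
    y[0] = model.labeled
    y[1] = model.unlabeled
    y[2] = model.protein
    times = protocol.times
    out = np.empty((times.size, 9))

    # absolute tolerance keyed to the smallest relevant pool so that species
    # far below the dominant concentration are still integrated accurately
    added = {"labeled": 0.0, "unlabeled": 0.0, "protein": 0.0}
    for _, sp, c in protocol.events:
        added[sp] += c
    pools = [model.protein + added["protein"],
             model.labeled + model.unlabeled + added["labeled"] + added["unlabeled"]]
    scale = min((p for p in pools if p > 0), default=1.0)
    atol = 1e-10 * scale

    boundaries = sorted({0.0, protocol.duration,
                         *(t for t, _, _ in protocol.events
                           if 0.0 < t < protocol.duration)})
    events_at = {t: [] for t in boundaries}
    for t, sp, c in protocol.events:
        if t in events_at:
            events_at[t].append((sp, c))
        elif t == 0.0:
            events_at[0.0].append((sp, c))

    filled = np.zeros(times.size, dtype=bool)
    for seg in range(len(boundaries) - 1):
        t0, t1 = boundaries[seg], boundaries[seg + 1]
        for sp, c in events_at.get(t0, ()):
            y[{"labeled": 0, "unlabeled": 1, "protein": 2}[sp]] += c
        sel = (times >= t0) & (times <= t1) & ~filled
        t_eval = times[sel]
        sol = solve_ivp(_rhs, (t0, t1), y, t_eval=t_eval if t_eval.size else None,
                        method="LSODA", rtol=1e-10, atol=atol, args=(model,))
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            out[sel] = sol.y.T
            filled |= sel
        y = sol.y[:, -1] if sol.y.size else y
    out[~filled] = y  # grid points exactly at duration boundary, if any
    signal = out[:, 3] + out[:, 5]
    return KineticTrace(times=times.copy(), signal=signal, noise_sd=0.0,
                        ground_truth={"model": model, "protocol": protocol},
                        species=out)


def make_binding_trace(model: TwoSiteModel, protocol: AssayProtocol,
                       noise_sd: float = 0.0, seed: int | None = 0) -> KineticTrace:
    """Noisy synthetic association trace (additive homoscedastic Gaussian noise,
    SD in signal units); ground truth stored on the trace."""
    tr = simulate_assay(model, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tr = KineticTrace(tr.times, tr.signal + noise_sd * rng.standard_normal(tr.times.size),
                          noise_sd=noise_sd, ground_truth=tr.ground_truth)
    return tr


# ---------------------------------------------------------------------------
# association fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One- or two-phase association fit."""

    form: str
    params: dict
    stderr: dict
    rss: float
    n_points: int
    f_test_p: float | None = None   # two-phase vs nested one-phase

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        y = p["y0"] + p["a1"] * (1 - np.exp(-p["k1"] * t))
        if self.form == "two_phase":
            y = y + p["a2"] * (1 - np.exp(-p["k2"] * t))
        return y


def _one_phase(t, y0, a1, k1):
    return y0 + a1 * (1 - np.exp(-k1 * t))


def _two_phase(t, y0, a1, k1, a2, k2):
    return y0 + a1 * (1 - np.exp(-k1 * t)) + a2 * (1 - np.exp(-k2 * t))


def _fit(f, t, y, p0, bounds, maxfev=20000):
    popt, pcov = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=maxfev)
    resid = f(t, *popt) - y
    return popt, np.sqrt(np.diag(pcov)), float(resid @ resid)


def fit_association(trace: KineticTrace, form: str = "one_phase") -> FitResult:
    """Least-squares fit of y(t) = y0 + A (1 - exp(-k_obs t)) (one phase) or
    the sum of two such exponentials with k_fast > k_slow (two phase).

    The two-phase result carries an F-test p-value against the nested
    one-phase fit.  Multi-start retries precede an explicit failure.
    """
    t = np.asarray(trace.times, dtype=float)
    y_raw = np.asarray(trace.signal, dtype=float)
    npar = 3 if form == "one_phase" else 5
    if t.size < 3 * npar:
        raise ValueError(f"need at least {3 * npar} points for a {form} fit")
    # fit on a unit-scaled signal so tolerances are scale-free
    scale = max(np.ptp(y_raw), 1e-300)
    offset = y_raw.min()
    y = (y_raw - offset) / scale
    span = 1.0
    tscale = max(t[-1], 1e-12)
    env = np.maximum.accumulate(y)
    i63 = int(np.searchsorted(env, y[0] + 0.632 * (env[-1] - y[0])))
    t63 = t[min(max(i63, 1), t.size - 1)]
    k_guess = 1.0 / max(t63, tscale * 1e-6)

    def try_one(starts):
        best = None
        err = None
        for p0 in starts:
            try:
                res = _fit(_one_phase, t, y, p0,
                           ([-np.inf, -np.inf, 0], [np.inf, np.inf, np.inf]))
            except RuntimeError as e:
                err = e
                continue
            if best is None or res[2] < best[2]:
                best = res
        if best is None:
            raise RuntimeError(f"one-phase fit failed to converge: {err}")
        return best

    one_starts = [[y[0], span, k_guess], [y[0], span, k_guess * 10],
                  [y[0], span, k_guess / 10]]
    def _unscale(names, popt, se, rss):
        conv = {"y0": lambda v: offset + v * scale,
                "a1": lambda v: v * scale, "a2": lambda v: v * scale,
                "k1": float, "k2": float}
        sconv = {"y0": lambda v: v * scale, "a1": lambda v: v * scale,
                 "a2": lambda v: v * scale, "k1": float, "k2": float}
        params = {n: float(conv[n](v)) for n, v in zip(names, popt)}
        stderr = {n: float(sconv[n](v)) for n, v in zip(names, se)}
        return params, stderr, rss * scale**2

    popt1, se1, rss1 = try_one(one_starts)
    if form == "one_phase":
        params, stderr, rss = _unscale(("y0", "a1", "k1"), popt1, se1, rss1)
        return FitResult("one_phase", params, stderr, rss, t.size)

    if form != "two_phase":
        raise ValueError("form must be one_phase|two_phase")
    best = None
    err = None
    for split in (5.0, 20.0, 100.0):
        p0 = [popt1[0], 0.7 * popt1[1], popt1[2] * np.sqrt(split),
              0.3 * popt1[1], popt1[2] / np.sqrt(split)]
        try:
            res = _fit(_two_phase, t, y, p0,
                       ([-np.inf, -np.inf, 0, -np.inf, 0],
                        [np.inf, np.inf, np.inf, np.inf, np.inf]))
        except RuntimeError as e:
            err = e
            continue
        if best is None or res[2] < best[2]:
            best = res
    if best is None:
        raise RuntimeError(f"two-phase fit failed to converge: {err}")
    popt2, se2, rss2 = best
    # order phases fast -> slow
    if popt2[4] > popt2[2]:
        popt2 = popt2[[0, 3, 4, 1, 2]]
        se2 = se2[[0, 3, 4, 1, 2]]
    dof2 = t.size - 5
    fstat = max((rss1 - rss2) / 2.0, 0.0) / max(rss2 / dof2, 1e-300)
    pval = float(f_dist.sf(fstat, 2, dof2))
    params, stderr, rss = _unscale(("y0", "a1", "k1", "a2", "k2"), popt2, se2, rss2)
    return FitResult("two_phase", params, stderr, rss, t.size, f_test_p=pval)


def fit_two_site(trace: KineticTrace, template: TwoSiteModel,
                 fit_names: tuple = ("kon1", "koff1", "ktrans"),
                 protocol: AssayProtocol | None = None) -> dict:
    """Recover rate constants by least squares against the full ODE model.

    ``template`` supplies concentrations, ``access2`` and any rates not being
    fitted; ``fit_names`` are optimized in log space (multi-start from the
    template values).  Returns the fitted rates and the residual sum of
    squares.
    """
    from scipy.optimize import least_squares

    if protocol is None:
        protocol = trace.ground_truth.get("protocol")
    if protocol is None:
        raise ValueError("no protocol available for refitting")
    y = np.asarray(trace.signal, dtype=float)

    def resid(logp):
        kw = {n: float(np.exp(v)) for n, v in zip(fit_names, logp)}
        m = replace(template, **kw)
        return simulate_assay(m, protocol).signal - y

    p0 = np.log([max(getattr(template, n), 1e-12) for n in fit_names])
    best = None
    for scale in (1.0, 3.0, 1 / 3.0):
        try:
            res = least_squares(resid, p0 + np.log(scale), method="lm",
                                x_scale="jac", max_nfev=200)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("two-site refit failed to converge")
    out = {n: float(np.exp(v)) for n, v in zip(fit_names, best.x)}
    out["rss"] = float(2 * best.cost)
    return out


# ---------------------------------------------------------------------------
# exchange / equilibrium
# ---------------------------------------------------------------------------


def exchange_summary(model: TwoSiteModel, protocol: AssayProtocol) -> dict:
    """Half-time and plateau of the labeled-bound decay after a chase event.

    The chase is the last event adding unlabeled nucleotide.  Returns
    ``{"t_half": s or inf, "plateau": M, "amplitude": M, "flag": ...}``.
    With all off-rates zero there is no decay (t_half = inf, flagged); a
    chase before any labeled binding yields a zero-amplitude flag.
    """
    chases = [t for t, sp, _ in protocol.events if sp == "unlabeled"]
    if not chases:
        raise ValueError("protocol contains no chase (unlabeled-addition) event")
    t_chase = chases[-1]
    tr = simulate_assay(model, protocol)
    after = tr.times >= t_chase
    s = tr.signal[after]
    t = tr.times[after] - t_chase
    s0 = s[0]
    if model.koff1 == 0 and model.koff2 == 0:
        return {"t_half": np.inf, "plateau": float(s[-1]),
                "amplitude": float(s0 - s[-1]), "flag": "no_decay"}
    if model.khyd == 0:
        # closed-form final plateau: at equilibrium the label is uniformly
        # mixed through every nucleotide pool
        added = {"labeled": 0.0, "unlabeled": 0.0, "protein": 0.0}
        for _, sp_name, c in protocol.events:
            added[sp_name] += c
        totals = replace(model,
                         labeled=model.labeled + added["labeled"],
                         unlabeled=model.unlabeled + added["unlabeled"],
                         protein=model.protein + added["protein"])
        eq = equilibrium_occupancies(totals)
        nt = totals.labeled + totals.unlabeled
        frac = totals.labeled / nt if nt > 0 else 0.0
        plateau = (eq["P1"] + eq["P2"]) * frac
    else:
        plateau = s[-1]
    amplitude = s0 - plateau
    if amplitude <= max(1e-12 * max(s0, 1e-30), 0.0) or s0 <= 0:
        return {"t_half": np.nan, "plateau": float(plateau),
                "amplitude": float(amplitude), "flag": "zero_amplitude"}
    half = plateau + 0.5 * amplitude
    below = np.nonzero(s <= half)[0]
    if below.size == 0:
        t_half = np.inf
    else:
        i = below[0]
        if i == 0:
            t_half = 0.0
        else:
            t_half = float(np.interp(half, [s[i], s[i - 1]], [t[i], t[i - 1]]))
    return {"t_half": t_half, "plateau": float(plateau),
            "amplitude": float(amplitude), "flag": "ok"}


def equilibrium_occupancies(model: TwoSiteModel) -> dict:
    """Closed-form steady state of the scheme with khyd = 0.

    Solves the flux-balance conditions
    ``kon1 P L = (koff1 + g) P1`` and ``g P1 = koff2 P2`` (g = access2*ktrans;
    with koff2 = 0 or g = 0 the site-2 branch empties or absorbs) together
    with the conservation laws, by bracketing on free protein.
    """
    if model.khyd != 0:
        raise ValueError("closed-form equilibrium requires khyd = 0")
    g = model.access2 * model.ktrans
    off2 = model.access2 * model.koff2
    nt = model.labeled + model.unlabeled
    pt = model.protein
    if model.kon1 == 0 or nt == 0 or pt == 0:
        return {"P1": 0.0, "P2": 0.0, "free_nucleotide": nt, "free_protein": pt}
    if g > 0 and off2 == 0:
        # site 2 is absorbing: everything transferable ends bound at site 2
        p2 = min(pt, nt)
        return {"P1": 0.0, "P2": p2, "free_nucleotide": nt - p2,
                "free_protein": pt - p2}

    def occupancy(p_free):
        # per-protein occupancy ratios given free nucleotide n
        # P1 = kon1 * P * N / (koff1 + g) ... with g->site2: P2 = g P1 / koff2
        c1 = model.kon1 / (model.koff1 + g) if (model.koff1 + g) > 0 else np.inf
        c2 = g / off2 if off2 > 0 else 0.0
        return c1, c2

    def resid(p_free):
        c1, c2 = occupancy(p_free)
        # solve free nucleotide from nucleotide conservation given p_free
        # N_free * (1 + c1 p (1 + c2)) = nt
        n_free = nt / (1.0 + c1 * p_free * (1.0 + c2))
        p1 = c1 * p_free * n_free
        p2 = c2 * p1
        return p_free + p1 + p2 - pt

    p_free = brentq(resid, 0.0, pt, xtol=1e-18, rtol=1e-14)
    c1, c2 = occupancy(p_free)
    n_free = nt / (1.0 + c1 * p_free * (1.0 + c2))
    p1 = c1 * p_free * n_free
    p2 = c2 * p1
    return {"P1": float(p1), "P2": float(p2), "free_nucleotide": float(n_free),
            "free_protein": float(p_free)}
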