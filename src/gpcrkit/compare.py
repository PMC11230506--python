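"""Inter-state structural geometry.

Quantifies how a helix moves between two conformational states of a complex
(axis tilt, about-axis spin, retraction along the axis) and detects the
noncovalent interactions that distinguish activation states: salt bridges,
hydrogen bonds (strong and weak), cation-pi and CH3-pi contacts, plus a
report over the conserved GPCR microswitches (PIF, Y-Y hydrogen bond, CWxP).

Sign conventions (documented because deposited structures do not carry a
viewpoint): helix axes are oriented N-terminal -> C-terminal; positive spin
is clockwise looking down the oriented axis; positive retraction is movement
of the helix centroid away from the core (the centroid of the alignment
selection), or along the oriented axis when no core is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import kabsch
from .selections import resolve
from .structure import StructureModel, Transform

__all__ = [
    "superpose",
    "helix_axis",
    "helix_rotation_retraction",
    "HelixChange",
    "detect_interactions",
    "InteractionCriteria",
    "microswitch_report",
]


def superpose(mobile: StructureModel, reference: StructureModel,
              selection) -> tuple[Transform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``
    over ``selection``; returns the transform and the post-fit RMSD (A)."""
    im = resolve(mobile, selection)
    ir = resolve(reference, selection)
    if im.size != ir.size:
        raise ValueError("selection resolves to different atom counts")
    pts = mobile.coords[im]
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 paired atoms")
    # collinearity check: smallest two singular values of the centered cloud
    s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if s[1] < 1e-8:
        raise ValueError("degenerate (collinear) selection")
    return kabsch(pts, reference.coords[ir])


def _ca_trace(model: StructureModel, selection) -> np.ndarray:
    idx = resolve(model, selection)
    ca = idx[np.asarray(model.name[idx], dtype=str) == "CA"]
    if ca.size == 0:
        ca = idx  # bead models: every particle is a trace point
    # order by (chain, resid) to follow the backbone
    order = np.lexsort((model.resid[ca], model.chain[ca].astype(str)))
    return model.coords[ca[order]]


def helix_axis(model: StructureModel, selection, window: int = 4
               ) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis direction (unit, N->C) and centroid from the C-alpha trace.

    Sliding-window midpoints of ``window`` consecutive C-alphas cancel the
    helical wobble; the principal direction of the midpoints is the axis.
    Requires at least 6 consecutive residues.
    """
    ca = _ca_trace(model, selection)
    if ca.shape[0] < 6:
        raise ValueError("helix axis needs at least 6 C-alpha positions")
    mids = np.array([ca[i:i + window].mean(axis=0)
                     for i in range(ca.shape[0] - window + 1)])
    centroid = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(mids - mids.mean(axis=0))
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis, centroid


@dataclass(frozen=True)
class HelixChange:
    """Axis tilt (deg), about-axis spin (deg) and retraction (A) of a helix
    between two states."""

    tilt: float
    spin: float
    retraction: float


def helix_rotation_retraction(state_a: StructureModel, state_b: StructureModel,
                              helix_selection, align_selection=None,
                              core_point: np.ndarray | None = None) -> HelixChange:
    """Decompose the motion of a helix between two states.

    After superposing B onto A over ``align_selection`` (skipped when None —
    the states are then assumed to share a frame): tilt is the angle between
    the two helix axes; spin is the circular mean of the paired-C-alpha
    angular offsets about the mean axis; retraction is the displacement of
    the helix centroid projected on the mean axis, with positive meaning
    away from the core (centroid of the alignment selection, or
    ``core_point``).
    """
    b = state_b
    if align_selection is not None:
        tr, _ = superpose(state_b, state_a, align_selection)
        b = state_b.transformed(tr)
        if core_point is None:
            core_point = state_a.coords[resolve(state_a, align_selection)].mean(axis=0)

    axis_a, cen_a = helix_axis(state_a, helix_selection)
    axis_b, cen_b = helix_axis(b, helix_selection)
    tilt = float(np.rad2deg(np.arccos(np.clip(axis_a @ axis_b, -1.0, 1.0))))

    n = axis_a + axis_b
    n = n / np.linalg.norm(n)

    ca_a = _ca_trace(state_a, helix_selection)
    ca_b = _ca_trace(b, helix_selection)
    if ca_a.shape[0] != ca_b.shape[0]:
        raise ValueError("helix selections pair different numbers of residues")
    center = 0.5 * (cen_a + cen_b)
    sines = []
    cosines = []
    for pa, pb in zip(ca_a, ca_b):
        ua = pa - center
        ua = ua - (ua @ n) * n
        ub = pb - center
        ub = ub - (ub @ n) * n
        wa, wb = np.linalg.norm(ua), np.linalg.norm(ub)
        if wa < 1e-6 or wb < 1e-6:
            continue
        ua, ub = ua / wa, ub / wb
        cosines.append(ua @ ub)
        sines.append(n @ np.cross(ua, ub))
    if not sines:
        raise ValueError("degenerate helix geometry: no off-axis C-alpha offsets")
    # positive spin = clockwise looking down the oriented (N->C) axis
    spin = float(np.rad2deg(np.arctan2(-np.mean(sines), np.mean(cosines))))

    disp = cen_b - cen_a
    direction = n
    if core_point is not None:
        away = cen_a - np.asarray(core_point, dtype=float)
        if (away @ n) < 0:
            direction = -n
    retraction = float(disp @ direction)
    return HelixChange(tilt=tilt, spin=spin, retraction=retraction)


# ---------------------------------------------------------------------------
# interaction detection
# ---------------------------------------------------------------------------

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

CATION_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

METHYL_CARBONS = {
    "ALA": ("CB",), "VAL": ("CG1", "CG2"), "LEU": ("CD1", "CD2"),
    "ILE": ("CG2", "CD1"), "THR": ("CG2",), "MET": ("CE",),
}

DONOR_ATOMS = {
    "*": ("N",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
}
ACCEPTOR_ATOMS = {
    "*": ("O", "OXT"),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"),
}

KNOWN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for interaction detection (A / deg)."""

    salt_bridge_max: float = 4.0
    hbond_max: float = 3.5
    weak_hbond_max: float = 4.0
    cation_pi_max: float = 6.0
    cation_pi_angle_max: float = 30.0
    ch3_pi_max: float = 4.5


def _residue_groups(model, table):
    """Yield (residue key, atom indices) for residues with all-template atoms present."""
    out = []
    keys = {}
    for i in range(model.n_atoms):
        key = (str(model.chain[i]), int(model.resid[i]), str(model.icode[i]))
        keys.setdefault(key, []).append(i)
    for key, idxs in keys.items():
        resname = str(model.resname[idxs[0]])
        if resname in table:
            names = {str(model.name[i]): i for i in idxs}
            hits = [names[a] for a in table[resname] if a in names]
            if hits:
                out.append((key, resname, np.array(hits)))
    return out


def _ring_normal(coords):
    c = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - c)
    return c, vt[2]


def detect_interactions(model: StructureModel,
                        criteria: InteractionCriteria | None = None) -> pd.DataFrame:
    """Detect salt bridges, H-bonds (strong/weak), cation-pi and CH3-pi pairs.

    Heavy-atom criteria (no hydrogens needed).  Returns a deterministic,
    canonically ordered DataFrame with one row per interacting residue pair
    per interaction type.  Residues outside the template tables are skipped
    with a warning.
    """
    crit = criteria or InteractionCriteria()
    unknown = sorted({str(r) for r in model.resname[~model.hetero]} - KNOWN_RESIDUES)
    if unknown:
        warnings.warn(f"no interaction templates for residues: {unknown}", stacklevel=2)

    rows = []

    def reskey(key, resname):
        return f"{key[0]}:{resname}{key[1]}{key[2]}"

    cations = _residue_groups(model, CATION_ATOMS)
    anions = _residue_groups(model, ANION_ATOMS)
    rings = _residue_groups(model, RING_ATOMS)
    methyls = _residue_groups(model, METHYL_CARBONS)

    # salt bridges: closest charged-group heavy-atom pair
    for ckey, cres, cidx in cations:
        for akey, ares, aidx in anions:
            if ckey == akey:
                continue
            d = np.linalg.norm(model.coords[cidx][:, None, :]
                               - model.coords[aidx][None, :, :], axis=2)
            dmin = float(d.min())
            if dmin <= crit.salt_bridge_max:
                rows.append(("salt_bridge", reskey(ckey, cres), reskey(akey, ares),
                             dmin, np.nan))

    # cation-pi: charged-group center to ring centroid, off-normal angle
    for ckey, cres, cidx in cations:
        cpos = model.coords[cidx].mean(axis=0)
        for rkey, rres, ridx in rings:
            if ckey == rkey:
                continue
            centroid, normal = _ring_normal(model.coords[ridx])
            v = cpos - centroid
            dist = float(np.linalg.norm(v))
            if dist > crit.cation_pi_max or dist < 1e-6:
                continue
            ang = np.rad2deg(np.arccos(np.clip(abs(v @ normal) / dist, -1, 1)))
            if ang <= crit.cation_pi_angle_max:
                rows.append(("cation_pi", reskey(ckey, cres), reskey(rkey, rres),
                             dist, float(ang)))

    # CH3-pi: methyl carbon to ring centroid
    for mkey, mres, midx in methyls:
        for rkey, rres, ridx in rings:
            if mkey == rkey:
                continue
            centroid, _ = _ring_normal(model.coords[ridx])
            d = np.linalg.norm(model.coords[midx] - centroid, axis=1)
            dmin = float(d.min())
            if dmin <= crit.ch3_pi_max:
                rows.append(("ch3_pi", reskey(mkey, mres), reskey(rkey, rres),
                             dmin, np.nan))

    # hydrogen bonds: donor/acceptor heavy atoms
    def _da_indices(table):
        out = []
        for i in range(model.n_atoms):
            resname = str(model.resname[i])
            name = str(model.name[i])
            if name in table.get("*", ()) or name in table.get(resname, ()):
                out.append(i)
        return np.array(out, dtype=int)

    don = _da_indices(DONOR_ATOMS)
    acc = _da_indices(ACCEPTOR_ATOMS)
    if don.size and acc.size:
        d = np.linalg.norm(model.coords[don][:, None, :]
                           - model.coords[acc][None, :, :], axis=2)
        # classify each residue pair once, by its shortest donor-acceptor contact
        best: dict[tuple, tuple] = {}
        for ii, jj in zip(*np.nonzero(d <= crit.weak_hbond_max)):
            i, j = don[ii], acc[jj]
            ki = (str(model.chain[i]), int(model.resid[i]), str(model.icode[i]))
            kj = (str(model.chain[j]), int(model.resid[j]), str(model.icode[j]))
            if ki == kj:
                continue
            dist = float(d[ii, jj])
            pair = (min(ki, kj), max(ki, kj))
            if pair not in best or dist < best[pair][0]:
                best[pair] = (dist, ki, kj,
                              str(model.resname[i]), str(model.resname[j]))
        for dist, ki, kj, rni, rnj in best.values():
            kind = "hbond" if dist <= crit.hbond_max else "weak_hbond"
            rows.append((kind, reskey(ki, rni), reskey(kj, rnj), dist, np.nan))

    df = pd.DataFrame(rows, columns=["type", "partner_a", "partner_b",
                                     "distance_A", "angle_deg"])
    return df.sort_values(["type", "partner_a", "partner_b", "distance_A"],
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# microswitch report
# ---------------------------------------------------------------------------


def _sidechain_ring(model, chain, resid):
    idx = model.residue_atoms(chain, resid)
    resname = str(model.resname[idx[0]]) if idx.size else ""
    names = {str(model.name[i]): i for i in idx}
    atoms = [names[a] for a in RING_ATOMS.get(resname, ()) if a in names]
    if len(atoms) < 3:
        return None
    c, _ = _ring_normal(model.coords[np.array(atoms)])
    return c


def _dihedral(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.rad2deg(np.arctan2(np.cross(v, w) @ b1, v @ w)))


def microswitch_report(model: StructureModel, residue_map: dict) -> pd.DataFrame:
    """Geometry of the conserved activation microswitches.

    ``residue_map`` maps Ballesteros-Weinstein positions (e.g. "5.50") to
    ``(chain, author residue id)``.  Rows cover the PIF hydrophobic switch
    (P5.50 and I3.40 side chains to the F6.44 ring centroid), the
    Y5.58-Y7.53 hydroxyl pair with an hbond/weak/none call, and the CWxP
    hinge context (phi/psi of P6.50).  Unmapped positions yield rows flagged
    "missing"; the others are still computed.
    """
    rows = []

    def get(bw):
        r = residue_map.get(bw)
        if r is None:
            return None
        return (str(r[0]), int(r[1]))

    def atom(res, name):
        if res is None:
            return None
        try:
            idx = model.residue_atoms(*res)
        except Exception:
            return None
        names = {str(model.name[i]): i for i in idx}
        return names.get(name)

    # PIF switch distances
    f644 = get("6.44")
    ring_c = _sidechain_ring(model, *f644) if f644 else None
    for bw, atoms in (("5.50", ("CB", "CG", "CD")), ("3.40", ("CG2", "CD1", "CB"))):
        res = get(bw)
        if res is None or ring_c is None:
            rows.append((f"PIF {bw}-6.44", "missing", np.nan, ""))
            continue
        cand = [atom(res, a) for a in atoms]
        cand = [c for c in cand if c is not None]
        if not cand:
            rows.append((f"PIF {bw}-6.44", "missing", np.nan, ""))
            continue
        dmin = float(min(np.linalg.norm(model.coords[c] - ring_c) for c in cand))
        rows.append((f"PIF {bw}-6.44", "ok", dmin, ""))

    # Y5.58 - Y7.53 hydroxyl pair
    y558, y753 = get("5.58"), get("7.53")
    i1 = atom(y558, "OH") if y558 else None
    i2 = atom(y753, "OH") if y753 else None
    if i1 is None or i2 is None:
        rows.append(("Y5.58-Y7.53 OH", "missing", np.nan, ""))
    else:
        d = float(np.linalg.norm(model.coords[i1] - model.coords[i2]))
        call = "hbond" if d <= 3.5 else ("weak_hbond" if d <= 4.0 else "none")
        rows.append(("Y5.58-Y7.53 OH", "ok", d, call))

    # CWxP hinge: phi/psi of P6.50
    p650 = get("6.50")
    done = False
    if p650 is not None:
        chain, num = p650
        ats = {}
        for off in (-1, 0, 1):
            idx = model.residue_atoms(chain, num + off)
            for i in idx:
                ats[(off, str(model.name[i]))] = model.coords[i]
        need_phi = [(-1, "C"), (0, "N"), (0, "CA"), (0, "C")]
        need_psi = [(0, "N"), (0, "CA"), (0, "C"), (1, "N")]
        if all(k in ats for k in need_phi) and all(k in ats for k in need_psi):
            phi = _dihedral(*(ats[k] for k in need_phi))
            psi = _dihedral(*(ats[k] for k in need_psi))
            rows.append(("CWxP P6.50 phi", "ok", phi, ""))
            rows.append(("CWxP P6.50 psi", "ok", psi, ""))
            done = True
    if not done:
        rows.append(("CWxP P6.50 phi/psi", "missing", np.nan, ""))

    return pd.DataFrame(rows, columns=["motif", "status", "value", "call"])
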