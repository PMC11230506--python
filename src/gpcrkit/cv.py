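"""Reaction coordinates: center-of-mass distances, C-alpha distances,
superposition RMSD and the AHD-Ras domain-orientation angle.

These are the coordinates used to map receptor-G-protein activation:
the distance between the receptor NPxxY motif and the C-terminal five
residues of the Galpha alpha5 helix, the TM3-TM6 intracellular-end
C-alpha distance, the nucleotide RMSD relative to its starting pose, and
the opening angle of the alpha-helical domain (AHD) relative to the
Ras-like domain.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .selections import SelectionError, resolve
from .structure import StructureModel, Transform

__all__ = ["com_distance", "ca_distance", "rmsd", "kabsch",
           "domain_angle", "domain_opening_angle"]


def _center(model: StructureModel, idx, mode: str = "mass") -> np.ndarray:
    pts = model.coords[idx]
    if mode == "geometric":
        return pts.mean(axis=0)
    if mode == "ca":
        ca = idx[np.asarray(model.name[idx], dtype=str) == "CA"]
        if ca.size == 0:
            raise SelectionError("no C-alpha atoms in selection for com mode 'ca'")
        return model.coords[ca].mean(axis=0)
    if mode == "mass":
        w = model.masses(idx)
        return (pts * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError("com mode must be mass|geometric|ca")


def com_distance(model: StructureModel, sel_a, sel_b, mode: str = "mass") -> float:
    """Distance (A) between the centers of two selections.

    ``mode`` chooses mass-weighted centers (default), plain geometric
    centers, or C-alpha-only geometric centers.
    """
    ia = resolve(model, sel_a)
    ib = resolve(model, sel_b)
    return float(np.linalg.norm(_center(model, ia, mode) - _center(model, ib, mode)))


def _residue_atom(model: StructureModel, residue, name="CA") -> int:
    if isinstance(residue, str) and ":" in residue:
        chain, num = residue.split(":")
        residue = (chain, int(num))
    chain, num = residue
    idx = model.residue_atoms(chain, num)
    if idx.size == 0:
        raise SelectionError(f"residue {chain}:{num} not found")
    hit = idx[np.asarray(model.name[idx], dtype=str) == name]
    if hit.size == 0:
        raise SelectionError(f"residue {chain}:{num} has no atom '{name}'")
    return int(hit[0])


def ca_distance(model: StructureModel, residue_a, residue_b) -> float:
    """C-alpha - C-alpha distance (A) between two residues ("A:102" or (chain, id))."""
    ia = _residue_atom(model, residue_a, "CA")
    ib = _residue_atom(model, residue_b, "CA")
    return float(np.linalg.norm(model.coords[ia] - model.coords[ib]))


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights=None) -> tuple[Transform, float]:
    """Least-squares rigid superposition of paired points (Kabsch).

    Returns the proper transform mapping ``mobile`` onto ``reference`` and
    the post-fit RMSD (A).
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ValueError("need >= 3 paired points of equal shape")
    w = None if weights is None else np.asarray(weights, dtype=float)
    cp = np.average(p, axis=0, weights=w)
    cq = np.average(q, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(q - cq, p - cp, weights=w)
    r = rot.as_matrix()
    tr = Transform(r, cq - r @ cp)
    d = tr.apply(p) - q
    if w is None:
        ms = np.mean(np.sum(d * d, axis=1))
    else:
        ms = np.average(np.sum(d * d, axis=1), weights=w)
    return tr, float(np.sqrt(ms))


def rmsd(model_a: StructureModel, model_b: StructureModel, selection,
         mode: str = "fit", align_selection=None) -> float:
    """RMSD (A) over ``selection`` between two same-topology models.

    ``mode="fit"`` superposes B onto A first (over ``align_selection`` if
    given, else over ``selection``); ``mode="nofit"`` compares raw
    coordinates — the convention for nucleotide displacement measured after
    aligning on the Ras-like domain.
    """
    ia = resolve(model_a, selection)
    ib = resolve(model_b, selection)
    if ia.size != ib.size:
        raise ValueError("selection resolves to different atom counts in the two models")
    pa = model_a.coords[ia]
    pb = model_b.coords[ib]
    if mode == "fit":
        asel = selection if align_selection is None else align_selection
        ja = resolve(model_a, asel)
        jb = resolve(model_b, asel)
        if ja.size != jb.size:
            raise ValueError("alignment selection resolves to different atom counts")
        tr, _ = kabsch(model_b.coords[jb], model_a.coords[ja])
        pb = tr.apply(pb)
    elif mode != "nofit":
        raise ValueError("mode must be fit|nofit")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def _vec_angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    ct = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(ct)))


def _anchor_center(model: StructureModel, anchor) -> np.ndarray:
    if isinstance(anchor, str) and ":" in anchor:
        chain, num = anchor.split(":")
        anchor = (chain, int(num))
    if isinstance(anchor, tuple) and len(anchor) == 2 and isinstance(anchor[1], int):
        idx = model.residue_atoms(*anchor)
        if idx.size == 0:
            raise SelectionError(f"anchor residue {anchor} not found")
    else:
        idx = resolve(model, anchor)
    return model.coords[idx].mean(axis=0)


def domain_angle(reference: StructureModel, current: StructureModel,
                 ahd_sel, ras_sel, anchor_a, anchor_b,
                 center_mode: str = "geometric") -> float:
    """AHD reorientation angle (deg) of ``current`` relative to ``reference``.

    The Ras-domain selection of ``current`` is Kabsch-aligned onto the
    reference Ras domain.  Vector 1 runs from the AHD center through the
    anchor residue (e.g. A161) center; vector 2 from the Ras center through
    its anchor (e.g. E299) and fixes the opening plane.  The reported angle
    is between vector 1 of the aligned current structure and vector 1 of the
    reference, in [0, 180] deg; identical structures give 0.
    """
    ira = resolve(reference, ras_sel)
    ica = resolve(current, ras_sel)
    if ira.size != ica.size:
        raise ValueError("Ras selection resolves to different atom counts")
    tr, _ = kabsch(current.coords[ica], reference.coords[ira])
    cur = current.transformed(tr)

    def v1(model):
        ahd_c = _center(model, resolve(model, ahd_sel), center_mode)
        a = _anchor_center(model, anchor_a)
        v = a - ahd_c
        if np.linalg.norm(v) < 1e-8:
            raise ValueError("degenerate vector: AHD anchor coincides with AHD center")
        return v

    ras_c = _center(reference, ira, center_mode)
    v2 = _anchor_center(reference, anchor_b) - ras_c
    if np.linalg.norm(v2) < 1e-8:
        raise ValueError("degenerate vector: Ras anchor coincides with Ras center")

    return _vec_angle(v1(cur), v1(reference))


def domain_opening_angle(model: StructureModel, ahd_sel, ras_sel,
                         anchor_a, anchor_b,
                         center_mode: str = "geometric") -> float:
    """Absolute AHD-Ras opening angle (deg) within one structure:
    the angle between the AHD-center->anchor and Ras-center->anchor vectors."""
    ahd_c = _center(model, resolve(model, ahd_sel), center_mode)
    ras_c = _center(model, resolve(model, ras_sel), center_mode)
    v1 = _anchor_center(model, anchor_a) - ahd_c
    v2 = _anchor_center(model, anchor_b) - ras_c
    if np.linalg.norm(v1) < 1e-8 or np.linalg.norm(v2) < 1e-8:
        raise ValueError("degenerate vector: anchor coincides with domain center")
    return _vec_angle(v1, v2)
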