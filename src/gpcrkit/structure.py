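"""Macromolecular coordinate container and PDB/mmCIF input/output.

`StructureModel` is a flat, array-backed view of a coordinate file (one
model), sufficient for geometric analysis: per-atom serial, name, element,
residue name/id/insertion code, chain, coordinates, occupancy and altloc.
Parsing and writing are delegated to gemmi; author residue numbering is
preserved (auth_ fields for mmCIF) so residues can be addressed with the
numbers used in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:
    import gemmi
except ImportError as _e:  # pragma: no cover
    raise ImportError("gpcrkit.structure requires gemmi") from _e

__all__ = ["StructureModel", "Transform", "read_structure", "write_structure"]


@dataclass(frozen=True)
class Transform:
    """Proper rigid transform ``x -> R x + t`` (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_axis_angle(axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "Transform":
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        r = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        return Transform(r, np.asarray(translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)


@dataclass
class StructureModel:
    """Array-backed macromolecular model (single coordinate model)."""

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    icode: np.ndarray
    chain: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray
    altloc: np.ndarray
    hetero: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "StructureModel":
        return StructureModel(*(np.array(getattr(self, f)) for f in (
            "serial", "name", "element", "resname", "resid", "icode", "chain",
            "coords", "occupancy", "altloc", "hetero")), metadata=dict(self.metadata))

    def transformed(self, tr: Transform) -> "StructureModel":
        out = self.copy()
        out.coords = tr.apply(self.coords)
        return out

    def masses(self, indices=None) -> np.ndarray:
        """Standard atomic masses (amu) for the selected atoms."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        return np.array([gemmi.Element(str(e)).weight for e in self.element[idx]])

    def residue_atoms(self, chain: str, resid: int, icode: str = "") -> np.ndarray:
        """Indices of the atoms of one residue (author numbering)."""
        m = (self.chain == chain) & (self.resid == int(resid)) & (self.icode == icode)
        return np.flatnonzero(m)

    def chains(self) -> list[str]:
        seen = []
        for c in self.chain:
            if c not in seen:
                seen.append(c)
        return seen

    @staticmethod
    def from_arrays(chain, resid, resname, name, element, coords,
                    occupancy=None, hetero=None) -> "StructureModel":
        """Build a model from parallel per-atom sequences (test/fixture path)."""
        n = len(name)
        coords = np.asarray(coords, dtype=float).reshape(n, 3)
        return StructureModel(
            serial=np.arange(1, n + 1),
            name=np.asarray(name, dtype=object),
            element=np.asarray(element, dtype=object),
            resname=np.asarray(resname, dtype=object),
            resid=np.asarray(resid, dtype=int),
            icode=np.asarray([""] * n, dtype=object),
            chain=np.asarray(chain, dtype=object),
            coords=coords,
            occupancy=np.ones(n) if occupancy is None else np.asarray(occupancy, float),
            altloc=np.asarray([""] * n, dtype=object),
            hetero=np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, bool),
        )


def read_structure(path, fmt: str | None = None, model_index: int = 0,
                   altloc_policy: str = "occupancy") -> StructureModel:
    """Read a PDB or mmCIF file into a `StructureModel`.

    ``fmt`` may be "pdb" or "mmcif"; by default the dialect is detected from
    the file.  ``altloc_policy``: "occupancy" keeps the highest-occupancy
    alternate location per (residue, atom name), "first" keeps the first
    encountered, "all" keeps every record.  Author residue numbering is used.
    """
    path = str(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(path)
        else:
            coor = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[fmt]
            st = gemmi.read_structure(path, format=coor)
    except (RuntimeError, ValueError, KeyError) as e:
        raise ValueError(f"could not parse '{path}': {e}") from e
    if len(st) == 0:
        raise ValueError(f"'{path}' contains no coordinate model")
    model = st[model_index]

    rows = []
    for ch in model:
        for res in ch:
            het = res.het_flag == "H"
            for atom in res:
                rows.append((atom.serial, atom.name, atom.element.name,
                             res.name, res.seqid.num, res.seqid.icode.strip(),
                             ch.name, atom.pos.x, atom.pos.y, atom.pos.z,
                             atom.occ, atom.altloc.strip(), het))
    if not rows:
        raise ValueError(f"'{path}' contains no atoms")

    if altloc_policy not in ("occupancy", "first", "all"):
        raise ValueError("altloc_policy must be occupancy|first|all")
    if altloc_policy != "all":
        best: dict[tuple, int] = {}
        for i, r in enumerate(rows):
            key = (r[6], r[4], r[5], r[3], r[1])
            if key not in best:
                best[key] = i
            elif altloc_policy == "occupancy" and r[10] > rows[best[key]][10]:
                best[key] = i
        keep = sorted(best.values())
        rows = [rows[i] for i in keep]

    cols = list(zip(*rows))
    return StructureModel(
        serial=np.asarray(cols[0], dtype=int),
        name=np.asarray(cols[1], dtype=object),
        element=np.asarray(cols[2], dtype=object),
        resname=np.asarray(cols[3], dtype=object),
        resid=np.asarray(cols[4], dtype=int),
        icode=np.asarray(cols[5], dtype=object),
        chain=np.asarray(cols[6], dtype=object),
        coords=np.column_stack([cols[7], cols[8], cols[9]]).astype(float),
        occupancy=np.asarray(cols[10], dtype=float),
        altloc=np.asarray(cols[11], dtype=object),
        hetero=np.asarray(cols[12], dtype=bool),
        metadata={"path": path},
    )


def write_structure(model: StructureModel, path) -> None:
    """Write a `StructureModel` as a PDB file (ATOM/HETATM records)."""
    st = gemmi.Structure()
    st.name = "gpcrkit"
    gm = gemmi.Model("1")
    # group atoms by chain, then residue, preserving file order
    chain_order: list[str] = []
    grouped: dict[str, list[tuple[tuple, list[int]]]] = {}
    for i in range(model.n_atoms):
        cname = str(model.chain[i])
        if cname not in grouped:
            grouped[cname] = []
            chain_order.append(cname)
        key = (int(model.resid[i]), str(model.icode[i]), str(model.resname[i]),
               bool(model.hetero[i]))
        if not grouped[cname] or grouped[cname][-1][0] != key:
            grouped[cname].append((key, []))
        grouped[cname][-1][1].append(i)
    for cname in chain_order:
        ch = gemmi.Chain(cname)
        for (resid, icode, resname, het), idxs in grouped[cname]:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resid, icode or " ")
            res.het_flag = "H" if het else "A"
            for i in idxs:
                atom = gemmi.Atom()
                atom.name = str(model.name[i])
                atom.element = gemmi.Element(str(model.element[i]))
                atom.pos = gemmi.Position(*model.coords[i])
                atom.occ = float(model.occupancy[i])
                atom.altloc = str(model.altloc[i]) if model.altloc[i] else "\0"
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
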