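"""Ideal C-alpha helix fixtures with known ground-truth transforms.

These are the constructed inputs for validating helix-geometry recovery:
an ideal alpha-helical C-alpha trace (default rise 1.5 A, twist 100 deg,
radius 2.3 A) built along +z, optionally spun about its own axis and
translated along it, with the applied motion recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import StructureModel, Transform, write_structure

__all__ = ["HelixFixtureSpec", "make_helix_fixture", "helix_chord_length"]


@dataclass(frozen=True)
class HelixFixtureSpec:
    """Ideal helix parameters plus an optional applied rigid motion.

    ``spin_deg`` is the about-axis rotation in the clockwise sense when
    looking down the N->C axis (the package-wide spin convention);
    ``shift_a`` translates along the axis (+ = toward C terminus).  A fully
    general motion can be supplied as ``transform`` instead.
    """

    n_residues: int = 20
    rise: float = 1.5            # A per residue
    twist: float = 100.0         # deg per residue
    radius: float = 2.3          # A
    spin_deg: float = 0.0
    shift_a: float = 0.0
    transform: Transform | None = None
    chain: str = "A"

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.rise <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")


def _base_coords(spec: HelixFixtureSpec) -> np.ndarray:
    i = np.arange(spec.n_residues)
    tau = np.deg2rad(spec.twist)
    return np.column_stack([spec.radius * np.cos(i * tau),
                            spec.radius * np.sin(i * tau),
                            spec.rise * i])


def make_helix_fixture(spec: HelixFixtureSpec, path=None) -> StructureModel:
    """Build the helix fixture; optionally write it as a PDB file.

    The returned model's ``metadata`` holds the ground truth:
    ``spin_deg``, ``shift_a`` and the full ``transform`` applied to the base
    helix (base helix axis = +z, N terminus at z=0).
    """
    coords = _base_coords(spec)
    if spec.transform is not None:
        tr = spec.transform
    else:
        # clockwise spin looking down +z == right-handed rotation by -spin
        tr = Transform.from_axis_angle((0, 0, 1), -spec.spin_deg,
                                       translation=(0, 0, spec.shift_a))
    coords = tr.apply(coords)
    n = spec.n_residues
    model = StructureModel.from_arrays(
        chain=[spec.chain] * n,
        resid=np.arange(1, n + 1),
        resname=["ALA"] * n,
        name=["CA"] * n,
        element=["C"] * n,
        coords=coords,
    )
    model.metadata.update(spin_deg=spec.spin_deg, shift_a=spec.shift_a,
                          transform=tr, spec=spec)
    if path is not None:
        write_structure(model, path)
    return model


def helix_chord_length(spec: HelixFixtureSpec, separation: int) -> float:
    """Closed-form C-alpha chord length between residues i and i+separation."""
    tau = np.deg2rad(spec.twist) * separation
    lateral = 2.0 * spec.radius * np.sin(tau / 2.0)
    axial = spec.rise * separation
    return float(np.hypot(lateral, axial))
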