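"""Helix rotation-retraction decomposition on a constructed ground truth.

Builds an ideal C-alpha helix, applies a known about-axis spin and axial
shift (the kind of motion the alpha5 helix of Galpha undergoes between the
intermediate and fully activated receptor complexes), and recovers both
numbers from coordinates alone."""

from gpcrkit.compare import helix_rotation_retraction
from gpcrkit.helix import HelixFixtureSpec, make_helix_fixture

base = make_helix_fixture(HelixFixtureSpec(n_residues=20))
moved = make_helix_fixture(HelixFixtureSpec(n_residues=20,
                                            spin_deg=2.0, shift_a=2.0))
change = helix_rotation_retraction(base, moved, "chain A")
print("applied motion: spin 2.0 deg (clockwise down the axis), shift 2.0 A")
print(f"recovered: spin {change.spin:.2f} deg, retraction "
      f"{change.retraction:.2f} A, axis tilt {change.tilt:.3f} deg")
print("spin/retraction are read from paired C-alpha offsets about the helix "
      "axis; tilt near zero confirms a pure about-axis motion")
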