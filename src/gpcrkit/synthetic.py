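"""One-stop surface for every synthetic-data generator in the package:
analytic potentials with exact reference free energies, the coarse-grained
receptor-G-protein bead system, ideal helix fixtures, synthetic 19F
spectra/FIDs and synthetic binding traces."""

from .helix import HelixFixtureSpec, helix_chord_length, make_helix_fixture
from .kinetics import AssayProtocol, TwoSiteModel, make_binding_trace
from .nmr import SyntheticSpectrumSpec, make_fid, make_spectrum
from .potentials import (GaussianWell, GProteinToy, ToyGProteinSpec,
                         check_forces, make_2d_multiwell, make_double_well,
                         make_gprotein_toy, r291a_analog_spec, wt_analog_spec)

__all__ = [
    "make_double_well", "make_2d_multiwell", "make_gprotein_toy",
    "make_helix_fixture", "make_spectrum", "make_fid", "make_binding_trace",
    "GaussianWell", "ToyGProteinSpec", "GProteinToy", "HelixFixtureSpec",
    "SyntheticSpectrumSpec", "TwoSiteModel", "AssayProtocol",
    "wt_analog_spec", "r291a_analog_spec", "helix_chord_length", "check_forces",
]
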