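"""Interaction detection on a constructed arginine-glutamate pair and a
tyrosine microswitch.

The detector uses heavy-atom geometric criteria (salt bridge <= 4.0 A,
H-bond <= 3.5 A, weak H-bond <= 4.0 A, cation-pi <= 6.0 A within 30 deg of
the ring normal, CH3-pi <= 4.5 A) — the classes of contacts that lock a
receptor-G-protein interface into one activation state or another."""

from gpcrkit.compare import detect_interactions, microswitch_report
from gpcrkit.structure import StructureModel

pair = StructureModel.from_arrays(
    chain=["A"] * 7, resid=[10] * 4 + [20] * 3,
    resname=["ARG"] * 4 + ["GLU"] * 3,
    name=["NE", "NH1", "NH2", "CZ", "OE1", "OE2", "CD"],
    element=["N", "N", "N", "C", "O", "O", "C"],
    coords=[[0, 0, 0], [1, 1, 0], [1, -1, 0], [0.7, 0, 0],
            [3.0, 1, 0], [4.0, -1, 0], [3.5, 0, 0]])
print(detect_interactions(pair).to_string(index=False))

tyr = StructureModel.from_arrays(
    chain=["A", "A"], resid=[197, 288], resname=["TYR", "TYR"],
    name=["OH", "OH"], element=["O", "O"],
    coords=[[0, 0, 0], [2.8, 0, 0]])
rep = microswitch_report(tyr, {"5.58": ("A", 197), "7.53": ("A", 288)})
print()
print(rep.to_string(index=False))
print("\nthe Y-Y hydroxyl pair at 2.8 A is a strong hydrogen bond — the "
      "hallmark of the active-state tyrosine lock")
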