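"""Annotate the interface of one synthetic hetero-dimer.

Builds two idealized chains, docks them at a designated binding site, and
prints the interacting residue pairs with their descriptors: d (minimal
inter-atomic distance, A) and dASA (surface area buried on binding, A^2).
"""

from ppivar.annotation import AnnotationConfig, annotate_interface
from ppivar.model import HeteroDimer
from ppivar.synthetic import binding_modes, build_chain, dock

chain_x = build_chain(60, fold_seed=1)
chain_y = build_chain(60, fold_seed=2)
mode = binding_modes(60, 2)[0]          # binding site centered at residue 20
placed_x, placed_y = dock(chain_x, chain_y, mode)

dimer = HeteroDimer("demo", placed_x, placed_y, "P1", "P2", "F1", "F2")
dimer.interface = annotate_interface(dimer, AnnotationConfig())

print(f"face on X: {dimer.interface.faceX}")
print(f"face on Y: {dimer.interface.faceY}")
print("pairs (posX, posY, d, dASA_X, dASA_Y, rule):")
for p in sorted(dimer.interface.pairs, key=lambda p: (p.posX, p.posY)):
    print(
        f"  {p.posX:3d} {p.posY:3d}  d={p.d:5.2f} A  "
        f"dASA=({p.dasa_X:6.1f}, {p.dasa_Y:6.1f}) A^2  {p.rule}"
    )
print(
    "\nEach row is one interacting residue pair; 'distance' pairs have an\n"
    "atom pair closer than 6 A, 'dasa' pairs are slightly farther but bury\n"
    "surface area on both sides. Both faces sit inside the designated\n"
    "window around residue 20, as planted."
)
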