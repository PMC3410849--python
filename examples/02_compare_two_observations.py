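"""Compare two observations of the same interaction with all three measures.

One pair binds at the planted site both times (conserved); a third
observation uses the alternative site.  Prints Face Position Similarity
(1 = same face residues), L_rms (ligand displacement after receptor
superposition) and I_rms (interface-region RMSD).
"""

from ppivar.annotation import AnnotationConfig, annotate_interface
from ppivar.model import HeteroDimer
from ppivar.similarity import similarity_record
from ppivar.synthetic import binding_modes, build_chain, dock

chain_x = build_chain(60, fold_seed=1)
chain_y = build_chain(60, fold_seed=2)
modes = binding_modes(60, 2)
config = AnnotationConfig()


def observe(assembly_id, mode):
    placed_x, placed_y = dock(chain_x, chain_y, mode)
    dimer = HeteroDimer(assembly_id, placed_x, placed_y, "P1", "P2", "F1", "F2")
    dimer.interface = annotate_interface(dimer, config)
    return dimer


obs1 = observe("expt1", modes[0])
obs2 = observe("expt2", modes[0])   # same binding mode, independent entry
obs3 = observe("expt3", modes[1])   # alternative binding mode

same = similarity_record(obs1, obs2)
diff = similarity_record(obs1, obs3)
print("same mode :", f"fps={same.fps:.2f}  L_rms={same.l_rms:.2f} A  "
      f"I_rms={same.i_rms:.2f} A")
print("cross mode:", f"fps={diff.fps:.2f}  L_rms={diff.l_rms:.2f} A  "
      f"I_rms={diff.i_rms:.2f} A")
print(
    "\nA repeated measurement of the same binding mode reproduces the\n"
    "interface exactly (fps 1, RMSDs 0); the alternative site shares no\n"
    "face residues (fps 0) and leaves the ligand tens of Angstrom away\n"
    "after superposing the receptors."
)
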