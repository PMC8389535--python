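"""Compute pocket descriptors for two contrasting synthetic binding sites.

A deep apolar cage and a shallow polar plane are generated, each pocket's
superligand negative print is built (crystal-ligand fallback, since no
docked poses are supplied), and the 12-descriptor vectors are printed.
"""

from pocketdrug import build_superligand, compute_descriptors
from pocketdrug.fixtures import PocketSpec, synthetic_pocket

for label, spec in [
    ("deep apolar cage", PocketSpec(geometry="closed_cage", polarity_mix=0.0,
                                    n_wall_atoms=80, seed=5)),
    ("shallow polar plane", PocketSpec(geometry="open_plane", polarity_mix=0.8,
                                       n_wall_atoms=64, seed=6)),
]:
    pocket, _ = synthetic_pocket(spec)
    sl = build_superligand(pocket, None)
    vec = compute_descriptors(pocket, sl)
    print(f"\n{label} ({sl.origin}, {sl.n_points} superligand points):")
    for name, value in vec.to_dict().items():
        print(f"  {name:>20s} = {value:.3f}")
# The deep pocket shows lower psa_r (less polar surface) and higher
# fr_buried_sl_atoms (more enclosed negative print) - the two signals a
# druggability classifier leans on most.
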