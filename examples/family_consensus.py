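"""Group pockets into families and score the prediction consensus.

Families are single-linkage clusters of pockets whose binding-site sequences
align above a similarity cutoff (85 %); the consensus C = |n_d - n_ld|/N x 100
says how unanimous the druggability predictions are within a family.
"""

from pocketdrug import cluster_families, consensus
from pocketdrug.families import score_families

# binding-site sequences for six pockets: two riboswitch variants and an
# unrelated site
sequences = {
    "tpp_a": "GAGCCUUAGGGACUAG",
    "tpp_b": "GAGCCUUAGGGACUAG",
    "tpp_c": "GAGCCUUAGGGACUAA",   # one substitution
    "ztp_a": "CCGGUUAACGGA",
    "ztp_b": "CCGGUUAACGGA",
    "other": "AAAAAAAAAAAAAAAA",
}
predictions = {
    "tpp_a": "druggable", "tpp_b": "less_druggable", "tpp_c": "less_druggable",
    "ztp_a": "druggable", "ztp_b": "druggable", "other": "less_druggable",
}

families = cluster_families(sequences, cutoff=85)
score_families(families, predictions)
for fam in sorted(families, key=lambda f: -len(f.member_ids)):
    print(f"family {sorted(fam.member_ids)}: "
          f"{fam.n_d} druggable / {fam.n_ld} less druggable, "
          f"consensus {fam.consensus:.1f}%")

# published worked values for three real families:
print("\nconsensus(7, 9)  =", consensus(7, 9), "% (16-member TPP family)")
print("consensus(1, 2)  =", round(consensus(1, 2), 1), "% (3-member ZTP family)")
print("consensus(2, 2)  =", consensus(2, 2), "% (4-member aminoglycoside family)")
# 100% means every family member got the same prediction; 0% an even split.
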