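"""Pocket families by sequence similarity and per-family prediction consensus.

Pockets (or whole chains) are compared by global pairwise alignment with
identity scoring; pairs above a similarity cutoff (>98 % for overall
sequence, >85 % for binding-site sequence) are linked, and families are the
transitive closure (single linkage).  The consensus of the druggability
predictions within a family is

    C = |n_d − n_ld| / N × 100

so that a unanimous family scores 100 % and an evenly split one 0 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

from ._tables import one_letter_code
from .structio import Pocket, Residue, ResidueClass
from .surface import SurfaceAnalysis


@dataclass
class BindingSiteSequence:
    pocket_id: str
    residue_codes: list[str]     # parent codes, ascending residue order

    def __post_init__(self) -> None:
        if not self.residue_codes:
            raise ValueError(f"{self.pocket_id}: empty binding-site sequence")

    def as_string(self) -> str:
        return "".join(one_letter_code(c) for c in self.residue_codes)


@dataclass
class Family:
    member_ids: set[str]
    linkage_basis: str           # "overall_sequence" | "binding_site"
    n_d: int = 0
    n_ld: int = 0

    @property
    def consensus(self) -> float:
        return consensus(self.n_d, self.n_ld)


#: infinitesimal gap penalty: breaks score ties toward gap-free alignments
#: (a zero penalty lets the aligner pad equal-scoring alignments with gaps,
#: inflating the alignment length) without materially changing the scoring
_GAP_TIEBREAK = 1e-6


def _make_aligner(match: float = 1.0, mismatch: float = 0.0,
                  gap: float = 0.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap - _GAP_TIEBREAK
    aligner.extend_gap_score = gap - _GAP_TIEBREAK
    return aligner


def sequence_similarity(a: str, b: str, match: float = 1.0,
                        mismatch: float = 0.0, gap: float = 0.0) -> float:
    """Percent similarity from a global pairwise alignment.

    Identity scoring by default (match = 1, mismatch = 0, no gap penalty);
    similarity = matches / alignment length × 100.  Symmetric.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(match, mismatch, gap)
    alignment = aligner.align(a, b)[0]
    matches = 0
    length = 0
    seq_a, seq_b = alignment[0], alignment[1]
    for x, y in zip(seq_a, seq_b):
        length += 1
        if x == y and x != "-":
            matches += 1
    return matches / length * 100.0 if length else 0.0


def extract_bs_sequence(pocket: Pocket, analysis: SurfaceAnalysis) -> BindingSiteSequence:
    """Binding-site sequence: residues contributing at least one binding-site
    atom, in ascending (chain, residue-number) order; modified nucleotides
    are emitted under their parent code."""
    touched: dict[tuple[str, int], Residue] = {}
    for rec in analysis.binding_site_records:
        res = rec.atom.residue
        if res is None:
            continue
        touched.setdefault((res.chain_id, res.seq_id), res)
    if not touched:
        raise ValueError(f"{pocket.pocket_id}: no binding-site residues")
    codes = []
    for key in sorted(touched):
        res = touched[key]
        if res.residue_class is ResidueClass.MODIFIED_NUCLEOTIDE and res.parent_code:
            codes.append(res.parent_code)
        else:
            codes.append(res.name)
    return BindingSiteSequence(pocket_id=pocket.pocket_id, residue_codes=codes)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_by_similarity(
    ids: Sequence[str],
    similarity: "np.ndarray | Sequence[Sequence[float]]",
    cutoff: float,
    linkage_basis: str = "binding_site",
) -> list[Family]:
    """Single-linkage clustering from a precomputed pairwise similarity
    matrix (percent): pairs strictly above ``cutoff`` are linked and
    families are the transitive closure."""
    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    n = len(ids)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if similarity[i][j] > cutoff:
                uf.union(i, j)
    groups: dict[int, set[str]] = {}
    for k, pid in enumerate(ids):
        groups.setdefault(uf.find(k), set()).add(pid)
    return [Family(member_ids=members, linkage_basis=linkage_basis)
            for members in groups.values()]


def cluster_families(
    items: Mapping[str, str],
    cutoff: float,
    linkage_basis: str = "binding_site",
) -> list[Family]:
    """Single-linkage clustering: items (id → sequence string) with pairwise
    similarity strictly above ``cutoff`` percent end up in the same family
    (transitive closure); every item lands in exactly one family."""
    ids = list(items)
    n = len(ids)
    sim = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            sim[i][j] = sim[j][i] = sequence_similarity(items[ids[i]], items[ids[j]])
    return cluster_by_similarity(ids, sim, cutoff, linkage_basis)


def consensus(n_d: int, n_ld: int) -> float:
    """Family prediction consensus C = |n_d − n_ld| / N × 100 (percent).

    100 when all members share a prediction, 0 for an even split."""
    total = n_d + n_ld
    if total < 1:
        raise ValueError("consensus of an empty family is undefined")
    if n_d < 0 or n_ld < 0:
        raise ValueError("negative class counts")
    return abs(n_d - n_ld) / total * 100.0


def score_families(families: Sequence[Family],
                   predictions: Mapping[str, str]) -> list[Family]:
    """Fill each family's druggable / less-druggable counts from a
    pocket_id → label mapping (labels: 'druggable' / 'less_druggable')."""
    for fam in families:
        fam.n_d = sum(1 for m in fam.member_ids if predictions.get(m) == "druggable")
        fam.n_ld = sum(1 for m in fam.member_ids if predictions.get(m) == "less_druggable")
    return list(families)
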