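"""Receptor family assignment by best hit plus tree placement.

Candidates are first labelled by their best-scoring reference protein
(local BLOSUM62 alignment, blastx-style); candidates whose best hit is a
taste receptor or other non-olfactory GPCR are rejected outright. Survivors
are placed in a neighbor-joining tree together with all reference proteins;
a candidate is retained only when it attaches inside its family's clade,
i.e. its smallest enclosing clade that contains any reference contains only
references of the assigned family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from Bio import Align

from .mining import DECOY_LABELS, GeneModel, ReferenceDB
from .phylogeny import nj_tree

_CAND = "__candidate__"


@dataclass
class FamilyAssignment:
    family: Optional[str]
    retained: bool
    reason: str
    best_hit_id: str = ""
    best_score: float = 0.0


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    a.open_end_gap_score = -2
    a.extend_end_gap_score = -1
    return a


def _sanitize(protein: str) -> str:
    return "".join("X" if c in "*!" else c for c in protein)


def _global_distance(a: str, b: str, aligner) -> float:
    """1 - identity over the global alignment span."""
    aln = aligner.align(a, b)[0]
    ta, qa = aln[0], aln[1]
    matches = sum(1 for x, y in zip(ta, qa) if x == y and x != "-")
    return 1.0 - matches / max(len(ta), 1)


def _ref_distance_matrix(refdb: ReferenceDB, aligner) -> dict:
    if refdb._ref_dist is None:
        n = len(refdb.records)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _global_distance(
                    refdb.records[i][1], refdb.records[j][1], aligner
                )
        refdb._ref_dist = {"matrix": d}
    return refdb._ref_dist


def assign_family(
    candidate: Union[GeneModel, str], refdb: ReferenceDB
) -> FamilyAssignment:
    """Two-stage family assignment (best hit, then tree placement)."""
    if not refdb.records:
        raise ValueError("empty reference database")
    protein = candidate.aligned_protein if isinstance(candidate, GeneModel) else candidate
    protein = _sanitize(protein)
    if not protein:
        raise ValueError("empty candidate protein")

    local = _local_aligner()
    best_id, best_label, best_score = "", "", -np.inf
    for rid, rseq, label in refdb.records:
        s = local.score(rseq, protein)
        if s > best_score:
            best_id, best_label, best_score = rid, label, s
    if best_label in DECOY_LABELS:
        return FamilyAssignment(
            family=None,
            retained=False,
            reason=f"best hit is {best_label} ({best_id})",
            best_hit_id=best_id,
            best_score=float(best_score),
        )

    glob = _global_aligner()
    ref_d = _ref_distance_matrix(refdb, glob)["matrix"]
    n = len(refdb.records)
    d = np.zeros((n + 1, n + 1))
    d[:n, :n] = ref_d
    for i, (_, rseq, _) in enumerate(refdb.records):
        d[i, n] = d[n, i] = _global_distance(rseq, protein, glob)
    labels = [rid for rid, _, _ in refdb.records] + [_CAND]
    tree = nj_tree(labels, d)

    label_of = {rid: lab for rid, _, lab in refdb.records}
    outgroups = [rid for rid, _, lab in refdb.records if lab in DECOY_LABELS]
    if outgroups:
        og = tree.find_node_with_taxon_label(outgroups[0])
        tree.to_outgroup_position(og, update_bipartitions=False)
    cand_leaf = tree.find_node_with_taxon_label(_CAND)
    node = cand_leaf.parent_node
    while node is not None:
        others = [
            lf.taxon.label
            for lf in node.leaf_iter()
            if lf.taxon.label != _CAND
        ]
        if others:
            fams = {label_of[o] for o in others}
            if fams == {best_label}:
                return FamilyAssignment(
                    family=best_label,
                    retained=True,
                    reason="nested within family clade",
                    best_hit_id=best_id,
                    best_score=float(best_score),
                )
            return FamilyAssignment(
                family=best_label,
                retained=False,
                reason=f"attaches outside the {best_label} clade (near {sorted(fams)})",
                best_hit_id=best_id,
                best_score=float(best_score),
            )
        node = node.parent_node
    return FamilyAssignment(
        family=best_label,
        retained=False,
        reason="tree placement inconclusive",
        best_hit_id=best_id,
        best_score=float(best_score),
    )
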