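"""Spliced protein-to-genome gene prediction and loss-of-function calls.

The aligner is a local dynamic program in the spirit of protein2genome
spliced alignment: the query protein is aligned to the locus DNA codon by
codon under BLOSUM62 with affine gaps, introns are permitted only between
codons, only with GT...AG terminal dinucleotides, and only with lengths in
``[min_intron_bp, max_intron_bp]``; frameshift states (codons of 1-2 nt, or
1-2 extra nt) are allowed at a fixed penalty so that pseudogenes align
through their disabling mutations. In-frame stop codons score like BLOSUM62
'*' and therefore do not interrupt the alignment either.

Ties are broken deterministically: codon continuation is preferred over
frameshifts, non-intron predecessors over introns (fewer introns), and the
leftmost best cell wins.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numba
import numpy as np

from ._seq import (
    AA_ALPHABET,
    BLOSUM62,
    STOP_CODE,
    STOP_CODONS,
    encode_dna,
    encode_protein,
    revcomp,
    translate,
    translate_codes,
)
from .mining import CandidateLocus, GeneModel, GenomeAssembly, LofEvent, MiningConfig

NEG = -(10**9)


@numba.njit(cache=True)
def _spliced_align_kernel(
    q,
    aa_at,
    is_gt,
    is_ag,
    submat,
    gap_open,
    gap_ext,
    codon_gap_ext,
    fs_pen,
    intron_pen,
    min_intron,
    max_intron,
    tb,
    tbx,
    tby,
    donor_all,
):  # pragma: no cover - exercised via predict_gene_model
    m = q.shape[0]
    n = aa_at.shape[0] - 1
    Mprev = np.full(n + 1, NEG, np.int32)
    Mcur = np.full(n + 1, NEG, np.int32)
    Xprev = np.full(n + 1, NEG, np.int32)
    Xcur = np.full(n + 1, NEG, np.int32)
    Yprev = np.full(n + 1, NEG, np.int32)
    Ycur = np.full(n + 1, NEG, np.int32)
    Iprev = np.full(n + 1, NEG, np.int32)
    Icur = np.full(n + 1, NEG, np.int32)
    dq_pos = np.empty(n + 2, np.int32)
    dq_val = np.empty(n + 2, np.int32)

    best = 0
    bi = -1
    bj = -1
    for i in range(1, m + 1):
        qc = q[i - 1]
        for j in range(0, n + 1):
            bestv = NEG
            code = 0
            if j >= 3 and aa_at[j] >= 0:
                s = submat[qc, aa_at[j]]
                pv = Mprev[j - 3]
                pc = 1
                if Xprev[j - 3] > pv:
                    pv = Xprev[j - 3]
                    pc = 2
                if Yprev[j - 3] > pv:
                    pv = Yprev[j - 3]
                    pc = 3
                if Iprev[j - 3] > pv:
                    pv = Iprev[j - 3]
                    pc = 4
                if pv < 0:
                    pv = 0
                    pc = 5
                bestv = pv + s
                code = pc
            if j >= 1:
                v = Mprev[j - 1] - fs_pen
                if v > bestv:
                    bestv = v
                    code = 6
                v = Mcur[j - 1] - fs_pen
                if v > bestv:
                    bestv = v
                    code = 8
            if j >= 2:
                v = Mprev[j - 2] - fs_pen
                if v > bestv:
                    bestv = v
                    code = 7
                v = Mcur[j - 2] - fs_pen
                if v > bestv:
                    bestv = v
                    code = 9
            Mcur[j] = bestv
            tb[i, j] = code
            if bestv > best:
                best = bestv
                bi = i
                bj = j
            # genome gap (skip a codon, no residue consumed)
            if j >= 3:
                xv = Mcur[j - 3] - gap_open
                xc = 1
                if Xcur[j - 3] - codon_gap_ext > xv:
                    xv = Xcur[j - 3] - codon_gap_ext
                    xc = 2
                Xcur[j] = xv
                tbx[i, j] = xc
            else:
                Xcur[j] = NEG
                tbx[i, j] = 0
            # query gap (residue unaligned, no nt consumed)
            yv = Mprev[j] - gap_open
            yc = 1
            if Yprev[j] - gap_ext > yv:
                yv = Yprev[j] - gap_ext
                yc = 2
            Ycur[j] = yv
            tby[i, j] = yc
        # intron layer for this row: sliding-window max over GT donors
        head = 0
        tail = 0
        for j in range(0, n + 1):
            jp = j - min_intron
            if jp >= 0 and is_gt[jp] == 1:
                v = Mcur[jp]
                if v > NEG // 2:
                    while tail > head and dq_val[tail - 1] < v:
                        tail -= 1
                    dq_pos[tail] = jp
                    dq_val[tail] = v
                    tail += 1
            while tail > head and dq_pos[head] < j - max_intron:
                head += 1
            if j >= 2 and is_ag[j] == 1 and tail > head:
                Icur[j] = dq_val[head] - intron_pen
                donor_all[i, j] = dq_pos[head]
            else:
                Icur[j] = NEG
                donor_all[i, j] = -1
        Mprev, Mcur = Mcur, Mprev
        Xprev, Xcur = Xcur, Xprev
        Yprev, Ycur = Ycur, Yprev
        Iprev, Icur = Icur, Iprev
    return best, bi, bj


def _traceback(tb, tbx, tby, donor_all, bi: int, bj: int) -> list:
    """Walk the traceback matrices from the best cell; returns ops 5'->3'.

    Op kinds (t-coordinates are locus-local, gene strand, half-open):
      ("codon", qpos, ts, te)    aligned codon (te-ts == 3)
      ("fs_codon", qpos, ts, te) frameshifted codon of 1-2 nt
      ("fs_ins", qpos, ts, te)   1-2 extra nt, no residue consumed
      ("tgap", -1, ts, te)       genome codon skipped (gap in query)
      ("qgap", qpos, ts, ts)     query residue unaligned
      ("intron", -1, ts, te)     spliced-out intron
    """
    ops = []
    state = 0  # 0=M, 1=X, 2=Y
    i, j = bi, bj
    while True:
        if state == 0:
            c = tb[i, j]
            if c == 0:
                raise AssertionError("invalid traceback")
            if c in (1, 2, 3, 4, 5):
                ops.append(("codon", i - 1, j - 3, j))
                if c == 5:
                    break
                if c == 4:
                    donor = int(donor_all[i - 1, j - 3])
                    ops.append(("intron", -1, donor, j - 3))
                    i, j, state = i - 1, donor, 0
                elif c == 1:
                    i, j, state = i - 1, j - 3, 0
                elif c == 2:
                    i, j, state = i - 1, j - 3, 1
                else:
                    i, j, state = i - 1, j - 3, 2
            elif c == 6:
                ops.append(("fs_codon", i - 1, j - 1, j))
                i, j = i - 1, j - 1
            elif c == 7:
                ops.append(("fs_codon", i - 1, j - 2, j))
                i, j = i - 1, j - 2
            elif c == 8:
                ops.append(("fs_ins", i, j - 1, j))
                j = j - 1
            elif c == 9:
                ops.append(("fs_ins", i, j - 2, j))
                j = j - 2
        elif state == 1:
            ops.append(("tgap", -1, j - 3, j))
            state = 0 if tbx[i, j] == 1 else 1
            j = j - 3
        else:
            ops.append(("qgap", i - 1, j, j))
            state = 0 if tby[i, j] == 1 else 2
            i = i - 1
    ops.reverse()
    return ops


def predict_gene_model(
    locus: CandidateLocus,
    query: str,
    genome: GenomeAssembly,
    config: Optional[MiningConfig] = None,
) -> Optional[GeneModel]:
    """Maximum-scoring spliced alignment of ``query`` to the locus DNA.

    Returns ``None`` when no positive-scoring local alignment exists.
    """
    config = config or MiningConfig()
    contig = genome.contigs[locus.contig_id]
    dna_fwd = contig[locus.start : locus.end]
    if len(dna_fwd) < 3:
        raise ValueError("locus shorter than one codon")
    if not query:
        raise ValueError("empty query")
    dna = dna_fwd if locus.strand == "+" else revcomp(dna_fwd)

    dc = encode_dna(dna)
    n = len(dna)
    q = encode_protein(query)
    m = len(q)

    # aa_at[j] = aa code of codon dna[j-3:j]; -1 where undefined
    aa_at = np.full(n + 1, -1, dtype=np.int8)
    if n >= 3:
        codes0 = translate_codes(dc)
        codes1 = translate_codes(dc[1:])
        codes2 = translate_codes(dc[2:])
        aa_at[3 + 3 * np.arange(len(codes0))] = codes0
        if len(codes1):
            aa_at[4 + 3 * np.arange(len(codes1))] = codes1
        if len(codes2):
            aa_at[5 + 3 * np.arange(len(codes2))] = codes2
    is_gt = np.zeros(n + 1, dtype=np.int8)
    is_ag = np.zeros(n + 1, dtype=np.int8)
    for jp in range(0, n - 1):
        if dna[jp] == "G" and dna[jp + 1] == "T":
            is_gt[jp] = 1
    for j in range(2, n + 1):
        if dna[j - 2] == "A" and dna[j - 1] == "G":
            is_ag[j] = 1

    tb = np.zeros((m + 1, n + 1), dtype=np.int8)
    tbx = np.zeros((m + 1, n + 1), dtype=np.int8)
    tby = np.zeros((m + 1, n + 1), dtype=np.int8)
    donor_all = np.full((m + 1, n + 1), -1, dtype=np.int32)
    submat = BLOSUM62.copy()
    submat[:, STOP_CODE] = -config.stop_penalty
    best, bi, bj = _spliced_align_kernel(
        q,
        aa_at,
        is_gt,
        is_ag,
        submat,
        config.gap_open,
        config.gap_extend,
        config.codon_gap_extend,
        config.frameshift_penalty,
        config.intron_penalty,
        config.min_intron_bp,
        config.max_intron_bp,
        tb,
        tbx,
        tby,
        donor_all,
    )
    if bi < 0 or best <= 0:
        return None
    ops = _traceback(tb, tbx, tby, donor_all, bi, bj)
    ops = _polish_ends(ops, dna, query, config)
    if not ops:
        return None
    return _ops_to_model(ops, dna, locus, query, float(best))


def _polish_ends(ops: list, dna: str, query: str, config) -> list:
    """Trim low-identity alignment ends (chance extensions into flanks).

    While the terminal ``end_polish_window`` aligned codons fall below
    ``end_polish_identity``, the outermost codon (and any non-codon ops
    beyond it) is removed. Genuine receptor models at the divergences this
    pipeline targets sit far above the floor and are left untouched.
    """
    w = config.end_polish_window
    thr = config.end_polish_identity

    def is_match(op) -> bool:
        _, qpos, ts, te = op
        return translate(dna[ts:te]) == query[qpos]

    codon_idx = [k for k, op in enumerate(ops) if op[0] == "codon"]
    if len(codon_idx) <= w:
        return ops
    matches = {k: is_match(ops[k]) for k in codon_idx}
    lo, hi = 0, len(codon_idx)  # active slice of codon ops
    while hi - lo > w:
        window = codon_idx[hi - w : hi]
        if sum(matches[k] for k in window) / w >= thr:
            break
        hi -= 1
    while hi - lo > w:
        window = codon_idx[lo : lo + w]
        if sum(matches[k] for k in window) / w >= thr:
            break
        lo += 1
    if lo == 0 and hi == len(codon_idx):
        return ops
    return ops[codon_idx[lo] : codon_idx[hi - 1] + 1]


def _ops_to_model(
    ops: list, dna: str, locus: CandidateLocus, query: str, score: float
) -> GeneModel:
    consuming = {"codon", "fs_codon", "fs_ins", "tgap"}
    # exon intervals in gene-strand locus-local coordinates, split at introns
    exons_local: List[Tuple[int, int]] = []
    cur_s = cur_e = None
    cds_parts: List[str] = []
    aligned_aa: List[str] = []
    qpositions = []
    n_match = 0
    n_codon = 0
    for kind, qpos, ts, te in ops:
        if kind == "intron":
            if cur_s is not None:
                exons_local.append((cur_s, cur_e))
                cur_s = cur_e = None
            continue
        if kind in consuming:
            if cur_s is None:
                cur_s, cur_e = ts, te
            else:
                cur_e = te
            cds_parts.append(dna[ts:te])
        if kind == "codon":
            n_codon += 1
            aa = translate(dna[ts:te])
            aligned_aa.append(aa)
            if aa == query[qpos]:
                n_match += 1
            qpositions.append(qpos)
        elif kind == "fs_codon":
            aligned_aa.append("!")
            qpositions.append(qpos)
        elif kind == "qgap":
            qpositions.append(qpos)
    if cur_s is not None:
        exons_local.append((cur_s, cur_e))

    L = locus.end - locus.start
    if locus.strand == "+":
        exons = [(locus.start + s, locus.start + e) for s, e in exons_local]
    else:
        exons = [(locus.end - e, locus.end - s) for s, e in exons_local]

    cds_nt = "".join(cds_parts)
    protein_full = translate(cds_nt)
    stop_at = protein_full.find("*")
    protein = protein_full if stop_at < 0 else protein_full[:stop_at]
    q_span = (max(qpositions) - min(qpositions) + 1) if qpositions else 0
    coverage = q_span / len(query)
    pid = 100.0 * n_match / n_codon if n_codon else 0.0
    return GeneModel(
        locus=locus,
        exons=exons,
        cds_nt=cds_nt,
        protein=protein,
        aligned_protein="".join(aligned_aa),
        query_coverage=coverage,
        percent_identity=pid,
        alignment=ops,
        query_id=locus.best_query_id,
        score=score,
    )


# ---------------------------------------------------------------------------
# Loss-of-function detection and status classification
# ---------------------------------------------------------------------------


def detect_lof(model: GeneModel) -> List[LofEvent]:
    """Premature stops and frameshifts read off the spliced alignment.

    Premature stop: an aligned codon translating to '*' strictly before the
    codon aligned to the query's last aligned residue; reported with its
    0-based query-aligned codon index. The terminal stop codon (downstream
    of the alignment) is never an event. Frameshift: any 1-2 nt codon or
    1-2 nt insertion; reported as a nt offset (3 x query residues consumed).
    """
    if not model.alignment:
        raise ValueError("model has empty alignment")
    codon_q = [qpos for kind, qpos, _, _ in model.alignment if kind in ("codon", "fs_codon")]
    if not codon_q:
        return []
    last_q = max(codon_q)
    events: List[Tuple[int, LofEvent]] = []
    codon_i = 0
    for kind, qpos, ts, te in model.alignment:
        if kind == "codon":
            aa = model.aligned_protein[codon_i]
            codon_i += 1
            if aa == "*" and qpos < last_q:
                events.append(
                    (3 * qpos, LofEvent("premature_stop", qpos, "in-frame stop codon"))
                )
        elif kind == "fs_codon":
            codon_i += 1
            events.append(
                (
                    3 * qpos,
                    LofEvent("frameshift", 3 * qpos, f"codon of {te - ts} nt (deletion)"),
                )
            )
        elif kind == "fs_ins":
            events.append(
                (
                    3 * qpos,
                    LofEvent("frameshift", 3 * qpos, f"{te - ts} extra nt (insertion)"),
                )
            )
    events.sort(key=lambda t: (t[0], t[1].kind))
    return [e for _, e in events]


def classify_status(
    model: GeneModel,
    lof: List[LofEvent],
    genome: GenomeAssembly,
    config: Optional[MiningConfig] = None,
) -> str:
    """Four-way mutually exclusive status call.

    complete: full-length ORF (ATG start, terminal stop, coverage >= 0.9)
    and no LOF event; pseudogene: >= 1 LOF event; otherwise truncated or
    edge depending on the distance of the genomic span to the contig ends.
    """
    config = config or MiningConfig()
    contig = genome.contigs[model.locus.contig_id]
    L = len(contig)
    s, e = model.span
    if lof:
        return "pseudogene"
    has_start = model.cds_nt[:3] == "ATG"
    if model.locus.strand == "+":
        nxt = contig[e : e + 3]
    else:
        nxt = revcomp(contig[max(0, s - 3) : s])
    has_stop = nxt in STOP_CODONS
    if has_start and has_stop and model.query_coverage >= config.complete_min_coverage:
        return "complete"
    if min(s, L - e) < config.edge_distance_bp:
        return "edge"
    return "truncated"
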