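"""Receptor gene mining: homology search, locus assembly, status calls.

The pipeline mirrors the classic chemoreceptor-census workflow: a translated
(six-frame) homology search seeds candidate regions, overlapping hit regions
are merged and extended, a spliced protein-to-genome alignment predicts the
gene model, loss-of-function mutations are read off the alignment, and each
candidate is classified as complete / pseudogene / truncated / edge and
assigned to a receptor family by best-hit plus tree placement.

Coordinates are 0-based half-open on the forward strand everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import (
    BLOSUM62,
    KA_K,
    KA_LAMBDA,
    encode_protein,
    revcomp,
    translate_codes,
    encode_dna,
    validate_dna,
)

logger = logging.getLogger(__name__)

FAMILIES = ("OR", "TAAR", "TARL", "V1R_ORA", "V2R_OLFC", "V2R_LIKE")
DECOY_LABELS = ("taste_receptor", "other_gpcr")
STATUSES = ("complete", "pseudogene", "truncated", "edge")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeAssembly:
    """A genome assembly held in memory as contig_id -> DNA sequence."""

    contigs: Dict[str, str]
    assembly_id: str = "assembly"

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            validate_dna(seq, f"contig {cid!r}")

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class MiningConfig:
    evalue_threshold: float = 1e-10
    extension_bp: int = 20_000
    min_intron_bp: int = 50
    max_intron_bp: int = 20_000
    edge_distance_bp: int = 5_000
    seed_word_size: int = 4
    xdrop: int = 20
    min_hsp_score: int = 40
    gap_open: int = 11
    gap_extend: int = 1  # query-side (residues unmatched), per residue
    codon_gap_extend: int = 3  # genome-side codon skips; pricier so chance
    # skip-and-match excursions into flanking sequence stay net-negative
    frameshift_penalty: int = 28
    intron_penalty: int = 40
    stop_penalty: int = 15  # aligning a residue to an in-frame stop; must
    # stay below 2x gap_open and the frameshift/intron penalties so real
    # pseudogene stops are aligned through, not hidden
    complete_min_coverage: float = 0.9
    end_polish_window: int = 10  # codons; terminal windows below the
    end_polish_identity: float = 0.3  # identity floor are trimmed; the
    # floor sits well below genuine diverged ends (~75% aa identity) and
    # well above chance extensions (~7-20%)

    def __post_init__(self) -> None:
        if not (0 < self.evalue_threshold <= 1):
            raise ValueError("evalue_threshold must be in (0, 1]")
        if self.extension_bp < 0:
            raise ValueError("extension_bp must be >= 0")
        if self.min_intron_bp >= self.max_intron_bp:
            raise ValueError("min_intron_bp must be < max_intron_bp")


@dataclass(frozen=True)
class HomologyHit:
    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    query_id: str
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must be < end")


@dataclass
class CandidateLocus:
    contig_id: str
    start: int
    end: int
    strand: str
    supporting_hits: List[HomologyHit]
    best_query_id: str


@dataclass(frozen=True)
class LofEvent:
    kind: str  # "premature_stop" | "frameshift"
    cds_position: int  # codon index for stops, nt offset for indels
    detail: str = ""


@dataclass
class GeneModel:
    locus: CandidateLocus
    exons: List[Tuple[int, int]]  # genomic forward coords, ordered 5'->3'
    cds_nt: str
    protein: str
    aligned_protein: str  # translation of every aligned codon, stops as '*'
    query_coverage: float
    percent_identity: float
    alignment: list  # list of ops, see genemodel.py
    query_id: str = ""
    score: float = 0.0

    @property
    def span(self) -> Tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass
class ReceptorGene:
    gene_model: GeneModel
    family: str
    status: str
    lof_events: List[LofEvent]
    name: str


@dataclass
class ReferenceDB:
    """Reference proteins labelled by receptor family or decoy class."""

    records: List[Tuple[str, str, str]]  # (record_id, protein, label)

    def __post_init__(self) -> None:
        labels = {lab for _, _, lab in self.records}
        missing = [f for f in ("OR", "TAAR", "V1R_ORA", "V2R_OLFC") if f not in labels]
        if missing:
            raise ValueError(f"reference DB missing olfactory families: {missing}")
        self._ref_dist: Optional[dict] = None

    def by_label(self, label: str) -> List[Tuple[str, str]]:
        return [(rid, seq) for rid, seq, lab in self.records if lab == label]


@dataclass
class ProbeConfig:
    max_mismatch_fraction: float = 0.24
    min_alignment_coverage: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.max_mismatch_fraction <= 1):
            raise ValueError("max_mismatch_fraction must be in [0,1]")
        if not (0 < self.min_alignment_coverage <= 1):
            raise ValueError("min_alignment_coverage must be in (0,1]")


# ---------------------------------------------------------------------------
# Translated homology search (seed + ungapped X-drop extension)
# ---------------------------------------------------------------------------


def _extend_hsp(
    qcodes: np.ndarray, tcodes: np.ndarray, qp: int, tp: int, k: int, xdrop: int
) -> Tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact k-mer seed.

    Returns (q_start, q_end, t_start, t_end, score), half-open in residues.
    """
    S = BLOSUM62
    score = 0
    for o in range(k):
        score = score + S[qcodes[qp + o], tcodes[tp + o]]
    # extend right
    best = score
    bq, bt = qp + k, tp + k
    cur = score
    i, j = qp + k, tp + k
    while i < len(qcodes) and j < len(tcodes):
        cur += S[qcodes[i], tcodes[j]]
        i += 1
        j += 1
        if cur > best:
            best, bq, bt = cur, i, j
        elif best - cur > xdrop:
            break
    q_end, t_end = bq, bt
    # extend left
    cur = best
    best2 = best
    bq, bt = qp, tp
    i, j = qp - 1, tp - 1
    while i >= 0 and j >= 0:
        cur += S[qcodes[i], tcodes[j]]
        if cur > best2:
            best2, bq, bt = cur, i, j
        elif best2 - cur > xdrop:
            break
        i -= 1
        j -= 1
    return bq, q_end, bt, t_end, int(best2)


def _kmer_codes(codes: np.ndarray, k: int, nsym: int) -> np.ndarray:
    """Rolling k-mer integer codes; positions containing X/* are mapped to -1."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    valid = c < 20  # only the 20 standard residues can seed
    code = np.zeros(len(c) - k + 1, dtype=np.int64)
    okay = np.ones(len(c) - k + 1, dtype=bool)
    for o in range(k):
        code = code * nsym + c[o : len(c) - k + 1 + o]
        okay &= valid[o : len(c) - k + 1 + o]
    code[~okay] = -1
    return code


def translated_homology_search(
    genome: GenomeAssembly,
    queries: Dict[str, str],
    config: Optional[MiningConfig] = None,
) -> List[HomologyHit]:
    """Six-frame translated search of protein queries against a genome.

    Exact amino-acid word seeds (word size ``config.seed_word_size``) are
    extended without gaps under BLOSUM62 with an X-drop rule; HSP scores are
    converted to e-values with the ungapped Karlin-Altschul parameters and
    filtered at ``config.evalue_threshold``.
    """
    config = config or MiningConfig()
    if not queries:
        raise ValueError("no queries")
    if not genome.contigs:
        return []
    k = config.seed_word_size
    nsym = len("ARNDCQEGHILKMFPSTWYVBZX*")
    total_nt = len(genome)

    qinfo = {}
    for qid, qseq in queries.items():
        if not qseq:
            raise ValueError(f"query {qid!r} is empty")
        qc = encode_protein(qseq)
        codes = _kmer_codes(qc, k, nsym)
        lut: Dict[int, List[int]] = {}
        for pos, code in enumerate(codes):
            if code >= 0:
                lut.setdefault(int(code), []).append(pos)
        qinfo[qid] = (qc, lut)

    hits: List[HomologyHit] = []
    for cid in sorted(genome.contigs):
        seq = genome.contigs[cid]
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            dc = encode_dna(s)
            for frame in range(3):
                tcodes = translate_codes(dc[frame:])
                if len(tcodes) < k:
                    continue
                fcodes = _kmer_codes(tcodes, k, nsym)
                for qid, (qc, lut) in qinfo.items():
                    if not lut:
                        continue
                    qarr = np.fromiter(lut.keys(), dtype=np.int64)
                    mask = np.isin(fcodes, qarr)
                    tpos = np.nonzero(mask)[0]
                    seen: set = set()
                    best_hsps: Dict[Tuple[int, int], int] = {}
                    for tp in tpos:
                        for qp in lut[int(fcodes[tp])]:
                            diag = int(tp) - qp
                            if (diag, int(tp) // 16) in seen:
                                continue
                            qs, qe, ts, te, sc = _extend_hsp(
                                qc, tcodes, qp, int(tp), k, config.xdrop
                            )
                            for blk in range(ts // 16, te // 16 + 1):
                                seen.add((diag, blk))
                            if sc < config.min_hsp_score:
                                continue
                            key = (ts, te)
                            if sc > best_hsps.get(key, -1):
                                best_hsps[key] = sc
                    for (ts, te), sc in best_hsps.items():
                        bit = (KA_LAMBDA * sc - np.log(KA_K)) / np.log(2.0)
                        evalue = len(queries[qid]) * total_nt * 2.0 ** (-bit)
                        if evalue > config.evalue_threshold:
                            continue
                        nt_s = frame + 3 * ts
                        nt_e = frame + 3 * te
                        if strand == "-":
                            nt_s, nt_e = L - nt_e, L - nt_s
                        hits.append(
                            HomologyHit(
                                contig_id=cid,
                                start=nt_s,
                                end=nt_e,
                                strand=strand,
                                frame=frame,
                                query_id=qid,
                                bit_score=float(bit),
                                evalue=float(evalue),
                            )
                        )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.strand, h.query_id))
    logger.info("translated search: %d hits over %d queries", len(hits), len(queries))
    return hits


# ---------------------------------------------------------------------------
# Merge and extend hit regions into candidate loci
# ---------------------------------------------------------------------------


def merge_and_extend_hits(
    hits: Sequence[HomologyHit],
    genome: GenomeAssembly,
    config: Optional[MiningConfig] = None,
) -> List[CandidateLocus]:
    """Merge hits (same contig+strand) whose extended intervals overlap.

    Each hit interval is widened by ``extension_bp`` on both sides, clipped
    to the contig, and overlapping widened intervals are unioned into one
    candidate locus.
    """
    config = config or MiningConfig()
    ext = config.extension_bp
    groups: Dict[Tuple[str, str], List[HomologyHit]] = {}
    for h in hits:
        if h.contig_id not in genome.contigs:
            raise ValueError(f"hit contig {h.contig_id!r} not in genome")
        L = len(genome.contigs[h.contig_id])
        if h.end > L:
            raise ValueError(f"hit {h} out of contig bounds (len {L})")
        groups.setdefault((h.contig_id, h.strand), []).append(h)

    loci: List[CandidateLocus] = []
    for (cid, strand), group in groups.items():
        L = len(genome.contigs[cid])
        group = sorted(group, key=lambda h: (h.start, h.end))
        cur: List[HomologyHit] = []
        cur_s = cur_e = None
        for h in group:
            s = max(0, h.start - ext)
            e = min(L, h.end + ext)
            if cur and s <= cur_e:
                cur_e = max(cur_e, e)
                cur.append(h)
            else:
                if cur:
                    loci.append(_make_locus(cid, strand, cur_s, cur_e, cur))
                cur, cur_s, cur_e = [h], s, e
        if cur:
            loci.append(_make_locus(cid, strand, cur_s, cur_e, cur))
    loci.sort(key=lambda l: (l.contig_id, l.start, l.strand))
    logger.info("merged %d hits into %d candidate loci", len(hits), len(loci))
    return loci


def _make_locus(cid, strand, s, e, hits_in) -> CandidateLocus:
    best = max(hits_in, key=lambda h: (h.bit_score, h.query_id))
    return CandidateLocus(
        contig_id=cid,
        start=int(s),
        end=int(e),
        strand=strand,
        supporting_hits=list(hits_in),
        best_query_id=best.query_id,
    )


# ---------------------------------------------------------------------------
# Probe cross-reactivity
# ---------------------------------------------------------------------------


def probe_cross_reactivity(
    probe: str,
    transcripts: Sequence[Tuple[str, str]],
    config: Optional[ProbeConfig] = None,
) -> List[Tuple[str, float]]:
    """Transcripts an RNA probe is expected to cross-hybridise with.

    Moderately stringent hybridisation tolerates a bounded mismatch fraction
    between probe and target. The probe (cDNA sense) is aligned into each
    transcript with an infix edit-distance alignment; genes whose best
    alignment has mismatch fraction <= ``max_mismatch_fraction`` are
    returned sorted by ascending mismatch fraction.
    """
    import edlib

    config = config or ProbeConfig()
    if len(probe) < 50:
        raise ValueError("probe must be at least 50 nt")
    if not transcripts:
        raise ValueError("empty transcript set")
    out = []
    for gid, cdna in transcripts:
        res = edlib.align(probe, cdna, mode="HW", task="distance")
        frac = res["editDistance"] / len(probe)
        if frac <= config.max_mismatch_fraction:
            out.append((gid, float(frac)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
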