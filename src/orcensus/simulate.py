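"""Ground-truthed synthetic data for every pipeline stage.

Four generators: (1) gene families evolved by a linear birth-death process
(per-copy duplication rate lambda, loss rate mu, events/lineage/Ma) along a
dated species tree, with every true event recorded; (2) loss-of-function
mutagenesis of coding sequences (premature stops, 1-2 nt indels); (3)
synthetic genome assemblies with receptor genes planted in all four status
categories on random strands in i.i.d. background sequence; (4) labeled-OSN
position tables with beta-distributed radial positions and Bernoulli
primary/secondary lamella assignment.

All generators are reproducible from (params, seed); the master seed fans
out to per-component substreams so generators do not perturb each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from ._seq import STOP_CODONS, revcomp, translate
from .expression import LabeledCell, LamellaMeasurement
from .mining import FAMILIES, GenomeAssembly, LofEvent, ReferenceDB

AA20 = "ARNDCQEGHILKMFPSTWYV"

# ---------------------------------------------------------------------------
# Gene family birth-death simulation
# ---------------------------------------------------------------------------


@dataclass
class FamilySimParams:
    species_tree: str  # newick with branch lengths in Ma (dendropy.Tree ok)
    dup_rate: float  # lambda, events / lineage / Ma
    loss_rate: float  # mu
    root_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.root_count < 1:
            raise ValueError("root_count must be >= 1")


@dataclass
class FamilySimTruth:
    gene_tree: Optional[str]  # newick; None when the family went extinct
    extinct: bool
    branch_events: Dict[str, Tuple[int, int]]  # species branch -> (dups, losses)
    ancestral_counts: Dict[str, int]  # species node -> copies arriving there
    extant_counts: Dict[str, int]
    total_duplications: int
    total_losses: int


class _GNode:
    __slots__ = ("children", "label")

    def __init__(self, label: Optional[str] = None):
        self.children: List["_GNode"] = []
        self.label = label

    def newick(self) -> str:
        if not self.children:
            return self.label or "?"
        return "(" + ",".join(c.newick() for c in self.children) + ")"


def simulate_gene_family(params: FamilySimParams) -> FamilySimTruth:
    """Evolve a gene family along the species tree; record every event.

    Each extant copy independently waits an exponential time at rate
    lambda+mu; the event is a duplication with probability
    lambda/(lambda+mu), else a loss. Copies surviving to an internal
    species node speciate into all child branches. The returned gene tree
    is pruned of extinct lineages (unary nodes collapsed); event counts
    include events inside subsequently extinct subtrees.
    """
    tree = params.species_tree
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(
            data=tree, schema="newick", preserve_underscores=True,
            rooting="force-rooted",
        )
    rng = np.random.default_rng(params.seed)
    lam, mu = params.dup_rate, params.loss_rate
    total = lam + mu

    def node_label(nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label if nd.taxon else nd.label
        return nd.label or "+".join(sorted(lf.taxon.label for lf in nd.leaf_iter()))

    branch_events: Dict[str, List[int]] = {}
    arrivals: Dict[str, int] = {}
    extant: Dict[str, int] = {}
    for nd in tree.preorder_node_iter():
        branch_events.setdefault(node_label(nd), [0, 0])
        arrivals.setdefault(node_label(nd), 0)
        if nd.is_leaf():
            extant[node_label(nd)] = 0

    def at_node(sp_node) -> Optional[_GNode]:
        """One gene copy present at ``sp_node``; subtree of survivors."""
        label = node_label(sp_node)
        if sp_node.is_leaf():
            extant[label] += 1
            return _GNode(f"{label}_g{extant[label]}")
        kids = []
        for child in sp_node.child_nodes():
            sub = along_branch(child)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        nd = _GNode()
        nd.children = kids
        return nd

    def along_branch(sp_child) -> Optional[_GNode]:
        label = node_label(sp_child)
        duration = sp_child.edge.length or 0.0

        def lineage(t_remain: float) -> Optional[_GNode]:
            if total > 0:
                wait = rng.exponential(1.0 / total)
            else:
                wait = np.inf
            if wait >= t_remain:
                arrivals[label] += 1
                return at_node(sp_child)
            if rng.random() < (lam / total if total > 0 else 0.0):
                branch_events[label][0] += 1
                a = lineage(t_remain - wait)
                b = lineage(t_remain - wait)
                if a is None:
                    return b
                if b is None:
                    return a
                nd = _GNode()
                nd.children = [a, b]
                return nd
            branch_events[label][1] += 1
            return None

        return lineage(duration)

    root = tree.seed_node
    root_label = node_label(root)
    roots = []
    for _ in range(params.root_count):
        sub = at_node(root)
        if sub is not None:
            roots.append(sub)
    arrivals[root_label] = params.root_count
    if not roots:
        gene_tree = None
    elif len(roots) == 1:
        gene_tree = roots[0].newick() + ";"
    else:
        top = _GNode()
        top.children = roots
        gene_tree = top.newick() + ";"

    return FamilySimTruth(
        gene_tree=gene_tree,
        extinct=gene_tree is None,
        branch_events={k: (v[0], v[1]) for k, v in branch_events.items()},
        ancestral_counts=dict(arrivals),
        extant_counts=dict(extant),
        total_duplications=sum(v[0] for v in branch_events.values()),
        total_losses=sum(v[1] for v in branch_events.values()),
    )


# ---------------------------------------------------------------------------
# Loss-of-function mutagenesis
# ---------------------------------------------------------------------------


def _check_orf(cds: str) -> None:
    if len(cds) % 3 != 0 or len(cds) < 30:
        raise ValueError("cds must be a multiple of 3 and >= 30 nt")
    if cds[:3] != "ATG":
        raise ValueError("cds must start with ATG")
    if "*" in translate(cds):
        raise ValueError("cds must not contain internal stop codons")


def pseudogenize(
    cds: str,
    events,
    seed: int = 0,
) -> Tuple[str, List[LofEvent]]:
    """Introduce premature stops and/or frameshifting indels into an ORF.

    ``events`` is either a list of ``(kind, position)`` pairs (codon index
    for ``premature_stop``, nt offset for ``frameshift``) or an integer
    count of random events. Returns the mutated CDS and the ground-truth
    event list in the coordinate convention of ``detect_lof`` (indel
    positions are snapped to codon boundaries in random mode).
    """
    _check_orf(cds)
    rng = np.random.default_rng(seed)
    ncod = len(cds) // 3
    if isinstance(events, int):
        n = events
        if n > (ncod - 25) // 3:
            raise ValueError("too many events for this cds")
        # keep random events >= 12 codons from the gene start and >= 10
        # from the end: a frameshift closer to a gene boundary than the
        # frameshift penalty is worth cannot be distinguished from a
        # trimmed local alignment
        codons = rng.choice(np.arange(12, ncod - 10), size=n, replace=False)
        codons = sorted(int(c) for c in codons)
        # events closer than ~12 codons are not independently resolvable:
        # absorbing the intervening out-of-frame stretch as mismatches can
        # cost less than a second frameshift state
        for a, b in zip(codons, codons[1:]):
            if b - a < 12:
                return pseudogenize(cds, n, seed + 1)
        kinds = rng.choice(["premature_stop", "frameshift"], size=n)
        events = [
            (k, c if k == "premature_stop" else 3 * c)
            for k, c in zip(kinds, codons)
        ]
    truth: List[LofEvent] = []
    seq = cds
    for kind, pos in sorted(events, key=lambda e: -(e[1] if e[0] == "frameshift" else 3 * e[1])):
        if kind == "premature_stop":
            if not (0 < pos < ncod):
                raise ValueError(f"stop position {pos} outside CDS")
            stop = str(rng.choice(list(STOP_CODONS)))
            seq = seq[: 3 * pos] + stop + seq[3 * pos + 3 :]
            truth.append(LofEvent("premature_stop", int(pos), f"codon -> {stop}"))
        elif kind == "frameshift":
            if not (0 < pos < len(seq)):
                raise ValueError(f"frameshift position {pos} outside CDS")
            k = int(rng.integers(1, 3))  # 1 or 2 nt
            if rng.random() < 0.5:
                seq = seq[:pos] + seq[pos + k :]
                truth.append(LofEvent("frameshift", int(pos), f"-{k} nt"))
            else:
                ins = "".join(rng.choice(list("ACGT"), k))
                seq = seq[:pos] + ins + seq[pos:]
                truth.append(LofEvent("frameshift", int(pos), f"+{k} nt"))
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    truth.sort(key=lambda e: (3 * e.cds_position if e.kind == "premature_stop" else e.cds_position))
    return seq, truth


# ---------------------------------------------------------------------------
# Synthetic genomes with planted receptor loci
# ---------------------------------------------------------------------------

DEFAULT_STATUS_PLAN: List[Tuple[str, str]] = [
    ("OR", "complete"),
    ("OR", "complete"),
    ("OR", "complete"),
    ("OR", "pseudogene"),
    ("OR", "truncated"),
    ("OR", "edge"),
    ("TAAR", "complete"),
    ("TAAR", "complete"),
    ("TAAR", "pseudogene"),
    ("V1R_ORA", "complete"),
]


@dataclass
class GenomeSimParams:
    templates: Optional[Dict[str, List[Tuple[str, str]]]] = None  # family -> [(name, cds)]
    divergence: float = 0.15  # nt substitution fraction, third-position biased
    status_plan: List[Tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_STATUS_PLAN)
    )
    intron_every: int = 3  # every k-th planted gene receives one intron
    intron_length_range: Tuple[int, int] = (200, 1500)
    contig_length: int = 30_000
    edge_offset_range: Tuple[int, int] = (100, 1200)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        for fam, status in self.status_plan:
            if status not in ("complete", "pseudogene", "truncated", "edge"):
                raise ValueError(f"unknown status {status!r}")


@dataclass
class PlantedGene:
    name: str
    family: str
    status: str
    contig_id: str
    start: int  # forward-strand, 0-based half-open, introns included
    end: int
    strand: str
    protein: str  # translation of the diverged (pre-mutation) CDS
    lof_events: List[LofEvent]
    n_introns: int


@dataclass
class SyntheticGenomeTruth:
    genes: List[PlantedGene]
    queries: Dict[str, str]  # template proteins used for planting

    def census(self) -> pd.DataFrame:
        rows = {}
        for g in self.genes:
            key = g.family
            rows.setdefault(
                key, {"family": key, "complete": 0, "pseudogene": 0, "truncated": 0, "edge": 0}
            )
            rows[key][g.status] += 1
        return (
            pd.DataFrame(sorted(rows.values(), key=lambda r: r["family"]))
            .reset_index(drop=True)
        )

    def gff3(self) -> str:
        lines = ["##gff-version 3"]
        for g in self.genes:
            attrs = f"ID={g.name};family={g.family};status={g.status}"
            lines.append(
                "\t".join(
                    [
                        g.contig_id,
                        "orcensus_sim",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
            )
        return "\n".join(lines) + "\n"


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate(a + b + c) not in ("*", "M")
]


def random_orf(n_codons: int, rng) -> str:
    """Random ORF: ATG + random non-stop, non-ATG codons (no terminal stop)."""
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 1)
    return "ATG" + "".join(body)


def make_default_templates(
    seed: int = 0, n_codons: int = 300, families: Sequence[str] = ("OR", "TAAR", "V1R_ORA", "V2R_OLFC")
) -> Dict[str, List[Tuple[str, str]]]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    return {fam: [(f"{fam}_tpl", random_orf(n_codons, rng))] for fam in families}


def diverge_cds(cds: str, divergence: float, rng) -> str:
    """Codon-aware divergence: substitutions with 3:1 third-position bias.

    The initial ATG and the final two codons are kept intact and no
    in-frame stop codon is ever introduced, so a planted 'complete' gene
    stays complete.
    """
    n = len(cds)
    ncod = n // 3
    n_sub = int(round(divergence * n))
    seq = list(cds)
    weights = np.ones(n)
    weights[2::3] = 3.0
    weights[:3] = 0.0
    weights[-6:] = 0.0
    weights /= weights.sum()
    done = 0
    attempts = 0
    while done < n_sub and attempts < 50 * n_sub:
        attempts += 1
        pos = int(rng.choice(n, p=weights))
        old = seq[pos]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        codon_i = pos // 3
        trial = seq[3 * codon_i : 3 * codon_i + 3]
        trial[pos % 3] = new
        if translate("".join(trial)) == "*":
            continue
        seq[pos] = new
        done += 1
    return "".join(seq)


def diverge_protein(protein: str, aa_divergence: float, rng) -> str:
    """Uniform amino-acid substitutions (for reference DB construction)."""
    seq = list(protein)
    n_sub = int(round(aa_divergence * len(seq)))
    idx = rng.choice(np.arange(1, len(seq)), size=min(n_sub, len(seq) - 1), replace=False)
    for i in idx:
        seq[i] = str(rng.choice([a for a in AA20 if a != seq[i]]))
    return "".join(seq)


def make_reference_db(
    templates: Dict[str, List[Tuple[str, str]]],
    seed: int = 0,
    n_refs_per_family: int = 3,
    ref_divergence: float = 0.08,
) -> ReferenceDB:
    """Reference proteins: diverged copies of each family template plus
    random decoy 'taste_receptor' and 'other_gpcr' proteins."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    records = []
    for fam in sorted(templates):
        for name, cds in templates[fam]:
            prot = translate(cds)
            for i in range(n_refs_per_family):
                records.append(
                    (f"{fam}_ref{i + 1}", diverge_protein(prot, ref_divergence, rng), fam)
                )
    for lab in ("taste_receptor", "other_gpcr"):
        for i in range(n_refs_per_family):
            records.append(
                (f"{lab}{i + 1}", translate(random_orf(300, rng)), lab)
            )
    return ReferenceDB(records)


def build_synthetic_genome(
    params: GenomeSimParams,
) -> Tuple[GenomeAssembly, SyntheticGenomeTruth]:
    """Plant one receptor gene per contig according to the status plan.

    Each planted gene is a diverged copy of its family template; statuses
    are realised by LOF mutagenesis (pseudogene), 3' truncation placed
    mid-contig (truncated), or 5' truncation placed within the edge
    distance of a contig end (edge). Strands are random; background is
    i.i.d. uniform ACGT.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 17]))
    templates = params.templates or make_default_templates(params.seed)
    contigs: Dict[str, str] = {}
    genes: List[PlantedGene] = []
    fam_counter: Dict[str, int] = {}
    for i, (fam, status) in enumerate(params.status_plan):
        if fam not in templates:
            raise ValueError(f"no template for family {fam!r}")
        tname, tcds = templates[fam][i % len(templates[fam])]
        cds = diverge_cds(tcds, params.divergence, rng)
        protein = translate(cds)
        lof: List[LofEvent] = []
        if status == "pseudogene":
            n_ev = int(rng.integers(1, 3))
            cds_m, lof = pseudogenize(cds, n_ev, seed=int(rng.integers(0, 2**31 - 1)))
            cassette = cds_m + "TAA"
        elif status == "complete":
            cassette = cds + "TAA"
        elif status == "truncated":
            keep = int(len(cds) // 3 * rng.uniform(0.5, 0.7)) * 3
            cassette = cds[:keep]
        else:  # edge: 5'-truncated gene close to a contig border
            cut = int(len(cds) // 3 * rng.uniform(0.3, 0.5)) * 3
            cassette = cds[cut:] + "TAA"
        n_introns = 0
        if params.intron_every and i % params.intron_every == 0 and status in (
            "complete",
            "pseudogene",
        ):
            # keep terminal exons >= 25 codons (a shorter diverged exon can
            # score below the intron open penalty and be legitimately
            # dropped), and keep splice sites >= 8 codons from any LOF
            # event (an intron boundary absorbs an adjacent frameshift,
            # since intron length is unconstrained modulo 3)
            ncod = len(cassette) // 3
            ev_codons = [
                e.cds_position if e.kind == "premature_stop" else e.cds_position // 3
                for e in lof
            ]
            for _ in range(100):
                at_codon = int(rng.integers(25, ncod - 25))
                if all(abs(at_codon - ev) >= 8 for ev in ev_codons):
                    break
            at = at_codon * 3
            ilen = int(rng.integers(*params.intron_length_range))
            intron = "GT" + "".join(rng.choice(list("ACGT"), ilen - 4)) + "AG"
            cassette = cassette[:at] + intron + cassette[at:]
            n_introns = 1

        L = params.contig_length
        margin = 6000
        if status == "edge":
            offset = int(rng.integers(*params.edge_offset_range))
        else:
            lo_off = margin
            hi_off = L - margin - len(cassette)
            if hi_off <= lo_off:
                raise ValueError("contig too short for plan")
            offset = int(rng.integers(lo_off, hi_off))
        if L < len(cassette) + offset:
            raise ValueError("contig too short for plan")
        n_bg = L - len(cassette)
        bg = "".join(rng.choice(list("ACGT"), n_bg))
        contig = bg[:offset] + cassette + bg[offset:]
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = offset, offset + len(cassette)
        if strand == "-":
            contig = revcomp(contig)
            start, end = len(contig) - end, len(contig) - start
        cid = f"contig{i + 1:02d}"
        contigs[cid] = contig
        fam_counter[fam] = fam_counter.get(fam, 0) + 1
        genes.append(
            PlantedGene(
                name=f"{fam.lower()}{fam_counter[fam]}",
                family=fam,
                status=status,
                contig_id=cid,
                start=start,
                end=end,
                strand=strand,
                protein=protein,
                lof_events=lof,
                n_introns=n_introns,
            )
        )
    queries = {
        f"{fam}_tpl{j}": translate(cds)
        for fam in sorted(templates)
        for j, (_, cds) in enumerate(templates[fam], 1)
    }
    assembly = GenomeAssembly(contigs, assembly_id=f"synthetic_seed{params.seed}")
    return assembly, SyntheticGenomeTruth(genes=genes, queries=queries)


# ---------------------------------------------------------------------------
# OSN position tables
# ---------------------------------------------------------------------------


@dataclass
class ReceptorSimSpec:
    n_cells: int
    alpha: float
    beta: float
    p_primary: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be > 0")
        if not (0 <= self.p_primary <= 1):
            raise ValueError("p_primary must be in [0,1]")


def default_receptor_specs() -> Dict[str, ReceptorSimSpec]:
    """Three archetypes mirroring the study's quantified genes: an
    apically-skewed, primary-lamella-biased coreceptor-like gene (v2r1), an
    apically-skewed gene with even lamella use (ora2), and a uniformly
    distributed, secondary-biased gene (taar1a)."""
    return {
        "v2r1": ReceptorSimSpec(n_cells=410, alpha=2.0, beta=5.0, p_primary=0.81),
        "ora2": ReceptorSimSpec(n_cells=110, alpha=2.0, beta=5.0, p_primary=0.47),
        "taar1a": ReceptorSimSpec(n_cells=300, alpha=1.0, beta=1.0, p_primary=0.28),
    }


@dataclass
class OsnSimParams:
    receptors: Dict[str, ReceptorSimSpec] = field(default_factory=default_receptor_specs)
    n_lamellae: int = 100
    lamella_length_range_um: Tuple[float, float] = (800.0, 2500.0)
    n_sections: int = 5
    seed: int = 0


def simulate_osn_positions(
    params: OsnSimParams,
) -> Tuple[List[LabeledCell], List[LamellaMeasurement]]:
    """Draw labeled-cell tables with known spatial structure.

    Normalized radial positions are Beta(alpha, beta) (0=apex), converted
    to um on a uniformly drawn lamella; lamella identity is
    Bernoulli(p_primary). Returns (cells, surveyed lamellae).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 23]))
    lengths = rng.uniform(*params.lamella_length_range_um, size=params.n_lamellae)
    lamellae = [
        LamellaMeasurement(
            lamella_id=f"lam{i + 1:03d}",
            measured_length=float(lengths[i]) / 1000.0,
            section_id=f"sec{i % params.n_sections + 1}",
        )
        for i in range(params.n_lamellae)
    ]
    cells: List[LabeledCell] = []
    for rid in sorted(params.receptors):
        spec = params.receptors[rid]
        lam_idx = rng.integers(0, params.n_lamellae, size=spec.n_cells)
        pos = rng.beta(spec.alpha, spec.beta, size=spec.n_cells)
        primary = rng.random(size=spec.n_cells) < spec.p_primary
        for k in range(spec.n_cells):
            li = int(lam_idx[k])
            cells.append(
                LabeledCell(
                    section_id=lamellae[li].section_id,
                    lamella_id=lamellae[li].lamella_id,
                    lamella_type="primary" if primary[k] else "secondary",
                    distance_from_apex=float(pos[k] * lengths[li]),
                    parent_lamella_length=float(lengths[li]),
                    receptor_id=rid,
                )
            )
    return cells, lamellae
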