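"""File I/O: FASTA, GFF3, TSV census tables, calibration files.

Internal coordinates are 0-based half-open; GFF3 emission converts to
1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import GenomeAssembly, ReceptorGene, ReferenceDB
from .phylogeny import CalibrationConstraint


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path, assembly_id: str = "") -> GenomeAssembly:
    return GenomeAssembly(read_fasta(path), assembly_id or Path(str(path)).stem)


def read_reference_fasta(path) -> ReferenceDB:
    """Reference FASTA with the class label as the last '|'-field of the id,
    e.g. ``>zOlfCc1|V2R_OLFC``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"reference record {rec.id!r} lacks a |label suffix")
        rid, label = rec.id.rsplit("|", 1)
        records.append((rid, str(rec.seq).upper(), label))
    return ReferenceDB(records)


def genes_to_gff3(genes: Sequence[ReceptorGene], assembly_id: str = "") -> str:
    """GFF3 with one gene feature plus exon children per retained gene."""
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = g.gene_model.span
        locus = g.gene_model.locus
        attrs = (
            f"ID={g.name};family={g.family};status={g.status};"
            f"query={g.gene_model.query_id};"
            f"coverage={g.gene_model.query_coverage:.3f};"
            f"identity={g.gene_model.percent_identity:.1f}"
        )
        if g.lof_events:
            lof = ",".join(f"{ev.kind}@{ev.cds_position}" for ev in g.lof_events)
            attrs += f";lof={lof}"
        lines.append(
            "\t".join(
                [locus.contig_id, "orcensus", "gene", str(s + 1), str(e), ".",
                 locus.strand, ".", attrs]
            )
        )
        for k, (xs, xe) in enumerate(sorted(g.gene_model.exons), 1):
            lines.append(
                "\t".join(
                    [locus.contig_id, "orcensus", "exon", str(xs + 1), str(xe), ".",
                     locus.strand, ".", f"ID={g.name}.exon{k};Parent={g.name}"]
                )
            )
    return "\n".join(lines) + "\n"


def write_gene_outputs(genes: Sequence[ReceptorGene], outdir, assembly_id: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{assembly_id}.gff3").write_text(genes_to_gff3(genes, assembly_id))
    write_fasta({g.name: g.gene_model.cds_nt for g in genes}, out / f"{assembly_id}.cds.fasta")
    write_fasta(
        {g.name: g.gene_model.protein for g in genes if g.gene_model.protein},
        out / f"{assembly_id}.protein.fasta",
    )


def write_census_tsv(census: pd.DataFrame, path) -> None:
    census.to_csv(str(path), sep="\t", index=False)


def read_calibrations_tsv(path) -> List[CalibrationConstraint]:
    """TSV columns: mrca_leaf_a, mrca_leaf_b, min_age, max_age."""
    df = pd.read_csv(str(path), sep="\t")
    return [
        CalibrationConstraint(
            taxa=(str(r.mrca_leaf_a), str(r.mrca_leaf_b)),
            min_age=float(r.min_age),
            max_age=float(r.max_age),
        )
        for r in df.itertuples()
    ]
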