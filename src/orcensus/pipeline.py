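"""End-to-end genome mining: search -> loci -> models -> status -> family."""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .family import assign_family
from .genemodel import classify_status, detect_lof, predict_gene_model
from .mining import (
    GenomeAssembly,
    MiningConfig,
    ReceptorGene,
    ReferenceDB,
    STATUSES,
    merge_and_extend_hits,
    translated_homology_search,
)

logger = logging.getLogger(__name__)


def mine_genome(
    genome: GenomeAssembly,
    queries: Dict[str, str],
    refdb: ReferenceDB,
    config: Optional[MiningConfig] = None,
    min_model_coverage: float = 0.15,
) -> List[ReceptorGene]:
    """Mine one assembly for receptor genes of the four olfactory families.

    Runs the translated search, merges and extends hit regions, predicts a
    spliced gene model per locus against its best query, detects
    loss-of-function mutations, classifies the status, and keeps only
    candidates that the two-stage family assignment retains. Output is
    deterministic, ordered by (contig, start, strand).
    """
    config = config or MiningConfig()
    hits = translated_homology_search(genome, queries, config)
    loci = merge_and_extend_hits(hits, genome, config)
    genes: List[ReceptorGene] = []
    fam_counter: Dict[str, int] = {}
    n_rejected = 0
    for locus in loci:
        model = predict_gene_model(locus, queries[locus.best_query_id], genome, config)
        if model is None or model.query_coverage < min_model_coverage:
            n_rejected += 1
            continue
        lof = detect_lof(model)
        status = classify_status(model, lof, genome, config)
        fam = assign_family(model, refdb)
        if not fam.retained:
            logger.info(
                "rejected locus %s:%d-%d: %s",
                locus.contig_id,
                locus.start,
                locus.end,
                fam.reason,
            )
            n_rejected += 1
            continue
        fam_counter[fam.family] = fam_counter.get(fam.family, 0) + 1
        genes.append(
            ReceptorGene(
                gene_model=model,
                family=fam.family,
                status=status,
                lof_events=lof,
                name=f"{fam.family.lower()}{fam_counter[fam.family]}",
            )
        )
    logger.info(
        "%s: %d hits, %d loci, %d genes retained, %d rejected",
        genome.assembly_id,
        len(hits),
        len(loci),
        len(genes),
        n_rejected,
    )
    return genes


def census_table(genes: List[ReceptorGene], assembly_id: str) -> pd.DataFrame:
    """Per-family, per-status counts (one row per family present)."""
    rows: Dict[str, dict] = {}
    for g in genes:
        r = rows.setdefault(
            g.family,
            {"assembly": assembly_id, "family": g.family, **{s: 0 for s in STATUSES}},
        )
        r[g.status] += 1
    return pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["family"]),
        columns=["assembly", "family", *STATUSES],
    )
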