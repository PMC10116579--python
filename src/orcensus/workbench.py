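"""Orchestration: multi-genome census runs and per-family evolution reports.

This is the layer that reproduces the study-level summary artifacts: a
census table of complete/pseudogene/truncated/edge counts per assembly and
family, and a per-family table of total duplications, losses, and ancestral
repertoire size from gene tree-species tree reconciliation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .mining import GenomeAssembly, MiningConfig, ReceptorGene, ReferenceDB, STATUSES
from .phylogeny import (
    PhyloConfig,
    ReconciliationResult,
    build_gene_tree,
    collapse_low_support,
    default_species_map,
    reconcile,
)
from .pipeline import census_table, mine_genome

logger = logging.getLogger(__name__)


@dataclass
class WorkbenchConfig:
    mining: MiningConfig = field(default_factory=MiningConfig)
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "WorkbenchConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            mining=MiningConfig(**raw.get("mining", {})),
            phylo=PhyloConfig(**raw.get("phylo", {})),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "mining": vars(self.mining),
            "phylo": vars(self.phylo),
            "seed": self.seed,
        }


def run_census(
    genomes: Sequence[GenomeAssembly],
    queries: Dict[str, str],
    refdb: ReferenceDB,
    config: Optional[WorkbenchConfig] = None,
) -> Tuple[pd.DataFrame, Dict[str, List[ReceptorGene]]]:
    """Mine every assembly; aggregate the per-family status counts.

    Returns the census table (one row per assembly x family) and the
    retained genes per assembly.
    """
    config = config or WorkbenchConfig()
    tables = []
    genes_by_assembly: Dict[str, List[ReceptorGene]] = {}
    for genome in genomes:
        genes = mine_genome(genome, queries, refdb, config.mining)
        genes_by_assembly[genome.assembly_id] = genes
        tables.append(census_table(genes, genome.assembly_id))
    if not tables:
        return (
            pd.DataFrame(columns=["assembly", "family", *STATUSES]),
            genes_by_assembly,
        )
    return pd.concat(tables, ignore_index=True), genes_by_assembly


def family_ranges(census: pd.DataFrame) -> pd.DataFrame:
    """Min/max complete-gene counts per family across assemblies."""
    if census.empty:
        return pd.DataFrame(columns=["family", "min_complete", "max_complete"])
    g = census.groupby("family")["complete"]
    return (
        pd.DataFrame({"min_complete": g.min(), "max_complete": g.max()})
        .reset_index()
    )


def run_evolution_report(
    gene_sets: Dict[str, Dict[str, str]],  # family -> {leaf label: aligned protein}
    species_tree,
    config: Optional[WorkbenchConfig] = None,
    species_map=default_species_map,
    gene_trees: Optional[Dict[str, object]] = None,
) -> Tuple[pd.DataFrame, Dict[str, ReconciliationResult]]:
    """Per-family duplication/loss totals and ancestral repertoire size.

    For each family, builds an NJ gene tree with bootstrap supports (unless
    a pre-built tree is supplied in ``gene_trees``), collapses nodes below
    the support threshold, and reconciles against the species tree.
    """
    config = config or WorkbenchConfig()
    rows = []
    results: Dict[str, ReconciliationResult] = {}
    for fam in sorted(gene_sets):
        seqs = gene_sets[fam]
        if gene_trees and fam in gene_trees:
            gt = gene_trees[fam]
        else:
            gt = build_gene_tree(seqs, config.phylo, seed=config.seed)
            gt = collapse_low_support(gt, config.phylo.support_collapse_threshold)
        res = reconcile(gt, species_tree, config.phylo, species_map=species_map)
        results[fam] = res
        root_label = _root_label(species_tree)
        rows.append(
            {
                "family": fam,
                "n_genes": sum(res.leaf_counts.values()),
                "duplications": res.total_duplications,
                "losses": res.total_losses,
                "root_ancestral_count": res.ancestral_counts.get(root_label, 0),
            }
        )
    return pd.DataFrame(rows), results


def _root_label(species_tree) -> str:
    from .phylogeny import SpeciesIndex, _ensure_tree

    sp = SpeciesIndex(_ensure_tree(species_tree, rooted=True))
    return sp.label[sp.root]


def events_table(result: ReconciliationResult) -> pd.DataFrame:
    """Per-species-branch events table (branch keyed by its child node)."""
    branches = sorted(set(result.events) | set(result.ancestral_counts))
    return pd.DataFrame(
        [
            {
                "branch_id": b,
                "duplications": result.events.get(b, (0, 0))[0],
                "losses": result.events.get(b, (0, 0))[1],
                "ancestral_count": result.ancestral_counts.get(b, 0),
            }
            for b in branches
        ]
    )


def write_provenance(outdir, config: WorkbenchConfig, extra: Optional[dict] = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    payload = {
        "tool": "orcensus",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    if extra:
        payload.update(extra)
    (out / "provenance.json").write_text(json.dumps(payload, indent=2, default=str))
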