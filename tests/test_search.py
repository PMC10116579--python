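"""Translated homology search and hit-region merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orcensus._seq import revcomp, translate
from orcensus.mining import (
    GenomeAssembly,
    HomologyHit,
    MiningConfig,
    merge_and_extend_hits,
    translated_homology_search,
)
from orcensus.simulate import random_orf

from conftest import plant_in_background


class TestTranslatedSearch:
    def test_planted_identity_forward(self, config):
        rng = np.random.default_rng(1)
        cds = random_orf(300, rng)
        contig = plant_in_background(cds, 100_000, 10_000, rng)
        genome = GenomeAssembly({"c1": contig}, "t")
        hits = translated_homology_search(genome, {"Q": translate(cds)}, config)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (10_000, 10_900, "+")
        assert h.evalue < 1e-50

    @pytest.mark.parametrize("seed", range(10))
    def test_reverse_complement_recovery(self, seed, config):
        """A gene planted on the minus strand is recovered with strand '-'
        and the same forward-strand interval."""
        rng = np.random.default_rng(100 + seed)
        cds = random_orf(200, rng)
        pos = int(rng.integers(1_000, 30_000))
        contig = plant_in_background(cds, 40_000, pos, rng, strand="-")
        genome = GenomeAssembly({"c": contig}, "t")
        hits = translated_homology_search(genome, {"Q": translate(cds)}, config)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (pos, pos + 600)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_query_no_hits(self, seed, config):
        """Unrelated random queries stay below the e-value threshold."""
        rng = np.random.default_rng(200 + seed)
        genome = GenomeAssembly(
            {"c": "".join(rng.choice(list("ACGT"), 20_000))}, "t"
        )
        query = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 300))
        assert translated_homology_search(genome, {"R": query}, config) == []

    def test_all_hits_pass_threshold_and_are_sorted(self, config):
        rng = np.random.default_rng(7)
        cds1, cds2 = random_orf(150, rng), random_orf(150, rng)
        contig = plant_in_background(cds1, 20_000, 2_000, rng)
        contig = contig[:10_000] + cds2 + contig[10_000:]
        genome = GenomeAssembly({"c": contig}, "t")
        hits = translated_homology_search(
            genome, {"Q1": translate(cds1), "Q2": translate(cds2)}, config
        )
        assert all(h.evalue <= config.evalue_threshold for h in hits)
        keys = [(h.contig_id, h.start, h.end, h.strand, h.query_id) for h in hits]
        assert keys == sorted(keys)

    def test_empty_query_set_errors(self, config):
        genome = GenomeAssembly({"c": "ACGT" * 100}, "t")
        with pytest.raises(ValueError, match="no queries"):
            translated_homology_search(genome, {}, config)

    def test_non_dna_characters_error(self):
        with pytest.raises(ValueError, match="non-DNA"):
            GenomeAssembly({"c": "ACGU" * 100}, "t")


def _mk_hit(contig, start, end, strand="+", q="Q", score=100.0):
    return HomologyHit(contig, start, end, strand, 0, q, score, 1e-40)


class TestMergeAndExtend:
    def test_overlap_merge_no_extension(self):
        genome = GenomeAssembly({"c": "A" * 10_000}, "t")
        cfg = MiningConfig(extension_bp=0)
        loci = merge_and_extend_hits(
            [_mk_hit("c", 1000, 1600), _mk_hit("c", 1400, 2000)], genome, cfg
        )
        assert [(l.start, l.end) for l in loci] == [(1000, 2000)]

    def test_boundary_clipping(self):
        genome = GenomeAssembly({"c": "A" * 1000}, "t")
        loci = merge_and_extend_hits(
            [_mk_hit("c", 500, 800)], genome, MiningConfig(extension_bp=20_000)
        )
        assert [(l.start, l.end) for l in loci] == [(0, 1000)]

    def test_extended_intervals_merge(self):
        genome = GenomeAssembly({"c": "A" * 60_000}, "t")
        loci = merge_and_extend_hits(
            [_mk_hit("c", 0, 900), _mk_hit("c", 30_000, 30_900)],
            genome,
            MiningConfig(extension_bp=20_000),
        )
        assert [(l.start, l.end) for l in loci] == [(0, 50_900)]

    def test_best_query_is_top_bit_score(self):
        genome = GenomeAssembly({"c": "A" * 10_000}, "t")
        loci = merge_and_extend_hits(
            [_mk_hit("c", 1000, 1600, q="low", score=50),
             _mk_hit("c", 1200, 1800, q="high", score=80)],
            genome,
            MiningConfig(extension_bp=0),
        )
        assert loci[0].best_query_id == "high"

    def test_out_of_bounds_hit_errors(self):
        genome = GenomeAssembly({"c": "A" * 100}, "t")
        with pytest.raises(ValueError, match="bounds"):
            merge_and_extend_hits([_mk_hit("c", 50, 200)], genome, MiningConfig())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 4500), st.integers(1, 400), st.sampled_from("+-")),
            min_size=1,
            max_size=12,
        ),
        st.integers(0, 300),
    )
    def test_matches_interval_arithmetic_oracle(self, raw, ext):
        """Merged loci equal a naive extend-clip-union interval oracle."""
        L = 5000
        genome = GenomeAssembly({"c": "A" * L}, "t")
        hits = [_mk_hit("c", s, min(s + w, L), strand) for s, w, strand in raw]
        loci = merge_and_extend_hits(hits, genome, MiningConfig(extension_bp=ext))
        for strand in "+-":
            ivals = sorted(
                (max(0, h.start - ext), min(L, h.end + ext))
                for h in hits
                if h.strand == strand
            )
            merged = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            got = [(l.start, l.end) for l in loci if l.strand == strand]
            assert sorted(got) == merged
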