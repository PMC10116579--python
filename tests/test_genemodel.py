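"""Spliced gene prediction and loss-of-function detection."""

import numpy as np
import pytest

from orcensus._seq import translate
from orcensus.genemodel import detect_lof, predict_gene_model
from orcensus.mining import CandidateLocus, GenomeAssembly, MiningConfig
from orcensus.simulate import pseudogenize, random_orf

from conftest import quick_model


def _intron(length: int, rng) -> str:
    return "GT" + "".join(rng.choice(list("ACGT"), length - 4)) + "AG"


class TestPredictGeneModel:
    def test_intronless_identity(self, orf300):
        cds, prot = orf300
        model, _ = quick_model(cds, prot)
        assert len(model.exons) == 1
        assert model.exons[0] == (300, 300 + 900)  # pad=300
        assert model.percent_identity == 100.0
        assert model.query_coverage == 1.0
        assert model.protein == prot

    @pytest.mark.parametrize("seed", range(8))
    def test_two_exon_intron_recovery(self, seed, orf300):
        """A planted GT..AG intron is spliced out at the exact boundaries."""
        cds, prot = orf300
        rng = np.random.default_rng(300 + seed)
        at = int(rng.integers(20, 280)) * 3
        ilen = int(rng.integers(120, 800))
        cassette = cds[:at] + _intron(ilen, rng) + cds[at:]
        model, _ = quick_model(cassette, prot, seed=seed)
        pad = 300
        assert model.exons == [(pad, pad + at), (pad + at + ilen, pad + 900 + ilen)]
        assert model.percent_identity == 100.0
        assert detect_lof(model) == []

    def test_short_deletion_is_frameshift_not_intron(self, orf300):
        """A 1 nt deletion must surface as a frameshift state; introns
        below the minimum length are forbidden."""
        cds, prot = orf300
        mutant = cds[:300] + cds[301:]
        model, _ = quick_model(mutant, prot)
        assert len(model.exons) == 1  # no spurious micro-intron
        events = detect_lof(model)
        assert [e.kind for e in events] == ["frameshift"]
        assert abs(events[0].cds_position - 300) <= 3

    def test_minimum_length_intron_allowed(self, orf300):
        cds, prot = orf300
        rng = np.random.default_rng(9)
        cfg = MiningConfig()
        cassette = cds[:450] + _intron(cfg.min_intron_bp, rng) + cds[450:]
        model, _ = quick_model(cassette, prot)
        assert len(model.exons) == 2
        assert detect_lof(model) == []

    def test_locus_shorter_than_codon_errors(self, config):
        genome = GenomeAssembly({"c": "ACGTACGT"}, "t")
        locus = CandidateLocus("c", 0, 2, "+", [], "q")
        with pytest.raises(ValueError, match="codon"):
            predict_gene_model(locus, "MA", genome, config)

    def test_unrelated_query_gives_no_usable_model(self, config):
        """Random DNA yields at most a chance micro-alignment, far below
        any usable query coverage."""
        rng = np.random.default_rng(11)
        genome = GenomeAssembly({"c": "".join(rng.choice(list("ACGT"), 600))}, "t")
        locus = CandidateLocus("c", 0, 600, "+", [], "q")
        model = predict_gene_model(locus, "W" * 50, genome, config)
        assert model is None or model.query_coverage < 0.15


class TestDetectLof:
    def test_clean_model_no_events(self, orf300):
        cds, prot = orf300
        model, _ = quick_model(cds, prot)
        assert detect_lof(model) == []

    def test_single_premature_stop(self, orf300):
        cds, prot = orf300
        mutant = cds[:450] + "TGA" + cds[453:]
        model, _ = quick_model(mutant, prot)
        events = detect_lof(model)
        assert [(e.kind, e.cds_position) for e in events] == [("premature_stop", 150)]

    def test_frameshift_then_stop(self, orf300):
        cds, prot = orf300
        mutant = cds[:600] + "TAA" + cds[603:]  # stop @ codon 200
        mutant = mutant[:90] + mutant[91:]  # 1 nt deletion @ nt 90
        model, _ = quick_model(mutant, prot)
        events = detect_lof(model)
        assert [e.kind for e in events] == ["frameshift", "premature_stop"]
        assert abs(events[0].cds_position - 90) <= 3
        assert events[1].cds_position == 200

    def test_terminal_stop_is_not_an_event(self, orf300):
        """The stop codon closing the ORF never counts as loss of function."""
        cds, prot = orf300
        model, _ = quick_model(cds, prot)  # quick_model appends TAA
        assert all(e.kind != "premature_stop" for e in detect_lof(model))

    @pytest.mark.parametrize("seed", range(20))
    def test_pseudogenize_roundtrip(self, seed, orf300):
        """Randomly planted stop/frameshift events are all recovered with
        matching kinds at the planted positions."""
        cds, prot = orf300
        rng = np.random.default_rng(seed)
        n_events = int(rng.integers(1, 4))
        mutant, truth = pseudogenize(cds, n_events, seed=seed)
        model, _ = quick_model(mutant, prot, seed=seed)
        events = detect_lof(model)
        assert len(events) == len(truth)
        for got, want in zip(events, truth):
            assert got.kind == want.kind
            if want.kind == "premature_stop":
                assert got.cds_position == want.cds_position
            else:
                # equal-scoring indel placements can shift by a codon or two
                assert abs(got.cds_position - want.cds_position) <= 6
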