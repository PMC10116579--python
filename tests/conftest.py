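import numpy as np
import pytest

from orcensus._seq import revcomp, translate
from orcensus.mining import CandidateLocus, GenomeAssembly, MiningConfig
from orcensus.genemodel import predict_gene_model
from orcensus.simulate import random_orf


@pytest.fixture(scope="session")
def config():
    return MiningConfig()


def plant_in_background(cassette: str, contig_len: int, pos: int, rng, strand: str = "+") -> str:
    """Embed a gene cassette in i.i.d. background at a fixed offset."""
    bg = "".join(rng.choice(list("ACGT"), contig_len - len(cassette)))
    s = cassette if strand == "+" else revcomp(cassette)
    return bg[:pos] + s + bg[pos:]


@pytest.fixture(scope="session")
def plant():
    return plant_in_background


def quick_model(cds_variant: str, query_protein: str, config=None, pad: int = 300, seed: int = 0):
    """Predict a gene model for a cassette embedded in a short padded contig.

    Small-locus path used to exercise the spliced aligner and LOF detector
    quickly: the locus is the whole (gene + padding) contig.
    """
    config = config or MiningConfig()
    rng = np.random.default_rng(seed)
    contig = plant_in_background(cds_variant + "TAA", len(cds_variant) + 3 + 2 * pad, pad, rng)
    genome = GenomeAssembly({"c": contig}, "quick")
    locus = CandidateLocus("c", 0, len(contig), "+", [], "q")
    return predict_gene_model(locus, query_protein, genome, config), genome


@pytest.fixture(scope="session")
def predict_quick():
    return quick_model


@pytest.fixture(scope="session")
def orf300():
    rng = np.random.default_rng(12345)
    cds = random_orf(300, rng)
    return cds, translate(cds)
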