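"""Low-level sequence helpers shared across the mining and simulation code.

Nucleotide sequences are plain upper-case strings over {A,C,G,T,N};
coordinates are 0-based half-open throughout the library.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN")

# Amino-acid alphabet used by all integer-coded kernels. Order follows the
# BLOSUM62 file so the matrix can be re-indexed without surprises.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
X_CODE = AA_INDEX["X"]
STOP_CODE = AA_INDEX["*"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(STANDARD_TABLE.stop_codons))  # ('TAA', 'TAG', 'TGA')

_CODON_AA = {}
for _c, _aa in STANDARD_TABLE.forward_table.items():
    _CODON_AA[_c] = _aa
for _c in STANDARD_TABLE.stop_codons:
    _CODON_AA[_c] = "*"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")


def translate(seq: str) -> str:
    """Translate a DNA string frame 0, stops as '*', ambiguous codons as 'X'."""
    n = len(seq) // 3
    out = []
    for i in range(n):
        out.append(_CODON_AA.get(seq[3 * i : 3 * i + 3], "X"))
    return "".join(out)


def encode_dna(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A,C,G,T,N -> 0..4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, 4, dtype=np.int8)
    for b, c in _NT_CODE.items():
        lut[ord(b)] = c
    return lut[arr]


def encode_protein(seq: str) -> np.ndarray:
    """Protein string -> int8 codes into AA_ALPHABET (unknown -> X)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, X_CODE, dtype=np.int8)
    for a, c in AA_INDEX.items():
        lut[ord(a)] = c
    return lut[arr]


def _build_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    out = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = int(mat[a][b])
    return out


BLOSUM62 = _build_blosum62()

# Karlin-Altschul parameters for ungapped BLOSUM62 (standard published values).
KA_LAMBDA = 0.3176
KA_K = 0.134


def _build_codon_code_to_aa() -> np.ndarray:
    """Map base-4 codon code (c0*16 + c1*4 + c2) -> aa code; N anywhere -> X."""
    out = np.full(64, X_CODE, dtype=np.int8)
    bases = "ACGT"
    for c0 in range(4):
        for c1 in range(4):
            for c2 in range(4):
                codon = bases[c0] + bases[c1] + bases[c2]
                out[c0 * 16 + c1 * 4 + c2] = AA_INDEX[_CODON_AA[codon]]
    return out


CODON_CODE_TO_AA = _build_codon_code_to_aa()


def translate_codes(dna_codes: np.ndarray) -> np.ndarray:
    """Frame-0 translation of int8 DNA codes to int8 aa codes (N -> X)."""
    n = dna_codes.shape[0] // 3
    c = dna_codes[: 3 * n].reshape(n, 3).astype(np.int32)
    ok = (c < 4).all(axis=1)
    code = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    code[~ok] = 0
    aa = CODON_CODE_TO_AA[code]
    aa[~ok] = X_CODE
    return aa.astype(np.int8)
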