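"""Standard genetic code bookkeeping shared by the simulation and likelihood code.

The 61 sense codons of the standard nuclear code are the state space of every
codon substitution model in this package.  This module precomputes, once at
import time, the index structures those models need: codon <-> integer maps,
amino-acid assignments, synonymous families, and the list of single-nucleotide
codon pairs annotated with transition/transversion and synonymous status.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: stop codons of the standard code
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: the 61 sense codons, alphabetically ordered; index into this list is the
#: state label used everywhere else
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) per sense codon
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

N_CODONS = len(SENSE_CODONS)  # 61

#: synonymous families: amino acid -> tuple of codon indices
FAMILIES: dict[str, tuple[int, ...]] = {}
for _i, _aa in enumerate(CODON_AA):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] = FAMILIES[_aa] + (_i,)

#: codons in families of size >= 2 (the 59 degenerate-family codons)
DEGENERATE_CODONS: tuple[int, ...] = tuple(
    i for aa, fam in FAMILIES.items() for i in fam if len(fam) >= 2
)

_NT_INDEX = {n: i for i, n in enumerate("ACGT")}

#: (61, 3) array of nucleotide indices (A=0, C=1, G=2, T=3) per codon position
CODON_NT: np.ndarray = np.array(
    [[_NT_INDEX[n] for n in codon] for codon in SENSE_CODONS], dtype=np.int8
)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _single_change_pairs():
    i_idx, j_idx, ts, syn, pos = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            i_idx.append(i)
            j_idx.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            syn.append(CODON_AA[i] == CODON_AA[j])
            pos.append(p)
    return (
        np.array(i_idx, dtype=np.int16),
        np.array(j_idx, dtype=np.int16),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
        np.array(pos, dtype=np.int8),
    )


#: ordered single-nucleotide-change codon pairs (i, j) with annotations
PAIR_I, PAIR_J, PAIR_TS, PAIR_SYN, PAIR_POS = _single_change_pairs()


def codons_to_indices(seq: str) -> np.ndarray:
    """Split an in-frame coding sequence into sense-codon indices.

    Raises ``ValueError`` on stop codons, on length not a multiple of 3, or on
    characters outside ACGT.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    seq = seq.upper()
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        idx = CODON_INDEX.get(codon)
        if idx is None:
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop codon {codon} at nt position {k}")
            raise ValueError(f"unrecognized codon {codon!r} at nt position {k}")
        out[k // 3] = idx
    return out


def indices_to_codons(indices: np.ndarray) -> str:
    """Inverse of :func:`codons_to_indices`."""
    return "".join(SENSE_CODONS[i] for i in np.asarray(indices))


def translate(indices: np.ndarray) -> str:
    """Amino-acid string for a vector of sense-codon indices."""
    return "".join(CODON_AA[i] for i in np.asarray(indices))
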