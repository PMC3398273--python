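"""In-frame, trimmed, transit-peptide-masked codon alignments per triplet.

The preparation chain for each orthologue triplet is:

    align_triplet -> trim_to_common_region -> trim_partial_codons
                  -> mask_transit_peptide  -> drop_unusable_codons

Alignment is progressive at the protein level: the two ingroup sequences
(mutually closest) are aligned first, the outgroup is aligned against the
resulting 2-row profile, and the amino-acid alignment is back-threaded to
nucleotides so gaps occur in multiples of three.  Codon columns containing a
gap, ambiguity or stop in any row are removed (complete deletion), leaving the
61-sense-codon matrix the likelihood machinery assumes.  Coordinates are
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .genetics import CODON_INDEX, STOP_CODONS

SPECIES = ("At", "Ci", "Cr")

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = str(_BLOSUM.alphabet)
_AA_INDEX = {a: i for i, a in enumerate(_AA_ALPHABET)}
_SUBMAT = np.array(_BLOSUM, dtype=np.float64)
_GAP_OPEN = -10.0
_GAP_EXTEND = -0.5
_PROFILE_GAP_SCORE = -1.0  # substitution contribution of a gap in a profile row

_STANDARD_TABLE = {}
for _codon, _idx in CODON_INDEX.items():
    from .genetics import CODON_AA

    _STANDARD_TABLE[_codon] = CODON_AA[_idx]


def _translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.get(codon, "X")


@dataclass
class TripletAlignment:
    """Three aligned nucleotide rows ('-' gaps) with the At frame offset.

    ``positions`` maps each row to the 0-based coordinate, on the unaligned
    input sequence, of every alignment column (-1 at gap columns).
    """

    rows: dict  # species -> aligned string
    frame: int = 0
    gene_id: str = ""
    positions: dict = field(default_factory=dict)

    def __post_init__(self):
        lens = {len(v) for v in self.rows.values()}
        if len(lens) != 1:
            raise ValueError("alignment rows must have equal length")
        if set(self.rows) != set(SPECIES):
            raise ValueError(f"rows must cover species {SPECIES}")
        if not self.positions:
            self.positions = {sp: _ungapped_positions(self.rows[sp]) for sp in SPECIES}

    @property
    def length(self) -> int:
        return len(self.rows["At"])

    def slice_columns(self, keep: np.ndarray) -> "TripletAlignment":
        keep = np.asarray(keep)
        return TripletAlignment(
            rows={sp: "".join(np.array(list(self.rows[sp]))[keep]) for sp in SPECIES},
            frame=self.frame,
            gene_id=self.gene_id,
            positions={sp: self.positions[sp][keep] for sp in SPECIES},
        )


def _ungapped_positions(row: str) -> np.ndarray:
    pos = np.full(len(row), -1, dtype=np.int64)
    p = 0
    for i, ch in enumerate(row):
        if ch != "-":
            pos[i] = p
            p += 1
    return pos


@dataclass
class TrimmedCodonAlignment:
    """3 x L sense-codon index matrix, the unit of likelihood computation.

    ``row_spans`` gives per-row 0-based half-open source coordinates of the
    region the retained codons came from; ``kept_codons`` indexes the retained
    codon columns within that region's alignment.
    """

    codon_matrix: np.ndarray  # (3, L) int16, rows in (At, Ci, Cr) order
    gene_id: str = ""
    row_spans: dict = field(default_factory=dict)
    kept_codons: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.codon_matrix = np.asarray(self.codon_matrix, dtype=np.int16)
        if self.codon_matrix.ndim != 2 or self.codon_matrix.shape[0] != 3:
            raise ValueError("codon_matrix must be (3, L)")
        if self.codon_matrix.shape[1] < 1:
            raise ValueError("empty codon alignment")

    @property
    def n_codons(self) -> int:
        return self.codon_matrix.shape[1]

    def sequences(self) -> dict:
        from .genetics import indices_to_codons

        return {sp: indices_to_codons(self.codon_matrix[i]) for i, sp in enumerate(SPECIES)}


# ---------------------------------------------------------------------------
# progressive protein-level alignment


@njit(cache=True)
def _gotoh_profile(a, prof, submat, gap_open, gap_extend, profile_gap):
    """Global affine-gap alignment of sequence ``a`` (int codes) against a
    2-row profile (int codes, -1 = gap).  Returns the traceback path as an
    array of moves (0 diagonal, 1 gap in profile, 2 gap in sequence)."""
    n, m = a.shape[0], prof.shape[0]
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in profile (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in sequence (consume profile)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        ptr_x[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        ptr_y[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 0.0
            cnt = 0
            for r in range(2):
                c = prof[j - 1, r]
                if c >= 0:
                    s += submat[a[i - 1], c]
                else:
                    s += profile_gap
                cnt += 1
            sub = s / cnt
            best_prev = M[i - 1, j - 1]
            pm = 0
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
                pm = 1
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
                pm = 2
            M[i, j] = best_prev + sub
            ptr_m[i, j] = pm
            if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend:
                X[i, j] = M[i - 1, j] + gap_open
                ptr_x[i, j] = 0
            else:
                X[i, j] = X[i - 1, j] + gap_extend
                ptr_x[i, j] = 1
            if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_extend:
                Y[i, j] = M[i, j - 1] + gap_open
                ptr_y[i, j] = 0
            else:
                Y[i, j] = Y[i, j - 1] + gap_extend
                ptr_y[i, j] = 2
    # traceback
    i, j = n, m
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        state = 2
    path = np.empty(n + m, dtype=np.int8)
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            path[k] = 0
            prev = ptr_m[i, j]
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            path[k] = 1
            prev = ptr_x[i, j]
            i -= 1
            state = prev
        else:
            path[k] = 2
            prev = ptr_y[i, j]
            j -= 1
            state = prev
        k += 1
    return path[:k][::-1].copy()


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = _BLOSUM
    a.open_gap_score = _GAP_OPEN
    a.extend_gap_score = _GAP_EXTEND
    return a


def _codon_split(seq: str, frame: int, gene_id: str, require_clean: bool):
    """(codons list, leading nt, trailing nt) for one sequence and frame;
    trailing stop codons join the trailing overhang."""
    core = seq[frame:]
    n_codons = len(core) // 3
    codons = [core[3 * k : 3 * k + 3] for k in range(n_codons)]
    trailing = core[3 * n_codons :]
    while codons and codons[-1] in STOP_CODONS:
        trailing = codons.pop() + trailing
    if require_clean:
        for k, c in enumerate(codons):
            if c in STOP_CODONS:
                raise ValueError(f"{gene_id or 'sequence'}: internal stop codon at codon {k + 1}")
    return codons, seq[:frame], trailing


def _best_frame(seq: str) -> int:
    """Frame with the fewest internal stop codons (ties -> smallest)."""
    best, best_stops = 0, None
    for f in range(3):
        core = seq[f:]
        codons = [core[3 * k : 3 * k + 3] for k in range(len(core) // 3)]
        stops = sum(c in STOP_CODONS for c in codons[:-1]) if codons else 0
        if best_stops is None or stops < best_stops:
            best, best_stops = f, stops
    return best


def align_triplet(seqs: dict, frame: int = 0, gene_id: str = "") -> TripletAlignment:
    """Progressive codon-aware alignment of one triplet.

    ``seqs`` maps species to nucleotide strings; ``frame`` is the At frame
    offset.  The ingroup pair is aligned first at the protein level, the
    outgroup is added against the pair profile, and the result is
    back-threaded to nucleotides.  Out-of-frame leading/trailing nucleotides
    (and terminal stop codons) are kept as gap-padded edge columns so each
    row's ungapped characters reconstruct its input.
    """
    for sp in SPECIES:
        if not seqs.get(sp):
            raise ValueError(f"{gene_id or 'triplet'}: empty {sp} sequence")
    seqs = {sp: seqs[sp].upper() for sp in SPECIES}
    if len(seqs["At"]) - frame < 3:
        raise ValueError(f"{gene_id}: At sequence shorter than one codon in frame {frame}")

    codons, lead, trail = {}, {}, {}
    frames = {"At": frame, "Ci": _best_frame(seqs["Ci"]), "Cr": _best_frame(seqs["Cr"])}
    for sp in SPECIES:
        codons[sp], lead[sp], trail[sp] = _codon_split(
            seqs[sp], frames[sp], gene_id, require_clean=(sp == "At")
        )
        if not codons[sp]:
            raise ValueError(f"{gene_id}: {sp} has no complete codon")
    prots = {
        sp: [_translate_codon(c) for c in codons[sp]] for sp in SPECIES
    }

    # ingroup pair first (mutually closest), outgroup against the profile
    aligner = _protein_aligner()
    pa = aligner.align(
        "".join("X" if p in "*X" else p for p in prots["Ci"]),
        "".join("X" if p in "*X" else p for p in prots["Cr"]),
    )[0]
    row_ci, row_cr = str(pa[0]), str(pa[1])
    prof = np.array(
        [
            [
                _AA_INDEX.get(row_ci[k], _AA_INDEX["X"]) if row_ci[k] != "-" else -1,
                _AA_INDEX.get(row_cr[k], _AA_INDEX["X"]) if row_cr[k] != "-" else -1,
            ]
            for k in range(len(row_ci))
        ],
        dtype=np.int64,
    )
    at_codes = np.array(
        [_AA_INDEX.get("X" if p in "*X" else p, _AA_INDEX["X"]) for p in prots["At"]],
        dtype=np.int64,
    )
    path = _gotoh_profile(at_codes, prof, _SUBMAT, _GAP_OPEN, _GAP_EXTEND, _PROFILE_GAP_SCORE)

    # back-thread to nucleotides
    out = {sp: [] for sp in SPECIES}
    at_iter = iter(codons["At"])
    ci_iter, cr_iter = iter(codons["Ci"]), iter(codons["Cr"])
    pcol = 0
    for move in path:
        if move in (0, 2):  # consume a profile column
            c_ci = next(ci_iter) if row_ci[pcol] != "-" else "---"
            c_cr = next(cr_iter) if row_cr[pcol] != "-" else "---"
            pcol += 1
        else:
            c_ci = c_cr = "---"
        c_at = next(at_iter) if move in (0, 1) else "---"
        out["At"].append(c_at)
        out["Ci"].append(c_ci)
        out["Cr"].append(c_cr)

    core = {sp: "".join(out[sp]) for sp in SPECIES}

    # edge blocks preserving out-of-frame overhangs, one block per species
    def pad_block(sp: str, text: str) -> dict:
        return {s: (text if s == sp else "-" * len(text)) for s in SPECIES}

    blocks = []
    for sp in SPECIES:
        if lead[sp]:
            blocks.append(pad_block(sp, lead[sp]))
    blocks.append(core)
    for sp in SPECIES:
        if trail[sp]:
            blocks.append(pad_block(sp, trail[sp]))
    rows = {sp: "".join(b[sp] for b in blocks) for sp in SPECIES}
    return TripletAlignment(rows=rows, frame=frame, gene_id=gene_id)


# ---------------------------------------------------------------------------
# trimming and masking


def trim_to_common_region(aln: TripletAlignment) -> TripletAlignment:
    """Remove columns before the first and after the last position at which
    all three rows have non-gap characters."""
    present = np.all(
        np.array([[c != "-" for c in aln.rows[sp]] for sp in SPECIES]), axis=0
    )
    idx = np.where(present)[0]
    if idx.size == 0:
        raise ValueError(f"{aln.gene_id}: no column covered by all three sequences")
    keep = np.arange(idx[0], idx[-1] + 1)
    return aln.slice_columns(keep)


def trim_partial_codons(aln: TripletAlignment) -> TripletAlignment:
    """Remove boundary columns so the At row starts and ends on codon
    boundaries of the input At sequence (given the frame offset)."""
    pos = aln.positions["At"]
    phase = np.where(pos >= 0, (pos - aln.frame) % 3, -1)
    starts = np.where(phase == 0)[0]
    ends = np.where(phase == 2)[0]
    if starts.size == 0 or ends.size == 0 or ends[-1] < starts[0]:
        raise ValueError(f"{aln.gene_id}: no complete At codon in window")
    keep = np.arange(starts[0], ends[-1] + 1)
    return aln.slice_columns(keep)


def load_transit_table(path) -> dict:
    """TSV (gene_id, cleavage_codon; 1-based) -> dict."""
    df = pd.read_csv(path, sep="\t")
    table = dict(zip(df["gene_id"].astype(str), df["cleavage_codon"].astype(int)))
    for g, c in table.items():
        if c < 1:
            raise ValueError(f"{g}: cleavage index must be >= 1")
    return table


def mask_transit_peptide(aln: TripletAlignment, table: dict) -> TripletAlignment:
    """Remove alignment columns of At codons 1..cleavage-1 (the transit
    peptide).  Genes absent from the table pass through unchanged."""
    cleavage = table.get(aln.gene_id)
    if cleavage is None or cleavage <= 1:
        return aln
    pos = aln.positions["At"]
    at_len = int(pos.max()) + 1
    if (cleavage - 1) * 3 + aln.frame > at_len:
        raise ValueError(f"{aln.gene_id}: cleavage codon {cleavage} beyond At length")
    codon_no = np.where(pos >= 0, (pos - aln.frame) // 3 + 1, 0)
    mature = np.where(codon_no >= cleavage)[0]
    if mature.size == 0:
        raise ValueError(f"{aln.gene_id}: nothing left after transit-peptide masking")
    keep = np.arange(mature[0], aln.length)
    return aln.slice_columns(keep)


_AMBIGUOUS = set("NRYSWKMBDHV")


def drop_unusable_codons(aln: TripletAlignment) -> TrimmedCodonAlignment:
    """Complete-deletion gap policy: drop every codon column containing a
    gap, an ambiguity character or a stop codon in any row."""
    L = aln.length
    if L % 3 != 0:
        raise ValueError(f"{aln.gene_id}: alignment length {L} not divisible into codons")
    n_codons = L // 3
    mat = []
    kept = []
    for k in range(n_codons):
        col = []
        ok = True
        for sp in SPECIES:
            codon = aln.rows[sp][3 * k : 3 * k + 3]
            if "-" in codon or any(ch in _AMBIGUOUS for ch in codon) or codon in STOP_CODONS:
                ok = False
                break
            idx = CODON_INDEX.get(codon)
            if idx is None:
                ok = False
                break
            col.append(idx)
        if ok:
            mat.append(col)
            kept.append(k)
    if not mat:
        raise ValueError(f"{aln.gene_id}: zero usable codons remain")
    spans = {}
    for sp in SPECIES:
        pos = aln.positions[sp]
        covered = pos[pos >= 0]
        spans[sp] = (int(covered.min()), int(covered.max()) + 1)
    return TrimmedCodonAlignment(
        codon_matrix=np.array(mat, dtype=np.int16).T,
        gene_id=aln.gene_id,
        row_spans=spans,
        kept_codons=np.array(kept, dtype=int),
    )


def prepare_triplet(
    seqs: dict, transit_table: dict | None = None, frame: int = 0, gene_id: str = ""
) -> TrimmedCodonAlignment:
    """Full preparation chain for one triplet."""
    aln = align_triplet(seqs, frame=frame, gene_id=gene_id)
    aln = trim_to_common_region(aln)
    aln = trim_partial_codons(aln)
    if transit_table:
        aln = mask_transit_peptide(aln, transit_table)
    return drop_unusable_codons(aln)


# ---------------------------------------------------------------------------
# I/O: FASTA and sequential PHYLIP round trips


def write_fasta(aln: TrimmedCodonAlignment, path) -> None:
    seqs = aln.sequences()
    Path(path).write_text("".join(f">{sp}\n{seqs[sp]}\n" for sp in SPECIES))


def write_phylip(aln: TrimmedCodonAlignment, path) -> None:
    seqs = aln.sequences()
    n = len(seqs["At"])
    lines = [f" 3 {n}"] + [f"{sp:<10s}{seqs[sp]}" for sp in SPECIES]
    Path(path).write_text("\n".join(lines) + "\n")


def read_codon_alignment(path, gene_id: str = "") -> TrimmedCodonAlignment:
    """Read a 3-row codon alignment from FASTA or sequential PHYLIP."""
    from .genetics import codons_to_indices

    text = Path(path).read_text().strip()
    seqs = {}
    if text.startswith(">"):
        name = None
        for line in text.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line.strip()
    else:
        lines = text.splitlines()
        for line in lines[1:]:
            name, seq = line[:10].strip(), line[10:].strip()
            seqs[name] = seq
    mat = np.array([codons_to_indices(seqs[sp]) for sp in SPECIES])
    return TrimmedCodonAlignment(codon_matrix=mat, gene_id=gene_id)
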