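"""Reciprocal-best-hit orthology across three coding-sequence sets.

Putative orthologue triplets (At, Ci, Cr) are those whose six directed
best-hit relations are mutually consistent.  Best hits come from local
alignment (k-mer seeding to shortlist subjects, exact affine-gap local
alignment to score them), followed by identity/coverage filtering and an
overhang rule: a query reports no best hit when the runner-up subject scores
within a margin of the top subject, suppressing paralogue-ambiguous
assignments.

External 7-column tabular hit files (qseqid, sseqid, pident, length, qlen,
slen, bitscore — a BLAST outfmt-6-style dialect) are accepted so real hit
tables can bypass the internal aligner.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

SPECIES = ("At", "Ci", "Cr")
_VALID = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    nucleotides: str

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if len(self.nucleotides) < 1:
            raise ValueError("empty sequence")
        if not _VALID.match(self.nucleotides.upper()):
            raise ValueError(f"{self.id}: sequence contains non-ACGTN characters")
        object.__setattr__(self, "nucleotides", self.nucleotides.upper())


@dataclass
class Hit:
    query_id: str
    subject_id: str
    score: float
    identity: float
    aligned_len_query: int
    aligned_len_subject: int
    query_len: int
    subject_len: int

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.aligned_len_query > self.query_len or self.aligned_len_subject > self.subject_len:
            raise ValueError("aligned length exceeds sequence length")


@dataclass
class AlignmentParams:
    """Scoring and seeding parameters for the local best-hit search."""

    seed_length: int = 11
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    overhang: float = 0.18
    max_candidates: int = 12
    min_seed_hits: int = 3
    sw_fallback_len: int = 5000

    def __post_init__(self):
        if self.seed_length < 8:
            raise ValueError("seed length must be >= 8")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_stats(alignment) -> tuple[float, int, int]:
    """(identity over alignment columns incl. gap columns, query span,
    subject span) for one Bio.Align local alignment (target = query)."""
    counts = alignment.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / total if total else 0.0
    tc, qc = alignment.coordinates[0], alignment.coordinates[1]
    return identity, int(tc[-1] - tc[0]), int(qc[-1] - qc[0])


def _pair_key(a: SequenceRecord, b: SequenceRecord):
    ka, kb = (a.species, a.id), (b.species, b.id)
    return (ka, kb) if ka <= kb else (kb, ka)


def _aligned_pair(
    a: SequenceRecord, b: SequenceRecord, aligner, cache: Optional[dict]
) -> tuple[float, float, int, int]:
    """(score, identity, span_a, span_b) of the local alignment of a vs b.

    Scores, identity and spans are symmetric, so results are cached per
    unordered pair and shared across the six directed searches.
    """
    key = _pair_key(a, b)
    if cache is not None and key in cache:
        score, identity, s0, s1 = cache[key]
    else:
        aln = aligner.align(a.nucleotides, b.nucleotides)[0]
        identity, sa, sb = _alignment_stats(aln)
        score = float(aln.score)
        s0, s1 = (sa, sb) if key[0] == (a.species, a.id) else (sb, sa)
        if cache is not None:
            cache[key] = (score, identity, s0, s1)
    if key[0] == (a.species, a.id):
        return score, identity, s0, s1
    return score, identity, s1, s0


def local_best_hits(
    queries: Iterable[SequenceRecord],
    subjects: Iterable[SequenceRecord],
    params: Optional[AlignmentParams] = None,
    pair_cache: Optional[dict] = None,
) -> list[Hit]:
    """Best local-alignment hit per query across the subject set.

    Candidate subjects are shortlisted by shared k-mer count (subjects well
    below the top seed count cannot approach the top alignment score and are
    skipped); shortlisted pairs are scored by exact affine-gap local
    alignment.  When seeding yields no candidate, sequences up to
    ``sw_fallback_len`` are aligned against every subject.  A hit is reported
    only when the best score exceeds the runner-up subject's score by the
    overhang margin: runner-up >= (1 - overhang) * top suppresses the hit.

    ``pair_cache`` (optional dict) shares symmetric alignment results across
    repeated searches over the same sequence sets.
    """
    params = params or AlignmentParams()
    queries = sorted(queries, key=lambda r: r.id)
    subjects = sorted(subjects, key=lambda r: r.id)
    if not subjects:
        return []
    aligner = params.aligner()
    k = params.seed_length
    index: dict[str, set] = defaultdict(set)
    for j, s in enumerate(subjects):
        for km in _kmers(s.nucleotides, k):
            index[km].add(j)

    hits = []
    for q in queries:
        shared = defaultdict(int)
        for km in _kmers(q.nucleotides, k):
            for j in index.get(km, ()):
                shared[j] += 1
        if shared:
            top = max(shared.values())
            floor = max(min(params.min_seed_hits, top), int(0.3 * top))
            cand = [j for j, c in shared.items() if c >= floor]
            cand = sorted(cand, key=lambda j: (-shared[j], subjects[j].id))
            cand = cand[: params.max_candidates]
        elif len(q.nucleotides) <= params.sw_fallback_len:
            cand = [
                j
                for j in range(len(subjects))
                if len(subjects[j].nucleotides) <= params.sw_fallback_len
            ]
        else:
            cand = []
        if not cand:
            continue
        stats = [_aligned_pair(q, subjects[j], aligner, pair_cache) for j in cand]
        scores = np.array([s[0] for s in stats])
        order = np.argsort(-scores, kind="mergesort")
        best_j, best_score = order[0], float(scores[order[0]])
        if best_score <= 0:
            continue
        if len(order) > 1:
            runner = float(scores[order[1]])
            if runner >= (1.0 - params.overhang) * best_score:
                continue  # no unique best hit
        subj = subjects[cand[best_j]]
        _, identity, qspan, sspan = stats[best_j]
        hits.append(
            Hit(
                query_id=q.id,
                subject_id=subj.id,
                score=best_score,
                identity=identity,
                aligned_len_query=qspan,
                aligned_len_subject=sspan,
                query_len=len(q.nucleotides),
                subject_len=len(subj.nucleotides),
            )
        )
    return hits


def filter_hits(
    hits: Iterable[Hit], min_identity: float = 0.70, min_coverage: float = 0.60
) -> list[Hit]:
    """Retain hits with identity >= min_identity and with either the query or
    the subject aligned over >= min_coverage of its length."""
    if not (0 < min_identity <= 1) or not (0 < min_coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    out = []
    for h in hits:
        cov_q = h.aligned_len_query / h.query_len
        cov_s = h.aligned_len_subject / h.subject_len
        if h.identity >= min_identity and (cov_q >= min_coverage or cov_s >= min_coverage):
            out.append(h)
    return out


@dataclass
class Triplet:
    At: str
    Ci: str
    Cr: str
    hits: dict = field(default_factory=dict)  # (query_species, subject_species) -> Hit


@dataclass
class TripletSet:
    triplets: list

    def __len__(self):
        return len(self.triplets)

    def __iter__(self):
        return iter(self.triplets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"At": t.At, "Ci": t.Ci, "Cr": t.Cr} for t in self.triplets]
        )


def _as_map(table: Iterable[Hit]) -> dict[str, Hit]:
    out: dict[str, Hit] = {}
    for h in table:
        if h.query_id in out:
            raise ValueError(f"duplicate query row {h.query_id!r} in hit table")
        out[h.query_id] = h
    return out


def reciprocal_best_triplets(hit_tables: dict) -> TripletSet:
    """Triplets whose six directed best-hit relations are mutually consistent.

    ``hit_tables`` maps every ordered species pair, e.g. ("At", "Ci"), to its
    best-hit list (one row per query).
    """
    pairs = [(a, b) for a in SPECIES for b in SPECIES if a != b]
    missing = [p for p in pairs if p not in hit_tables]
    if missing:
        raise ValueError(f"missing hit tables for pairs {missing}")
    maps = {p: _as_map(hit_tables[p]) for p in pairs}
    triplets = []
    for a_id, h_ab in sorted(maps[("At", "Ci")].items()):
        b_id = h_ab.subject_id
        h_ac = maps[("At", "Cr")].get(a_id)
        if h_ac is None:
            continue
        c_id = h_ac.subject_id
        checks = {
            ("Ci", "At"): (b_id, a_id),
            ("Ci", "Cr"): (b_id, c_id),
            ("Cr", "At"): (c_id, a_id),
            ("Cr", "Ci"): (c_id, b_id),
        }
        consistent = True
        support = {("At", "Ci"): h_ab, ("At", "Cr"): h_ac}
        for pair, (qid, expected) in checks.items():
            h = maps[pair].get(qid)
            if h is None or h.subject_id != expected:
                consistent = False
                break
            support[pair] = h
        if consistent:
            triplets.append(Triplet(At=a_id, Ci=b_id, Cr=c_id, hits=support))
    return TripletSet(triplets)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path, species: str) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, species=species, nucleotides=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


_HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "qlen", "slen", "bitscore"]


def write_hit_table(hits: Iterable[Hit], path) -> None:
    """7-column tabular dialect: qseqid, sseqid, pident (percent), length
    (query span), qlen, slen, bitscore (the local alignment score)."""
    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.subject_id,
            "pident": round(100.0 * h.identity, 3),
            "length": h.aligned_len_query,
            "qlen": h.query_len,
            "slen": h.subject_len,
            "bitscore": h.score,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> list[Hit]:
    """Read the 7-column dialect, or 12-column BLAST outfmt 6 extended with
    qlen/slen appended (14 columns)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:7]) != _HIT_COLUMNS:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 14:
            raise ValueError(
                "expected the 7-column dialect with header, or headerless "
                "outfmt-6 plus qlen and slen (14 columns)"
            )
        df = df.rename(
            columns={0: "qseqid", 1: "sseqid", 2: "pident", 3: "length", 11: "bitscore", 12: "qlen", 13: "slen"}
        )
    hits = []
    for r in df.itertuples(index=False):
        qspan = min(int(r.length), int(r.qlen))
        hits.append(
            Hit(
                query_id=str(r.qseqid),
                subject_id=str(r.sseqid),
                score=float(r.bitscore),
                identity=float(r.pident) / 100.0,
                aligned_len_query=qspan,
                aligned_len_subject=min(int(r.length), int(r.slen)),
                query_len=int(r.qlen),
                subject_len=int(r.slen),
            )
        )
    return hits
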