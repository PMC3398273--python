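"""Optimal-codon inference and per-gene codon-usage statistics.

Species-specific optimal (preferred) codons are inferred from a reference
gene set (typically ribosomal genes): genes are ordered along the first axis
of a correspondence analysis of their relative synonymous codon usage (RSCU),
the highest- and lowest-biased halves are pooled, and codons significantly
overrepresented in the high-bias pool are flagged optimal.  Per-gene summary
statistics are Fop (frequency of optimal codons), GC and GC3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .genetics import CODON_INDEX, FAMILIES, N_CODONS, SENSE_CODONS

#: families with >= 2 codons (6-fold families treated as single families)
DEGENERATE_FAMILIES = {aa: fam for aa, fam in FAMILIES.items() if len(fam) >= 2}


@dataclass
class CodonCounts:
    """Sense-codon counts of one coding sequence."""

    gene_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CODONS,) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 61-vector")

    @property
    def n_codons(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_sequence(cls, seq: str, gene_id: str = "") -> "CodonCounts":
        counts = np.zeros(N_CODONS)
        seq = seq.upper()
        for k in range(0, len(seq) - len(seq) % 3, 3):
            idx = CODON_INDEX.get(seq[k : k + 3])
            if idx is not None:
                counts[idx] += 1
        return cls(gene_id=gene_id, counts=counts)


def rscu(counts: CodonCounts) -> np.ndarray:
    """Relative synonymous codon usage: count * family_size / family_total.

    Codons of unobserved families are NaN (flagged missing); single-codon
    families are always 1 when observed.
    """
    if counts.n_codons < 1:
        raise ValueError("empty codon counts")
    out = np.full(N_CODONS, np.nan)
    for fam in FAMILIES.values():
        fam = list(fam)
        total = counts.counts[fam].sum()
        if total > 0:
            out[fam] = counts.counts[fam] * len(fam) / total
    return out


def rscu_matrix(counts_set: list[CodonCounts]) -> pd.DataFrame:
    """Genes x codons RSCU table (missing families as NaN)."""
    return pd.DataFrame(
        [rscu(c) for c in counts_set],
        index=[c.gene_id for c in counts_set],
        columns=list(SENSE_CODONS),
    )


def correspondence_axis(rscu_mat: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Axis-1 gene scores of a correspondence analysis of the RSCU matrix.

    Chi-square-metric SVD of the centred profile matrix; NaNs (unobserved
    families) enter as zero usage.  The sign is fixed so the gene with the
    largest overall bias (sum of squared RSCU deviations from 1) scores
    positive.
    """
    X = np.asarray(rscu_mat, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an RSCU matrix with >= 3 genes")
    Xf = np.nan_to_num(X, nan=0.0)
    keep = Xf.sum(axis=0) > 0
    Xf = Xf[:, keep]
    total = Xf.sum()
    if total <= 0:
        raise ValueError("degenerate RSCU matrix")
    P = Xf / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0):
        raise ValueError("gene with empty codon usage")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    if sv[0] <= 1e-12:
        return np.zeros(X.shape[0])
    scores = U[:, 0] * sv[0] / np.sqrt(r)
    bias = np.nansum((X - 1.0) ** 2, axis=1)
    if scores[int(np.argmax(bias))] < 0:
        scores = -scores
    return scores


@dataclass
class OptimalCodonSet:
    """Codons flagged optimal for one species, with per-codon test audit."""

    species: str
    codons: frozenset
    stats: pd.DataFrame  # codon, amino_acid, statistic, pvalue, optimal

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons


def infer_optimal_codons(
    counts_set: list[CodonCounts],
    species: str = "",
    min_codons: int = 100,
    split: float = 0.50,
    alpha: float = 0.01,
) -> OptimalCodonSet:
    """Optimal codons from a reference gene set.

    Genes shorter than ``min_codons`` are discarded; the remaining genes are
    ranked by the correspondence-analysis axis-1 score and the top/bottom
    ``split`` fractions pooled.  Per codon, a 2x2 test (codon vs rest of
    family, high- vs low-bias pool; Pearson chi-square with Yates correction,
    Fisher exact when any expected cell < 5) flags codons significantly
    overrepresented in the high-bias pool at ``alpha``.
    """
    kept = [c for c in counts_set if c.n_codons >= min_codons]
    if len(kept) < 4:
        raise ValueError(f"need >= 4 reference genes of >= {min_codons} codons, got {len(kept)}")
    scores = correspondence_axis(rscu_matrix(kept))
    order = np.argsort(-scores, kind="mergesort")
    n_pool = max(2, int(round(split * len(kept))))
    high = np.sum([kept[i].counts for i in order[:n_pool]], axis=0)
    low = np.sum([kept[i].counts for i in order[-n_pool:]], axis=0)

    rows = []
    optimal = set()
    for aa, fam in sorted(DEGENERATE_FAMILIES.items()):
        fam = list(fam)
        for i in fam:
            rest = [j for j in fam if j != i]
            tab = np.array(
                [[high[i], high[rest].sum()], [low[i], low[rest].sum()]], dtype=float
            )
            if tab.sum() == 0 or tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                stat, p = 0.0, 1.0
            else:
                expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
                if expected.min() < 5:
                    stat, p = fisher_exact(tab.astype(int), alternative="two-sided")
                else:
                    stat, p, _, _ = chi2_contingency(tab, correction=True)
            f_high = high[i] / max(high[fam].sum(), 1e-12)
            f_low = low[i] / max(low[fam].sum(), 1e-12)
            is_opt = bool(p < alpha and f_high > f_low)
            if is_opt:
                optimal.add(SENSE_CODONS[i])
            rows.append(
                {
                    "codon": SENSE_CODONS[i],
                    "amino_acid": aa,
                    "statistic": float(stat),
                    "pvalue": float(p),
                    "freq_high": f_high,
                    "freq_low": f_low,
                    "optimal": is_opt,
                }
            )
    return OptimalCodonSet(species=species, codons=frozenset(optimal), stats=pd.DataFrame(rows))


def fop(counts: CodonCounts, optimal: OptimalCodonSet | frozenset | set) -> float:
    """Frequency of optimal codons.

    Numerator: codons in the optimal set; denominator: codons of families
    that contain at least one optimal codon (single-codon families never
    contribute).  NaN (flagged) when the denominator is zero.
    """
    if counts.n_codons < 1:
        raise ValueError("empty codon counts")
    opt = optimal.codons if isinstance(optimal, OptimalCodonSet) else frozenset(optimal)
    opt_idx = {CODON_INDEX[c] for c in opt}
    num = den = 0.0
    for aa, fam in DEGENERATE_FAMILIES.items():
        if not any(i in opt_idx for i in fam):
            continue
        den += counts.counts[list(fam)].sum()
        num += sum(counts.counts[i] for i in fam if i in opt_idx)
    if den == 0:
        warnings.warn(f"{counts.gene_id}: no codons in optimal-bearing families", stacklevel=2)
        return np.nan
    return float(num / den)


def gc_stats(seq_or_counts) -> tuple[float, float]:
    """(GC over all positions, GC3 over third positions of sense codons)."""
    if isinstance(seq_or_counts, CodonCounts):
        counts = seq_or_counts.counts
        total_nt = 3.0 * counts.sum()
        gc_all = sum(
            counts[i] * sum(ch in "GC" for ch in SENSE_CODONS[i]) for i in range(N_CODONS)
        )
        gc3 = sum(counts[i] for i in range(N_CODONS) if SENSE_CODONS[i][2] in "GC")
        return float(gc_all / total_nt), float(gc3 / counts.sum())
    seq = seq_or_counts.upper()
    n = len(seq) - len(seq) % 3
    gc_all = sum(ch in "GC" for ch in seq[:n]) / n if n else np.nan
    thirds = [seq[k + 2] for k in range(0, n, 3) if seq[k : k + 3] in CODON_INDEX]
    gc3 = sum(ch in "GC" for ch in thirds) / len(thirds) if thirds else np.nan
    return float(gc_all), float(gc3)


def usage_profiles(
    sequences: dict, optimal: OptimalCodonSet
) -> pd.DataFrame:
    """Per-gene UsageProfile table (Fop, GC, GC3) from id -> sequence."""
    rows = []
    for gid, seq in sorted(sequences.items()):
        counts = CodonCounts.from_sequence(seq, gid)
        gc, gc3 = gc_stats(counts)
        rows.append({"gene_id": gid, "fop": fop(counts, optimal), "gc": gc, "gc3": gc3})
    return pd.DataFrame(rows).set_index("gene_id")
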