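"""Canonical k-mer enumeration, five-bin Fisher enrichment, feature matrices.

A k-mer and its reverse complement are one feature; the canonical form is
the lexicographically smaller of the two.  Presence is per gene (set
semantics) over the union of the upstream, gene-body and downstream regions.
Feature k-mers are those enriched (one-sided Fisher, BH q < alpha) among the
positive class in EVERY one of five disjoint, class-stratified training bins.

Internally k-mers are base-4 integer codes; all counting and testing is
vectorised, with scipy's hypergeometric distribution as the single exact
Fisher core.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genes import GeneRecord, REGIONS
from .simulate import InsufficientExamplesError

DEFAULT_K_RANGE = (5, 6, 7, 8)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


@lru_cache(maxsize=None)
def _revcomp_table(k: int) -> np.ndarray:
    """rc[code] = code of the reverse complement, for all 4**k codes."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def encode_seq(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Codes of all k-windows on the given strand; windows with non-ACGT skipped."""
    enc = encode_seq(seq)
    if len(enc) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid].astype(np.int64) @ powers


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = _revcomp_table(k)
    return np.minimum(codes, rc[codes])


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        v = int(_ENC[ord(b)])
        if v > 3:
            raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
        code = (code << 2) | v
    return code


def canonical(seq: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    k = len(seq)
    code = kmer_to_code(seq)
    return code_to_kmer(int(canonical_codes(np.array([code]), k)[0]), k)


def gene_kmer_presence(
    gene: GeneRecord, k_range: tuple[int, ...] = DEFAULT_K_RANGE
) -> set[str]:
    """All canonical k-mers present in any of the gene's three regions."""
    out: set[str] = set()
    for k in k_range:
        codes: list[np.ndarray] = [
            kmer_codes(gene.region(r), k) for r in REGIONS
        ]
        allc = np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)
        for c in np.unique(canonical_codes(allc, k)):
            out.add(code_to_kmer(int(c), k))
    return out


class PresenceIndex:
    """Per-gene unique canonical k-mer codes, built once and reused.

    Supports fast per-class presence counting (for the binned Fisher screen)
    and binary feature-matrix construction.
    """

    def __init__(self, genes: list[GeneRecord], k_range: tuple[int, ...] = DEFAULT_K_RANGE):
        self.k_range = tuple(k_range)
        self.gene_ids = [g.gene_id for g in genes]
        self._row = {gid: i for i, gid in enumerate(self.gene_ids)}
        self.codes: dict[int, list[np.ndarray]] = {k: [] for k in self.k_range}
        for g in genes:
            for k in self.k_range:
                parts = [kmer_codes(g.region(r), k) for r in REGIONS]
                allc = np.concatenate(parts)
                self.codes[k].append(
                    np.unique(canonical_codes(allc, k)).astype(np.int64)
                )

    def counts(self, gene_ids: list[str], k: int) -> np.ndarray:
        """Number of the given genes containing each canonical code (len 4**k)."""
        rows = [self._row[g] for g in gene_ids]
        if not rows:
            return np.zeros(4 ** k, dtype=np.int64)
        allc = np.concatenate([self.codes[k][r] for r in rows])
        return np.bincount(allc, minlength=4 ** k)

    def presence_matrix(self, gene_ids: list[str], kmers: list[str]) -> np.ndarray:
        """Binary genes x kmers matrix (canonical presence)."""
        cols_by_k: dict[int, list[tuple[int, int]]] = {}
        for j, km in enumerate(kmers):
            k = len(km)
            code = int(canonical_codes(np.array([kmer_to_code(km)]), k)[0])
            cols_by_k.setdefault(k, []).append((j, code))
        X = np.zeros((len(gene_ids), len(kmers)), dtype=np.uint8)
        for i, gid in enumerate(gene_ids):
            row = self._row[gid]
            for k, pairs in cols_by_k.items():
                present = self.codes[k][row]
                for j, code in pairs:
                    idx = np.searchsorted(present, code)
                    if idx < len(present) and present[idx] == code:
                        X[i, j] = 1
        return X


@dataclass
class EnrichmentResult:
    kmer: str
    a: int  # positives with the k-mer
    b: int  # positives without
    c: int  # negatives with
    d: int  # negatives without
    odds_ratio: float
    p: float
    q: float = float("nan")


def fisher_pvalues(a, b, c, d) -> np.ndarray:
    """One-sided (enrichment) Fisher exact p, vectorised.

    P(X >= a) with X hypergeometric over total M = a+b+c+d draws of size
    a+b from a+c successes.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    M = a + b + c + d
    return hypergeom.sf(a - 1, M, a + b, a + c)


def odds_ratios(a, b, c, d) -> np.ndarray:
    """(a*d)/(b*c) with a 0.5 Haldane correction when any cell is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (np.where(zero, x + 0.5, x) for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_enrichment(kmer: str, a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Single-table enrichment result (q left for the caller's BH pass)."""
    if a + b == 0 or c + d == 0:
        raise InsufficientExamplesError("insufficient-examples: empty class")
    p = float(fisher_pvalues(a, b, c, d))
    orat = float(odds_ratios(a, b, c, d))
    return EnrichmentResult(kmer=kmer, a=a, b=b, c=c, d=d, odds_ratio=orat, p=p)


def _bh(p: np.ndarray) -> np.ndarray:
    # local BH step-up (the enrichment module re-exports the public version)
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def binned_enrichment(
    index: PresenceIndex,
    train_pos: list[str],
    train_neg: list[str],
    n_bins: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    return_tables: bool = False,
):
    """K-mers with BH q < alpha in every one of n_bins stratified bins.

    Bins are disjoint and class-stratified; within each bin every canonical
    k-mer present in the training genes is tested for enrichment among that
    bin's positives, and BH is applied jointly across all k simultaneously.
    Returns the selected canonical k-mers (sorted by length then sequence);
    with ``return_tables`` also a per-bin DataFrame of all tested k-mers.
    """
    rng = np.random.default_rng(seed)
    if len(train_pos) < n_bins or len(train_neg) < n_bins:
        raise InsufficientExamplesError(
            f"insufficient-examples: need >= {n_bins} genes per class"
        )
    pos = np.array(sorted(train_pos))
    neg = np.array(sorted(train_neg))
    rng.shuffle(pos)
    rng.shuffle(neg)
    pos_bins = np.array_split(pos, n_bins)
    neg_bins = np.array_split(neg, n_bins)

    # candidate codes per k: present in at least one training gene
    train_all = list(pos) + list(neg)
    cand: dict[int, np.ndarray] = {}
    for k in index.k_range:
        cand[k] = np.flatnonzero(index.counts(train_all, k))

    pass_all: dict[int, np.ndarray] = {
        k: np.ones(len(cand[k]), dtype=bool) for k in index.k_range
    }
    tables = []
    for b_idx in range(n_bins):
        bp, bn = list(pos_bins[b_idx]), list(neg_bins[b_idx])
        a_parts, c_parts = [], []
        for k in index.k_range:
            a_parts.append(index.counts(bp, k)[cand[k]])
            c_parts.append(index.counts(bn, k)[cand[k]])
        a = np.concatenate(a_parts)
        c = np.concatenate(c_parts)
        b = len(bp) - a
        d = len(bn) - c
        p = fisher_pvalues(a, b, c, d)
        q = _bh(p)
        sig = q < alpha
        start = 0
        for k, a_k in zip(index.k_range, a_parts):
            n_k = len(a_k)
            pass_all[k] &= sig[start:start + n_k]
            start += n_k
        if return_tables:
            kmer_names = [
                code_to_kmer(int(code), k)
                for k in index.k_range
                for code in cand[k]
            ]
            tables.append(
                pd.DataFrame(
                    {"bin": b_idx, "kmer": kmer_names, "a": a, "b": b, "c": c,
                     "d": d, "odds_ratio": odds_ratios(a, b, c, d), "p": p,
                     "q": q}
                )
            )
    selected = [
        code_to_kmer(int(code), k)
        for k in index.k_range
        for code in cand[k][pass_all[k]]
    ]
    selected.sort(key=lambda s: (len(s), s))
    if return_tables:
        return selected, pd.concat(tables, ignore_index=True)
    return selected


@dataclass
class KmerFeatureMatrix:
    genes: list[str]
    kmers: list[str]
    values: np.ndarray  # binary, genes x kmers
    class_labels: np.ndarray  # 1 positive / 0 negative

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.kmers)
        df.insert(0, "class", self.class_labels)
        return df


def build_matrix(
    index: PresenceIndex,
    kmers: list[str],
    pos_ids: list[str],
    neg_ids: list[str],
) -> KmerFeatureMatrix:
    """Binary presence matrix over positives then negatives, in given order."""
    if not kmers:
        raise ValueError("no-features: empty k-mer list")
    gene_ids = list(pos_ids) + list(neg_ids)
    X = index.presence_matrix(gene_ids, kmers)
    y = np.array([1] * len(pos_ids) + [0] * len(neg_ids))
    return KmerFeatureMatrix(genes=gene_ids, kmers=list(kmers), values=X,
                             class_labels=y)
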