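"""PWM similarity: best-alignment Pearson correlation and TFBM matching.

Two motifs are compared by sliding one PWM along the other over every
ungapped offset with at least ``min_overlap`` overlapping columns (and, by
default, also against the reverse complement), computing the Pearson
correlation of the two flattened 4 x overlap probability blocks, and keeping
the maximum.  For one-hot k-mers of equal length k with m matching positions
and full overlap this reduces to pcc = (4m - k) / (3k).

A pCRE is matched to a known TFBM library by its best PCC; the match is
significant when the PCC exceeds the empirical 95th percentile of pairwise
PCCs among TFBMs of the matched motif's family (or, configurably, between
families).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import PWM, TFBMRecord, kmer_to_pwm


@dataclass
class MotifSimilarityResult:
    query: str
    target: str
    pcc: float
    offset: int
    orientation: str  # forward / revcomp
    significant: bool = False
    background_p95: float = float("nan")
    family: str = ""
    zero_variance: bool = False


def _pcc_flat(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    a = a.ravel()
    b = b.ravel()
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return 0.0, True  # uniform block: correlation undefined, defined as 0
    return float(np.corrcoef(a, b)[0, 1]), False


def pwm_pcc(
    p: PWM,
    q: PWM,
    min_overlap: int = 5,
    allow_rc: bool = True,
) -> MotifSimilarityResult:
    """Maximum Pearson correlation over all admissible ungapped alignments.

    ``offset`` is the position of q's first column relative to p's first
    column (negative: q starts before p).
    """
    min_overlap = min(min_overlap, len(p), len(q))
    best: MotifSimilarityResult | None = None
    variants = [("forward", q.matrix)]
    if allow_rc:
        variants.append(("revcomp", q.reverse_complement().matrix))
    for orientation, qm in variants:
        for offset in range(-(len(q) - min_overlap), len(p) - min_overlap + 1):
            lo_p = max(0, offset)
            hi_p = min(len(p), offset + len(q))
            block_p = p.matrix[lo_p:hi_p]
            block_q = qm[lo_p - offset: hi_p - offset]
            pcc, zero_var = _pcc_flat(block_p, block_q)
            if best is None or pcc > best.pcc:
                best = MotifSimilarityResult(
                    query=p.name, target=q.name, pcc=pcc, offset=offset,
                    orientation=orientation, zero_variance=zero_var,
                )
    assert best is not None
    return best


def family_background(
    library: list[TFBMRecord],
    family: str,
    scope: str = "within_family",
    min_overlap: int = 5,
) -> float:
    """Empirical 95th percentile of pairwise TFBM PCCs in the scope set.

    within_family: pairs among the family's own TFBMs; between_family:
    pairs of TFBMs from different families (the family argument is ignored
    beyond scope selection).  Too small a scope set returns 1.0 so nothing
    passes the strict ``>`` rule ("insufficient-background").
    """
    if scope == "within_family":
        members = [r for r in library if r.family == family]
        pairs = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    elif scope == "between_family":
        pairs = [
            (library[i], library[j])
            for i in range(len(library))
            for j in range(i + 1, len(library))
            if library[i].family != library[j].family
        ]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not pairs:
        return 1.0
    pccs = [pwm_pcc(a.pwm, b.pwm, min_overlap=min_overlap).pcc for a, b in pairs]
    return float(np.percentile(pccs, 95))  # linear interpolation


def match_tfbm(
    pcre: str,
    library: list[TFBMRecord],
    scope: str = "within_family",
    min_overlap: int = 5,
    backgrounds: dict[str, float] | None = None,
) -> list[MotifSimilarityResult]:
    """PCC of a pCRE against every library TFBM, best first.

    Each result carries the 95th-percentile background of its TFBM's family
    and a significance flag (strict ``pcc > background_p95``).  A pCRE whose
    best match is not significant is "unknown".
    """
    if not library:
        raise ValueError("TFBM library is empty")
    query = kmer_to_pwm(pcre)
    if backgrounds is None:
        backgrounds = {}
        for fam in {r.family for r in library}:
            backgrounds[fam] = family_background(
                library, fam, scope=scope, min_overlap=min_overlap
            )
    results = []
    for rec in library:
        r = pwm_pcc(query, rec.pwm, min_overlap=min_overlap)
        r.target = rec.pwm.name or rec.tf_name
        r.family = rec.family
        r.background_p95 = backgrounds[rec.family]
        r.significant = r.pcc > r.background_p95
        results.append(r)
    results.sort(key=lambda r: (-r.pcc, r.target))
    return results


def best_match(results: list[MotifSimilarityResult]) -> MotifSimilarityResult | None:
    """Top hit, or None ("unknown" pCRE) when no hit is significant."""
    top = results[0]
    return top if top.significant else None


# ---------------------------------------------------------------------------
# sequence scanning (used by the TFBM-presence models)

_SCAN_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _SCAN_ENC[ord(_b)] = _i


def _window_scores(seq: str, score_matrix: np.ndarray) -> np.ndarray:
    """Sum of per-position scores over every window, both strands."""
    enc = _SCAN_ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    w = score_matrix.shape[0]
    if len(enc) < w:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (win < 4).all(axis=1)
    win = np.where(win < 4, win, 0)
    fwd = np.take_along_axis(
        np.broadcast_to(score_matrix, (len(win), w, 4)),
        win[:, :, None].astype(np.int64), axis=2,
    )[:, :, 0].sum(axis=1)
    rc = score_matrix[::-1, [3, 2, 1, 0]]
    rev = np.take_along_axis(
        np.broadcast_to(rc, (len(win), w, 4)),
        win[:, :, None].astype(np.int64), axis=2,
    )[:, :, 0].sum(axis=1)
    scores = np.maximum(fwd, rev)
    return scores[valid]


def scan_best_pcc(seq: str, pwm: PWM) -> float:
    """Best one-hot-window-to-PWM Pearson correlation over the sequence.

    For a one-hot window x and PWM block q of width w the correlation is a
    linear function of the match score S = sum_i q[i, x_i]:
    pcc = (S - w/4) / sqrt(3w/4 * (sum q^2 - w/4)), so a single additive
    scan suffices.
    """
    w = len(pwm)
    sqq = float((pwm.matrix ** 2).sum() - w / 4.0)
    if sqq <= 0:
        return 0.0  # uniform PWM: correlation undefined, defined as 0
    scores = _window_scores(seq, pwm.matrix)
    if len(scores) == 0:
        return -1.0
    s_best = float(scores.max())
    return (s_best - w / 4.0) / np.sqrt(3.0 * w / 4.0 * sqq)


def scan_best_logodds(seq: str, pwm: PWM, background: float = 0.25,
                      pseudocount: float = 1e-3) -> float:
    """Best window log-odds score, as a fraction of the maximum achievable."""
    lom = np.log2((pwm.matrix + pseudocount) / background)
    scores = _window_scores(seq, lom)
    if len(scores) == 0:
        return -np.inf
    max_score = float(lom.max(axis=1).sum())
    if max_score <= 0:
        return -np.inf
    return float(scores.max()) / max_score
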