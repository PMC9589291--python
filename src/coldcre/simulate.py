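"""Synthetic cold-stress regulatory datasets with planted motifs.

The generator emulates the statistical structure the downstream analysis
assumes: a six-time-point cold time course plus three other stress
conditions, a cascading (non-decreasing) fraction of responsive genes over
time with Markov persistence between adjacent time points, i.i.d. background
promoter/gene-body/downstream sequences at a configured GC content, motif
instances planted preferentially into the flanks of responsive genes, GO
annotations with a responsiveness-linked term, and a TFBM library holding
both the planted PWMs and decoys.  A truth ledger records every planted
instance so recovery can be scored exactly.

Everything is reproducible: the same config and seed produce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genes import GeneRecord
from .pwm import PWM, TFBMRecord, kmer_to_pwm

DEFAULT_TIME_POINTS = ("0.5", "1", "3", "6", "16", "24")
DEFAULT_OTHER_CONDITIONS = ("dehydration", "salt", "drought")
COLD = "cold"


class InsufficientExamplesError(ValueError):
    """Raised when a class ends up with too few genes ("insufficient-examples")."""


class MotifTooLongError(ValueError):
    """Raised when a motif cannot fit in its target region ("motif-too-long")."""


@dataclass
class PlantedMotif:
    """A motif to plant: consensus (or PWM), its target time points and rates.

    ``p_signal`` is the probability that a gene up-regulated at a target time
    point receives an instance; ``p_background`` the probability for any
    other gene.
    """

    motif: str | PWM
    target_time_points: tuple[str, ...]
    p_signal: float = 0.8
    p_background: float = 0.05
    name: str = ""

    def pwm(self) -> PWM:
        if isinstance(self.motif, PWM):
            return self.motif
        return kmer_to_pwm(self.motif, name=self.name or self.motif)

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return self.motif if isinstance(self.motif, str) else (self.motif.name or "motif")


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    upstream_len: int = 1000
    body_len_range: tuple[int, int] = (500, 3000)
    downstream_len: int = 1000
    gc_content: float = 0.44
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    other_conditions: tuple[str, ...] = DEFAULT_OTHER_CONDITIONS
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    # cascading structure: fraction of genes up-regulated at each time point
    responsive_fraction_per_timepoint: tuple[float, ...] = (
        0.05, 0.07, 0.10, 0.15, 0.20, 0.25,
    )
    down_fraction_per_timepoint: tuple[float, ...] | None = None
    persistence: float = 0.7
    other_condition_fraction: float = 0.10
    effect_size: tuple[float, float] = (2.5, 0.5)
    null_sd: float = 0.2
    n_go_terms: int = 20
    go_terms_per_gene: float = 2.0
    n_decoy_tfbms: int = 10
    tfbm_family_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.responsive_fraction_per_timepoint
        if len(fr) != len(self.time_points):
            raise ValueError("one responsive fraction per time point required")
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ValueError("responsive fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(fr, fr[1:])):
            raise ValueError(
                "responsive fractions must be non-decreasing over time "
                "(cascading response structure)"
            )
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        for m in self.planted_motifs:
            if len(m.pwm()) > self.upstream_len:
                raise MotifTooLongError(
                    f"motif {m.label} longer than upstream region"
                )

    def down_fractions(self) -> tuple[float, ...]:
        if self.down_fraction_per_timepoint is not None:
            return self.down_fraction_per_timepoint
        return tuple(0.5 * f for f in self.responsive_fraction_per_timepoint)


@dataclass
class TruthEntry:
    """One planted motif instance: where it went and what was written."""

    gene_id: str
    motif: str
    region: str
    offset: int
    orientation: str  # forward / revcomp
    instance: str  # the bases actually written, in region coordinates


def plant_instance(
    seq: str,
    pwm: PWM,
    rng: np.random.Generator,
    orientation: str | None = None,
) -> tuple[str, int, str, str]:
    """Overwrite one uniformly placed window of ``seq`` with a PWM sample.

    Returns ``(new_seq, offset, orientation, written)``.  The written bases
    are a draw from the PWM columns, reverse-complemented first when the
    (uniformly chosen) orientation is ``revcomp``.  Sequence length is
    preserved.
    """
    w = len(pwm)
    if w > len(seq):
        raise MotifTooLongError(
            f"motif of length {w} does not fit in sequence of length {len(seq)}"
        )
    offset = int(rng.integers(0, len(seq) - w + 1))
    if orientation is None:
        orientation = "forward" if rng.random() < 0.5 else "revcomp"
    site = pwm.sample(rng)
    if orientation == "revcomp":
        site = _revcomp(site)
    new_seq = seq[:offset] + site + seq[offset + w:]
    return new_seq, offset, orientation, site


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _markov_membership(
    n_genes: int,
    fractions: tuple[float, ...],
    persistence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean (n_genes, n_time) responsiveness with target marginals.

    A first-order chain: a gene responsive at time t stays responsive at
    t+1 with probability ``persistence`` (raised when needed to keep the
    non-decreasing marginal attainable); newly responsive genes are recruited
    so the marginal fraction matches the configured cascade.
    """
    n_t = len(fractions)
    out = np.zeros((n_genes, n_t), dtype=bool)
    out[:, 0] = rng.random(n_genes) < fractions[0]
    for t in range(1, n_t):
        f_prev, f_now = fractions[t - 1], fractions[t]
        p_stay = persistence
        if f_prev > 0:
            # keep the target marginal attainable: f_now >= f_prev * p_stay
            p_stay = min(p_stay, f_now / f_prev) if f_now < f_prev * p_stay else p_stay
        p_new = 0.0
        if f_prev < 1.0:
            p_new = (f_now - f_prev * p_stay) / (1.0 - f_prev)
            p_new = float(np.clip(p_new, 0.0, 1.0))
        u = rng.random(n_genes)
        out[:, t] = np.where(out[:, t - 1], u < p_stay, u < p_new)
    return out


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], pd.DataFrame, list[TFBMRecord], list[TruthEntry]]:
    """Generate genes, a DE table, a TFBM library and the truth ledger.

    The DE table covers every gene at every cold time point and every other
    stress condition, with columns ``gene_id condition time log2FC adj_p``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    if n == 0:
        de = pd.DataFrame(columns=["gene_id", "condition", "time", "log2FC", "adj_p"])
        return [], de, _tfbm_library(config, rng), []

    up = _markov_membership(
        n, config.responsive_fraction_per_timepoint, config.persistence, rng
    )
    down = _markov_membership(n, config.down_fractions(), config.persistence, rng)
    down &= ~up  # a gene is never both up and down at one time point
    other = rng.random((n, len(config.other_conditions))) < config.other_condition_fraction

    genes = _generate_genes(config, gene_ids, up, rng)
    truth = _plant_motifs(config, genes, gene_ids, up, rng)
    _assign_go(config, genes, up, rng)
    de = _de_table(config, gene_ids, up, down, other, rng)
    library = _tfbm_library(config, rng)
    return genes, de, library, truth


def _generate_genes(config, gene_ids, up, rng) -> list[GeneRecord]:
    lo, hi = config.body_len_range
    genes = []
    for i, gid in enumerate(gene_ids):
        body_len = int(rng.integers(lo, hi + 1))
        genes.append(
            GeneRecord(
                gene_id=gid,
                upstream_seq=_random_seq(config.upstream_len, config.gc_content, rng),
                body_seq=_random_seq(body_len, config.gc_content, rng),
                downstream_seq=_random_seq(config.downstream_len, config.gc_content, rng),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return genes


def _plant_motifs(config, genes, gene_ids, up, rng) -> list[TruthEntry]:
    tp_index = {tp: j for j, tp in enumerate(config.time_points)}
    truth: list[TruthEntry] = []
    for motif in config.planted_motifs:
        pwm = motif.pwm()
        targets = [tp_index[t] for t in motif.target_time_points]
        is_signal = up[:, targets].any(axis=1) if targets else np.zeros(len(genes), bool)
        p = np.where(is_signal, motif.p_signal, motif.p_background)
        gets = rng.random(len(genes)) < p
        for i in np.flatnonzero(gets):
            g = genes[i]
            new_seq, offset, orientation, site = plant_instance(
                g.upstream_seq, pwm, rng
            )
            g.upstream_seq = new_seq
            truth.append(
                TruthEntry(
                    gene_id=gene_ids[i], motif=motif.label, region="upstream",
                    offset=offset, orientation=orientation, instance=site,
                )
            )
    return truth


def _assign_go(config, genes, up, rng) -> None:
    if config.n_go_terms <= 0:
        return
    terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    ever_up = up.any(axis=1)
    p_base = min(1.0, config.go_terms_per_gene / config.n_go_terms)
    for i, g in enumerate(genes):
        member = rng.random(config.n_go_terms) < p_base
        g.go_terms = {t for t, m in zip(terms, member) if m}
        # first term tracks responsiveness so GO enrichment has signal
        if ever_up[i] and rng.random() < 0.5:
            g.go_terms.add(terms[0])


def _de_table(config, gene_ids, up, down, other, rng) -> pd.DataFrame:
    mu, sd = config.effect_size
    rows = []
    for j, tp in enumerate(config.time_points):
        lfc = rng.normal(0.0, config.null_sd, size=len(gene_ids))
        adj_p = rng.uniform(0.2, 1.0, size=len(gene_ids))
        for arr, sign in ((up[:, j], 1.0), (down[:, j], -1.0)):
            idx = np.flatnonzero(arr)
            lfc[idx] = sign * rng.normal(mu, sd, size=len(idx))
            adj_p[idx] = rng.uniform(0.0, 0.05, size=len(idx))
        rows.append(
            pd.DataFrame(
                {"gene_id": gene_ids, "condition": COLD, "time": tp,
                 "log2FC": lfc, "adj_p": adj_p}
            )
        )
    for c, cond in enumerate(config.other_conditions):
        lfc = rng.normal(0.0, config.null_sd, size=len(gene_ids))
        adj_p = rng.uniform(0.2, 1.0, size=len(gene_ids))
        idx = np.flatnonzero(other[:, c])
        sign = np.where(rng.random(len(idx)) < 0.5, 1.0, -1.0)
        lfc[idx] = sign * rng.normal(mu, sd, size=len(idx))
        adj_p[idx] = rng.uniform(0.0, 0.05, size=len(idx))
        rows.append(
            pd.DataFrame(
                {"gene_id": gene_ids, "condition": cond, "time": "NA",
                 "log2FC": lfc, "adj_p": adj_p}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _jitter_pwm(pwm: PWM, amount: float, rng) -> PWM:
    m = pwm.matrix + rng.uniform(0, amount, size=pwm.matrix.shape)
    m = m / m.sum(axis=1, keepdims=True)
    return PWM(m)


def _tfbm_library(config, rng) -> list[TFBMRecord]:
    """Planted-motif PWMs (plus a jittered sibling per family) and decoys."""
    library: list[TFBMRecord] = []
    for i, motif in enumerate(config.planted_motifs):
        family = f"FAM_{motif.label}"
        base = motif.pwm()
        for s in range(max(1, config.tfbm_family_size)):
            pwm = base if s == 0 else _jitter_pwm(base, 0.25, rng)
            pwm = PWM(pwm.matrix, name=f"TF_{motif.label}_{s}")
            library.append(TFBMRecord(tf_name=f"TF_{motif.label}_{s}",
                                      family=family, pwm=pwm))
    for d in range(config.n_decoy_tfbms):
        width = int(rng.integers(6, 11))
        m = rng.dirichlet(np.full(4, 0.3), size=width)
        family = f"DECOYFAM_{d // max(1, config.tfbm_family_size)}"
        pwm = PWM(m, name=f"DECOY_{d}")
        library.append(TFBMRecord(tf_name=f"DECOY_{d}", family=family, pwm=pwm))
    return library


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str,
                                            "time": str}, keep_default_na=False,
                     na_values=[])
    required = {"gene_id", "condition", "time", "log2FC", "adj_p"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(
            f"incomplete-table: DE table missing column(s) {sorted(missing)}"
        )
    return de


def write_truth_ledger(truth: list[TruthEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmotif\tregion\toffset\torientation\tinstance\n")
        for t in truth:
            fh.write(
                f"{t.gene_id}\t{t.motif}\t{t.region}\t{t.offset}\t"
                f"{t.orientation}\t{t.instance}\n"
            )
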