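"""Position weight matrices and the MEME-minimal motif library format.

A PWM is stored as an ``(L, 4)`` array of per-position nucleotide
probabilities in A, C, G, T order.  Transcription-factor binding motifs
(TFBMs) carry a TF name and family label on top of the PWM, mirroring how
DAP-seq / CIS-BP style libraries annotate their matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# complement permutation of the A,C,G,T columns
_COMP = np.array([3, 2, 1, 0])


@dataclass
class PWM:
    """A position weight matrix: per-column probability vectors over ACGT."""

    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError("PWM matrix must have shape (L, 4) with L >= 1")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, _COMP].copy(), name=self.name)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one site from the column distributions."""
        return "".join(
            ALPHABET[rng.choice(4, p=col / col.sum())] for col in self.matrix
        )


@dataclass
class TFBMRecord:
    """A known TF binding motif with its family label."""

    tf_name: str
    family: str
    pwm: PWM
    source: str = "simulated"

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("TFBM family label must be non-empty")


def kmer_to_pwm(kmer: str, name: str | None = None) -> PWM:
    """One-hot PWM of a k-mer: probability 1 on the observed base."""
    kmer = kmer.upper()
    if any(b not in _BASE_INDEX for b in kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    m = np.zeros((len(kmer), 4))
    for i, b in enumerate(kmer):
        m[i, _BASE_INDEX[b]] = 1.0
    return PWM(m, name=name if name is not None else kmer)


def write_meme(motifs: list[TFBMRecord] | list[PWM], path_or_handle) -> None:
    """Write motifs in MEME minimal format (readable by Bio.motifs)."""
    if hasattr(path_or_handle, "write"):
        _write_meme_handle(motifs, path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write_meme_handle(motifs, fh)


def _write_meme_handle(motifs, fh) -> None:
    fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for rec in motifs:
        pwm = rec.pwm if isinstance(rec, TFBMRecord) else rec
        name = rec.tf_name if isinstance(rec, TFBMRecord) else pwm.name
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 1000000 E= 0\n"
        )
        for row in pwm.matrix:
            fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("\n")


def read_meme(path_or_handle) -> list[PWM]:
    """Parse a MEME minimal motif file via Biopython's minimal parser."""
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        records = bio_motifs.parse(path_or_handle, "minimal")
    else:
        with open(path_or_handle) as fh:
            records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        arr = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in ALPHABET])
        arr = arr / arr.sum(axis=1, keepdims=True)
        out.append(PWM(arr, name=m.name))
    return out


def write_family_map(records: list[TFBMRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf_name\tfamily\n")
        for r in records:
            fh.write(f"{r.pwm.name or r.tf_name}\t{r.tf_name}\t{r.family}\n")


def read_tfbm_library(meme_path, family_map_path, source: str = "simulated") -> list[TFBMRecord]:
    """Load a TFBM library from a MEME minimal file plus a family-map TSV."""
    import csv

    pwms = {p.name: p for p in read_meme(meme_path)}
    records = []
    with open(family_map_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pwm = pwms[row["motif_id"]]
            records.append(
                TFBMRecord(tf_name=row["tf_name"], family=row["family"], pwm=pwm,
                           source=source)
            )
    return records


def meme_text(motifs) -> str:
    buf = io.StringIO()
    write_meme(motifs, buf)
    return buf.getvalue()
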