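"""Per-time-point response labels, U/D/N temporal profiles, train/test split.

A gene is up-regulated at a time point when log2FC >= 1 and BH-adjusted
p <= 0.05 (down: log2FC <= -1), and non-responsive only when at EVERY cold
time point and in every other stress condition |log2FC| < 0.5 or adjusted
p > 0.05.  Genes in the intermediate zone at some time point are excluded
from modelling at that time point; non-responsive genes form one shared
negative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import COLD, InsufficientExamplesError


class IncompleteTableError(ValueError):
    """DE table missing a required (gene, condition, time) record."""


@dataclass
class ResponseLabelSet:
    time: str
    up_genes: set[str]
    down_genes: set[str]
    negatives: set[str]
    train_ids: dict[str, set[str]] = field(default_factory=dict)
    test_ids: dict[str, set[str]] = field(default_factory=dict)

    def positives(self, direction: str) -> set[str]:
        if direction == "up":
            return self.up_genes
        if direction == "down":
            return self.down_genes
        raise ValueError(f"direction must be up or down, got {direction!r}")


@dataclass
class ExpressionProfile:
    gene_id: str
    profile: str  # string over U/D/N, ordered by time


def _up_mask(df: pd.DataFrame, up_fc: float, alpha: float) -> pd.Series:
    return (df["log2FC"] >= up_fc) & (df["adj_p"] <= alpha)


def _down_mask(df: pd.DataFrame, down_fc: float, alpha: float) -> pd.Series:
    return (df["log2FC"] <= down_fc) & (df["adj_p"] <= alpha)


def label_genes(
    de: pd.DataFrame,
    up_fc: float = 1.0,
    down_fc: float = -1.0,
    alpha: float = 0.05,
    null_fc: float = 0.5,
    time_points: tuple[str, ...] | None = None,
) -> dict[str, ResponseLabelSet]:
    """Label genes per cold time point; negatives shared across time points.

    The non-responsive rule is OR within a condition (|log2FC| < null_fc
    or adj_p > alpha) and AND across all cold time points and other stress
    conditions.
    """
    cold = de[de["condition"] == COLD]
    if time_points is None:
        time_points = tuple(dict.fromkeys(cold["time"]))
    genes = sorted(de["gene_id"].unique())
    n_genes = len(genes)

    # completeness check for the cold time course
    counts = cold.groupby("time", sort=False)["gene_id"].nunique()
    for tp in time_points:
        if counts.get(tp, 0) < n_genes:
            raise IncompleteTableError(
                f"incomplete-table: missing cold records at time {tp}"
            )

    nonresp_each = (de["log2FC"].abs() < null_fc) | (de["adj_p"] > alpha)
    nonresp = nonresp_each.groupby(de["gene_id"]).all()
    negatives = set(nonresp.index[nonresp])

    out: dict[str, ResponseLabelSet] = {}
    for tp in time_points:
        sub = cold[cold["time"] == tp]
        up = set(sub.loc[_up_mask(sub, up_fc, alpha), "gene_id"])
        down = set(sub.loc[_down_mask(sub, down_fc, alpha), "gene_id"])
        out[tp] = ResponseLabelSet(
            time=tp, up_genes=up, down_genes=down,
            negatives=negatives - up - down,
        )
    if not negatives:
        raise InsufficientExamplesError("no-negative-examples")
    return out


def encode_profile(
    gene_de: pd.DataFrame,
    time_points: tuple[str, ...],
    up_fc: float = 1.0,
    down_fc: float = -1.0,
    alpha: float = 0.05,
) -> ExpressionProfile:
    """Encode one gene's cold time course as a U/D/N string ordered by time."""
    cold = gene_de[gene_de["condition"] == COLD].set_index("time")
    gene_ids = gene_de["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError("encode_profile expects records for exactly one gene")
    chars = []
    for tp in time_points:
        if tp not in cold.index:
            raise IncompleteTableError(f"incomplete-table: missing time {tp}")
        rec = cold.loc[tp]
        if rec["log2FC"] >= up_fc and rec["adj_p"] <= alpha:
            chars.append("U")
        elif rec["log2FC"] <= down_fc and rec["adj_p"] <= alpha:
            chars.append("D")
        else:
            chars.append("N")
    return ExpressionProfile(gene_id=str(gene_ids[0]), profile="".join(chars))


def encode_profiles(
    de: pd.DataFrame,
    time_points: tuple[str, ...],
    up_fc: float = 1.0,
    down_fc: float = -1.0,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Vectorised U/D/N profiles for every gene in the table."""
    cold = de[de["condition"] == COLD].copy()
    code = np.where(
        (cold["log2FC"] >= up_fc) & (cold["adj_p"] <= alpha), "U",
        np.where((cold["log2FC"] <= down_fc) & (cold["adj_p"] <= alpha), "D", "N"),
    )
    cold["code"] = code
    pivot = cold.pivot_table(index="gene_id", columns="time", values="code",
                             aggfunc="first")
    missing = [tp for tp in time_points if tp not in pivot.columns]
    if missing or pivot[list(time_points)].isna().any().any():
        raise IncompleteTableError("incomplete-table: missing cold time points")
    joined = pivot[list(time_points)].agg("".join, axis=1)
    return joined.to_dict()


def split_train_test(
    labels: ResponseLabelSet,
    direction: str = "up",
    fraction: float = 0.8,
    seed: int = 0,
    min_per_class: int = 5,
) -> ResponseLabelSet:
    """Stratified 80/20 split of positives and negatives for one time point.

    The test share is floored so small classes keep at least one training
    gene per later bin.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    pos = sorted(labels.positives(direction))
    neg = sorted(labels.negatives)
    for name, ids in (("positive", pos), ("negative", neg)):
        if len(ids) < min_per_class:
            raise InsufficientExamplesError(
                f"insufficient-examples: {name} class has {len(ids)} genes"
            )
    train: dict[str, set[str]] = {}
    test: dict[str, set[str]] = {}
    for cls, ids in (("positive", pos), ("negative", neg)):
        ids = np.array(ids)
        rng.shuffle(ids)
        n_test = len(ids) - int(np.floor(len(ids) * fraction + 1e-9))
        test[cls] = set(ids[:n_test])
        train[cls] = set(ids[n_test:])
    labels.train_ids = train
    labels.test_ids = test
    return labels
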