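"""Differential ranking of miRNAs between the two conditions.

The ranked list — rank 1 is the miRNA most up-regulated in condition 2
relative to condition 1 — is the sole input to the set-enrichment statistic.
The default score is the log2 fold change of condition means on the 2^-dCq
relative-expression scale (equivalently -ddCq); a signal-to-noise option is
offered for consistency with the GSEA lineage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr import ExpressionMatrix

logger = logging.getLogger(__name__)

METRICS = ("log2_fold_change", "signal_to_noise")


@dataclass
class RankedList:
    """miRNAs ordered by a differential score, descending."""

    names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != self.scores.size:
            raise ValueError("names and scores length mismatch")
        if len(self.names) < 2:
            raise ValueError("a ranked list needs at least 2 miRNAs")
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked names must be unique")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing with rank")

    @property
    def N(self) -> int:
        return len(self.names)

    def rank_of(self, name: str) -> int:
        """1-based rank of a miRNA."""
        return self.names.index(name) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mirna": self.names, "score": self.scores})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read(cls, path: str | Path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(names=df["mirna"].tolist(), scores=df["score"].to_numpy())


def _condition_stats(matrix: ExpressionMatrix, condition: str):
    cols = matrix.samples_of(condition)
    if not cols:
        raise ValueError(f"condition {condition!r} has zero samples")
    sub = matrix.values[cols]
    return sub.mean(axis=1, skipna=True), sub.std(axis=1, ddof=1, skipna=True)


def rank_differential(
    matrix: ExpressionMatrix, metric: str = "log2_fold_change"
) -> RankedList:
    """Rank miRNAs by differential expression, condition 2 over condition 1.

    Scores are computed on condition means over defined values; miRNAs with
    no defined value in either condition are dropped. Ties are broken
    lexicographically by name for determinism. A zero condition mean (which
    would give an infinite log ratio) is mapped to +/-(max finite |score| + 1)
    with a warning, keeping the list total and finite.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    cond1, cond2 = matrix.condition_order
    m1, s1 = _condition_stats(matrix, cond1)
    m2, s2 = _condition_stats(matrix, cond2)

    defined = m1.notna() & m2.notna()
    if (~defined).any():
        logger.info(
            "rank_differential: dropping %d miRNAs with no defined value in a condition",
            int((~defined).sum()),
        )
    m1, m2 = m1[defined], m2[defined]
    s1, s2 = s1[defined].fillna(0.0), s2[defined].fillna(0.0)

    if metric == "log2_fold_change":
        with np.errstate(divide="ignore"):
            raw = np.log2(m2.to_numpy() / m1.to_numpy())
    else:  # signal_to_noise
        denom = (s1 + s2).to_numpy()
        diff = (m2 - m1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(denom > 0, diff / denom, np.inf * np.sign(diff))
        raw = np.where(np.isnan(raw), 0.0, raw)  # zero diff, zero spread

    finite = np.isfinite(raw)
    if not finite.all():
        cap = float(np.abs(raw[finite]).max()) + 1.0 if finite.any() else 1.0
        warnings.warn(
            f"{int((~finite).sum())} miRNAs had a zero/degenerate condition mean; "
            f"scores capped at +/-{cap}",
            stacklevel=2,
        )
        raw = np.clip(raw, -cap, cap)

    df = pd.DataFrame({"mirna": m1.index, "score": raw})
    df = df.sort_values(["score", "mirna"], ascending=[False, True], kind="mergesort")
    return RankedList(names=df["mirna"].tolist(), scores=df["score"].to_numpy())
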