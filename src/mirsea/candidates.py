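"""Target-prediction consensus and final candidate annotation.

A miRNA counts as a predicted regulator of the target gene (WWOX in the
motivating contrast) when at least ``min_tools`` distinct prediction tools
list it. Candidate annotations join enriched-set membership (from the
filtered enrichment report) with that consensus; because set members are
hairpin-level names (hsa-mir-182) while prediction evidence is mature-level
(miR-182-5p), matching is done at base-name level by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentResult
from .set_collections import base_name, normalize_mirna_name

EVIDENCE_COLUMNS = ["mirna", "target_gene", "tool"]


def read_prediction_evidence(path: str | Path) -> pd.DataFrame:
    """Read (miRNA, target gene, tool) evidence triples from tabular text."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: evidence table lacks columns {missing}")
    if df.duplicated(EVIDENCE_COLUMNS).any():
        raise ValueError(f"{path}: duplicate (mirna, target_gene, tool) triples")
    return df[EVIDENCE_COLUMNS]


def consensus_targets(
    evidence: pd.DataFrame, gene: str, min_tools: int = 2
) -> dict[str, list[str]]:
    """miRNAs predicted to regulate ``gene`` by at least ``min_tools`` tools.

    Returns a mapping from normalized miRNA name (arm suffix preserved) to
    the sorted list of distinct supporting tools. Monotone in ``min_tools``:
    raising the threshold never adds a miRNA.
    """
    ev = evidence[evidence["target_gene"].str.upper() == gene.upper()].copy()
    ev["mirna"] = ev["mirna"].map(normalize_mirna_name)
    out: dict[str, list[str]] = {}
    for mirna, grp in ev.groupby("mirna"):
        tools = sorted(set(grp["tool"]))
        if len(tools) >= min_tools:
            out[mirna] = tools
    return out


@dataclass(frozen=True)
class CandidateAnnotation:
    """One selected miRNA: its enriched sets and target-prediction support."""

    mirna_name: str
    enriched_sets: tuple[str, ...]
    is_predicted_regulator: bool
    supporting_tools: tuple[str, ...]

    def __post_init__(self) -> None:
        if bool(self.supporting_tools) != self.is_predicted_regulator:
            raise ValueError("supporting_tools must be non-empty iff predicted regulator")


def annotate_candidates(
    retained_sets: Sequence[EnrichmentResult],
    consensus: Mapping[str, Sequence[str]],
    base_name_match: bool = True,
) -> list[CandidateAnnotation]:
    """Annotate every miRNA occurring in at least one retained enriched set.

    Each annotation lists all retained sets containing the miRNA and flags
    whether the consensus mapping predicts it (directly, or via its base
    name when ``base_name_match`` is on — the hairpin hsa-mir-182 matches
    mature evidence for miR-182-5p). Ordered by (predicted-regulator flag,
    number of enriched sets, name), flag and count descending.
    """
    membership: dict[str, list[str]] = {}
    for r in retained_sets:
        for m in sorted(r.members):
            membership.setdefault(m, []).append(r.set_name)

    cons_exact = {normalize_mirna_name(k): list(v) for k, v in consensus.items()}
    cons_base: dict[str, list[str]] = {}
    for k, tools in cons_exact.items():
        cons_base.setdefault(base_name(k), [])
        cons_base[base_name(k)] = sorted(set(cons_base[base_name(k)]) | set(tools))

    annotations = []
    for mirna, sets in membership.items():
        tools = cons_exact.get(mirna)
        if tools is None and base_name_match:
            tools = cons_base.get(base_name(mirna))
        annotations.append(
            CandidateAnnotation(
                mirna_name=mirna,
                enriched_sets=tuple(dict.fromkeys(sets)),
                is_predicted_regulator=tools is not None,
                supporting_tools=tuple(tools) if tools else (),
            )
        )
    annotations.sort(
        key=lambda a: (-int(a.is_predicted_regulator), -len(a.enriched_sets), a.mirna_name)
    )
    return annotations


def candidates_to_frame(annotations: Sequence[CandidateAnnotation]) -> pd.DataFrame:
    """Tabular candidate report (machine-readable Table-4-style records)."""
    return pd.DataFrame(
        {
            "mirna": [a.mirna_name for a in annotations],
            "enriched_sets": [", ".join(a.enriched_sets) for a in annotations],
            "predicted_regulator": [a.is_predicted_regulator for a in annotations],
            "supporting_tools": [", ".join(a.supporting_tools) for a in annotations],
        }
    )
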