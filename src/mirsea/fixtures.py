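"""Loaders for the packaged worked-example reference tables.

These bundle the published result tables of the motivating WWOX/TNBC
cisplatin-resistance contrast: the top enriched miRNA sets with their ES and
p-values, the manually selected functional sets, the WWOX target-prediction
evidence, and the final candidate annotations. They drive worked examples,
regression tests and the report filters; they are reference output, not
input the pipeline could recompute (the study's raw panel data are not
deposited).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .enrichment import EnrichmentResult
from .set_collections import MiRNASetCollection, normalize_mirna_name, read_gmt


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mirsea.data").joinpath(name)))


def load_enriched_sets_table() -> pd.DataFrame:
    """The six top enriched sets (ES, p, members) of the reference contrast."""
    return pd.read_csv(_data_path("table1_enriched_sets.tsv"), sep="\t", comment="#")


def load_functional_sets_table() -> pd.DataFrame:
    """The four manually selected functional sets (ES, p, members)."""
    return pd.read_csv(_data_path("table2_functional_sets.tsv"), sep="\t", comment="#")


def load_wwox_prediction_evidence() -> pd.DataFrame:
    """WWOX target-prediction evidence triples (miRNA, gene, tool)."""
    from .candidates import read_prediction_evidence

    return read_prediction_evidence(_data_path("table3_wwox_predictions.tsv"))


def load_candidate_reference() -> pd.DataFrame:
    """The published candidate miRNAs and their annotation strings."""
    return pd.read_csv(_data_path("table4_candidates.tsv"), sep="\t", comment="#")


def load_reference_collection() -> MiRNASetCollection:
    """All reference sets as a GMT-backed collection (category annotated)."""
    return read_gmt(_data_path("tables12_sets.gmt"))


def load_category_counts() -> pd.DataFrame:
    """Per-category enriched-set counts of the reference result space."""
    return pd.read_csv(_data_path("enriched_category_counts.tsv"), sep="\t", comment="#")


def _table_to_results(df: pd.DataFrame) -> list[EnrichmentResult]:
    results = []
    for row in df.itertuples(index=False):
        members = frozenset(normalize_mirna_name(m) for m in row.members.split(","))
        results.append(
            EnrichmentResult(
                set_name=row.set_name,
                category=row.category,
                es=float(row.es),
                nes=math.nan,
                p_nominal=float(row.p_value),
                fdr_q=math.nan,
                set_size=len(members),
                peak_rank=0,
                leading_members=(),
                members=members,
            )
        )
    return results


def enriched_sets_as_results() -> list[EnrichmentResult]:
    """Top enriched sets as EnrichmentResult records (NES/FDR undefined)."""
    return _table_to_results(load_enriched_sets_table())


def functional_sets_as_results() -> list[EnrichmentResult]:
    """Functional sets as EnrichmentResult records (NES/FDR undefined)."""
    return _table_to_results(load_functional_sets_table())
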