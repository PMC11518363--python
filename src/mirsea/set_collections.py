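"""miRNA set collections in the six-category scheme.

Sets are grouped into six categories — ``target`` (common target genes,
experimentally validated interactions), ``regulator`` (common upstream
transcription factors), ``cluster`` (adjacent genomic coordinates),
``family`` (common ancestral hairpin), ``tissue`` (tissue-restricted
expression, index of tissue specificity >= 0.7) and ``function`` (curated
functional/pathway groupings). Collections are consumed from GMT-style
tabular text; no live database access is performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CATEGORIES = ("target", "regulator", "cluster", "family", "tissue", "function")

_ARM_SUFFIX = re.compile(r"-(3p|5p)$")
_LETTER_SUFFIX = re.compile(r"(?<=\d)[a-z]+$")


def normalize_mirna_name(name: str) -> str:
    """Canonicalize a miRNA name to lowercase ``hsa-mir-*`` form.

    ``hsa-miR-182`` and ``miR-182`` both normalize to ``hsa-mir-182``; a
    ``hs-`` species prefix (a common typo) is corrected to ``hsa-``. Arm
    suffixes (``-3p``/``-5p``) are preserved.
    """
    n = name.strip().lower()
    if not n:
        raise ValueError("empty miRNA name")
    if n.startswith("hs-"):
        n = "hsa-" + n[3:]
    if not n.startswith(("hsa-", "mmu-", "rno-", "cel-")):
        n = "hsa-" + n
    return n


def base_name(name: str) -> str:
    """Strip the arm suffix (-3p/-5p) and trailing paralog letters.

    ``hsa-mir-182-5p`` -> ``hsa-mir-182``; ``hsa-mir-34c-5p`` -> ``hsa-mir-34``.
    Used for base-level matching between set members (hairpin names) and
    target-prediction evidence (mature names).
    """
    n = _ARM_SUFFIX.sub("", normalize_mirna_name(name))
    return _LETTER_SUFFIX.sub("", n)


@dataclass(frozen=True)
class MiRNASet:
    """A named miRNA set with its category and optional provenance."""

    name: str
    category: str
    members: frozenset[str]
    provenance: str = ""
    tissue_specificity_index: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"set {self.name!r}: category {self.category!r} not one of {CATEGORIES}"
            )
        if not self.members:
            raise ValueError(f"set {self.name!r}: members must be non-empty")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MiRNASetCollection:
    """An ordered list of miRNA sets; set names are unique within a category."""

    sets: list[MiRNASet] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.sets:
            key = (s.category, s.name)
            if key in seen:
                raise ValueError(f"duplicate set name {s.name!r} in category {s.category!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def by_category(self, category: str) -> list[MiRNASet]:
        return [s for s in self.sets if s.category == category]

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sets:
            out[s.category] = out.get(s.category, 0) + 1
        return out


def _parse_description(desc: str) -> tuple[str, float | None]:
    """Parse the GMT description field: ``category[;tsi=<value>]``."""
    parts = [p.strip() for p in desc.split(";") if p.strip()]
    if not parts:
        raise ValueError("empty description field")
    category = parts[0].lower()
    tsi = None
    for extra in parts[1:]:
        if extra.startswith("tsi="):
            tsi = float(extra[4:])
    return category, tsi


def read_gmt(path: str | Path) -> MiRNASetCollection:
    """Read a GMT-style collection: set name TAB description TAB members...

    The description field carries the category, optionally followed by
    ``;tsi=<index>`` for tissue sets. Member names are normalized to the
    canonical ``hsa-mir-*`` form. Malformed lines (fewer than three fields)
    are reported with their line numbers and skipped.
    """
    path = Path(path)
    text = path.read_text()
    sets: list[MiRNASet] = []
    malformed: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            malformed.append(lineno)
            continue
        name, desc = fields[0].strip(), fields[1]
        category, tsi = _parse_description(desc)
        members = frozenset(normalize_mirna_name(m) for m in fields[2:] if m.strip())
        if not members:
            malformed.append(lineno)
            continue
        sets.append(
            MiRNASet(
                name=name,
                category=category,
                members=members,
                provenance=str(path.name),
                tissue_specificity_index=tsi,
            )
        )
    if malformed:
        logger.warning("%s: skipped malformed GMT lines: %s", path, malformed)
    if not sets:
        raise ValueError(f"{path}: no miRNA sets parsed (empty or fully malformed file)")
    return MiRNASetCollection(sets)


def write_gmt(collection: MiRNASetCollection, path: str | Path) -> None:
    """Write a collection in the GMT dialect read by :func:`read_gmt`."""
    path = Path(path)
    lines = []
    for s in collection:
        desc = s.category
        if s.tissue_specificity_index is not None:
            desc += f";tsi={s.tissue_specificity_index:g}"
        lines.append("\t".join([s.name, desc, *sorted(s.members)]))
    path.write_text("\n".join(lines) + "\n")


def filter_tissue_sets(
    collection: MiRNASetCollection, min_index: float = 0.7
) -> MiRNASetCollection:
    """Drop tissue-category sets whose specificity index is below ``min_index``.

    The threshold is inclusive (an index of exactly 0.7 is retained). Sets in
    other categories pass through untouched. A tissue set without an index is
    a validation error.
    """
    kept: list[MiRNASet] = []
    for s in collection:
        if s.category != "tissue":
            kept.append(s)
            continue
        if s.tissue_specificity_index is None:
            raise ValueError(f"tissue set {s.name!r} lacks a tissue specificity index")
        if s.tissue_specificity_index >= min_index:
            kept.append(s)
    return MiRNASetCollection(kept)


def restrict_to_universe(
    collection: MiRNASetCollection,
    universe: Iterable[str] | Sequence[str],
    min_size: int = 2,
) -> MiRNASetCollection:
    """Intersect every set with the ranked universe; drop undersized sets.

    The running-sum statistic is only defined for sets with at least one
    member inside and one outside the ranked list, so enrichment always
    operates on universe-restricted sets. Sets smaller than ``min_size``
    after intersection are dropped and reported via logging.
    """
    uni = {normalize_mirna_name(m) for m in universe}
    kept: list[MiRNASet] = []
    dropped: list[tuple[str, int]] = []
    for s in collection:
        inter = s.members & uni
        if len(inter) < min_size:
            dropped.append((s.name, len(inter)))
            continue
        kept.append(replace(s, members=frozenset(inter)))
    if dropped:
        logger.info(
            "restrict_to_universe: dropped %d sets below min_size=%d: %s",
            len(dropped), min_size, dropped,
        )
    return MiRNASetCollection(kept)
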