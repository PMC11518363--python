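"""Running-sum miRNA set enrichment: ES, permutation NES, nominal p and FDR.

The enrichment score of a set is the signed maximum deviation from zero of a
Kolmogorov-Smirnov-style running sum walked down the ranked list: the sum
rises by 1/G at each of the G set members and falls by 1/(N-G) at each of
the N-G non-members, so it always terminates at zero and |ES| <= 1. The
increments are unweighted (classic enhance/reduce cumulative summation).

The null model permutes set labels: B uniformly random G-member subsets of
the ranked universe (exhaustive enumeration when C(N, G) is small). NES is
ES divided by the mean magnitude of same-sign null scores; the nominal p is
the add-one permutation estimator, so p >= 1/(B+1) and p is never zero. FDR
q-values follow the GSEA convention of comparing tail fractions of pooled
null NES against observed NES, computed within each category by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ranking import RankedList
from .set_collections import MiRNASetCollection

logger = logging.getLogger(__name__)

#: Switch to exhaustive subset enumeration when C(N, G) is at most this.
EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class EnrichmentScore:
    """ES with the 1-based rank of the running-sum peak and the full trace."""

    es: float
    peak_rank: int
    running_sum: np.ndarray


def enrichment_score(
    ranked: RankedList | Sequence[str], members: Iterable[str]
) -> EnrichmentScore:
    """Running-sum enrichment score of ``members`` along the ranked list.

    Requires 1 <= G < N after intersecting the members with the ranked
    universe. On an exact tie between the positive and negative extreme the
    positive peak wins; among equal values the earlier rank wins.
    """
    names = ranked.names if isinstance(ranked, RankedList) else list(ranked)
    member_set = set(members)
    hits = np.fromiter((n in member_set for n in names), dtype=bool, count=len(names))
    N = hits.size
    G = int(hits.sum())
    if G == 0 or G == N:
        raise ValueError(
            f"enrichment score undefined for G={G} of N={N} "
            "(need at least one member and one non-member in the universe)"
        )
    inc = np.where(hits, 1.0 / G, -1.0 / (N - G))
    running = np.cumsum(inc)
    pos, neg = float(running.max()), float(running.min())
    # positive peak preferred on a tie; the epsilon absorbs accumulation error
    if pos >= -neg - 1e-12:
        es, peak = pos, int(np.argmax(running)) + 1
    else:
        es, peak = neg, int(np.argmin(running)) + 1
    return EnrichmentScore(es=es, peak_rank=peak, running_sum=running)


def _es_from_positions(positions: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ES for batches of sorted 1-based hit positions.

    On each descending segment the running sum is extremal at its endpoints,
    so the signed maximum deviation is determined by the values just after
    each hit (i/G - (p_i - i)/(N-G)) and just before each hit (the same minus
    1/G), together with the terminal zero.
    """
    P = np.asarray(positions, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    G = P.shape[1]
    i = np.arange(1, G + 1, dtype=float)
    after = i / G - (P - i) / (N - G)
    before = after - 1.0 / G
    pos = np.maximum(after.max(axis=1), 0.0)
    neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos >= -neg - 1e-12, pos, neg)


def _sample_subsets(N: int, G: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B sorted G-subsets of {1..N} without replacement (vectorized rejection)."""
    draw = rng.integers(1, N + 1, size=(B, G))
    draw.sort(axis=1)
    bad = np.flatnonzero((np.diff(draw, axis=1) == 0).any(axis=1)) if G > 1 else np.array([], int)
    while bad.size:
        redraw = rng.integers(1, N + 1, size=(bad.size, G))
        redraw.sort(axis=1)
        draw[bad] = redraw
        bad = bad[(np.diff(draw[bad], axis=1) == 0).any(axis=1)]
    return draw


def permutation_null(
    ranked: RankedList | int,
    G: int,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: str = "auto",
) -> np.ndarray:
    """Null ES sample for random G-member sets from an N-miRNA universe.

    ``exhaustive='auto'`` enumerates every C(N, G) subset when that count is
    at most ``EXHAUSTIVE_LIMIT``, otherwise draws B Monte-Carlo subsets;
    'always'/'never' force the choice. Deterministic under a fixed seed.
    """
    N = ranked.N if isinstance(ranked, RankedList) else int(ranked)
    if not (1 <= G < N):
        raise ValueError(f"need 1 <= G < N (got G={G}, N={N})")
    if B < 1:
        raise ValueError("B must be >= 1")
    n_total = math.comb(N, G)
    do_exhaustive = {"auto": n_total <= EXHAUSTIVE_LIMIT, "always": True, "never": False}[
        exhaustive
    ]
    if do_exhaustive:
        pos = np.array(list(combinations(range(1, N + 1), G)), dtype=float)
        return _es_from_positions(pos, N)
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = _sample_subsets(N, G, B, rng)
    return _es_from_positions(pos, N)


def normalize_and_test(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """NES and nominal p of an observed ES against a permutation null.

    NES = ES / mean(|null ES| of the same sign); p is the add-one estimator
    over same-sign null scores, (1 + #{|null| >= |ES|}) / (1 + #same-sign).
    When no same-sign null scores exist the magnitudes of the full null
    sample are used, with a warning.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("null sample must be non-empty")
    if es == 0.0:
        return 0.0, 1.0
    same = null_es[null_es > 0] if es > 0 else null_es[null_es < 0]
    if same.size == 0:
        warnings.warn(
            "no same-sign null enrichment scores; falling back to |null ES|",
            stacklevel=2,
        )
        same = null_es
    mags = np.abs(same)
    nes = es / float(mags.mean())
    p = (1.0 + float((mags >= abs(es)).sum())) / (1.0 + same.size)
    return float(nes), float(min(p, 1.0))


def _null_nes(null_es: np.ndarray) -> np.ndarray:
    """Normalize a null ES sample into null NES (per sign class)."""
    out = np.zeros_like(null_es, dtype=float)
    pos = null_es > 0
    neg = null_es < 0
    if pos.any():
        out[pos] = null_es[pos] / null_es[pos].mean()
    if neg.any():
        out[neg] = null_es[neg] / np.abs(null_es[neg]).mean()
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set enrichment statistics plus the leading-edge members."""

    set_name: str
    category: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    set_size: int
    peak_rank: int
    leading_members: tuple[str, ...]
    members: frozenset[str] = frozenset()


def compute_fdr(
    results: Sequence[EnrichmentResult],
    null_samples: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """GSEA-style FDR q per set from pooled null NES, monotone-corrected.

    For each set, q is the ratio of the same-sign tail fraction of the pooled
    null NES at its NES to the same tail fraction among the observed NES,
    clipped to [0, 1]; within each sign class q is then made monotone
    non-decreasing in the nominal p.
    """
    if not results:
        return {}
    pooled = np.concatenate(
        [_null_nes(np.asarray(null_samples[r.set_name], float)) for r in results]
    )
    obs = np.array([r.nes for r in results])
    raw: dict[str, float] = {}
    for r in results:
        n = r.nes
        if n > 0:
            num = float((pooled >= n).sum()) / max(float((pooled > 0).sum()), 1.0)
            den = float((obs >= n).sum()) / max(float((obs > 0).sum()), 1.0)
        elif n < 0:
            num = float((pooled <= n).sum()) / max(float((pooled < 0).sum()), 1.0)
            den = float((obs <= n).sum()) / max(float((obs < 0).sum()), 1.0)
        else:
            raw[r.set_name] = 1.0
            continue
        raw[r.set_name] = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else 1.0

    # Monotone correction: within each sign class, q never decreases as the
    # nominal p grows.
    out = dict(raw)
    for sign in (1, -1):
        grp = [r for r in results if (r.nes > 0) == (sign > 0) and r.nes != 0]
        grp.sort(key=lambda r: (r.p_nominal, -abs(r.nes), r.set_name))
        running = 0.0
        for r in grp:
            running = max(running, raw[r.set_name])
            out[r.set_name] = running
    return out


@dataclass
class EnrichmentReport:
    """Category-grouped enrichment results with the thresholds applied.

    Within each category the results are ordered by descending |NES|
    (ties broken by set name).
    """

    results: list[EnrichmentResult]
    p_cut: float = 0.05
    abs_es_cut: float = 0.25
    permutations: int = 1000
    field_order = (
        "category", "set_name", "set_size", "es", "peak_rank",
        "nes", "p_nominal", "fdr_q", "leading_members",
    )

    def grouped(self) -> dict[str, list[EnrichmentResult]]:
        cats = sorted({r.category for r in self.results})
        return {
            c: sorted(
                (r for r in self.results if r.category == c),
                key=lambda r: (-abs(r.nes), r.set_name),
            )
            for c in cats
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, group in self.grouped().items():
            for r in group:
                rows.append(
                    {
                        "category": cat,
                        "set_name": r.set_name,
                        "set_size": r.set_size,
                        "es": r.es,
                        "peak_rank": r.peak_rank,
                        "nes": r.nes,
                        "p_nominal": r.p_nominal,
                        "fdr_q": r.fdr_q,
                        "leading_members": ",".join(r.leading_members),
                    }
                )
        return pd.DataFrame(rows, columns=list(self.field_order))

    def significance_table(self) -> pd.DataFrame:
        """Per-set NES vs nominal p and FDR: the significance-plot data."""
        df = self.to_frame()
        return df[["category", "set_name", "nes", "p_nominal", "fdr_q"]]

    def es_rank_table(self) -> pd.DataFrame:
        """Per-set ES vs within-category rank, positive to negative ES."""
        rows = []
        for cat in sorted({r.category for r in self.results}):
            group = sorted(
                (r for r in self.results if r.category == cat),
                key=lambda r: (-r.es, r.set_name),
            )
            for rank, r in enumerate(group, start=1):
                rows.append(
                    {"category": cat, "set_name": r.set_name, "es": r.es,
                     "rank_in_category": rank}
                )
        return pd.DataFrame(rows, columns=["category", "set_name", "es", "rank_in_category"])


def enrich_collection(
    ranked: RankedList,
    collection: MiRNASetCollection,
    B: int = 1000,
    seed: int = 0,
    p_cut: float = 0.05,
    abs_es_cut: float = 0.25,
    fdr_scope: str = "category",
) -> EnrichmentReport:
    """Score every set in the collection against one ranked list.

    Sets whose universe-restricted size is 0 or N are skipped with a log
    message (the statistic is undefined there). Null ES samples are shared
    across sets of equal size G — the null depends only on G — and FDR is
    computed within each category (``fdr_scope='global'`` pools everything).
    """
    if fdr_scope not in ("category", "global"):
        raise ValueError("fdr_scope must be 'category' or 'global'")
    rng = np.random.default_rng(seed)
    universe = set(ranked.names)
    null_cache: dict[int, np.ndarray] = {}
    partial: list[tuple[EnrichmentResult, np.ndarray]] = []
    for s in collection:
        members = s.members & universe
        G = len(members)
        if G == 0 or G == ranked.N:
            logger.info("skipping set %r: undefined statistic (G=%d)", s.name, G)
            continue
        score = enrichment_score(ranked, members)
        if G not in null_cache:
            null_cache[G] = permutation_null(ranked, G, B=B, rng=rng)
        nes, p = normalize_and_test(score.es, null_cache[G])
        if score.es >= 0:
            leading = tuple(n for n in ranked.names[: score.peak_rank] if n in members)
        else:
            leading = tuple(n for n in ranked.names[score.peak_rank - 1 :] if n in members)
        partial.append(
            (
                EnrichmentResult(
                    set_name=s.name,
                    category=s.category,
                    es=score.es,
                    nes=nes,
                    p_nominal=p,
                    fdr_q=math.nan,
                    set_size=G,
                    peak_rank=score.peak_rank,
                    leading_members=leading,
                    members=frozenset(members),
                ),
                null_cache[G],
            )
        )

    results: list[EnrichmentResult] = []
    groups: dict[str, list[tuple[EnrichmentResult, np.ndarray]]] = {}
    for r, null in partial:
        key = r.category if fdr_scope == "category" else "all"
        groups.setdefault(key, []).append((r, null))
    for group in groups.values():
        rs = [r for r, _ in group]
        qs = compute_fdr(rs, {r.set_name: null for r, null in group})
        for r, _ in group:
            results.append(replace(r, fdr_q=qs[r.set_name]))
    return EnrichmentReport(
        results=results, p_cut=p_cut, abs_es_cut=abs_es_cut, permutations=B
    )


@dataclass
class ReportFilters:
    """Outcome of the two report filters.

    ``significant``: sets passing the nominal-p threshold (p <= p_cut).
    ``es_retained``: sets passing the |ES| threshold (inclusive, so an ES of
    exactly -0.25 survives an abs_es_cut of 0.25).
    ``retained``: their union, the basis for candidate annotation.
    """

    significant: list[EnrichmentResult] = field(default_factory=list)
    es_retained: list[EnrichmentResult] = field(default_factory=list)

    @property
    def retained(self) -> list[EnrichmentResult]:
        seen: set[tuple[str, str]] = set()
        out = []
        for r in [*self.significant, *self.es_retained]:
            key = (r.category, r.set_name)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return out


def apply_report_filters(
    report: EnrichmentReport | Sequence[EnrichmentResult],
    p_cut: float = 0.05,
    abs_es_cut: float = 0.25,
) -> ReportFilters:
    """Apply the significance (p <= p_cut) and |ES| >= abs_es_cut filters."""
    results = report.results if isinstance(report, EnrichmentReport) else list(report)
    return ReportFilters(
        significant=[r for r in results if r.p_nominal <= p_cut],
        es_retained=[r for r in results if abs(r.es) >= abs_es_cut],
    )
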