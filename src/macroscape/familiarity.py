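"""Synonym-count familiarity scoring.

The number of database synonyms a compound has accumulated is used as a
proxy for how widely it is recognized (trade names, trivial names, vendor
aliases all add synonyms). Compounds at or above a fixed threshold —
five by default, where the sorted synonym-count curve turns upward — are
flagged as well-known. An elbow detector on the sorted curve is provided
as an advisory alternative to the fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

import pandas as pd

DEFAULT_THRESHOLD = 5


@dataclass(frozen=True)
class SynonymRecord:
    inchi_key: str
    query_id: str
    synonym_count: Optional[int]
    is_well_known: Optional[bool] = None


class SynonymBackend(Protocol):
    def lookup(self, query_id: str) -> Optional[int]:
        """Synonym count for one compound id, or None when unknown."""


class TableBackend:
    """Synonym counts from a CSV table (columns query_id, synonym_count)."""

    def __init__(self, source: str | Path | Mapping[str, int]):
        if isinstance(source, Mapping):
            self._table = dict(source)
        else:
            df = pd.read_csv(source)
            if not {"query_id", "synonym_count"} <= set(df.columns):
                raise ValueError(
                    f"synonym table needs query_id/synonym_count columns, got {list(df.columns)}"
                )
            self._table = {
                str(r.query_id): int(r.synonym_count) for r in df.itertuples()
            }

    def lookup(self, query_id: str) -> Optional[int]:
        return self._table.get(query_id)


class PubChemBackend:
    """Live PubChem synonym lookup (requires pubchempy)."""

    def __init__(self):  # pragma: no cover - needs the client package
        try:
            import pubchempy  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "pubchempy is required for live synonym lookup; use a TableBackend offline"
            ) from exc
        self._pcp = pubchempy

    def lookup(self, query_id: str) -> Optional[int]:  # pragma: no cover
        hits = self._pcp.get_synonyms(query_id, "name")
        if not hits:
            return None
        return len(hits[0].get("Synonym", []))


def count_synonyms(
    compounds: Sequence[tuple[str, str]],
    backend: SynonymBackend,
    retries: int = 2,
) -> list[SynonymRecord]:
    """One record per unique structure; failures recorded as absent, not zero.

    ``compounds`` is a sequence of (inchi_key, query_id). Duplicate
    structures share a single lookup.
    """
    cache: dict[str, Optional[int]] = {}
    records: list[SynonymRecord] = []
    seen: set[str] = set()
    hard_failures: list[str] = []
    for inchi_key, query_id in compounds:
        if inchi_key in seen:
            continue
        seen.add(inchi_key)
        if query_id not in cache:
            count = None
            for attempt in range(retries + 1):
                try:
                    count = backend.lookup(query_id)
                    break
                except Exception:
                    if attempt == retries:
                        hard_failures.append(query_id)
            cache[query_id] = count
        records.append(
            SynonymRecord(
                inchi_key=inchi_key, query_id=query_id, synonym_count=cache[query_id]
            )
        )
    if hard_failures:
        raise RuntimeError(f"synonym backend failed for: {', '.join(hard_failures)}")
    return records


def classify_familiarity(
    records: Sequence[SynonymRecord],
    threshold: int = DEFAULT_THRESHOLD,
    inclusive: bool = True,
) -> list[SynonymRecord]:
    """Flag records at/above the threshold as well-known (boundary inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = []
    for r in records:
        if r.synonym_count is None:
            out.append(replace(r, is_well_known=None))
        elif inclusive:
            out.append(replace(r, is_well_known=r.synonym_count >= threshold))
        else:
            out.append(replace(r, is_well_known=r.synonym_count > threshold))
    return out


@dataclass
class ElbowCurve:
    ranks: list[int]
    counts: list[int]
    suggested_threshold: Optional[int]  # count at the sharpest upturn, or None
    flat: bool


def elbow_curve(records: Sequence[SynonymRecord]) -> ElbowCurve:
    """Sorted (rank, count) series with a discrete-second-difference knee.

    The suggestion is advisory only: the default classification threshold
    stays at five regardless. A flat series yields no suggestion.
    """
    counts = sorted(
        r.synonym_count for r in records if r.synonym_count is not None
    )
    if len(counts) < 2:
        raise ValueError("need at least 2 records with counts")
    ranks = list(range(1, len(counts) + 1))
    if counts[0] == counts[-1]:
        return ElbowCurve(ranks=ranks, counts=counts, suggested_threshold=None, flat=True)
    best_idx, best_d2 = None, 0
    for i in range(1, len(counts) - 1):
        d2 = counts[i + 1] - 2 * counts[i] + counts[i - 1]
        if d2 > best_d2:
            best_d2, best_idx = d2, i
    suggested = counts[best_idx] if best_idx is not None else None
    return ElbowCurve(ranks=ranks, counts=counts, suggested_threshold=suggested, flat=False)
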