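"""Bioactivity curation cascade: raw records to curated compound-target pairs.

The cascade applies, in a fixed and recorded order:

1. macrocycle filter (keep records whose compound has a 9-30 ring),
2. unit filter (keep plain nanomolar values; no unit conversion),
3. relation filter (drop interval records marked ``>`` or ``<``),
4. deduplication on (structure, target, type, value),
5. unique-structure count (a stage metric, not a filter),
6. optional one-ring restriction (exactly one macro-ring),
7. activity threshold (drop values strictly above 10 uM),
8. pChEMBL standardization: p = 9 - log10(value in nM).

Stage counts and derived percentage ratios are collected in a
:class:`CascadeReport`; percentages are printed to one decimal,
round-half-up, so that reported ratios are reproducible from the counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

from .chem_core import MacrocycleProfile, macro_profile
from .ingest import ActivityRecord, TargetEntry

DEFAULT_ACTIVE_THRESHOLD_NM = 10_000.0  # 10 uM

#: Canonical stage names in application order.
STAGE_ORDER = [
    "retrieved",
    "macrocycle",
    "units_nM",
    "relation",
    "dedup",
    "one_ring",
    "activity_threshold",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CascadeConfig:
    active_threshold_nM: float = DEFAULT_ACTIVE_THRESHOLD_NM
    one_ring_only: bool = True
    threshold_inclusive: bool = True  # keep values == threshold ("above" is strict)
    min_ring: int = 9
    max_ring: int = 30

    def __post_init__(self) -> None:
        if self.active_threshold_nM <= 0:
            raise ConfigurationError("active_threshold_nM must be positive")


@dataclass(frozen=True)
class CuratedPair:
    """A deduplicated compound-target activity with standardized potency."""

    inchi_key: str
    smiles: str
    target: TargetEntry
    standard_type: str
    value_nM: float
    pchembl: float
    active: bool
    source_record_ids: tuple[str, ...]
    profile: Optional[MacrocycleProfile] = None


@dataclass
class CascadeReport:
    """Stage-by-stage record counts plus derived ratios (a Table-style twin)."""

    n_retrieved: int = 0
    n_macrocycle_points: int = 0
    n_unique_structures: int = 0
    n_unique_pairs: int = 0
    n_one_ring_pairs: int = 0
    n_below_threshold: int = 0
    n_ic50_pairs: int = 0
    n_unparsable: int = 0
    per_type_tally: dict[str, int] = field(default_factory=dict)
    derived_ratios: dict[str, float] = field(default_factory=dict)
    stage_order: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    db_version: str = "unknown"
    label: str = ""

    def compute_ratios(self) -> dict[str, float]:
        """(Re)compute the derived percentage ratios from the stored counts."""
        self.derived_ratios = {
            "macrocycle_share_of_retrieved": pct(
                self.n_macrocycle_points, self.n_retrieved
            ),
            "unique_structure_share": pct(
                self.n_unique_structures, self.n_macrocycle_points
            ),
            "one_ring_share": pct(self.n_one_ring_pairs, self.n_macrocycle_points),
            "ic50_share": pct(self.n_ic50_pairs, self.n_macrocycle_points),
        }
        return self.derived_ratios

    @classmethod
    def from_counts(
        cls,
        n_retrieved: int,
        n_macrocycle_points: int,
        n_unique_structures: int,
        n_unique_pairs: int,
        n_one_ring_pairs: int,
        n_below_threshold: int,
        n_ic50_pairs: int,
        label: str = "",
        db_version: str = "unknown",
    ) -> "CascadeReport":
        """Build a report from pre-counted stage totals (e.g. a printed table row)."""
        report = cls(
            n_retrieved=n_retrieved,
            n_macrocycle_points=n_macrocycle_points,
            n_unique_structures=n_unique_structures,
            n_unique_pairs=n_unique_pairs,
            n_one_ring_pairs=n_one_ring_pairs,
            n_below_threshold=n_below_threshold,
            n_ic50_pairs=n_ic50_pairs,
            label=label,
            db_version=db_version,
        )
        report.compute_ratios()
        return report


def pct(numerator: float, denominator: float, places: int = 1) -> float:
    """Percentage to ``places`` decimals, round-half-up; 0 when denominator is 0."""
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) * 100 / Decimal(denominator)
    step = Decimal(1).scaleb(-places)
    return float(q.quantize(step, rounding=ROUND_HALF_UP))


def to_pchembl(value_nM: float) -> float:
    """Standardized potency: -log10 of the molar value, i.e. 9 - log10(nM)."""
    if value_nM <= 0:
        raise ValueError(f"value_nM must be positive, got {value_nM}")
    return 9.0 - math.log10(value_nM)


def profile_records(
    records: Sequence[ActivityRecord],
    min_ring: int = 9,
    max_ring: int = 30,
) -> dict[str, MacrocycleProfile]:
    """Macro-ring profiles keyed by InChIKey; unparsable compounds skipped."""
    profiles: dict[str, MacrocycleProfile] = {}
    for rec in records:
        if rec.compound.parse_ok and rec.compound.inchi_key not in profiles:
            profiles[rec.compound.inchi_key] = macro_profile(
                rec.compound, min_size=min_ring, max_size=max_ring
            )
    return profiles


def filter_macrocycles(
    records: Sequence[ActivityRecord],
    profiles: Mapping[str, MacrocycleProfile],
) -> list[ActivityRecord]:
    """Keep records whose compound carries at least one macro-ring."""
    return [
        r
        for r in records
        if r.compound.parse_ok
        and profiles[r.compound.inchi_key].is_macrocycle
    ]


def filter_units_nM(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Keep plain nanomolar records with a value; no unit conversion is done."""
    return [
        r
        for r in records
        if r.standard_units == "nM" and r.standard_value is not None
    ]


def filter_relations(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Drop interval records: any relation containing ``>`` or ``<``."""
    return [
        r
        for r in records
        if not (r.standard_relation and (">" in r.standard_relation or "<" in r.standard_relation))
    ]


def _dedup_key(r: ActivityRecord) -> tuple:
    return (
        r.compound.inchi_key,
        r.target.uniprot_id,
        r.standard_type,
        r.standard_value,
    )


def deduplicate(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse records sharing (structure, target, type, value).

    The survivor is the record with the lexicographically smallest
    (document_id, assay_id), a stable tie-break; merged source ids are
    tracked separately by the cascade. Records differing in type or in
    value are never merged (mixed IC50/Ki duplicates survive side by side).
    """
    groups: dict[tuple, list[ActivityRecord]] = {}
    order: list[tuple] = []
    for r in records:
        key = _dedup_key(r)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    return [
        min(groups[key], key=lambda r: (r.document_id, r.assay_id)) for key in order
    ]


def duplicate_sources(records: Sequence[ActivityRecord]) -> dict[tuple, list[str]]:
    """Source record ids per dedup group (compound_id:assay:document triples)."""
    out: dict[tuple, list[str]] = {}
    for r in records:
        out.setdefault(_dedup_key(r), []).append(
            f"{r.compound_id}:{r.document_id}:{r.assay_id}"
        )
    return out


def mixed_type_duplicates(records: Sequence[ActivityRecord]) -> list[tuple]:
    """Compound-target groups measured under more than one standard type.

    The automated cascade keeps these side by side; the list supports the
    manual review pass needed before any per-compound aggregation.
    """
    types: dict[tuple, set[str]] = {}
    for r in records:
        types.setdefault((r.compound.inchi_key, r.target.uniprot_id), set()).add(
            r.standard_type
        )
    return sorted(k for k, v in types.items() if len(v) > 1)


def filter_one_ring(
    records: Sequence[ActivityRecord],
    profiles: Mapping[str, MacrocycleProfile],
) -> list[ActivityRecord]:
    """Keep records whose compound has exactly one macro-ring."""
    return [r for r in records if profiles[r.compound.inchi_key].macro_ring_count == 1]


def filter_activity(
    records: Sequence[ActivityRecord],
    active_threshold_nM: float = DEFAULT_ACTIVE_THRESHOLD_NM,
    inclusive: bool = True,
) -> list[ActivityRecord]:
    """Drop records with value above the threshold.

    "Above" is strict by default: a value exactly at 10,000 nM is kept.
    """
    if active_threshold_nM <= 0:
        raise ConfigurationError("active_threshold_nM must be positive")
    if inclusive:
        return [r for r in records if r.standard_value <= active_threshold_nM]
    return [r for r in records if r.standard_value < active_threshold_nM]


def tally_types(pairs: Sequence) -> dict[str, int]:
    """Count entries per standard_type; counts sum to the input size."""
    tally: dict[str, int] = {}
    for p in pairs:
        tally[p.standard_type] = tally.get(p.standard_type, 0) + 1
    return tally


def run_cascade(
    records: Sequence[ActivityRecord],
    profiles: Optional[Mapping[str, MacrocycleProfile]] = None,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[CuratedPair], CascadeReport]:
    """Run the full filter cascade and assemble the stage report.

    ``profiles`` may be precomputed; otherwise they are derived here with
    the config's ring window. Any stage failure is re-raised with the
    stage name attached.
    """
    if profiles is None:
        profiles = profile_records(records, config.min_ring, config.max_ring)

    report = CascadeReport()
    report.n_retrieved = len(records)
    report.n_unparsable = sum(1 for r in records if not r.compound.parse_ok)

    stage = "macrocycle"
    try:
        macro = filter_macrocycles(records, profiles)
        report.n_macrocycle_points = len(macro)

        stage = "units_nM"
        nm = filter_units_nM(macro)

        stage = "relation"
        eq = filter_relations(nm)

        stage = "dedup"
        sources = duplicate_sources(eq)
        deduped = deduplicate(eq)
        report.n_unique_pairs = len(deduped)
        report.n_unique_structures = len({r.compound.inchi_key for r in deduped})

        stage = "one_ring"
        one_ring = filter_one_ring(deduped, profiles)
        report.n_one_ring_pairs = len(one_ring)
        selected = one_ring if config.one_ring_only else deduped

        stage = "activity_threshold"
        kept = filter_activity(
            selected, config.active_threshold_nM, inclusive=config.threshold_inclusive
        )
        report.n_below_threshold = len(kept)

        stage = "pchembl"
        pairs = [
            CuratedPair(
                inchi_key=r.compound.inchi_key,
                smiles=r.compound.raw_smiles,
                target=r.target,
                standard_type=r.standard_type,
                value_nM=r.standard_value,
                pchembl=to_pchembl(r.standard_value),
                active=r.standard_value <= config.active_threshold_nM,
                source_record_ids=tuple(sources.get(_dedup_key(r), [])),
                profile=profiles[r.compound.inchi_key],
            )
            for r in kept
        ]
    except Exception as exc:
        raise RuntimeError(f"cascade stage {stage!r} failed: {exc}") from exc

    report.per_type_tally = tally_types(pairs)
    report.n_ic50_pairs = report.per_type_tally.get("IC50", 0)
    report.compute_ratios()
    return pairs, report
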