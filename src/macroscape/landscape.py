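"""Aggregate landscape tables and cohort comparisons.

Turns curated pairs plus macro-ring profiles into the summary tables a
target-class landscape study reports: distinct ring scaffolds per target,
targets reached per ring size, peptide-like breakdowns, side-by-side
cascade comparisons between two target classes, and the joined map export
consumed by plotting front-ends. All percentages are printed to one
decimal, round-half-up, and are recomputable from the integer cells of
the same table.
"""

from __future__ import annotations

import json
from pathlib import Path
from statistics import median
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cascade import CascadeReport, CuratedPair, pct
from .chem_core import MacrocycleProfile
from .tsne import ProjectedPoint


def _profile_for(pair: CuratedPair, profiles: Optional[Mapping[str, MacrocycleProfile]]) -> MacrocycleProfile:
    if pair.profile is not None:
        return pair.profile
    if profiles is None or pair.inchi_key not in profiles:
        raise KeyError(f"no profile for {pair.inchi_key}")
    return profiles[pair.inchi_key]


def scaffolds_per_target(
    pairs: Sequence[CuratedPair],
    profiles: Optional[Mapping[str, MacrocycleProfile]] = None,
) -> pd.DataFrame:
    """Distinct ring-size signatures per target (set semantics) plus a global row.

    A signature is counted once per target however many records carry it.
    The global distinct-signature count appears as target_id ``__all__``.
    """
    sigs: dict[str, set[str]] = {}
    all_sigs: set[str] = set()
    for pair in pairs:
        sig = _profile_for(pair, profiles).scaffold_signature
        sigs.setdefault(pair.target.uniprot_id, set()).add(sig)
        all_sigs.add(sig)
    rows = [
        {"target_id": t, "n_scaffolds": len(s), "scaffolds": "|".join(sorted(s))}
        for t, s in sorted(sigs.items())
    ]
    rows.append(
        {"target_id": "__all__", "n_scaffolds": len(all_sigs), "scaffolds": "|".join(sorted(all_sigs))}
    )
    return pd.DataFrame(rows, columns=["target_id", "n_scaffolds", "scaffolds"])


def targets_per_ring_size(
    pairs: Sequence[CuratedPair],
    profiles: Optional[Mapping[str, MacrocycleProfile]] = None,
    min_size: int = 9,
    max_size: int = 30,
) -> pd.DataFrame:
    """For each ring size, the number and share of targets reached.

    A target counts once per size when at least one of its compounds
    carries a ring of that size; the denominator is the number of
    distinct targets among the pairs.
    """
    targets_by_size: dict[int, set[str]] = {s: set() for s in range(min_size, max_size + 1)}
    all_targets: set[str] = set()
    for pair in pairs:
        profile = _profile_for(pair, profiles)
        all_targets.add(pair.target.uniprot_id)
        for size in set(profile.macro_ring_sizes):
            if min_size <= size <= max_size:
                targets_by_size[size].add(pair.target.uniprot_id)
    n_total = len(all_targets)
    rows = [
        {
            "ring_size": size,
            "n_targets": len(ts),
            "pct_targets": pct(len(ts), n_total) if n_total else 0.0,
        }
        for size, ts in sorted(targets_by_size.items())
    ]
    return pd.DataFrame(rows, columns=["ring_size", "n_targets", "pct_targets"])


def compare_cohorts(
    report_a: CascadeReport,
    report_b: CascadeReport,
    allow_version_mismatch: bool = False,
) -> pd.DataFrame:
    """Side-by-side stage counts and derived ratios for two target classes.

    Refuses to compare cascades taken from different database versions
    unless explicitly overridden; symmetric up to column order.
    """
    if (
        report_a.db_version != report_b.db_version
        and not allow_version_mismatch
        and "unknown" not in (report_a.db_version, report_b.db_version)
    ):
        raise ValueError(
            f"database version mismatch: {report_a.db_version} vs {report_b.db_version} "
            "(pass allow_version_mismatch=True to override)"
        )
    name_a = report_a.label or "cohort_a"
    name_b = report_b.label or "cohort_b"
    rows = []
    count_fields = [
        ("retrieved", "n_retrieved"),
        ("macrocycle_points", "n_macrocycle_points"),
        ("unique_structures", "n_unique_structures"),
        ("unique_pairs", "n_unique_pairs"),
        ("one_ring_pairs", "n_one_ring_pairs"),
        ("below_threshold", "n_below_threshold"),
        ("ic50_pairs", "n_ic50_pairs"),
    ]
    for label, attr in count_fields:
        rows.append({"quantity": label, name_a: getattr(report_a, attr), name_b: getattr(report_b, attr)})
    for report in (report_a, report_b):
        if not report.derived_ratios:
            report.compute_ratios()
    for ratio in report_a.derived_ratios:
        rows.append(
            {
                "quantity": f"{ratio}_pct",
                name_a: report_a.derived_ratios[ratio],
                name_b: report_b.derived_ratios.get(ratio),
            }
        )
    fold = (
        round(report_b.n_macrocycle_points / report_a.n_macrocycle_points, 1)
        if report_a.n_macrocycle_points
        else None
    )
    rows.append({"quantity": "macrocycle_points_fold_b_over_a", name_a: 1.0, name_b: fold})
    return pd.DataFrame(rows, columns=["quantity", name_a, name_b])


def peptide_breakdown(
    pairs: Sequence[CuratedPair],
    profiles: Optional[Mapping[str, MacrocycleProfile]] = None,
) -> dict:
    """Peptide-like vs other pairs, split by family and macro-ring-count class.

    Ring-count classes are 1, 2, 3 and "4+" (multi-ring macrocycles above
    three rings are rare and pooled). Class totals sum to the pair total.
    """
    n_total = len(pairs)
    n_peptide = 0
    by_family: dict[str, dict[str, int]] = {}
    by_ring_class: dict[str, dict[str, int]] = {}
    for pair in pairs:
        profile = _profile_for(pair, profiles)
        family = pair.target.family_code or "other"
        ring_class = str(profile.macro_ring_count) if profile.macro_ring_count < 4 else "4+"
        kind = "peptide_like" if profile.is_peptide_like else "other"
        if profile.is_peptide_like:
            n_peptide += 1
        by_family.setdefault(family, {"peptide_like": 0, "other": 0})[kind] += 1
        by_ring_class.setdefault(ring_class, {"peptide_like": 0, "other": 0})[kind] += 1
    return {
        "n_pairs": n_total,
        "n_peptide_like": n_peptide,
        "pct_peptide_like": pct(n_peptide, n_total) if n_total else 0.0,
        "by_family": dict(sorted(by_family.items())),
        "by_ring_class": dict(sorted(by_ring_class.items())),
    }


def aggregate_pchembl(pairs: Sequence[CuratedPair]) -> dict[tuple[str, str], float]:
    """Median pChEMBL per (structure, family): the map's activity annotation."""
    values: dict[tuple[str, str], list[float]] = {}
    for pair in pairs:
        key = (pair.inchi_key, pair.target.family_code or "other")
        values.setdefault(key, []).append(pair.pchembl)
    return {k: median(v) for k, v in values.items()}


MAP_COLUMNS = ["inchi_key", "family", "x", "y", "smiles", "aggregated_pchembl"]


def export_map(
    points: Sequence[ProjectedPoint],
    pairs: Sequence[CuratedPair],
    out_path: str | Path,
    fmt: str = "csv",
) -> pd.DataFrame:
    """Join projections onto curated pairs: one row per compound-family combo.

    A compound active on two families appears twice with the same
    coordinates. Rows are sorted (inchi_key, family) so re-export is
    byte-identical; pairs lacking a projection go to a ``.skipped.json``
    sidecar instead of failing the export.
    """
    out_path = Path(out_path)
    coords: dict[str, tuple[float, float]] = {p.inchi_key: (p.x, p.y) for p in points}
    agg = aggregate_pchembl(pairs)
    smiles_by_key = {p.inchi_key: p.smiles for p in pairs}
    rows = []
    skipped = []
    for (key, family), pch in sorted(agg.items()):
        if key not in coords:
            skipped.append({"inchi_key": key, "family": family})
            continue
        x, y = coords[key]
        rows.append(
            {
                "inchi_key": key,
                "family": family,
                "x": x,
                "y": y,
                "smiles": smiles_by_key[key],
                "aggregated_pchembl": round(pch, 4),
            }
        )
    df = pd.DataFrame(rows, columns=MAP_COLUMNS)
    if fmt == "csv":
        df.to_csv(out_path, index=False)
    elif fmt == "json":
        out_path.write_text(json.dumps(rows, indent=2))
    else:
        raise ValueError(f"unknown export format: {fmt}")
    if skipped:
        out_path.with_suffix(".skipped.json").write_text(json.dumps(skipped, indent=2))
    return df
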