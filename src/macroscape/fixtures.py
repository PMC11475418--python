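"""Deterministic synthetic fixtures with planted, known ground truth.

Every generator is a pure function of its arguments (including the seed),
so tests can assert exact, analytically forced outcomes: a single
n-membered ring has largest ring n; a cyclic glycine homopolymer
cyclo(Gly)_k has ring size 3k and exactly k ring amides; an activity
table built from a stage-removal plan reproduces that plan exactly in
the curation cascade; clustered binary fingerprints have known labels
and controllable intra/inter-cluster Hamming separation.

These generators emulate record *structure*, not chemistry: ring sizes,
amide counts, filter trip-wires and cluster geometry are planted, while
real bioactivity data brings assay noise, correlated scaffolds and
heavy-tailed value distributions that no fixture here imitates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chem_core import standardize
from .ingest import ActivityRecord, TargetEntry, assign_family


def ring_smiles(n: int, kind: str = "carbocycle") -> str:
    """SMILES of a single ring of exactly ``n`` atoms.

    ``lactam``/``lactone`` variants carry exactly one ring amide/ester;
    the carbocycle carries none.
    """
    if not 3 <= n <= 60:
        raise ValueError(f"ring size {n} out of supported range [3, 60]")
    if kind == "carbocycle":
        return "C1" + "C" * (n - 1) + "1"
    if kind == "lactam":
        return "O=C1" + "C" * (n - 2) + "N1"
    if kind == "lactone":
        return "O=C1" + "C" * (n - 2) + "O1"
    raise ValueError(f"unknown ring kind: {kind!r}")


def cyclo_gly(k: int) -> str:
    """Cyclic glycine homopolymer cyclo(Gly)_k: ring size 3k, k ring amides."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return "O=C1" + "CNC(=O)" * (k - 1) + "CN1"


def two_ring_smiles(n: int = 9) -> str:
    """Two linked n-membered carbocycles (a two-macro-ring compound)."""
    ring = "C" * (n - 2)
    return f"C1{ring}C1C1{ring}C1"


@dataclass(frozen=True)
class CascadePlan:
    """Stage survivor counts for a planted activity table.

    The chain must be non-increasing: records >= macrocyclic >= nM-unit
    >= equality-relation >= deduplicated >= one-ring >= below-threshold.
    ``n_ic50`` of the final survivors carry type IC50 (the rest Ki).
    """

    n_records: int = 20
    n_macro: int = 12
    n_nM: int = 10
    n_eq: int = 9
    n_dedup: int = 7
    n_one_ring: int = 5
    n_active: int = 4
    n_ic50: Optional[int] = None

    def validate(self) -> None:
        chain = [
            self.n_records,
            self.n_macro,
            self.n_nM,
            self.n_eq,
            self.n_dedup,
            self.n_one_ring,
            self.n_active,
        ]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"stage counts must be non-increasing: {chain}")
        if any(c < 0 for c in chain):
            raise ValueError("stage counts must be non-negative")
        if self.n_ic50 is not None and not 0 <= self.n_ic50 <= self.n_active:
            raise ValueError("n_ic50 must be within [0, n_active]")


_FIXTURE_TARGETS = [
    ("P23975", "CHEMBL222", "SLC6A2"),
    ("Q9Y6L6", "CHEMBL1697668", "SLCO1B1"),
    ("P31639", "CHEMBL3884", "SLC5A2"),
]


def fixture_targets() -> list[TargetEntry]:
    """Three transporter targets spanning three families."""
    return [
        assign_family(
            TargetEntry(uniprot_id=u, chembl_target_id=c, gene_symbol=g)
        )
        for u, c, g in _FIXTURE_TARGETS
    ]


def _make_record(
    smiles: str,
    index: int,
    target: TargetEntry,
    standard_type: str = "IC50",
    relation: str = "=",
    value: Optional[float] = 100.0,
    units: str = "nM",
    document_id: Optional[str] = None,
) -> ActivityRecord:
    return ActivityRecord(
        compound=standardize(smiles),
        compound_id=f"MOL{index:04d}",
        target=target,
        standard_type=standard_type,
        standard_relation=relation,
        standard_value=value,
        standard_units=units,
        pchembl_value=None,
        assay_id=f"ASSAY{index:04d}",
        document_id=document_id or f"DOC{index:04d}",
    )


def activity_table(plan: CascadePlan = CascadePlan(), seed: int = 0) -> list[ActivityRecord]:
    """Activity records whose cascade stage counts equal ``plan`` exactly.

    Each removal stage gets a dedicated planted group: acyclic compounds
    (fail the macrocycle filter), micromolar units, interval relations,
    exact duplicate measurements, two-ring compounds (fail the one-ring
    restriction) and supra-threshold values. The record order is shuffled
    by ``seed``; the counts are seed-independent by construction.
    """
    plan.validate()
    targets = fixture_targets()
    n_ic50 = plan.n_ic50 if plan.n_ic50 is not None else plan.n_active
    records: list[ActivityRecord] = []
    idx = 0

    def nxt() -> int:
        nonlocal idx
        idx += 1
        return idx

    def one_ring(i: int) -> str:
        return ring_smiles(9 + (i % 22), kind="carbocycle" if i % 2 else "lactam")

    # final survivors: one-ring macrocycles, nM, "=", value under threshold
    for i in range(plan.n_active):
        records.append(
            _make_record(
                one_ring(i),
                nxt(),
                targets[i % len(targets)],
                standard_type="IC50" if i < n_ic50 else "Ki",
                value=100.0 + i,
            )
        )
    # removed by the activity threshold (strictly above 10 uM)
    for i in range(plan.n_one_ring - plan.n_active):
        records.append(
            _make_record(one_ring(i), nxt(), targets[i % len(targets)], value=20_000.0 + i)
        )
    # removed by the one-ring restriction
    for i in range(plan.n_dedup - plan.n_one_ring):
        records.append(
            _make_record(
                two_ring_smiles(9 + (i % 5)), nxt(), targets[i % len(targets)], value=500.0 + i
            )
        )
    # removed by deduplication: exact copies of survivors, later document ids
    for i in range(plan.n_eq - plan.n_dedup):
        twin = records[i % max(plan.n_dedup, 1)]
        records.append(
            ActivityRecord(
                compound=standardize(twin.compound.raw_smiles),
                compound_id=twin.compound_id,
                target=twin.target,
                standard_type=twin.standard_type,
                standard_relation=twin.standard_relation,
                standard_value=twin.standard_value,
                standard_units=twin.standard_units,
                pchembl_value=None,
                assay_id=f"ASSAY9{i:03d}",
                document_id=f"DOC9{i:03d}",  # sorts after the original DOC0xxx
            )
        )
    # removed by the interval-relation filter
    for i in range(plan.n_nM - plan.n_eq):
        records.append(
            _make_record(
                one_ring(i), nxt(), targets[i % len(targets)], relation=">", value=50.0
            )
        )
    # removed by the nM-unit filter
    for i in range(plan.n_macro - plan.n_nM):
        records.append(
            _make_record(
                one_ring(i), nxt(), targets[i % len(targets)], value=1.0, units="uM"
            )
        )
    # removed by the macrocycle filter (acyclic chains)
    for i in range(plan.n_records - plan.n_macro):
        records.append(
            _make_record("C" * (3 + i % 6) + "O", nxt(), targets[i % len(targets)])
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def clustered_fingerprints(
    n_clusters: int = 3,
    per_cluster: int = 20,
    flip_rate: float = 0.02,
    n_bits: int = 2048,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled binary vectors: random prototypes plus per-member bit flips.

    Prototypes are uniform random bit vectors (mutual Hamming distance
    ~n_bits/2, far above the within-cluster distance of ~2*flip_rate*n_bits),
    so cluster structure is planted and known. Returns (X, labels).
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    prototypes = rng.integers(0, 2, size=(n_clusters, n_bits), dtype=np.uint8)
    X = np.empty((n_clusters * per_cluster, n_bits), dtype=np.uint8)
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    for i, lab in enumerate(labels):
        flips = rng.random(n_bits) < flip_rate
        X[i] = prototypes[lab] ^ flips.astype(np.uint8)
    return X, labels


def synonym_counts(
    n_obscure: int = 40, n_known: int = 10, seed: int = 0
) -> dict[str, int]:
    """Synonym-count table with a planted knee at five synonyms.

    Obscure compounds draw counts in [0, 4], well-known ones in [5, 200];
    keys are synthetic query ids.
    """
    rng = np.random.default_rng(seed)
    table: dict[str, int] = {}
    for i in range(n_obscure):
        table[f"OBSCURE{i:03d}"] = int(rng.integers(0, 5))
    for i in range(n_known):
        table[f"KNOWN{i:03d}"] = int(rng.integers(5, 201))
    return table
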