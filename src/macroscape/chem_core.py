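"""Structure parsing, ring analysis and macrocycle classification.

A *macrocycle* here is a molecule carrying at least one ring of 9-30 atoms
(smallest-set-of-smallest-rings perception). A *peptide-like* macrocycle
additionally carries at least three amide (peptide) bonds whose N and
carbonyl carbon both sit inside such a macro-ring, matched by a SMARTS
pattern in which both the N-C(=O) and the C(=O)-C bonds are ring bonds.

All operations take a :class:`Compound` produced by :func:`standardize`,
which canonicalizes the structure to InChI/InChIKey so that duplicate
detection is independent of the input atom order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

#: Inclusive macro-ring atom-count window.
MACRO_RING_MIN = 9
MACRO_RING_MAX = 30

#: Ring-bond amide motif: N-C(=O)-C with both backbone bonds in a ring.
PEPTIDE_BOND_SMARTS = "[NX3]-@[CX3](=[OX1])-@[#6]"

#: A macrocycle is peptide-like when it has at least this many ring amides.
MIN_PEPTIDE_BONDS = 3


class ConfigurationError(ValueError):
    """Raised for invalid ring windows, SMARTS overrides or thresholds."""


@dataclass(frozen=True)
class Compound:
    """A parsed structure with canonical identifiers.

    ``inchi_key`` is atom-order invariant: two SMILES of the same structure
    map to the same key, which makes it the deduplication handle downstream.
    A failed parse yields ``parse_ok=False`` with all other fields empty;
    such records are retained and flagged, never silently dropped.
    """

    raw_smiles: str
    canonical_inchi: str = ""
    inchi_key: str = ""
    parse_ok: bool = False
    mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class MacrocycleProfile:
    """Per-compound macro-ring analysis.

    ``macro_ring_sizes`` is the sorted multiset of SSSR ring sizes inside
    the window; ``scaffold_signature`` is its "+"-joined text form (e.g.
    ``"12+14"``), used for per-target scaffold tallies.
    """

    macro_ring_sizes: tuple[int, ...]
    ring_amide_count: int
    min_size: int = MACRO_RING_MIN
    max_size: int = MACRO_RING_MAX

    @property
    def macro_ring_count(self) -> int:
        return len(self.macro_ring_sizes)

    @property
    def largest_macro_ring(self) -> Optional[int]:
        return max(self.macro_ring_sizes) if self.macro_ring_sizes else None

    @property
    def scaffold_signature(self) -> str:
        return "+".join(str(s) for s in self.macro_ring_sizes)

    @property
    def is_macrocycle(self) -> bool:
        return self.macro_ring_count >= 1

    @property
    def is_peptide_like(self) -> bool:
        return self.is_macrocycle and self.ring_amide_count >= MIN_PEPTIDE_BONDS


@dataclass(frozen=True)
class DescriptorSet:
    """Rule-of-five style physicochemical descriptors.

    HBD counts donor heavy atoms (each N or O carrying at least one H
    counts once, so water has one donor); HBA uses the toolkit's default
    acceptor perception. The convention is recorded in output metadata by
    callers.
    """

    slogp: float
    tpsa: float
    amw: float
    n_rotatable: int
    n_hbd: int
    n_hba: int


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular (ECFP-like) fingerprint as a dense 0/1 vector."""

    bits: np.ndarray
    radius: int
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits.shape != (self.n_bits,):
            raise ValueError("fingerprint length does not match n_bits")


def standardize(raw_smiles: str) -> Compound:
    """Parse a SMILES and attach canonical InChI / InChIKey.

    Unparsable input returns a flagged ``Compound`` (``parse_ok=False``)
    rather than raising, so that record-level bookkeeping can count it.
    """
    if not raw_smiles:
        raise ValueError("raw_smiles must be non-empty")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Compound(raw_smiles=raw_smiles)
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        return Compound(raw_smiles=raw_smiles)
    key = Chem.InchiToInchiKey(inchi)
    return Compound(
        raw_smiles=raw_smiles,
        canonical_inchi=inchi,
        inchi_key=key,
        parse_ok=True,
        mol=mol,
    )


def _require_parsed(compound: Compound) -> Chem.Mol:
    if not compound.parse_ok or compound.mol is None:
        raise ValueError(f"compound {compound.raw_smiles!r} did not parse")
    return compound.mol


def _macro_rings(mol: Chem.Mol, min_size: int, max_size: int) -> list[frozenset[int]]:
    rings = mol.GetRingInfo().AtomRings()
    return [frozenset(r) for r in rings if min_size <= len(r) <= max_size]


def count_ring_amides(
    compound: Compound,
    min_size: int = MACRO_RING_MIN,
    max_size: int = MACRO_RING_MAX,
    pattern: str = PEPTIDE_BOND_SMARTS,
    ring_scope: str = "macro",
) -> int:
    """Count amide motifs whose backbone lies in a (macro-)ring.

    A match counts only when both the amide N and the carbonyl carbon are
    members of at least one perceived ring inside the size window: a bare
    ring-bond SMARTS would also pick up small lactams such as caprolactam.
    ``ring_scope="any"`` lifts the size restriction (counts amides in any
    ring), exposed because published ring-membership conventions vary.
    """
    mol = _require_parsed(compound)
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ConfigurationError(f"invalid SMARTS pattern: {pattern!r}")
    if ring_scope not in ("macro", "any"):
        raise ConfigurationError(f"unknown ring_scope: {ring_scope!r}")
    matches = mol.GetSubstructMatches(query)
    if ring_scope == "any":
        return len(matches)
    rings = _macro_rings(mol, min_size, max_size)
    n = 0
    for match in matches:
        n_atom, c_atom = match[0], match[1]
        if any(n_atom in ring and c_atom in ring for ring in rings):
            n += 1
    return n


def macro_profile(
    compound: Compound,
    min_size: int = MACRO_RING_MIN,
    max_size: int = MACRO_RING_MAX,
) -> MacrocycleProfile:
    """Perceive macro-rings and classify the compound.

    Ring sizes come from the smallest set of smallest rings, consistent
    with SMARTS ``r<n>`` semantics; envelope rings of fused systems that
    vanish under SSSR are not counted.
    """
    if min_size > max_size:
        raise ConfigurationError(f"min_size {min_size} > max_size {max_size}")
    mol = _require_parsed(compound)
    sizes = sorted(
        len(r)
        for r in mol.GetRingInfo().AtomRings()
        if min_size <= len(r) <= max_size
    )
    amides = count_ring_amides(compound, min_size=min_size, max_size=max_size)
    return MacrocycleProfile(
        macro_ring_sizes=tuple(sizes),
        ring_amide_count=amides,
        min_size=min_size,
        max_size=max_size,
    )


_DONOR_QUERY = Chem.MolFromSmarts("[#7,#8;!H0]")


def descriptors(compound: Compound) -> DescriptorSet:
    """Compute the six dashboard descriptors (SlogP, TPSA, AMW, RotB, HBD, HBA)."""
    mol = _require_parsed(compound)
    return DescriptorSet(
        slogp=Crippen.MolLogP(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        amw=Descriptors.MolWt(mol),
        n_rotatable=rdMolDescriptors.CalcNumRotatableBonds(mol),
        n_hbd=len(mol.GetSubstructMatches(_DONOR_QUERY)),
        n_hba=rdMolDescriptors.CalcNumHBA(mol),
    )


def ecfp(compound: Compound, radius: int = 3, n_bits: int = 2048) -> Fingerprint:
    """Hashed Morgan/ECFP fingerprint (radius 3, 2048 bits by default)."""
    if n_bits <= 0:
        raise ConfigurationError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ConfigurationError(f"radius must be >= 0, got {radius}")
    mol = _require_parsed(compound)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits)
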