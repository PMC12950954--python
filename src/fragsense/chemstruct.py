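"""Molecular structure model, descriptors, Rule-of-3 filter, fingerprints and
the Tanimoto coefficient.

The ``Molecule`` type is a light heavy-atom graph (element, formal charge,
aromaticity per atom; order-labelled bonds) built on top of an RDKit mol,
which carries the chemistry perception.  Standard physicochemical descriptors
are delegated to RDKit; the Rule-of-3 logic and the Tanimoto coefficient
Tc = c / (a + b - c) are implemented here natively on plain bit vectors.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, rdBase
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator


class ChemError(Exception):
    """Base class for structure-handling errors."""


class StructureParseError(ChemError):
    """Raised when a SMILES/SDF record cannot be parsed into a molecule."""

    def __init__(self, message: str, position: Optional[int] = None):
        super().__init__(message)
        self.position = position


class UnknownSchemeError(ChemError):
    """Raised for a fingerprint scheme identifier that is not supported."""


class SchemeMismatchError(ChemError):
    """Raised when two fingerprints of different schemes are compared."""


#: bond order labels: 1, 2, 3 or "ar" (aromatic)
_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


@dataclass
class Molecule:
    """Heavy-atom molecular graph.

    atoms: sequence of ``(element symbol, formal charge, aromatic flag)``
    bonds: sequence of ``(i, j, order)`` with order in ``{1, 2, 3, "ar"}``
    source: the SMILES string as provided by the caller
    """

    id: str
    atoms: tuple
    bonds: tuple
    source: str
    _rdmol: Chem.Mol = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        if n == 0:
            raise ValueError(f"molecule {self.id!r} is empty")
        seen = set()
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"molecule {self.id!r}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id!r}: bond ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def rdmol(self) -> Chem.Mol:
        if self._rdmol is None:
            self._rdmol = Chem.MolFromSmiles(self.source)
            if self._rdmol is None:
                raise StructureParseError(
                    f"stored SMILES for {self.id!r} no longer parses: {self.source!r}"
                )
        return self._rdmol

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


def molecule_from_rdmol(rdmol: Chem.Mol, mol_id: str, source: Optional[str] = None) -> Molecule:
    """Wrap a (sanitised) RDKit mol as a :class:`Molecule`."""
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic()) for a in rdmol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1))
        for b in rdmol.GetBonds()
    )
    return Molecule(
        id=mol_id,
        atoms=atoms,
        bonds=bonds,
        source=source if source is not None else Chem.MolToSmiles(rdmol),
        _rdmol=rdmol,
    )


def parse_structure(text: str, mol_id: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Aromaticity is perceived by RDKit sanitisation; formal charges are kept as
    written (zwitterions such as trigonelline stay charged).  An unparsable
    string raises :class:`StructureParseError` carrying, where RDKit reports
    one, the offending token position.
    """
    if not text or not text.strip():
        raise StructureParseError(f"empty SMILES for {mol_id!r}")
    text = text.strip()

    # RDKit reports SMILES syntax problems on its error log only; capture it
    # so the position survives into the raised exception.
    log = logging.getLogger("rdkit")
    records: list[str] = []
    handler = _ListHandler(records)
    rdBase.LogToPythonLogger()
    log.addHandler(handler)
    try:
        rdmol = Chem.MolFromSmiles(text)
    finally:
        log.removeHandler(handler)
    if rdmol is None:
        message = "; ".join(records) or f"cannot parse SMILES {text!r}"
        pos = None
        m = re.search(r"position[:\s]+(\d+)", message)
        if m:
            pos = int(m.group(1))
        raise StructureParseError(f"{mol_id!r}: {message}", position=pos)
    return molecule_from_rdmol(rdmol, mol_id, source=text)


class _ListHandler(logging.Handler):
    def __init__(self, sink: list):
        super().__init__()
        self._sink = sink

    def emit(self, record):  # pragma: no cover - trivial
        self._sink.append(record.getMessage())


# ---------------------------------------------------------------------------
# descriptors and the Rule of 3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorRecord:
    """Physicochemical descriptors used by the fragment (Rule-of-3) filter."""

    molecular_weight: float  # g/mol
    hbd: int                 # H-bond donors
    hba: int                 # H-bond acceptors
    clogp: float             # Crippen logP, unitless
    rotatable_bonds: int
    tpsa: float              # topological polar surface area, A^2

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if min(self.hbd, self.hba, self.rotatable_bonds) < 0:
            raise ValueError("descriptor counts must be non-negative")


def compute_descriptors(mol: Molecule) -> DescriptorRecord:
    """Descriptor set used by the fragment filter; deterministic per molecule.

    Weight, cLogP (Crippen), rotatable bonds and TPSA are the RDKit
    definitions.  H-bond counts follow the heavy-atom convention of the
    rule-based screening literature: a donor is any N or O carrying at least
    one hydrogen (water counts 1), an acceptor is any N or O.
    """
    m = mol.rdmol
    hbd = sum(
        1
        for a in m.GetAtoms()
        if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() >= 1
    )
    hba = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8))
    return DescriptorRecord(
        molecular_weight=Descriptors.MolWt(m),
        hbd=hbd,
        hba=hba,
        clogp=Crippen.MolLogP(m),
        rotatable_bonds=Lipinski.NumRotatableBonds(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
    )


@dataclass(frozen=True)
class Ro3Thresholds:
    """Rule-of-3 fragment-library criteria; boundaries are inclusive.

    The community convention for Ro3 fragment libraries: MW <= 300,
    cLogP <= 3, donors <= 3, acceptors <= 3, with the common extensions
    rotatable bonds <= 3 and TPSA <= 60 A^2.  Any criterion can be disabled
    by setting it to ``None``.
    """

    molecular_weight: Optional[float] = 300.0
    clogp: Optional[float] = 3.0
    hbd: Optional[int] = 3
    hba: Optional[int] = 3
    rotatable_bonds: Optional[int] = 3
    tpsa: Optional[float] = 60.0


def ro3_filter(
    rec: DescriptorRecord, thresholds: Ro3Thresholds = Ro3Thresholds()
) -> tuple[bool, list[str]]:
    """Apply the Rule of 3; returns (pass, every violated criterion)."""
    failed = [
        name
        for name in (
            "molecular_weight", "clogp", "hbd", "hba", "rotatable_bonds", "tpsa",
        )
        if getattr(thresholds, name) is not None
        and getattr(rec, name) > getattr(thresholds, name)
    ]
    return (not failed, failed)


# ---------------------------------------------------------------------------
# fingerprints and the Tanimoto coefficient
# ---------------------------------------------------------------------------

_RDKIT_FP = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
_MORGAN_FP = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

#: scheme identifier -> (bit length, RDKit bit-vector factory)
SCHEMES = {
    # 166 public structural keys (167-long vector; bit 0 unused by convention)
    "structural-keys-166": (167, MACCSkeys.GenMACCSKeys),
    "path-based": (2048, _RDKIT_FP.GetFingerprint),
    "circular-r2": (2048, _MORGAN_FP.GetFingerprint),
    # substructure-screening pattern fingerprint; 1024 bits.  This is the
    # scheme the Tables calibration selects (see screening.calibrate_scheme).
    "substructure-pattern": (1024, lambda m: Chem.PatternFingerprint(m, fpSize=1024)),
}


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit vector under a named scheme."""

    scheme: str
    bits: np.ndarray = field(compare=False)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise UnknownSchemeError(f"unknown fingerprint scheme {self.scheme!r}")
        expected = SCHEMES[self.scheme][0]
        if len(self.bits) != expected:
            raise ValueError(
                f"scheme {self.scheme!r} expects {expected} bits, got {len(self.bits)}"
            )

    @property
    def popcount(self) -> int:
        return int(np.count_nonzero(self.bits))

    def __eq__(self, other):
        return (
            isinstance(other, Fingerprint)
            and self.scheme == other.scheme
            and bool(np.array_equal(self.bits, other.bits))
        )


def compute_fingerprint(mol: Molecule, scheme: str = "structural-keys-166") -> Fingerprint:
    """Fingerprint a molecule under one of the supported schemes."""
    if scheme not in SCHEMES:
        raise UnknownSchemeError(
            f"unknown fingerprint scheme {scheme!r}; supported: {sorted(SCHEMES)}"
        )
    _length, factory = SCHEMES[scheme]
    bv = factory(mol.rdmol)
    bits = np.zeros(bv.GetNumBits(), dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(scheme=scheme, bits=bits)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient Tc = c / (a + b - c) on two same-scheme bit vectors.

    ``a`` and ``b`` are the set-bit counts of the two fingerprints and ``c``
    the count of their intersection.  Two empty fingerprints give 0 (with a
    warning) rather than 0/0.
    """
    if fp_a.scheme != fp_b.scheme:
        raise SchemeMismatchError(
            f"cannot compare schemes {fp_a.scheme!r} and {fp_b.scheme!r}"
        )
    a = fp_a.popcount
    b = fp_b.popcount
    if a == 0 and b == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    c = int(np.count_nonzero(fp_a.bits & fp_b.bits))
    return c / (a + b - c)


def round_tc(value: float, ndigits: int = 2) -> float:
    """Round half-up, matching the printed "Tc ratio" convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
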