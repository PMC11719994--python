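"""Structure parsing, canonicalization, fingerprints, descriptors, and compound I/O.

Every downstream stage (QSAR training, similarity matching, SAR profiling,
BBB scoring) consumes the records, fingerprints, and descriptor sets produced
here, so molecular featurization is defined in exactly one place.

Molecules are handled as canonical SMILES. Salts and mixtures are reduced to
their largest organic fragment at parse time, so the canonical form, the
fingerprint, and the descriptors always describe the same single component.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

logger = logging.getLogger(__name__)

# RDKit prints parse diagnostics to stderr by default; we report skips ourselves.
RDLogger.DisableLog("rdApp.error")

DEFAULT_N_BITS = 2048
DEFAULT_RADIUS = 2


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, row_index: int | None = None):
        self.smiles = smiles
        self.row_index = row_index
        where = f" (row {row_index})" if row_index is not None else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


class SchemaError(ValueError):
    """Raised when an input table is missing a required column."""


@dataclass(frozen=True)
class CompoundRecord:
    """A compound with its identity, canonical structure, and optional provenance."""

    id: str
    smiles: str
    canonical_smiles: str
    name: str | None = None
    sources: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular (Morgan) fingerprint of a molecule.

    ``bits`` is a dense uint8 0/1 vector of length ``n_bits``; ``radius`` is
    the maximum bond radius of the hashed atom environments.
    """

    bits: np.ndarray
    n_bits: int
    radius: int

    def __post_init__(self):
        if self.bits.shape != (self.n_bits,):
            raise ValueError("bit vector length does not match n_bits")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors used by SAR profiling and BBB scoring.

    mol_wt in Da; log_p is the Crippen atom-contribution octanol/water
    estimate; tpsa is the Ertl fragment-additive polar surface area in Å²;
    h_donors / h_acceptors are Lipinski donor/acceptor counts.
    """

    mol_wt: float
    log_p: float
    h_donors: int
    h_acceptors: int
    tpsa: float
    extras: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {
            "mol_wt": self.mol_wt,
            "log_p": self.log_p,
            "h_donors": self.h_donors,
            "h_acceptors": self.h_acceptors,
            "tpsa": self.tpsa,
        }
        d.update(self.extras)
        return d


def _mol_from_smiles(smiles: str, row_index: int | None = None) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), row_index)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, row_index)
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    # prefer fragments containing carbon; break ties by heavy-atom count
    def key(m: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
        return (has_c, m.GetNumHeavyAtoms())

    return max(frags, key=key)


def parse_and_canonicalize(smiles: str, row_index: int | None = None) -> str:
    """Parse a SMILES string and return the canonical SMILES of its largest
    organic fragment.

    Two different valid encodings of one structure map to the same canonical
    string, and the operation is idempotent. Raises :class:`SmilesParseError`
    for malformed input, carrying the offending string and optional row index.
    """
    mol = _mol_from_smiles(smiles, row_index)
    mol = _largest_fragment(mol)
    return Chem.MolToSmiles(mol)


def mol_from_record(record: CompoundRecord | str) -> Chem.Mol:
    """Return the RDKit molecule for a record (or raw SMILES string)."""
    smiles = record.canonical_smiles if isinstance(record, CompoundRecord) else record
    return _mol_from_smiles(smiles)


def compute_fingerprint(
    record: CompoundRecord | str,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> Fingerprint:
    """Compute a binary circular fingerprint (Morgan, hashed to ``n_bits``).

    Deterministic: identical canonical structures under identical parameters
    yield bit-identical vectors across runs.
    """
    if n_bits < 64:
        raise ValueError(f"n_bits must be >= 64, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mol = mol_from_record(record)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, n_bits=n_bits, radius=radius)


def fingerprint_matrix(
    records: list[CompoundRecord],
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """Stack fingerprints of many records into an (n, n_bits) uint8 matrix."""
    return np.vstack(
        [compute_fingerprint(r, n_bits=n_bits, radius=radius).bits for r in records]
    )


def compute_descriptors(
    record: CompoundRecord | str, extras: tuple[str, ...] = ()
) -> DescriptorSet:
    """Compute the five BBB-relevant descriptors (MW, LogP, HBD, HBA, TPSA).

    ``extras`` names additional RDKit descriptor functions (by their
    ``Descriptors`` attribute name) appended to the extensible map.
    """
    mol = mol_from_record(record)
    extra_vals = {name: float(getattr(Descriptors, name)(mol)) for name in extras}
    return DescriptorSet(
        mol_wt=float(Descriptors.MolWt(mol)),
        log_p=float(Crippen.MolLogP(mol)),
        h_donors=int(Lipinski.NumHDonors(mol)),
        h_acceptors=int(Lipinski.NumHAcceptors(mol)),
        tpsa=float(Descriptors.TPSA(mol)),
        extras=extra_vals,
    )


def _parse_sources(cell: str | float | None, delimiter: str = ";") -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    parts = str(cell).split(delimiter)
    return frozenset(p.strip().casefold() for p in parts if p.strip())


def read_compound_table(
    path, source_delimiter: str = ";"
) -> tuple[list[CompoundRecord], int]:
    """Read a compound CSV (columns: id, smiles [, name, sources]).

    Rows with unparseable SMILES are logged and skipped. Returns the records
    and the number of skipped rows. Missing required columns raise
    :class:`SchemaError`; an empty file yields an empty list with a warning.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise SchemaError(f"compound table {path} is missing column {col!r}")
    if df.empty:
        logger.warning("compound table %s is empty", path)
        return [], 0

    records: list[CompoundRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            canonical = parse_and_canonicalize(row["smiles"], row_index=int(idx))
        except SmilesParseError as exc:
            logger.warning("skipping compound row: %s", exc)
            n_skipped += 1
            continue
        name = row.get("name")
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                smiles=str(row["smiles"]),
                canonical_smiles=canonical,
                name=None if pd.isna(name) else str(name),
                sources=_parse_sources(row.get("sources"), source_delimiter),
            )
        )
    if n_skipped:
        logger.info("skipped %d unparseable rows in %s", n_skipped, path)
    return records, n_skipped


def read_sdf(path) -> tuple[list[CompoundRecord], int]:
    """Read structures from an SDF (V2000) file into compound records.

    Molecule name/_Name is used as the id; unparseable blocks are skipped.
    """
    records: list[CompoundRecord] = []
    n_skipped = 0
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            n_skipped += 1
            continue
        smiles = Chem.MolToSmiles(_largest_fragment(mol))
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        records.append(
            CompoundRecord(
                id=mol_id or f"sdf_{i}",
                smiles=smiles,
                canonical_smiles=smiles,
            )
        )
    return records, n_skipped


def write_compound_table(records: list[CompoundRecord], path) -> pd.DataFrame:
    """Write a canonicalized compound table with appended descriptor columns."""
    rows = []
    for r in records:
        d = compute_descriptors(r)
        rows.append(
            {
                "id": r.id,
                "name": r.name or "",
                "smiles": r.smiles,
                "canonical_smiles": r.canonical_smiles,
                "sources": ";".join(sorted(r.sources)),
                **d.as_dict(),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
    return df
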