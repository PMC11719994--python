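"""Synthetic compound, activity, clustering, and food-source fixtures.

Every pipeline stage is testable without external databases: this module
generates chemically valid compound tables by randomly decorating a small
scaffold library (benzene, chromone, flavone, coumarin, simple chains) with
common substituents, plants a linear fingerprint-bit → pIC50 signal with
Gaussian noise on top, and builds clustering and food-source fixtures with
known ground truth. Everything is deterministic under the spec seed.

The generator emulates the shape of real ligand-activity data — shared
scaffolds, substituent-driven activity differences, nanomolar-to-micromolar
IC50 ranges — but not the property distributions of medicinal-chemistry
libraries; planted signals are exactly linear in fingerprint bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import compute_fingerprint, fingerprint_matrix, parse_and_canonicalize
from .chem import CompoundRecord, DEFAULT_N_BITS, DEFAULT_RADIUS
from .qsar import pic50_to_ic50
from .sources import SourceMap

DEFAULT_TARGETS = ("AChE", "APP", "BACE1", "MAPT", "PSEN1", "TNF-alpha", "VCP")

# canonical SMILES of the reference flavonoids used by the BBB regression
# suite (dietary compounds screened in neurodegeneration studies)
REFERENCE_COMPOUNDS = {
    "coumarin": "O=c1ccc2ccccc2o1",
    "dihydromyricetin": "O=C1c2c(O)cc(O)cc2OC(c2cc(O)c(O)c(O)c2)C1O",
    "quercetin": "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",
    "kaempferol": "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",
    "luteolin": "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",
    "astragalin": "O=c1c(OC2OC(CO)C(O)C(O)C2O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",
    "apigenin": "O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",
}

# six-source fixture mirrors the shape of a top-foods analysis:
# ranked counts with ties, plus a planted common core found in every source
DEFAULT_SOURCE_COUNTS = (
    ("black walnut", 40),
    ("safflower", 37),
    ("fig", 32),
    ("pepper", 32),
    ("corn", 31),
    ("ginger", 31),
)
DEFAULT_COMMON_CORE = 25

SCAFFOLDS = {
    "benzene": "c1ccccc1",
    "chromone": "O=c1ccoc2ccccc12",
    "flavone": "O=c1cc(-c2ccccc2)oc2ccccc12",
    "coumarin": "O=c1ccc2ccccc2o1",
    "pentane": "CCCCC",
    "cyclohexanone": "O=C1CCCCC1",
}

SUBSTITUENTS = {
    "hydroxyl": "O",
    "methoxy": "OC",
    "carboxyl": "C(=O)O",
    "formyl": "C=O",
    "methyl": "C",
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study: cohort size, targets, planted signal."""

    n_compounds: int = 300
    targets: tuple[str, ...] = DEFAULT_TARGETS
    planted_weights: dict[int, float] | None = None
    base_pic50: float = 6.5
    noise_sd: float = 0.3
    n_signal_bits: int = 12
    max_substituents: int = 3
    k_blobs: int = 6
    blob_separation: float = 10.0
    blob_dim: int = 4
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")


def _decorate(scaffold: Chem.Mol, substituents: list[str], rng: np.random.Generator) -> str:
    """Attach substituent fragments to random H-bearing carbons of a scaffold."""
    mol = scaffold
    for sub_smiles in substituents:
        frag = Chem.MolFromSmiles(sub_smiles)
        # H counts are only valid on a sanitized molecule, so sanitize per step
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
        ]
        if not sites:
            break
        site = int(rng.choice(sites))
        offset = mol.GetNumAtoms()
        rw = Chem.RWMol(Chem.CombineMols(mol, frag))
        rw.AddBond(site, offset, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_compounds(spec: FixtureSpec) -> pd.DataFrame:
    """Generate a valid compound table (id, name, smiles) by scaffold decoration.

    Every emitted SMILES parses and canonicalizes; the decoration grammar only
    bonds single-valence fragments to carbons with a free hydrogen, so no
    valence errors are possible.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold_names = sorted(SCAFFOLDS)
    sub_names = sorted(SUBSTITUENTS)
    scaffold_mols = {k: Chem.MolFromSmiles(v) for k, v in SCAFFOLDS.items()}
    rows = []
    for i in range(spec.n_compounds):
        scaf = scaffold_names[int(rng.integers(len(scaffold_names)))]
        n_sub = int(rng.integers(0, spec.max_substituents + 1))
        subs = [sub_names[int(rng.integers(len(sub_names)))] for _ in range(n_sub)]
        smiles = _decorate(scaffold_mols[scaf], [SUBSTITUENTS[s] for s in subs], rng)
        rows.append(
            {
                "id": f"NC{i:05d}",
                "name": f"{scaf}" + ("_" + "_".join(subs) if subs else ""),
                "smiles": smiles,
            }
        )
    return pd.DataFrame(rows)


def plant_weights(
    compounds: pd.DataFrame, spec: FixtureSpec
) -> dict[int, float]:
    """Choose signal bits among informative fingerprint positions.

    Bits set in 20–80% of the cohort are eligible; ``n_signal_bits`` of them
    receive weights of magnitude 0.4–0.8 with random sign, giving the planted
    activity a signal standard deviation well above the default noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    records = _records_from_table(compounds)
    X = fingerprint_matrix(records, n_bits=spec.n_bits, radius=spec.radius)
    freq = X.mean(axis=0)
    eligible = np.where((freq >= 0.2) & (freq <= 0.8))[0]
    if eligible.size == 0:
        raise ValueError("no informative fingerprint bits in compound set")
    n_sig = min(spec.n_signal_bits, eligible.size)
    chosen = rng.choice(eligible, size=n_sig, replace=False)
    weights = rng.uniform(0.4, 0.8, size=n_sig) * rng.choice([-1.0, 1.0], size=n_sig)
    return {int(b): float(w) for b, w in zip(chosen, weights)}


def _records_from_table(compounds: pd.DataFrame) -> list[CompoundRecord]:
    return [
        CompoundRecord(
            id=str(r["id"]),
            smiles=str(r["smiles"]),
            canonical_smiles=parse_and_canonicalize(r["smiles"]),
            name=str(r["name"]) if "name" in r and pd.notna(r["name"]) else None,
        )
        for _, r in compounds.iterrows()
    ]


def generate_activities(compounds: pd.DataFrame, spec: FixtureSpec) -> pd.DataFrame:
    """Attach planted activities: pIC50 linear in fingerprint bits plus noise.

    pIC50 = base + Σ planted_weights over present bits + N(0, noise_sd²), and
    ic50_nm = 10^(9 − pIC50). Each compound is assayed against one target
    drawn uniformly from ``spec.targets``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    weights = (
        spec.planted_weights
        if spec.planted_weights is not None
        else plant_weights(compounds, spec)
    )
    records = _records_from_table(compounds)
    X = fingerprint_matrix(records, n_bits=spec.n_bits, radius=spec.radius)
    w = np.zeros(spec.n_bits)
    for b, v in weights.items():
        w[b] = v
    pic50 = (
        spec.base_pic50
        + X.astype(float) @ w
        + rng.normal(0.0, spec.noise_sd, size=len(records))
    )
    target_idx = rng.integers(len(spec.targets), size=len(records))
    df = compounds[["id", "smiles"]].copy()
    df["target"] = [spec.targets[i] for i in target_idx]
    df["pic50"] = np.round(pic50, 6)
    df["ic50_nm"] = pic50_to_ic50(df["pic50"].to_numpy())
    return df


def generate_cluster_fixture(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs with configurable separation; returns (X, true labels).

    Blob centers are placed by rejection sampling so every pair is at least
    ``blob_separation`` apart (in units of the unit within-blob SD).
    """
    if spec.k_blobs < 1:
        raise ValueError("k_blobs must be >= 1")
    rng = np.random.default_rng(spec.seed + 3)
    box = spec.blob_separation * max(spec.k_blobs, 2)
    centers = []
    while len(centers) < spec.k_blobs:
        c = rng.uniform(-box, box, size=spec.blob_dim)
        if all(np.linalg.norm(c - prev) >= spec.blob_separation for prev in centers):
            centers.append(c)
    per = max(spec.n_compounds // spec.k_blobs, 2)
    X = np.vstack(
        [c + rng.normal(size=(per, spec.blob_dim)) for c in centers]
    )
    labels = np.repeat(np.arange(spec.k_blobs), per)
    return X, labels


def generate_source_map(
    spec: FixtureSpec,
    counts: tuple[tuple[str, int], ...] = DEFAULT_SOURCE_COUNTS,
    common_core: int = DEFAULT_COMMON_CORE,
) -> SourceMap:
    """Source map with planted per-source counts and a planted common core.

    The first ``common_core`` compound ids belong to every source; each source
    is then topped up with unique ids to its planted count.
    """
    if any(c < common_core for _, c in counts):
        raise ValueError("every planted count must be >= the common core size")
    m = SourceMap()
    core = [f"NC_core_{i:03d}" for i in range(common_core)]
    serial = 0
    for source, count in counts:
        for cid in core:
            m.add(cid, source)
        for _ in range(count - common_core):
            m.add(f"NC_uniq_{serial:04d}", source)
            serial += 1
    return m


def source_long_table(source_map: SourceMap) -> pd.DataFrame:
    rows = [
        {"compound": cid, "source": s}
        for s in sorted(source_map.by_source)
        for cid in sorted(source_map.by_source[s])
    ]
    return pd.DataFrame(rows)


def generate_candidates(spec: FixtureSpec) -> pd.DataFrame:
    """Candidate natural-compound table (id, name, smiles, sources).

    Reuses the scaffold-decoration generator and assigns each candidate 1–3
    food sources from the fixture's source list.
    """
    rng = np.random.default_rng(spec.seed + 4)
    df = generate_compounds(
        FixtureSpec(
            n_compounds=spec.n_compounds,
            seed=spec.seed + 5,
            max_substituents=spec.max_substituents,
        )
    )
    df["id"] = [f"CAND{i:05d}" for i in range(len(df))]
    foods = [s for s, _ in DEFAULT_SOURCE_COUNTS]
    src_col = []
    for _ in range(len(df)):
        n_src = int(rng.integers(1, 4))
        picks = rng.choice(foods, size=n_src, replace=False)
        src_col.append(";".join(sorted(picks)))
    df["sources"] = src_col
    return df


def write_fixture_tables(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Emit activities.csv, candidates.csv, sources.csv for a fixture spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    compounds = generate_compounds(spec)
    activities = generate_activities(compounds, spec)
    candidates = generate_candidates(spec)
    srcs = source_long_table(generate_source_map(spec))
    paths = {
        "activities": out / "activities.csv",
        "candidates": out / "candidates.csv",
        "sources": out / "sources.csv",
    }
    activities.to_csv(paths["activities"], index=False)
    candidates.to_csv(paths["candidates"], index=False)
    srcs.to_csv(paths["sources"], index=False)
    return paths
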