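"""Candidate potency prediction, clustering, and structure–activity profiling.

The profiling stage takes the candidates retained by the similarity matcher,
predicts their pIC50 with the fitted QSAR ensemble, clusters them on
standardized physicochemical descriptors plus predicted potency (k chosen by
silhouette, with the SSE elbow reported alongside), and summarizes
structure–activity relationships per cluster and per activity tier: descriptor
statistics, fingerprint-bit frequencies, maximum common substructures, and
functional-group occurrence.

Activity tiers follow the potency convention
low: pIC50 ≤ 5, medium: 5 < pIC50 ≤ 7, high: pIC50 > 7.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import rdFMCS
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .chem import CompoundRecord, compute_descriptors, mol_from_record
from .qsar import QSARModel

logger = logging.getLogger(__name__)

ACTIVITY_CLASSES = ("low", "medium", "high")
LOW_MAX = 5.0   # low iff pIC50 <= 5
MEDIUM_MAX = 7.0  # medium iff 5 < pIC50 <= 7; high iff pIC50 > 7

DESCRIPTOR_COLUMNS = ("mol_wt", "log_p", "h_donors", "h_acceptors", "tpsa")

# silhouette below this across all k is reported as "no cluster structure"
NO_STRUCTURE_SILHOUETTE = 0.25


def classify_activity(pic50: float) -> str:
    """Map a pIC50 to its potency tier; boundaries 5 and 7 are inclusive below."""
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    if pic50 <= LOW_MAX:
        return "low"
    if pic50 <= MEDIUM_MAX:
        return "medium"
    return "high"


def predict_potency(
    model: QSARModel, candidates: list[CompoundRecord]
) -> tuple[dict[str, float], list[str]]:
    """Predict pIC50 for candidates with a fitted QSAR model.

    Returns (id → predicted pIC50, list of skipped ids). Candidates whose
    structures cannot be featurized are skipped with a log entry rather than
    aborting the profile.
    """
    predictions: dict[str, float] = {}
    skipped: list[str] = []
    usable: list[CompoundRecord] = []
    for c in candidates:
        try:
            mol_from_record(c)
            usable.append(c)
        except ValueError as exc:
            logger.warning("skipping unfeaturizable candidate %s: %s", c.id, exc)
            skipped.append(c.id)
    if usable:
        values = model.predict(usable)
        predictions = {c.id: float(v) for c, v in zip(usable, values)}
    return predictions, skipped


@dataclass
class ChooseKResult:
    """Outcome of cluster-count selection: silhouette winner plus elbow."""

    chosen_k: int
    elbow_k: int | None
    table: pd.DataFrame  # columns k, sse, silhouette
    has_structure: bool


def choose_k(
    features: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> ChooseKResult:
    """Select the number of clusters by silhouette, reporting the SSE elbow.

    The silhouette-maximizing k is chosen; the elbow (k with the largest
    second difference of the SSE curve) is reported alongside. When the best
    silhouette is weak the result is flagged as having no cluster structure.
    """
    X = np.asarray(features, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ValueError(
            f"k_range [{ks[0]}, {ks[-1]}] outside valid range [2, {X.shape[0] - 1}]"
        )
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        sil = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else float("nan")
        rows.append({"k": k, "sse": float(km.inertia_), "silhouette": sil})
    table = pd.DataFrame(rows)

    chosen_k = int(table.loc[table["silhouette"].idxmax(), "k"])
    elbow_k = None
    if len(ks) >= 3:
        sse = table["sse"].to_numpy()
        second_diff = sse[:-2] - 2 * sse[1:-1] + sse[2:]
        elbow_k = int(table["k"].iloc[1 + int(np.argmax(second_diff))])
    has_structure = bool(table["silhouette"].max() >= NO_STRUCTURE_SILHOUETTE)
    if not has_structure:
        logger.warning(
            "no cluster structure detected: best silhouette %.3f",
            table["silhouette"].max(),
        )
    return ChooseKResult(chosen_k=chosen_k, elbow_k=elbow_k, table=table, has_structure=has_structure)


@dataclass(frozen=True)
class ClusterAssignment:
    """One compound's cluster label and its distance to the cluster centroid."""

    compound_id: str
    cluster: int
    distance: float


def cluster_kmeans(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    ids: list[str] | None = None,
    n_init: int = 10,
) -> tuple[list[ClusterAssignment], float]:
    """K-means (Lloyd's algorithm, best of ``n_init`` restarts).

    Returns the per-compound assignments and the total within-cluster SSE.
    Labels are stable under a fixed seed. If a restart produces an empty
    cluster the fit is retried with a reseeded state and a warning.
    """
    X = np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if X.shape[0] <= k:
        raise ValueError(f"need more rows ({X.shape[0]}) than clusters ({k})")
    ids = ids if ids is not None else [str(i) for i in range(X.shape[0])]

    for attempt in range(3):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        labels = km.fit_predict(X)
        if len(set(labels)) == k:
            break
        logger.warning("empty cluster at seed %d; re-seeding", seed + attempt)
    distances = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
    assignments = [
        ClusterAssignment(compound_id=i, cluster=int(l), distance=float(d))
        for i, l, d in zip(ids, labels, distances)
    ]
    return assignments, float(km.inertia_)


def cluster_features(
    descriptor_table: pd.DataFrame, pic50s: dict[str, float]
) -> tuple[np.ndarray, list[str]]:
    """Standardized descriptor vectors concatenated with predicted pIC50.

    ``descriptor_table`` must be indexed by compound id and contain the five
    descriptor columns. Returns the feature matrix and the id order used.
    """
    ids = [i for i in descriptor_table.index if i in pic50s]
    sub = descriptor_table.loc[ids, list(DESCRIPTOR_COLUMNS)].astype(float)
    mat = np.column_stack([sub.to_numpy(), [pic50s[i] for i in ids]])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd, ids


def sar_summary(
    assignments: list[ClusterAssignment],
    descriptor_table: pd.DataFrame,
    pic50s: dict[str, float],
    fingerprints: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-cluster descriptor/potency statistics and a bit-frequency matrix.

    Returns a long-format table with mean/median/SD of each descriptor and of
    pIC50 per cluster, and (when fingerprints are given, rows aligned with
    ``assignments``) a cluster × bit count matrix whose rows sum to the
    cluster sizes and whose column sums equal the global bit counts.
    """
    by_id = {a.compound_id: a.cluster for a in assignments}
    ids = [a.compound_id for a in assignments]
    df = descriptor_table.loc[ids, list(DESCRIPTOR_COLUMNS)].astype(float).copy()
    df["pic50"] = [pic50s[i] for i in ids]
    df["cluster"] = [by_id[i] for i in ids]

    stats = (
        df.groupby("cluster")
        .agg(["mean", "median", "std", "count"])
        .round(6)
    )
    stats.columns = [f"{col}_{stat}" for col, stat in stats.columns]
    stats = stats.reset_index()

    bit_freq = None
    if fingerprints is not None:
        fp = np.asarray(fingerprints)
        if fp.shape[0] != len(assignments):
            raise ValueError("fingerprint rows must align with assignments")
        clusters = sorted({a.cluster for a in assignments})
        labels = np.array([a.cluster for a in assignments])
        bit_freq = pd.DataFrame(
            [fp[labels == c].sum(axis=0) for c in clusters],
            index=pd.Index(clusters, name="cluster"),
        )
    return stats, bit_freq


@dataclass(frozen=True)
class MCSResult:
    """Maximum common substructure of a set of molecules."""

    smarts: str
    n_atoms: int
    n_bonds: int
    scope: str = ""

    @property
    def is_empty(self) -> bool:
        return self.n_atoms == 0


def find_mcs(
    molecules: list[CompoundRecord | str | Chem.Mol],
    timeout_s: int = 10,
    scope: str = "",
) -> MCSResult:
    """Maximum common substructure under element + bond-order comparison.

    The returned SMARTS matches every input molecule; maximality holds within
    the timeout. An empty result (no common substructure of at least one
    atom) is returned with ``n_atoms == 0``.
    """
    if len(molecules) < 2:
        raise ValueError("MCS requires at least 2 molecules")
    mols = [
        m if isinstance(m, Chem.Mol) else mol_from_record(m) for m in molecules
    ]
    res = rdFMCS.FindMCS(
        mols,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=False,
        timeout=timeout_s,
    )
    if res.canceled:
        logger.warning("MCS search timed out after %ds; result may be suboptimal", timeout_s)
    if res.numAtoms == 0:
        return MCSResult(smarts="", n_atoms=0, n_bonds=0, scope=scope)
    return MCSResult(
        smarts=res.smartsString, n_atoms=res.numAtoms, n_bonds=res.numBonds, scope=scope
    )


def _load_group_library() -> dict[str, str]:
    text = (
        importlib.resources.files("ncscreen.data")
        .joinpath("functional_groups.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


_GROUP_PATTERNS: dict[str, Chem.Mol] | None = None


def _group_patterns(extra: dict[str, str] | None = None) -> dict[str, Chem.Mol]:
    global _GROUP_PATTERNS
    if _GROUP_PATTERNS is None:
        _GROUP_PATTERNS = {
            name: Chem.MolFromSmarts(smarts)
            for name, smarts in _load_group_library().items()
        }
    patterns = dict(_GROUP_PATTERNS)
    for name, smarts in (extra or {}).items():
        patterns[name] = Chem.MolFromSmarts(smarts)
    return patterns


def detect_functional_groups(
    molecule: CompoundRecord | str | Chem.Mol,
    extra_patterns: dict[str, str] | None = None,
) -> set[str]:
    """Names of functional groups present in a molecule.

    The shipped library covers ether, ketone, aldehyde, carboxyl, and
    aromatic, with exclusion rules so a carboxyl carbon is not double-counted
    as ketone or aldehyde and an ester oxygen is not counted as an ether.
    ``extra_patterns`` maps additional group names to SMARTS.
    """
    mol = molecule if isinstance(molecule, Chem.Mol) else mol_from_record(molecule)
    return {
        name
        for name, patt in _group_patterns(extra_patterns).items()
        if patt is not None and mol.HasSubstructMatch(patt)
    }


def tier_profiles(
    records: list[CompoundRecord],
    pic50s: dict[str, float],
    mcs_timeout_s: int = 10,
) -> dict[str, dict]:
    """Per-activity-tier MCS and functional-group profile.

    Groups compounds into potency tiers by predicted pIC50, then reports for
    each non-empty tier the member count, the tier MCS (when the tier has at
    least two members), and the functional-group occurrence counts.
    """
    tiers: dict[str, list[CompoundRecord]] = {c: [] for c in ACTIVITY_CLASSES}
    for r in records:
        if r.id in pic50s:
            tiers[classify_activity(pic50s[r.id])].append(r)
    out: dict[str, dict] = {}
    for tier, members in tiers.items():
        if not members:
            continue
        group_counts: dict[str, int] = {}
        for m in members:
            for g in detect_functional_groups(m):
                group_counts[g] = group_counts.get(g, 0) + 1
        entry: dict = {
            "n": len(members),
            "ids": sorted(m.id for m in members),
            "functional_groups": dict(sorted(group_counts.items())),
        }
        if len(members) >= 2:
            mcs = find_mcs(members, timeout_s=mcs_timeout_s, scope=tier)
            entry["mcs"] = {
                "smarts": mcs.smarts,
                "n_atoms": mcs.n_atoms,
                "n_bonds": mcs.n_bonds,
            }
        out[tier] = entry
    return out
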