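"""Similarity-based matching of candidate compounds to known active ligands.

A candidate is called a potential hit for a target when the cosine similarity
between its fingerprint and at least one of the target's known actives
exceeds a decision threshold (default 0.5, strictly greater). For binary
fingerprints the cosine lies in [0, 1] and equals
|bits(a) ∩ bits(b)| / sqrt(|bits(a)| · |bits(b)|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import CompoundRecord, Fingerprint

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class LabeledPair:
    """A ligand pair with a binary interaction label (1 = positive)."""

    ligand_a: Fingerprint
    ligand_b: Fingerprint
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class MatchResult:
    """Best-active similarity of one candidate against one target's actives."""

    candidate_id: str
    target: str
    best_similarity: float
    matched_ligand: str
    is_hit: bool


def cosine_similarity(a: Fingerprint | np.ndarray, b: Fingerprint | np.ndarray) -> float:
    """Cosine similarity dot(a,b)/(‖a‖‖b‖); symmetric, 1.0 for identical vectors.

    Raises on length mismatch or an all-zero vector (undefined norm).
    """
    va = np.asarray(a.bits if isinstance(a, Fingerprint) else a, dtype=float)
    vb = np.asarray(b.bits if isinstance(b, Fingerprint) else b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for an all-zero vector")
    return float(va @ vb / (na * nb))


def _similarity_matrix(cand: np.ndarray, act: np.ndarray) -> np.ndarray:
    """Pairwise cosine matrix between candidate rows and active rows."""
    cand = np.asarray(cand, dtype=float)
    act = np.asarray(act, dtype=float)
    cn = np.linalg.norm(cand, axis=1)
    an = np.linalg.norm(act, axis=1)
    if np.any(cn == 0) or np.any(an == 0):
        raise ValueError("cosine similarity is undefined for an all-zero vector")
    return (cand @ act.T) / np.outer(cn, an)


def predict_candidates(
    candidates: list[tuple[CompoundRecord, np.ndarray]],
    actives_by_target: dict[str, list[tuple[str, np.ndarray]]],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchResult]:
    """Score each candidate against every target's actives.

    ``candidates`` is a list of (record, fingerprint-bit-vector) pairs;
    ``actives_by_target`` maps target name to (ligand id, bit vector) pairs.
    For each (candidate, target) the best similarity over that target's
    actives is taken, and the pair is a hit iff it is strictly above the
    threshold. Results are sorted by similarity descending, ties broken by
    candidate id for a stable order.
    """
    results: list[MatchResult] = []
    for target, actives in actives_by_target.items():
        if not actives:
            raise ValueError(f"no active ligands for target {target!r}")
        act_ids = [aid for aid, _ in actives]
        act_mat = np.vstack([fp for _, fp in actives])
        cand_mat = np.vstack([fp for _, fp in candidates])
        sims = _similarity_matrix(cand_mat, act_mat)
        best_idx = sims.argmax(axis=1)
        for i, (record, _) in enumerate(candidates):
            best = float(sims[i, best_idx[i]])
            results.append(
                MatchResult(
                    candidate_id=record.id,
                    target=target,
                    best_similarity=best,
                    matched_ligand=act_ids[best_idx[i]],
                    is_hit=best > threshold,
                )
            )
    results.sort(key=lambda r: (-r.best_similarity, r.candidate_id, r.target))
    return results


def recall_score(results: list[MatchResult], truth: dict[tuple[str, str], int]) -> float:
    """Recall TP/(TP+FN) of hit calls against (candidate_id, target) labels."""
    tp = fn = 0
    for r in results:
        key = (r.candidate_id, r.target)
        if key not in truth:
            raise ValueError(f"missing truth label for {key}")
        if truth[key] == 1:
            if r.is_hit:
                tp += 1
            else:
                fn += 1
    if tp + fn == 0:
        raise ValueError("recall is undefined: no positive truth labels")
    return tp / (tp + fn)
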