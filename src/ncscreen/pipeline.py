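"""End-to-end screening pipeline: config, orchestration, and provenance.

Stages run in a fixed order — featurize, train-qsar, filter-ad, predict-nc,
potency, profile, bbb, sources — each consuming the previous stage's output.
A manifest (JSON) records the config hash, the seed, and per-stage row counts
so a run can be audited and reproduced; any stage failure halts the run with
an error naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bbb as bbb_mod
from . import chem, match, profiling, qsar, sources as sources_mod
from .fixtures import DEFAULT_TARGETS

logger = logging.getLogger(__name__)

STAGES = (
    "featurize",
    "train-qsar",
    "filter-ad",
    "predict-nc",
    "potency",
    "profile",
    "bbb",
    "sources",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All pipeline settings; round-trips through YAML unchanged."""

    activities: str = "activities.csv"
    candidates: str = "candidates.csv"
    out_dir: str = "run"
    n_bits: int = chem.DEFAULT_N_BITS
    radius: int = chem.DEFAULT_RADIUS
    train_fraction: float = 0.8
    k_folds: int = 5
    n_estimators: int = 500
    pic50_min: float = qsar.DEFAULT_PIC50_MIN
    residual_q: float = qsar.DEFAULT_RESIDUAL_Q
    similarity_threshold: float = match.DEFAULT_THRESHOLD
    k_min: int = 2
    k_max: int = 10
    pooled_potency_model: bool = True
    min_target_records: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.residual_q < 1:
            raise ValueError("residual_q must be in (0, 1)")
        if not 0 <= self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("require 2 <= k_min <= k_max")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _featurize_candidates(config: PipelineConfig):
    records, n_skipped = chem.read_compound_table(config.candidates)
    fps = chem.fingerprint_matrix(records, n_bits=config.n_bits, radius=config.radius)
    return records, fps, n_skipped


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    # featurize: read activity + candidate tables and fingerprint candidates
    stage = "featurize"
    try:
        activities, n_bad_act = qsar.read_activity_table(config.activities)
        candidates, cand_fps, n_bad_cand = _featurize_candidates(config)
        chem.write_compound_table(candidates, out / "candidates_featurized.csv")
        manifest["stages"][stage] = {
            "n_activities": len(activities),
            "n_candidates": len(candidates),
            "n_skipped_activities": n_bad_act,
            "n_skipped_candidates": n_bad_cand,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # train-qsar: one model per target with enough records
    stage = "train-qsar"
    try:
        by_target: dict[str, list[qsar.ActivityRecord]] = {}
        for rec in activities:
            by_target.setdefault(rec.target, []).append(rec)
        models: dict[str, qsar.QSARModel] = {}
        test_sets: dict[str, list[qsar.ActivityRecord]] = {}
        metrics_rows = []
        qcfg = qsar.QSARConfig(
            n_estimators=config.n_estimators,
            k_folds=config.k_folds,
            n_bits=config.n_bits,
            radius=config.radius,
            seed=config.seed,
        )
        for target, recs in sorted(by_target.items()):
            if len(recs) < config.min_target_records:
                logger.warning(
                    "target %s has %d records (< %d); skipped",
                    target, len(recs), config.min_target_records,
                )
                continue
            train, test = qsar.split_dataset(recs, config.train_fraction, config.seed)
            model = qsar.train_qsar(train, qcfg)
            model.test_metrics = qsar.evaluate_model(model, test)
            models[target] = model
            test_sets[target] = test
            model.save(out / "models" / target)
            metrics_rows.append(
                {"target": target, "n_train": len(train), "n_test": len(test),
                 **{f"test_{k}": v for k, v in model.test_metrics.items()}}
            )
        if not models:
            raise ValueError("no target had enough records to train a model")
        pd.DataFrame(metrics_rows).to_csv(out / "qsar_metrics.csv", index=False)
        manifest["stages"][stage] = {
            "n_models": len(models),
            "targets": sorted(models),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # filter-ad: potency pre-filter + residual-percentile domain filter
    stage = "filter-ad"
    try:
        filtered: dict[str, list[qsar.ActivityRecord]] = {}
        reports = []
        for target, model in models.items():
            kept, report = qsar.filter_applicability(
                by_target[target], model,
                q=config.residual_q, pic50_min=config.pic50_min,
            )
            filtered[target] = kept
            reports.append({"target": target, **report.as_dict()})
        pd.DataFrame(reports).to_csv(out / "ad_filter_report.csv", index=False)
        n_filtered = sum(len(v) for v in filtered.values())
        if n_filtered == 0:
            raise ValueError("applicability filter retained no ligands")
        manifest["stages"][stage] = {
            "n_input": sum(len(by_target[t]) for t in models),
            "n_retained": n_filtered,
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # predict-nc: cosine-similarity matching of candidates to filtered actives
    stage = "predict-nc"
    try:
        cand_pairs = list(zip(candidates, cand_fps))
        actives_by_target = {}
        for target, recs in filtered.items():
            if not recs:
                continue
            fps = models[target].featurize(recs)
            actives_by_target[target] = [
                (r.compound.id, fp) for r, fp in zip(recs, fps)
            ]
        results = match.predict_candidates(
            cand_pairs, actives_by_target, threshold=config.similarity_threshold
        )
        hits_df = pd.DataFrame(
            [
                {
                    "id": r.candidate_id,
                    "target": r.target,
                    "best_similarity": r.best_similarity,
                    "matched_ligand": r.matched_ligand,
                    "is_hit": r.is_hit,
                }
                for r in results
            ]
        )
        hits_df.to_csv(out / "hits.csv", index=False)
        hit_ids = sorted({r.candidate_id for r in results if r.is_hit})
        hit_records = [c for c in candidates if c.id in set(hit_ids)]
        manifest["stages"][stage] = {
            "n_candidates": len(candidates),
            "n_pairs": len(results),
            "n_hit_compounds": len(hit_ids),
        }
        if not hit_records:
            raise ValueError("no candidate passed the similarity threshold")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # potency: predict pIC50 of hit candidates with a pooled (or first) model
    stage = "potency"
    try:
        if config.pooled_potency_model:
            pooled_train = [
                qsar.ActivityRecord(r.compound, "pooled", r.ic50_nm, r.pic50)
                for recs in filtered.values()
                for r in recs
            ]
            potency_model = qsar.train_qsar(pooled_train, qcfg)
        else:
            potency_model = models[sorted(models)[0]]
        pic50s, skipped = profiling.predict_potency(potency_model, hit_records)
        potency_df = pd.DataFrame(
            [
                {"id": cid, "pic50_pred": v, "activity_class": profiling.classify_activity(v)}
                for cid, v in sorted(pic50s.items())
            ]
        )
        potency_df.to_csv(out / "potency.csv", index=False)
        manifest["stages"][stage] = {
            "n_input": len(hit_records),
            "n_predicted": len(pic50s),
            "n_skipped": len(skipped),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # profile: cluster-count selection, k-means, SAR and tier summaries
    stage = "profile"
    try:
        desc_rows = {
            r.id: chem.compute_descriptors(r).as_dict() for r in hit_records
        }
        desc_table = pd.DataFrame.from_dict(desc_rows, orient="index")
        X, ids = profiling.cluster_features(desc_table, pic50s)
        k_max = min(config.k_max, len(ids) - 1)
        choice = profiling.choose_k(
            X, range(config.k_min, k_max + 1), seed=config.seed
        )
        choice.table.to_csv(out / "choose_k.csv", index=False)
        assignments, sse = profiling.cluster_kmeans(
            X, choice.chosen_k, seed=config.seed, ids=ids
        )
        pd.DataFrame(
            [
                {"id": a.compound_id, "cluster": a.cluster, "distance": a.distance}
                for a in assignments
            ]
        ).to_csv(out / "clusters.csv", index=False)
        id_set = set(ids)
        fp_rows = np.vstack(
            [fp for c, fp in zip(candidates, cand_fps) if c.id in id_set]
        )
        order = [c.id for c in candidates if c.id in id_set]
        fp_rows = fp_rows[[order.index(i) for i in ids]]
        stats, bit_freq = profiling.sar_summary(assignments, desc_table, pic50s, fp_rows)
        stats.to_csv(out / "sar_summary.csv", index=False)
        if bit_freq is not None:
            bit_freq.loc[:, bit_freq.sum(axis=0) > 0].to_csv(out / "bit_frequency.csv")
        tiers = profiling.tier_profiles(hit_records, pic50s)
        (out / "mcs_per_class.json").write_text(json.dumps(tiers, indent=2))
        groups_df = pd.DataFrame(
            [
                {"id": r.id, "groups": ";".join(sorted(profiling.detect_functional_groups(r)))}
                for r in hit_records
            ]
        )
        groups_df.to_csv(out / "groups.csv", index=False)
        manifest["stages"][stage] = {
            "n_input": len(pic50s),
            "chosen_k": choice.chosen_k,
            "elbow_k": choice.elbow_k,
            "has_structure": choice.has_structure,
            "sse": sse,
            "tier_counts": {t: v["n"] for t, v in tiers.items()},
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # bbb: five-criterion permeability score for every hit candidate
    stage = "bbb"
    try:
        bbb_df = bbb_mod.score_table(hit_records)
        bbb_df.to_csv(out / "bbb.csv", index=False)
        manifest["stages"][stage] = {
            "n_input": len(hit_records),
            "n_scored": len(bbb_df),
            "n_perfect": int((bbb_df["score_percent"] == 100).sum()),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # sources: rank foods contributing hits; Venn over the top six
    stage = "sources"
    try:
        smap = sources_mod.SourceMap.from_records(hit_records)
        if smap.by_source:
            n_top = min(10, len(smap.by_source))
            top = sources_mod.top_sources_table(smap, n_top)
            top.to_csv(out / "top_sources.csv", index=False)
            venn_names = [s for s, _ in sources_mod.top_sources(smap, min(6, len(smap.by_source)))]
            if len(venn_names) >= 2:
                regions = sources_mod.venn_intersections(smap, venn_names)
                (out / "venn_regions.json").write_text(
                    json.dumps({"sources": venn_names, "regions": regions}, indent=2)
                )
            manifest["stages"][stage] = {
                "n_input": len(hit_records),
                "n_sources": len(smap.by_source),
            }
        else:
            manifest["stages"][stage] = {"n_input": len(hit_records), "n_sources": 0}
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
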