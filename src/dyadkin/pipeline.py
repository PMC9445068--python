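"""End-to-end orchestration: simulate -> extract -> anova -> classify -> rsa.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
one seed; per-stage child seeds are spawned deterministically so stages can
be re-run in isolation.  Outputs are plain CSV/JSON at fixed float precision
so re-running a saved config reproduces every file bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from dyadkin.scene_io import Scene, write_dataset
from dyadkin.synthetic_scenes import (
    EMOTIONS,
    ArchetypeParams,
    RaterModel,
    generate_dataset,
    simulate_ratings,
)
from dyadkin.intra_features import INTRA_FEATURES, reduce_intrapersonal
from dyadkin.inter_features import INTER_FEATURES, reduce_interpersonal
from dyadkin.group_stats import anova_table, recognition_vs_chance
from dyadkin.emotion_classifier import compare_models, model_spec
from dyadkin import rsa_pipeline as rsa

__all__ = [
    "FEATURE_ORDER",
    "extract_features",
    "features_table",
    "RunConfig",
    "run_all",
]

FEATURE_ORDER = tuple(INTRA_FEATURES) + tuple(INTER_FEATURES)

_FLOAT_FMT = "%.10g"

log = logging.getLogger("dyadkin")


def extract_features(scene: Scene) -> dict[str, float]:
    """All 20 named feature scalars of one scene."""
    out = dict(reduce_intrapersonal(scene))
    out.update(reduce_interpersonal(scene))
    return {k: out[k] for k in FEATURE_ORDER}


def features_table(scenes: list[Scene]) -> pd.DataFrame:
    """Scene-indexed table with the 20 feature columns plus ``emotion``."""
    rows = {}
    emotions = {}
    for scene in scenes:
        rows[scene.scene_id] = extract_features(scene)
        emotions[scene.scene_id] = scene.emotion
    table = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_ORDER)]
    table.index.name = "scene_id"
    table.insert(0, "emotion", pd.Series(emotions))
    return table


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    seed: int = 0
    out_dir: str = "run"
    n_scenes_per_emotion: int = 12
    jitter_rel_sd: float = 0.12
    archetypes: dict[str, dict] = field(default_factory=dict)  # overrides
    n_raters: int = 31
    valence_sd: float = 1.2
    n_trees: int = 200
    models: tuple[str, ...] = ("M1", "M2", "M3")
    rsa_statistic_emotion: str = "tau_a"
    rsa_statistic_valence: str = "pearson"
    n_permutations: int = 1000
    fdr_alpha: float = 0.05
    write_scenes: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def archetype_table(self) -> dict[str, ArchetypeParams] | None:
        if not self.archetypes:
            return None
        return {k: ArchetypeParams(**v) for k, v in self.archetypes.items()}


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, float_format=_FLOAT_FMT, index=index)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("scenes", "ratings", "classify", "rsa")
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}

    def stage(name: str):
        log.info("stage %s starting", name)
        return time.perf_counter()

    try:
        # --- simulate ---------------------------------------------------
        t0 = stage("simulate")
        scenes = generate_dataset(
            config.archetype_table(),
            n_scenes_per_emotion=config.n_scenes_per_emotion,
            seed=seeds["scenes"],
            jitter_rel_sd=config.jitter_rel_sd,
        )
        rater_model = RaterModel(
            n_raters=config.n_raters, valence_sd=config.valence_sd, seed=seeds["ratings"]
        )
        ratings = simulate_ratings(scenes, rater_model)
        if config.write_scenes:
            write_dataset(scenes, out / "scenes")
        _write_csv(ratings, out / "ratings.csv", index=False)
        summary["n_scenes"] = len(scenes)
        log.info("simulate done in %.1fs", time.perf_counter() - t0)

        # --- features ---------------------------------------------------
        t0 = stage("features")
        table = features_table(scenes)
        _write_csv(table, out / "features.csv")
        log.info("features done in %.1fs", time.perf_counter() - t0)

        # --- anova ------------------------------------------------------
        t0 = stage("anova")
        feats_only = table[list(FEATURE_ORDER)]
        anovas = anova_table(feats_only, table["emotion"])
        anova_rows = []
        for name, res in anovas.items():
            row = {
                "feature": name,
                "F": res.F,
                "df_between": res.df[0],
                "df_within": res.df[1],
                "p": res.p,
                "eta_sq": res.eta_sq,
            }
            for emo in EMOTIONS:
                row[f"mean_{emo}"] = res.group_means.get(emo, float("nan"))
                row[f"sem_{emo}"] = res.group_sems.get(emo, float("nan"))
            anova_rows.append(row)
        _write_csv(pd.DataFrame(anova_rows).set_index("feature"), out / "anova.csv")
        recog = recognition_vs_chance(ratings)
        _write_csv(recog, out / "recognition.csv")
        summary["recognition_accuracy"] = recog["accuracy"].to_dict()
        log.info("anova done in %.1fs", time.perf_counter() - t0)

        # --- classify ---------------------------------------------------
        t0 = stage("classify")
        specs = [
            model_spec(m, n_trees=config.n_trees, seed=seeds["classify"])
            for m in config.models
        ]
        reports = compare_models(feats_only, table["emotion"], specs=specs)
        (out / "classify").mkdir(exist_ok=True)
        summary["classification"] = {}
        for name, rep in reports.items():
            payload = {
                "model": name,
                "overall_accuracy": rep.overall_accuracy,
                "per_class_accuracy": rep.per_class_accuracy,
                "fold_predictions": rep.fold_predictions,
                "importance_mean": rep.importance_mean,
                "importance_std": rep.importance_std,
                "n_folds": rep.n_folds,
            }
            (out / "classify" / f"{name}.json").write_text(json.dumps(payload, indent=1))
            summary["classification"][name] = {
                "overall_accuracy": rep.overall_accuracy,
                "per_class_accuracy": rep.per_class_accuracy,
                "top_feature": max(rep.importance_mean, key=rep.importance_mean.get),
            }
        log.info("classify done in %.1fs", time.perf_counter() - t0)

        # --- rsa --------------------------------------------------------
        t0 = stage("rsa")
        rsa_dir = out / "rsa"
        rsa_dir.mkdir(exist_ok=True)
        categories = table["emotion"].to_dict()
        emo_model = rsa.model_rdm(categories, "emotion_model", "model_emotion")
        valence_class = {
            sid: ("positive" if emo in ("happiness", "affection") else "negative")
            for sid, emo in categories.items()
        }
        val_model = rsa.model_rdm(valence_class, "valence_model", "model_valence")
        f_rdms = rsa.feature_rdms(feats_only)
        intra_rdms = {k: f_rdms[k] for k in INTRA_FEATURES}
        inter_rdms = {k: f_rdms[k] for k in INTER_FEATURES}

        model_rdms = {"emotion_model": emo_model, "valence_model": val_model}
        for set_name, rdm_set in (("intra", intra_rdms), ("inter", inter_rdms)):
            taus, tests, mds = rsa.relate_models_to_features(
                model_rdms,
                rdm_set,
                n_permutations=config.n_permutations,
                seed=seeds["rsa"],
            )
            _write_csv(taus, rsa_dir / f"model_feature_tau_{set_name}.csv")
            _write_csv(tests, rsa_dir / f"model_feature_tests_{set_name}.csv", index=False)
            _write_csv(mds, rsa_dir / f"mds_{set_name}.csv")

        emo_subj, val_subj, emo_group, val_group = rsa.behavioural_rdms(ratings)
        summary["rsa"] = {}
        for tag, subj, stat in (
            ("emotion", emo_subj, config.rsa_statistic_emotion),
            ("valence", val_subj, config.rsa_statistic_valence),
        ):
            summ, per_subject, ceiling = rsa.relate_features_to_behaviour(
                f_rdms, subj, statistic=stat, fdr_alpha=config.fdr_alpha
            )
            pair_table, _ = rsa.pairwise_feature_tests(per_subject, config.fdr_alpha)
            _write_csv(summ, rsa_dir / f"feature_vs_{tag}.csv")
            _write_csv(per_subject, rsa_dir / f"per_subject_{tag}.csv")
            _write_csv(pair_table, rsa_dir / f"pairwise_{tag}.csv", index=False)
            best = summ["mean_corr"].idxmax()
            summary["rsa"][tag] = {
                "best_feature": str(best),
                "best_corr": float(summ["mean_corr"].max()),
                "noise_ceiling": [ceiling.lower, ceiling.upper],
            }
        log.info("rsa done in %.1fs", time.perf_counter() - t0)

        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        config.to_yaml(out / "config.yaml")
        return summary
    except Exception as exc:
        log.error("run aborted: %s", exc)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
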