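"""End-to-end orchestration: generate -> extract -> combine -> score -> refine.

`run_pipeline` executes the whole workflow at desk scale on a synthetic
corpus: corpus generation, train/devel split, the exhaustive feature-class
combination experiment for the trigger phase, AEE scoring with theoretical
bounds, and the greedy variant refinement.  All randomness derives from one
root seed; a manifest records the configuration, stage timings, and a
checksum for every artifact written.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .algorithm import aee_scores, bounds, greedy_refine
from .combinations import (
    CombinationRanking,
    enumerate_subsets,
    ranking_to_rows,
    run_experiment,
)
from .corpus import write_corpus
from .detector import DetectorConfig, FeatureCache, make_subset_evaluator
from .features import (
    TRIGGER_CLASS_NAMES,
    FeatureClassId,
)
from .synth import SynthConfig, generate, split

#: trigger classes with a defined modified variant
TRIGGER_VARIANTS = {
    4: FeatureClassId("trigger", 4, "prime"),
    6: FeatureClassId("trigger", 6, "prime"),
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _experiment(
    train_corpus, devel_corpus, classes_by_id: dict, config: DetectorConfig
) -> CombinationRanking:
    cache = FeatureCache(
        train_corpus,
        devel_corpus,
        "trigger",
        list(classes_by_id.values()),
        window=config.window,
        depth=config.depth,
    )
    evaluator = make_subset_evaluator(cache, config)
    subsets = enumerate_subsets(sorted(classes_by_id))
    return run_experiment(subsets, evaluator, n=len(classes_by_id))


def aee_report(ranking: CombinationRanking) -> dict:
    """Per-feature AEE1/AEE2 plus theoretical bounds, tables-style layout."""
    table = aee_scores(ranking)
    bnd = bounds(ranking.n)
    report = {
        "n_classes": ranking.n,
        "n_ranked": len(ranking),
        "complete": ranking.complete,
        "features": [
            {
                "id": f,
                "name": TRIGGER_CLASS_NAMES.get(f, str(f)),
                "aee1": round(table.aee1[f], 2),
                "aee2": round(table.aee2[f], 2),
            }
            for f in table.features
        ],
        "theoretical": {
            "max_aee1": round(bnd.max_aee1, 2),
            "min_aee1": round(bnd.min_aee1, 2),
            "max_aee2": round(bnd.max_aee2, 2),
            "min_aee2": round(bnd.min_aee2, 2),
        },
    }
    if not ranking.complete:
        report["warning"] = (
            f"incomplete ranking ({len(ranking)} of {2**ranking.n - 1} subsets); "
            "bounds refer to complete rankings"
        )
    return report


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    synth_config: SynthConfig | None = None,
    detector_config: DetectorConfig | None = None,
    refine: bool = True,
) -> dict:
    """Run all stages and return the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_config = synth_config or SynthConfig(seed=seed)
    if detector_config is None:
        detector_config = DetectorConfig.for_phase(
            "trigger", [1, 2, 3, 4, 5, 6], seed=seed
        )
    manifest: dict = {
        "tool_version": __version__,
        "seed": seed,
        "synth_config": {
            k: v for k, v in asdict(synth_config).items() if k != "priors"
        },
        "priors": synth_config.priors,
        "detector_config": {
            "C": detector_config.C,
            "beta": detector_config.beta,
            "window": detector_config.window,
            "depth": detector_config.depth,
            "classes": [str(c) for c in detector_config.classes],
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        manifest["stages"][name] = {"started": time.time()}

    def done(name):
        entry = manifest["stages"][name]
        entry["seconds"] = round(time.time() - entry["started"], 3)
        del entry["started"]

    def emit(name: str, path: Path, text: str) -> None:
        path.write_text(text)
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    stage("generate")
    corpus = generate(synth_config, seed=seed)
    emit("corpus", out / "corpus.xml", write_corpus(corpus))
    done("generate")

    stage("split")
    train_c, devel_c, test_c = split(corpus, (0.6, 0.2, 0.2), seed=seed)
    emit("train", out / "train.xml", write_corpus(train_c))
    emit("devel", out / "devel.xml", write_corpus(devel_c))
    emit("test", out / "test.xml", write_corpus(test_c))
    done("split")

    stage("experiment")
    base_classes = {c.id: c for c in detector_config.classes}
    ranking = _experiment(train_c, devel_c, base_classes, detector_config)
    rows = ranking_to_rows(ranking)
    emit(
        "ranking",
        out / "ranking.tsv",
        "rank\tsubset\tf_score\tfeature_size\n"
        + "".join(
            f"{r['rank']}\t{r['subset']}\t{r['f_score']}\t{r['feature_size']}\n"
            for r in rows
        ),
    )
    done("experiment")

    stage("aee")
    report = aee_report(ranking)
    done("aee")

    refinement_audit = []
    if refine:
        stage("refine")
        variants = {
            fid: var for fid, var in TRIGGER_VARIANTS.items() if fid in base_classes
        }
        result = greedy_refine(
            ranking,
            variants,
            rerun=lambda classes: _experiment(
                train_c, devel_c, classes, detector_config
            ),
            classes=base_classes,
        )
        refinement_audit = [
            {
                "swapped": [str(base_classes[f]) + "->" + str(result.classes[f])
                            if f in result.classes else str(f)
                            for f in step.swapped],
                "best_subset": "&".join(str(x) for x in sorted(step.best_subset)),
                "best_f": round(100.0 * step.best_f, 2),
                "accepted": step.accepted,
            }
            for step in result.history
        ]
        report["refinement"] = {
            "final_classes": [str(result.classes[f]) for f in sorted(result.classes)],
            "final_best_f": round(100.0 * result.best_f, 2),
            "audit": refinement_audit,
            "warnings": result.warnings,
        }
        done("refine")

    report["best_subset"] = rows[0]["subset"] if rows else None
    report["best_f"] = rows[0]["f_score"] if rows else None
    emit("report", out / "report.json", json.dumps(report, indent=2, sort_keys=True))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
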