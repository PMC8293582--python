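"""End-to-end driver: ingest -> map -> reduce -> evaluate -> vote.

Wires the stages together under one run configuration with a single master
seed, so a full run is deterministic and independent of chunk processing
order. Also provides a fixture mode that runs the voting layer alone on
the packaged reference lists.
"""

from __future__ import annotations

import json
import logging
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ingest import Chunk, FeatureSchema, ingest_file, schema_from_cohort_config
from .mapreduce import map_chunk, shuffle_merge
from .selectors import (
    DEFAULT_SELECTOR_IDS,
    ModelPerformance,
    RankedFeatureList,
    SelectorSpec,
    evaluate_performance,
    run_selector,
)
from .synthetic import CohortConfig, generate_cohort, inject_missingness, write_cohort
from .voting import (
    STRATEGIES,
    VoteTally,
    WeightScheme,
    assign_model_weights,
    canonicalize,
    default_rank_weights,
    select_top_k,
    tally_votes,
    write_tally,
)

logger = logging.getLogger("bfsmr.pipeline")

__all__ = ["RunConfig", "BFSMRResult", "run_bfsmr", "export_report"]


@dataclass
class RunConfig:
    """All knobs of one ensemble feature-selection run."""

    input_path: str | None = None
    cohort: CohortConfig | None = None  # synthetic mode if set
    schema: FeatureSchema | None = None
    chunk_size: int = 10_000
    split_ratio: float = 0.8
    bootstrap_frac: float = 0.1
    k: int = 10
    selector_ids: tuple[str, ...] = DEFAULT_SELECTOR_IDS
    selector_params: dict = field(default_factory=dict)  # selector_id -> params dict
    strategy: str = "voting3"
    tiers: Mapping[str, str] | str = "auto"
    tier_ladder: tuple[float, ...] = (1.0, 0.5, 0.2)
    aliases: dict = field(default_factory=dict)
    percentile: float = 90.0
    positive_label: int = 1
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_path is None and self.cohort is None:
            raise ValueError("need an input path or a synthetic cohort config")
        if len(set(self.selector_ids)) != len(self.selector_ids):
            raise ValueError("selector ids must be unique")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.split_ratio < 1 or not 0 < self.bootstrap_frac <= 1:
            raise ValueError("split_ratio in (0,1), bootstrap_frac in (0,1] required")


@dataclass
class BFSMRResult:
    ranked_lists: list[RankedFeatureList]
    performances: list[ModelPerformance]
    tallies: dict[str, VoteTally]
    final_top_k: list[tuple[str, float]]
    feature_space: list[str]
    manifest: dict


def _selector_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, 0x5E1, index]).generate_state(1)[0] % (2**31))


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_bfsmr(config: RunConfig) -> BFSMRResult:
    """Execute the full pipeline; deterministic given ``config.master_seed``.

    Set-id groups are processed independently (running them in any order,
    or concurrently, gives identical results) because every random draw is
    seeded from the master seed and a stage-local key.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    tmp_holder = None
    with _stage("ingest"):
        if config.cohort is not None:
            cohort = inject_missingness(generate_cohort(config.cohort))
            if out_dir:
                input_path = out_dir / "cohort.csv"
            else:
                tmp_holder = tempfile.TemporaryDirectory()
                input_path = Path(tmp_holder.name) / "cohort.csv"
            write_cohort(cohort, input_path)
            schema = config.schema or schema_from_cohort_config(config.cohort)
        else:
            input_path = Path(config.input_path)
            if config.schema is None:
                raise ValueError("a FeatureSchema is required when reading a file")
            schema = config.schema
        chunks: dict[int, Chunk] = {}
        for chunk in ingest_file(
            input_path, schema, chunk_size=config.chunk_size, percentile=config.percentile
        ):
            chunks[chunk.chunk_index] = chunk

    M = len(config.selector_ids)
    with _stage("map"):
        assignments = []
        for chunk in chunks.values():
            assignments.extend(
                map_chunk(
                    chunk,
                    M=M,
                    split_ratio=config.split_ratio,
                    frac=config.bootstrap_frac,
                    master_seed=config.master_seed,
                )
            )

    with _stage("shuffle"):
        merged = shuffle_merge(assignments, chunks)
        if 0 not in merged.sets:
            raise ValueError("no test pool (sid 0) — all chunks were skipped?")
        X_test, y_test = merged[0]

    ranked_lists: list[RankedFeatureList] = []
    performances: list[ModelPerformance] = []
    with _stage("reduce"):
        for i, selector_id in enumerate(config.selector_ids):
            sid = i + 1
            X, y = merged[sid]
            spec = SelectorSpec(
                selector_id=selector_id,
                k=config.k,
                params=config.selector_params.get(selector_id, {}),
                seed=_selector_seed(config.master_seed, i),
            )
            result = run_selector(spec, X, y, merged.feature_names)
            ranked_lists.append(result.ranked)
            performances.append(
                evaluate_performance(
                    result, X_test, y_test, positive_label=config.positive_label
                )
            )

    with _stage("vote"):
        canonical, feature_space = canonicalize(ranked_lists, config.aliases)
        w2 = assign_model_weights(performances, config.tiers, ladder=config.tier_ladder)
        scheme = WeightScheme(
            w1=default_rank_weights(config.k),
            w2=w2,
            rank_tiers=dict(config.tiers) if isinstance(config.tiers, Mapping) else {},
        )
        tallies = {s: tally_votes(canonical, s, scheme) for s in STRATEGIES}
        final = select_top_k(tallies[config.strategy], config.k)

    n_labeled = sum(c.n_records for c in chunks.values())
    n_dropped = sum(c.n_dropped for c in chunks.values())
    manifest = {
        "config": {
            "chunk_size": config.chunk_size,
            "split_ratio": config.split_ratio,
            "bootstrap_frac": config.bootstrap_frac,
            "k": config.k,
            "selector_ids": list(config.selector_ids),
            "strategy": config.strategy,
            "percentile": config.percentile,
            "master_seed": config.master_seed,
            "synthetic": config.cohort is not None,
        },
        "n_input_rows": n_labeled + n_dropped,
        "n_labeled_rows": n_labeled,
        "n_dropped_rows": n_dropped,
        "n_chunks": len(chunks),
        "set_sizes": {str(sid): int(merged[sid][0].shape[0]) for sid in merged.sids},
        "test_prevalence": float(np.mean(y_test)),
        "majority_baseline_accuracy": float(max(np.mean(y_test), 1.0 - np.mean(y_test))),
        "selector_seeds": {
            sel: _selector_seed(config.master_seed, i)
            for i, sel in enumerate(config.selector_ids)
        },
        "model_weights": {k: float(v) for k, v in w2.items()},
    }
    if tmp_holder is not None:
        tmp_holder.cleanup()

    result = BFSMRResult(
        ranked_lists=ranked_lists,
        performances=performances,
        tallies=tallies,
        final_top_k=final,
        feature_space=feature_space,
        manifest=manifest,
    )
    if out_dir:
        export_report(result, out_dir)
    return result


def export_report(result: BFSMRResult, path: str | Path) -> list[Path]:
    """Write the run's tables as delimited text plus a score-share figure.

    Outputs: per-selector ranked lists, the performance table, the
    per-strategy vote tally, the final top-K list, the run manifest, and a
    bar chart of each feature's percentage share of the total vote mass.
    Re-exporting the same result writes byte-identical text files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = path / "ranked_lists.csv"
    with open(p, "w") as fh:
        fh.write("selector_id,rank,feature,importance,sign\n")
        for lst in result.ranked_lists:
            for e in lst.entries:
                fh.write(f"{lst.selector_id},{e.rank},{e.feature},{e.importance:.6g},{e.sign}\n")
    written.append(p)

    p = path / "performance.csv"
    with open(p, "w") as fh:
        fh.write("selector_id,accuracy,f_score,n_test\n")
        for perf in result.performances:
            fh.write(f"{perf.selector_id},{perf.accuracy:.4f},{perf.f_score:.4f},{perf.n_test}\n")
    written.append(p)

    written.append(write_tally(result.tallies, path / "vote_tally.csv"))

    p = path / "top_features.csv"
    with open(p, "w") as fh:
        fh.write("rank,feature,score\n")
        for r, (feat, score) in enumerate(result.final_top_k, start=1):
            fh.write(f"{r},{feat},{score:.1f}\n")
    written.append(p)

    p = path / "manifest.json"
    p.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)

    written.append(_score_share_figure(result, path / "score_share.png"))
    return written


def _score_share_figure(result: BFSMRResult, path: Path) -> Path:
    """Percentage of each feature's score out of the whole set, per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strategies = list(result.tallies)
    features = [f for f, _ in result.final_top_k] or result.feature_space
    fig, ax = plt.subplots(figsize=(8, max(3, 0.35 * len(features))))
    y_pos = np.arange(len(features), dtype=float)
    height = 0.8 / max(len(strategies), 1)
    for i, s in enumerate(strategies):
        tally = result.tallies[s]
        total = tally.total or 1.0
        shares = [100.0 * float(tally.scores.get(f, 0)) / total for f in features]
        ax.barh(y_pos + i * height, shares, height=height, label=s)
    ax.set_yticks(y_pos + 0.4 - height / 2)
    ax.set_yticklabels(features)
    ax.invert_yaxis()
    ax.set_xlabel("share of total voting score (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
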