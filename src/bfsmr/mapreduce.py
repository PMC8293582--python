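"""Map and shuffle stages: per-chunk splitting, bootstrap draws, merging by set id.

Each chunk is split once into a train and a test partition. The test
partition is emitted whole under set id 0 and is never touched by any
training-side draw; M bootstrap samples (with replacement, uniform over
train rows) are emitted under set ids 1..M. Merging stacks rows with the
same set id across chunks in canonical (chunk_index, draw) order, so the
result is independent of the order in which chunks were processed.

Seeding is per chunk — the RNG for chunk p derives from
(master_seed, chunk_index) — which makes the whole stage reproducible and
trivially parallelizable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .ingest import Chunk

__all__ = ["SampleAssignment", "MergedSets", "map_chunk", "shuffle_merge", "spill_merged_sets"]


@dataclass(frozen=True)
class SampleAssignment:
    """Row indices (into one chunk) for one set id.

    sid 0 carries the chunk's full test partition (no multiplicity);
    sids >= 1 carry with-replacement bootstrap draws from the train
    partition and may repeat indices.
    """

    sid: int
    chunk_index: int
    row_indices: np.ndarray


@dataclass
class MergedSets:
    """Per-sid pooled matrices and labels over all chunks."""

    sets: dict[int, tuple[np.ndarray, np.ndarray]]
    feature_names: list[str]

    def __getitem__(self, sid: int) -> tuple[np.ndarray, np.ndarray]:
        return self.sets[sid]

    @property
    def sids(self) -> list[int]:
        return sorted(self.sets)


def _chunk_rng(master_seed: int, chunk_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, chunk_index]))


def map_chunk(
    chunk: Chunk,
    M: int,
    split_ratio: float = 0.8,
    frac: float = 0.1,
    master_seed: int = 0,
) -> list[SampleAssignment]:
    """Split one chunk and draw its M bootstrap samples.

    Test partition size is round((1 - split_ratio) * n); each bootstrap
    sample has floor(frac * train size) rows. A chunk with fewer than M + 1
    rows is skipped with a warning.
    """
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must be in (0, 1)")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if M < 1:
        raise ValueError("M must be >= 1")
    n = chunk.n_records
    if n < M + 1:
        warnings.warn(
            f"chunk {chunk.chunk_index} has {n} rows (< M+1={M + 1}); skipped", stacklevel=2
        )
        return []
    rng = _chunk_rng(master_seed, chunk.chunk_index)
    perm = rng.permutation(n)
    n_test = int(np.floor((1.0 - split_ratio) * n + 0.5))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    sample_size = int(np.floor(frac * len(train_idx)))
    out = [SampleAssignment(sid=0, chunk_index=chunk.chunk_index, row_indices=test_idx)]
    for sid in range(1, M + 1):
        draws = rng.integers(0, len(train_idx), size=sample_size)
        out.append(
            SampleAssignment(
                sid=sid, chunk_index=chunk.chunk_index, row_indices=train_idx[draws]
            )
        )
    return out


def shuffle_merge(
    assignments: Iterable[SampleAssignment], chunks: Mapping[int, Chunk] | Iterable[Chunk]
) -> MergedSets:
    """Pool rows by set id across chunks, stacking in (chunk_index, draw) order."""
    if not isinstance(chunks, Mapping):
        chunks = {c.chunk_index: c for c in chunks}
    by_sid: dict[int, list[SampleAssignment]] = {}
    for a in assignments:
        by_sid.setdefault(a.sid, []).append(a)
    feature_names: list[str] = []
    if chunks:
        feature_names = next(iter(chunks.values())).feature_names
    sets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for sid, group in by_sid.items():
        group = sorted(group, key=lambda a: a.chunk_index)
        xs = [chunks[a.chunk_index].matrix[a.row_indices] for a in group]
        ys = [chunks[a.chunk_index].labels[a.row_indices] for a in group]
        sets[sid] = (np.vstack(xs), np.concatenate(ys))
    return MergedSets(sets=sets, feature_names=feature_names)


def spill_merged_sets(merged: MergedSets, out_dir: str | Path, delimiter: str = ",") -> list[Path]:
    """Optionally persist each sid pool as one delimited text file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    header = delimiter.join(merged.feature_names + ["label"])
    for sid in merged.sids:
        X, y = merged[sid]
        path = out_dir / f"set_sid{sid}.csv"
        table = np.column_stack([X, y.astype(float)])
        np.savetxt(path, table, delimiter=delimiter, header=header, comments="")
        paths.append(path)
    return paths
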