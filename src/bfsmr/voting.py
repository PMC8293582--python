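"""Weighted rank-fusion voting across selector feature lists.

The ensemble's final ranking is a vote over the union feature space F of
the M per-selector top-K lists. Three strategies of increasing refinement:

* voting1 — every list appearance contributes one vote;
* voting2 — an appearance at rank k contributes the rank weight w1_k
  (default w1_k = K + 1 - k, a Borda-style linear ladder);
* voting3 — an appearance at rank k in selector j's list contributes
  w1_k * w2_j, where the model weight w2_j reflects the selector's
  performance tier (default ladder 1 / 0.5 / 0.2).

Weights are handled as exact rationals internally so tallies carry no
floating-point accumulation error; reported scores are exact decimals.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .selectors import ModelPerformance, RankEntry, RankedFeatureList

__all__ = [
    "AliasMap",
    "WeightScheme",
    "VoteTally",
    "STRATEGIES",
    "DEFAULT_ALIASES",
    "REFERENCE_TIERS",
    "DEFAULT_TIER_LADDER",
    "default_rank_weights",
    "canonicalize",
    "assign_model_weights",
    "tally_votes",
    "select_top_k",
    "load_reference_lists",
    "write_tally",
]

STRATEGIES = ("voting1", "voting2", "voting3")

#: folds the negatively-signed "adequate" physical-exercise dummy into its
#: "inadequate" counterpart — the one merge the packaged reference lists need
DEFAULT_ALIASES: dict[str, str] = {"PE_Adequate": "PE_Inadequate"}

#: performance tiers of the five reference selectors (regularized linear
#: models strongest; filter and SVM-RFE intermediate; forest weakest)
REFERENCE_TIERS: dict[str, str] = {
    "lasso": "tier1",
    "ridge": "tier1",
    "filter_mi": "tier2",
    "svm_rfe": "tier2",
    "random_forest": "tier3",
}

DEFAULT_TIER_LADDER: tuple[float, ...] = (1.0, 0.5, 0.2)


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclass(frozen=True)
class AliasMap:
    """Encoded-name to canonical-name folding (canonical names are fixed points)."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.pairs.items():
            if dst in self.pairs and self.pairs[dst] != dst:
                raise ValueError(f"alias chain {src} -> {dst} -> {self.pairs[dst]}")

    def resolve(self, name: str) -> str:
        return self.pairs.get(name, name)


@dataclass
class WeightScheme:
    """Rank weights w1 (per list position) and model weights w2 (per selector)."""

    w1: dict[int, Fraction]
    w2: dict[str, Fraction]
    rank_tiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w1 = {int(k): _frac(v) for k, v in self.w1.items()}
        self.w2 = {k: _frac(v) for k, v in self.w2.items()}
        ranks = sorted(self.w1)
        if any(self.w1[r] <= 0 for r in ranks):
            raise ValueError("w1 must be strictly positive")
        for a, b in zip(ranks, ranks[1:]):
            if self.w1[a] < self.w1[b]:
                raise ValueError("w1 must be non-increasing in rank")
        if any(v <= 0 for v in self.w2.values()):
            raise ValueError("w2 must be positive")


def default_rank_weights(k: int = 10) -> dict[int, int]:
    """Linear rank ladder: rank 1 -> K, ..., rank K -> 1."""
    return {r: k + 1 - r for r in range(1, k + 1)}


@dataclass
class VoteTally:
    """Per-canonical-feature voting scores under one strategy."""

    strategy: str
    scores: dict[str, Fraction]
    support: dict[str, int]  # number of lists containing the feature
    feature_space: list[str]

    def score(self, feature: str) -> float:
        return float(self.scores[feature])

    def as_floats(self) -> dict[str, float]:
        return {f: float(s) for f, s in self.scores.items()}

    @property
    def total(self) -> float:
        return float(sum(self.scores.values(), Fraction(0)))


def canonicalize(
    lists: Sequence[RankedFeatureList], aliases: AliasMap | Mapping[str, str] | None = None
) -> tuple[list[RankedFeatureList], list[str]]:
    """Map list entries through the alias map and form the union feature space F.

    Ranks are untouched; if aliasing makes two entries of one list share a
    canonical name, both entries are kept (each contributes its own rank
    weight downstream).
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    if aliases is None:
        aliases = AliasMap({})
    elif not isinstance(aliases, AliasMap):
        aliases = AliasMap(dict(aliases))
    out: list[RankedFeatureList] = []
    names: set[str] = set()
    for lst in lists:
        entries = [
            RankEntry(
                feature=aliases.resolve(e.feature),
                rank=e.rank,
                importance=e.importance,
                sign=e.sign,
            )
            for e in lst.entries
        ]
        names.update(e.feature for e in entries)
        out.append(RankedFeatureList(selector_id=lst.selector_id, entries=entries))
    return out, sorted(names)


def assign_model_weights(
    performances: Sequence[ModelPerformance],
    tiers: Mapping[str, str] | str = "auto",
    ladder: Sequence[float] = DEFAULT_TIER_LADDER,
    tol: float = 0.01,
) -> dict[str, Fraction]:
    """Model weights w2 from performance tiers.

    An explicit selector -> tier map takes precedence (tiers ordered by
    first appearance of their label in the ladder sense, i.e. sorted tier
    labels get ladder weights in order). In "auto" mode selectors are
    sorted by mean(accuracy, F-score) and grouped greedily: a new tier
    starts when a selector falls more than ``tol`` below its tier's best.
    """
    ladder = [_frac(w) for w in ladder]
    known = {p.selector_id for p in performances}
    if isinstance(tiers, str):
        if tiers != "auto":
            raise ValueError("tiers must be a mapping or 'auto'")
        ranked = sorted(performances, key=lambda p: (-(p.accuracy + p.f_score) / 2, p.selector_id))
        weights: dict[str, Fraction] = {}
        tier_idx = 0
        tier_top = None
        for p in ranked:
            score = (p.accuracy + p.f_score) / 2
            if tier_top is None:
                tier_top = score
            elif score < tier_top - tol:
                tier_idx += 1
                tier_top = score
            weights[p.selector_id] = ladder[min(tier_idx, len(ladder) - 1)]
        return weights
    unknown = set(tiers) - known
    if unknown:
        raise ValueError(f"tier map names unknown selectors: {sorted(unknown)}")
    missing = known - set(tiers)
    if missing:
        raise ValueError(f"tier map missing selectors: {sorted(missing)}")
    labels = sorted(set(tiers.values()))
    label_weight = {
        lab: ladder[min(i, len(ladder) - 1)] for i, lab in enumerate(labels)
    }
    return {sel: label_weight[lab] for sel, lab in tiers.items()}


def tally_votes(
    lists: Sequence[RankedFeatureList],
    strategy: str,
    scheme: WeightScheme | None = None,
) -> VoteTally:
    """Sum each canonical feature's weighted votes over all lists."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy != "voting1" and scheme is None:
        raise ValueError(f"{strategy} requires a WeightScheme")
    scores: dict[str, Fraction] = {}
    support: dict[str, set[str]] = {}
    for lst in lists:
        for e in lst.entries:
            if strategy == "voting1":
                w = Fraction(1)
            else:
                try:
                    w = scheme.w1[e.rank]
                except KeyError:
                    raise ValueError(f"no rank weight w1 for rank {e.rank}") from None
                if strategy == "voting3":
                    try:
                        w *= scheme.w2[lst.selector_id]
                    except KeyError:
                        raise ValueError(
                            f"no model weight w2 for selector {lst.selector_id!r}"
                        ) from None
            scores[e.feature] = scores.get(e.feature, Fraction(0)) + w
            support.setdefault(e.feature, set()).add(lst.selector_id)
    return VoteTally(
        strategy=strategy,
        scores=scores,
        support={f: len(s) for f, s in support.items()},
        feature_space=sorted(scores),
    )


def select_top_k(tally: VoteTally, k: int) -> list[tuple[str, float]]:
    """Top-K features by score; ties broken by (support desc, name asc)."""
    if k > len(tally.feature_space):
        warnings.warn(
            f"K={k} exceeds |F|={len(tally.feature_space)}; returning all features",
            stacklevel=2,
        )
    ordered = sorted(
        tally.scores.items(),
        key=lambda kv: (-kv[1], -tally.support[kv[0]], kv[0]),
    )
    return [(f, float(s)) for f, s in ordered[:k]]


# ---------------------------------------------------------------- fixture IO


def load_reference_lists(path: str | Path | None = None) -> list[RankedFeatureList]:
    """Load the packaged five top-10 reference lists (selector, rank, feature, sign).

    List-position importances (K + 1 - rank) are attached so the objects
    satisfy the ranked-list invariants; the voting layer uses ranks only.
    """
    if path is None:
        source = resources.files("bfsmr.data").joinpath("table1_lists.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    by_selector: dict[str, list[RankEntry]] = {}
    for row in rows:
        by_selector.setdefault(row["selector_id"], []).append(
            RankEntry(
                feature=row["feature"],
                rank=int(row["rank"]),
                importance=0.0,
                sign=row["sign"],
            )
        )
    lists = []
    for selector_id, entries in by_selector.items():
        entries.sort(key=lambda e: e.rank)
        k = len(entries)
        entries = [
            RankEntry(e.feature, e.rank, float(k + 1 - e.rank), e.sign) for e in entries
        ]
        lists.append(RankedFeatureList(selector_id=selector_id, entries=entries))
    return lists


def write_tally(
    tallies: Mapping[str, VoteTally], path: str | Path, decimals: int = 1
) -> Path:
    """Write per-strategy scores as delimited text (feature, voting1..3)."""
    path = Path(path)
    strategies = [s for s in STRATEGIES if s in tallies]
    features: list[str] = sorted(
        {f for t in tallies.values() for f in t.feature_space}
    )
    order_key = tallies[strategies[-1]] if strategies else None
    if order_key is not None:
        features.sort(key=lambda f: (-order_key.scores.get(f, Fraction(0)), f))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature"] + strategies)
        for f in features:
            writer.writerow(
                [f]
                + [
                    f"{float(tallies[s].scores.get(f, Fraction(0))):.{decimals}f}"
                    for s in strategies
                ]
            )
    return path
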