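"""Virtual-screening benchmark: ranking, retrieval metrics, rank aggregation.

A labelled dataset (actives/decoys) is scored against a small set of query
actives by *max fusion* (each member's score is its best similarity to any
query), then ranked and evaluated with the standard early-recognition
metrics: ROC AUC, enrichment factors EF1/EF5, and the exponentially weighted
RIE and BEDROC at alpha = 20 and 100.  Across datasets, competing fingerprint
variants are compared by their average rank per metric.

Tie handling is pessimistic for actives: within a tie block decoys are ranked
first, so reported enrichment never benefits from score ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DegenerateLabelsError",
    "score_by_max_fusion",
    "auc",
    "enrichment_factor",
    "rie",
    "bedroc",
    "METRICS",
    "ScreeningDataset",
    "compute_all_metrics",
    "run_benchmark",
    "average_ranks",
]

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """Metrics need at least one active and one decoy."""


def _as_active_mask(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bi":
        return arr.astype(bool)
    return arr == "active"


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    actives = _as_active_mask(labels)
    if scores.shape != actives.shape:
        raise ValueError("scores and labels must be aligned")
    if actives.all() or not actives.any():
        raise DegenerateLabelsError("need at least one active and one decoy")
    return scores, actives


def score_by_max_fusion(
    query_fps: Sequence,
    dataset_fps: Sequence,
    similarity: Callable,
) -> np.ndarray:
    """Score each dataset member by its best similarity to any query."""
    if len(query_fps) == 0:
        raise ValueError("need at least one query fingerprint")
    scores = np.empty(len(dataset_fps))
    for i, fp in enumerate(dataset_fps):
        scores[i] = max(similarity(q, fp) for q in query_fps)
    return scores


def _pessimistic_ranks(scores: np.ndarray, actives: np.ndarray) -> np.ndarray:
    """1-based ranks of the actives, best score = rank 1, decoys first in ties."""
    # sort by descending score; within a tie block decoys (False) precede actives
    order = np.lexsort((actives, -scores))
    ranks = np.empty(len(scores), dtype=np.int64)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks[actives]


def auc(scores, labels) -> float:
    """Probability that a random active outscores a random decoy (ties count half)."""
    scores, actives = _check(scores, labels)
    n_act = int(actives.sum())
    n_dec = len(scores) - n_act
    ranks = rankdata(scores)  # average ranks, ascending
    u = ranks[actives].sum() - n_act * (n_act + 1) / 2
    return float(u / (n_act * n_dec))


def enrichment_factor(scores, labels, fraction: float) -> float:
    """Active rate in the top ``fraction`` of the ranking over the base rate."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores, actives = _check(scores, labels)
    n = len(scores)
    top = math.ceil(fraction * n)
    act_ranks = _pessimistic_ranks(scores, actives)
    hits = int((act_ranks <= top).sum())
    return (hits / top) / (actives.sum() / n)


def _rie_sum(ranks: np.ndarray, n_total: int, alpha: float) -> float:
    return float(np.exp(-alpha * ranks / n_total).sum())


def rie(scores, labels, alpha: float) -> float:
    """Robust Initial Enhancement: exponentially weighted mean active rank,
    normalized by its expectation under uniform random ranking."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    scores, actives = _check(scores, labels)
    n = len(scores)
    n_act = int(actives.sum())
    ranks = _pessimistic_ranks(scores, actives)
    observed = _rie_sum(ranks, n, alpha)
    # expectation of sum(exp(-alpha*r/N)) over uniform ranks
    expected = n_act / n * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1)
    return observed / expected


def bedroc(scores, labels, alpha: float) -> float:
    """RIE rescaled to [0, 1] between its worst- and best-possible values."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    scores, actives = _check(scores, labels)
    n = len(scores)
    n_act = int(actives.sum())
    ranks = _pessimistic_ranks(scores, actives)
    observed = _rie_sum(ranks, n, alpha)
    best = _rie_sum(np.arange(1, n_act + 1), n, alpha)
    worst = _rie_sum(np.arange(n - n_act + 1, n + 1), n, alpha)
    return (observed - worst) / (best - worst)


#: Metric name -> callable(scores, labels); the benchmark's standard panel.
METRICS: dict[str, Callable] = {
    "AUC": auc,
    "EF1": lambda s, l: enrichment_factor(s, l, 0.01),
    "EF5": lambda s, l: enrichment_factor(s, l, 0.05),
    "BEDROC20": lambda s, l: bedroc(s, l, 20.0),
    "BEDROC100": lambda s, l: bedroc(s, l, 100.0),
    "RIE20": lambda s, l: rie(s, l, 20.0),
    "RIE100": lambda s, l: rie(s, l, 100.0),
}


def compute_all_metrics(scores, labels) -> dict[str, float]:
    return {name: fn(scores, labels) for name, fn in METRICS.items()}


@dataclass(frozen=True)
class ScreeningDataset:
    """A labelled analog dataset ready for screening.

    ``structures`` are the SMILES of the members (aligned with ``labels``);
    ``name`` identifies the dataset in benchmark tables.
    """

    name: str
    structures: list[str]
    labels: list[str]

    def __post_init__(self):
        if len(self.structures) != len(self.labels):
            raise ValueError("structures and labels must be aligned")

    @property
    def active_indices(self) -> np.ndarray:
        return np.nonzero(_as_active_mask(self.labels))[0]


def run_benchmark(
    datasets: Sequence[ScreeningDataset],
    variants: Sequence,
    fingerprint_fn: Callable,
    similarity_fn: Callable,
    repetitions: int = 5,
    queries_per_repetition: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every dataset with every fingerprint variant.

    Per repetition, ``queries_per_repetition`` actives are drawn (without
    replacement, per-dataset, reproducibly from ``seed``) as the query set;
    the remaining members are scored by max fusion and all metrics recorded.
    Datasets with too few actives are skipped with a warning.

    ``fingerprint_fn(structures, variant)`` must return fingerprints aligned
    with the input; ``similarity_fn(variant)`` returns the similarity callable
    appropriate for that variant (Jaccard estimate for MinHashed, Dice for
    folded).  Returns a tidy frame with one row per
    (dataset, variant, repetition) and one column per metric.
    """
    rows = []
    for ds in datasets:
        act_idx = ds.active_indices
        if len(act_idx) < queries_per_repetition:
            logger.warning(
                "dataset %s skipped: %d actives < %d queries",
                ds.name, len(act_idx), queries_per_repetition,
            )
            continue
        # one query draw per repetition, shared across variants
        rng = np.random.default_rng(seed)
        draws = [
            rng.choice(act_idx, size=queries_per_repetition, replace=False)
            for _ in range(repetitions)
        ]
        for variant in variants:
            fps = fingerprint_fn(ds.structures, variant)
            sim = similarity_fn(variant)
            for rep, query_idx in enumerate(draws):
                mask = np.ones(len(fps), dtype=bool)
                mask[query_idx] = False
                rest = np.nonzero(mask)[0]
                scores = score_by_max_fusion(
                    [fps[i] for i in query_idx], [fps[i] for i in rest], sim
                )
                labels = [ds.labels[i] for i in rest]
                row = {
                    "dataset": ds.name,
                    "variant": getattr(variant, "name", str(variant)),
                    "repetition": rep,
                }
                row.update(compute_all_metrics(scores, labels))
                rows.append(row)
    return pd.DataFrame(rows)


def average_ranks(results: pd.DataFrame, metric: str = "AUC") -> pd.Series:
    """Average rank of each variant across datasets for one metric (1 = best).

    Repetitions are averaged within each (dataset, variant) first; within a
    dataset, variants are ranked by descending metric with ties sharing the
    mean rank; ranks are then averaged over datasets.
    """
    per_ds = (
        results.groupby(["dataset", "variant"])[metric].mean().reset_index()
    )
    ranked = per_ds.assign(
        rank=per_ds.groupby("dataset")[metric].rank(
            ascending=False, method="average"
        )
    )
    return ranked.groupby("variant")["rank"].mean().sort_values()
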