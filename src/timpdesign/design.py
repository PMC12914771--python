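"""Selective candidate design: top-k by one target, percentile-ranked off-target.

The design procedure mirrors a two-step selectivity screen:

1. Enumerate the fully mutated space (every targeted position non-WT), score
   each variant with the primary target's affinity model, and keep the k
   variants with the strongest predicted log2 ER (a streaming top-k over
   batches, so the full 19^7 space never has to be held in memory).
2. For every candidate and every off-target model, compute the percentage of
   the *whole* variant space (all alphabet^n signatures, WT letters included)
   whose predicted log2 ER is strictly greater than the candidate's.  A low
   percentile on the intended target and a high percentile on the off-targets
   marks a selectivity-switched candidate.

The percentile space can be scanned exhaustively (reduced schemes, cluster
runs) or estimated by seeded Monte-Carlo sampling with a binomial standard
error (the desk-scale default for 20^7).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import EnsembleModel
from .variant_space import (
    ReferenceScheme,
    enumerate_full_space,
    enumerate_fully_mutated,
    fully_mutated_space_size,
    sample_variant_space,
)


@dataclass(frozen=True)
class SpaceMode:
    """How the ranking space is evaluated: exhaustive or sampled(n, seed)."""

    kind: str  # "exhaustive" | "sampled"
    n: int = 0
    seed: int = 0

    @classmethod
    def exhaustive(cls) -> "SpaceMode":
        return cls(kind="exhaustive")

    @classmethod
    def sampled(cls, n: int, seed: int) -> "SpaceMode":
        return cls(kind="sampled", n=n, seed=seed)


@dataclass
class CandidateReport:
    signature: str
    rank: int
    predicted_log2_er: dict[str, float]
    percentile_exceeding: dict[str, float]
    percentile_se: dict[str, float] = field(default_factory=dict)
    space_mode: SpaceMode = field(default_factory=SpaceMode.exhaustive)


def top_k_fully_mutated(
    model: EnsembleModel,
    scheme: ReferenceScheme,
    k: int = 5,
    batch_positions: tuple[int, int] | None = None,
    sample_n: int | None = None,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """The k fully mutated signatures with the strongest predicted log2 ER.

    Streams the batched enumeration of the all-positions-mutated space and
    maintains a global top-k heap, so the result is independent of the batch
    position choice.  ``sample_n`` replaces the exhaustive stream with a
    seeded uniform sample of the fully mutated space (rejection-sampling the
    full space), for desk-scale runs where (a-1)^n is out of reach.

    Returns (signature, prediction) pairs sorted by prediction descending,
    ties broken lexicographically.
    """
    space = fully_mutated_space_size(scheme)
    if k < 1 or k > (sample_n if sample_n is not None else space):
        raise ValueError(f"k={k} out of range for space of size {space}")

    if sample_n is not None:
        batches = iter([_sample_fully_mutated(scheme, sample_n, seed)])
    else:
        batches = enumerate_fully_mutated(scheme, batch_positions)

    # Heap of (prediction, reversed-tiebreak, signature): keep highest
    # predictions; on prediction ties prefer lexicographically smaller
    # signatures, so push the *larger* signature out first.
    heap: list[tuple[float, tuple[int, ...], str]] = []
    for batch in batches:
        preds = model.predict_signatures(batch)
        for sig, pred in zip(batch, preds):
            entry = (float(pred), tuple(-ord(c) for c in sig), sig)
            if len(heap) < k:
                heapq.heappush(heap, entry)
            elif entry > heap[0]:
                heapq.heapreplace(heap, entry)
    result = sorted(heap, key=lambda e: (-e[0], e[2]))
    return [(sig, pred) for pred, _, sig in result]


def _sample_fully_mutated(scheme: ReferenceScheme, n: int, seed: int) -> list[str]:
    """Uniform sample of signatures with every position non-WT."""
    rng = np.random.default_rng(seed)
    wt = scheme.wt_signature
    non_wt = [np.array([aa for aa in scheme.alphabet if aa != wt[i]]) for i in range(scheme.n_positions)]
    columns = [letters[rng.integers(0, len(letters), size=n)] for letters in non_wt]
    return ["".join(row) for row in zip(*columns)]


def _space_predictions(
    model: EnsembleModel, scheme: ReferenceScheme, mode: SpaceMode
) -> np.ndarray:
    """Model predictions over the ranking space (exhaustive or sampled)."""
    if mode.kind == "exhaustive":
        preds: list[np.ndarray] = []
        batch: list[str] = []
        for sig in enumerate_full_space(scheme):
            batch.append(sig)
            if len(batch) == 65536:
                preds.append(model.predict_signatures(batch))
                batch = []
        if batch:
            preds.append(model.predict_signatures(batch))
        return np.concatenate(preds)
    if mode.kind == "sampled":
        if mode.n < 10:
            raise ValueError("sampled mode needs n >= 10")
        sample = sample_variant_space(scheme, mode.n, mode.seed)
        return model.predict_signatures(sample)
    raise ValueError(f"unknown space mode {mode.kind!r}")


def _percentile_from_preds(space_preds: np.ndarray, candidate_pred: float, mode: SpaceMode) -> tuple[float, float]:
    frac = float((space_preds > candidate_pred).mean())
    se = 0.0 if mode.kind == "exhaustive" else math.sqrt(frac * (1.0 - frac) / mode.n)
    return 100.0 * frac, 100.0 * se


def selectivity_percentile(
    candidate: str,
    model: EnsembleModel,
    scheme: ReferenceScheme,
    mode: SpaceMode,
) -> tuple[float, float]:
    """Percentage of the variant space predicted strictly above the candidate.

    Exhaustive mode scans all ``alphabet^n`` signatures (including WT
    letters); sampled mode draws ``mode.n`` signatures uniformly and returns
    the Monte-Carlo estimate with its binomial standard error (exhaustive
    mode returns SE = 0).  Ties with the candidate's prediction count as not
    exceeding.
    """
    candidate_pred = float(model.predict_signatures([candidate])[0])
    return _percentile_from_preds(_space_predictions(model, scheme, mode), candidate_pred, mode)


def rank_candidates(
    candidates: Sequence[str],
    primary_model: EnsembleModel,
    off_target_models: Mapping[str, EnsembleModel],
    scheme: ReferenceScheme,
    mode: SpaceMode,
    primary_name: str = "primary",
) -> list[CandidateReport]:
    """Per-candidate predictions and off-target percentiles, primary-sorted.

    No automatic final pick is made: the report exposes each candidate's
    predicted affinity for the primary target and, for every off-target
    model, the fraction of the variant space predicted to bind better.  The
    final choice among near-ties is left to the caller.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if not off_target_models:
        raise ValueError("need at least one off-target model")
    for name, m in {primary_name: primary_model, **off_target_models}.items():
        if m.scheme.targeted_positions != scheme.targeted_positions or m.scheme.alphabet != scheme.alphabet:
            raise ValueError(f"model {name!r} was trained on a different scheme")

    primary_preds = primary_model.predict_signatures(list(candidates))
    order = sorted(
        range(len(candidates)), key=lambda i: (-primary_preds[i], candidates[i])
    )
    # One space scan per off-target model, shared across all candidates.
    off_preds = {
        name: m.predict_signatures(list(candidates)) for name, m in off_target_models.items()
    }
    space_preds = {
        name: _space_predictions(m, scheme, mode) for name, m in off_target_models.items()
    }
    reports = []
    for rank, i in enumerate(order, start=1):
        sig = candidates[i]
        preds = {primary_name: float(primary_preds[i])}
        pct: dict[str, float] = {}
        se: dict[str, float] = {}
        for name in off_target_models:
            preds[name] = float(off_preds[name][i])
            pct[name], se[name] = _percentile_from_preds(
                space_preds[name], preds[name], mode
            )
        reports.append(
            CandidateReport(
                signature=sig,
                rank=rank,
                predicted_log2_er=preds,
                percentile_exceeding=pct,
                percentile_se=se,
                space_mode=mode,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row: dict = {"rank": r.rank, "signature": r.signature}
        for name, val in r.predicted_log2_er.items():
            row[f"pred_{name}"] = val
        for name, val in r.percentile_exceeding.items():
            row[f"pct_exceeding_{name}"] = val
        for name, val in r.percentile_se.items():
            row[f"pct_se_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
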