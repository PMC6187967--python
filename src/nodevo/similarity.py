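"""Cross-species expression concordance statistics.

For a pair of species, each ortholog group contributes a *dissonance
score*: the mean absolute difference between every fold change of one
species' members and every fold change of the other's,

    D = (sum_i sum_j |A_i - B_j|) / (m * n).

The overall dissonance is the sum of D over all representative groups.
Its significance is assessed by permutation: fold-change values are
reshuffled across transcripts within each species (group sizes kept),
and the p-value is the fraction of permuted overall scores at or below
the observed one — small when the two species' nodule/root expression
shifts agree more than chance predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import DataError
from .expression import EnhancementCall

__all__ = [
    "DissonancePair",
    "DissonanceResult",
    "CorrelationResult",
    "dissonance_score",
    "overall_dissonance",
    "permutation_test",
    "representative_fc_pairs",
    "pearson",
]


@dataclass
class DissonancePair:
    """Per-group member fold-change vectors for one species pair."""

    species_a: str
    species_b: str
    groups_a: dict[str, np.ndarray]  # group_id -> fold changes of species A members
    groups_b: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.groups_a) != set(self.groups_b):
            raise DataError("species A and B must cover the same groups")
        for gid in self.groups_a:
            a = np.asarray(self.groups_a[gid], dtype=float)
            b = np.asarray(self.groups_b[gid], dtype=float)
            if a.size == 0 or b.size == 0:
                raise DataError(f"group {gid}: empty member vector")
            if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
                raise DataError(f"group {gid}: non-finite fold change")
            self.groups_a[gid] = a
            self.groups_b[gid] = b

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups_a)


@dataclass
class DissonanceResult:
    species_a: str
    species_b: str
    observed_total: float
    permutation_scores: np.ndarray
    p_value: float          # inclusive: (# scores <= observed) / N
    p_plus_one: float       # (k + 1) / (N + 1)
    seed: int

    def summary(self) -> dict:
        return {
            "species_a": self.species_a,
            "species_b": self.species_b,
            "observed": self.observed_total,
            "p_inclusive": self.p_value,
            "p_plus_one": self.p_plus_one,
            "n_perm": int(self.permutation_scores.size),
            "perm_mean": float(self.permutation_scores.mean()),
            "perm_sd": float(self.permutation_scores.std(ddof=1)),
            "seed": self.seed,
        }


@dataclass
class CorrelationResult:
    subset: str  # all | nodule_co_enhanced | root_co_enhanced
    r: float
    p_value: float
    n_groups: int
    defined: bool = True


def dissonance_score(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute pairwise fold-change difference between two member sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("dissonance_score: empty fold-change vector")
    return float(np.abs(a[:, None] - b[None, :]).mean())


def overall_dissonance(pair: DissonancePair) -> float:
    """Sum of per-group dissonance scores over all representative groups."""
    return float(
        sum(dissonance_score(pair.groups_a[g], pair.groups_b[g]) for g in pair.groups_a)
    )


def _layout(groups: Mapping[str, np.ndarray]) -> tuple[np.ndarray, list[slice]]:
    """Concatenate member vectors; return values and per-group slices."""
    values = []
    slices = []
    start = 0
    for gid in sorted(groups):
        v = groups[gid]
        values.append(v)
        slices.append(slice(start, start + v.size))
        start += v.size
    return np.concatenate(values), slices


def permutation_test(
    pair: DissonancePair,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    permute_both: bool = True,
) -> DissonanceResult:
    """Permutation null for the overall dissonance score.

    Each replicate reshuffles the pooled fold-change values across
    transcripts within each species (both species by default), keeping
    group sizes, and recomputes the overall score.  The primary p-value
    is the inclusive fraction of replicates at or below the observed
    score; the (k+1)/(N+1) estimator is reported alongside because the
    inclusive fraction degenerates to 0 below the permutation
    resolution.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = overall_dissonance(pair)
    vals_a, slices_a = _layout(pair.groups_a)
    vals_b, slices_b = _layout(pair.groups_b)
    singleton = vals_a.size == len(slices_a) and vals_b.size == len(slices_b)

    scores = np.empty(n_perm)
    for r in range(n_perm):
        pa = rng.permutation(vals_a) if permute_both else vals_a
        pb = rng.permutation(vals_b)
        if singleton:
            scores[r] = float(np.abs(pa - pb).sum())
        else:
            total = 0.0
            for sa, sb in zip(slices_a, slices_b):
                total += float(np.abs(pa[sa][:, None] - pb[sb][None, :]).mean())
            scores[r] = total
    k = int(np.sum(scores <= observed))
    return DissonanceResult(
        pair.species_a,
        pair.species_b,
        observed,
        scores,
        p_value=k / n_perm,
        p_plus_one=(k + 1) / (n_perm + 1),
        seed=seed,
    )


def representative_fc_pairs(
    pair: DissonancePair,
    calls: Mapping[tuple[str, str], EnhancementCall] | None = None,
) -> dict[str, list[tuple[float, float]]]:
    """One (fc_a, fc_b) pair per group, for the Pearson subsets.

    For multi-paralog groups the most similar pair of fold changes is
    chosen (minimum |fc_a - fc_b|; ties broken toward the
    lexicographically smallest (fc_a, fc_b)).  Subsets: ``all`` groups;
    groups nodule-enhanced in both species; groups root-enhanced in
    both species (the latter two only when calls are supplied).
    """
    out: dict[str, list[tuple[float, float]]] = {
        "all": [],
        "nodule_co_enhanced": [],
        "root_co_enhanced": [],
    }
    for gid in pair.group_ids:
        a = pair.groups_a[gid]
        b = pair.groups_b[gid]
        diff = np.abs(a[:, None] - b[None, :])
        best = np.min(diff)
        ii, jj = np.nonzero(diff == best)
        cand = sorted((float(a[i]), float(b[j])) for i, j in zip(ii, jj))
        chosen = cand[0]
        out["all"].append(chosen)
        if calls is not None:
            ca = calls.get((gid, pair.species_a))
            cb = calls.get((gid, pair.species_b))
            if ca and cb:
                if ca.counts_as("nodule") and cb.counts_as("nodule"):
                    out["nodule_co_enhanced"].append(chosen)
                if ca.counts_as("root") and cb.counts_as("root"):
                    out["root_co_enhanced"].append(chosen)
    return out


def pearson(pairs: Sequence[tuple[float, float]], subset: str = "all") -> CorrelationResult:
    """Sample Pearson r with two-sided t-test p-value over fc pairs."""
    if len(pairs) < 3:
        raise DataError("pearson: need at least 3 pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(subset, float("nan"), float("nan"), len(pairs), False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(subset, float(r), float(p), len(pairs))
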