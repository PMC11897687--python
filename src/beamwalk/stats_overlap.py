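"""Overlap, enrichment and LDA-space summaries of prioritized features.

Given the consensus feature lists from independent experiments (e.g.
three mutant lines, or two cohorts of the same line), three questions are
answered:

* is the overlap between the lists larger than chance?  Assessed by a
  bootstrap in which every list is redrawn uniformly without replacement
  from the feature universe (default 100,000 repetitions);
* are particular feature categories (the statistic family mean/min/max/
  variance, or the constituent family distance/angle/height) enriched in
  a prioritized list?  Upper-tail hypergeometric test;
* how separated are the groups in a linear-discriminant projection of
  the full feature set?  Euclidean distances of samples to a reference
  group's centroid quantify intra- vs inter-group spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .features import FeatureDef


@dataclass(frozen=True)
class OverlapResult:
    set_sizes: tuple[int, ...]
    observed: int               # overlap common to all sets
    pairwise: dict              # (i, j) -> observed pairwise overlap
    p_value: float              # bootstrap p for the all-sets overlap
    pairwise_p: dict            # (i, j) -> bootstrap p
    reps: int
    seed: int


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int                      # category members in the list
    n: int                      # list size
    K: int                      # category size in the universe
    N: int                      # universe size
    fold: float                 # (k/n) / (K/N)
    p_value: float              # hypergeometric upper tail P(X >= k)


# --------------------------------------------------------------------------
# Bootstrap overlap
# --------------------------------------------------------------------------


def _membership_masks(
    rng: np.random.Generator, reps: int, universe: int, size: int
) -> np.ndarray:
    """(reps, universe) boolean masks of uniform draws without replacement."""
    scores = rng.random((reps, universe))
    idx = np.argpartition(scores, size - 1, axis=1)[:, :size]
    masks = np.zeros((reps, universe), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def bootstrap_overlap(
    universe_size: int,
    list_sizes: Sequence[int],
    observed: int,
    pairwise_observed: Mapping[tuple[int, int], int] | None = None,
    reps: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> OverlapResult:
    """Monte-Carlo p-value of a feature-list overlap.

    Each repetition draws every list uniformly without replacement from a
    universe of ``universe_size`` features and counts the members common
    to all lists; ``p = (1 + #{rep >= observed}) / (reps + 1)``.  Pairwise
    overlaps are evaluated in the same repetitions when
    ``pairwise_observed`` is given.
    """
    sizes = [int(s) for s in list_sizes]
    if any(s > universe_size for s in sizes):
        raise ValueError("list size exceeds the universe")
    if observed > min(sizes):
        raise ValueError("observed overlap exceeds the smallest list")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = sorted(pairwise_observed) if pairwise_observed else []
    count_all = 0
    count_pair = {p: 0 for p in pairs}
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        masks = [_membership_masks(rng, m, universe_size, s) for s in sizes]
        common = masks[0].copy()
        for other in masks[1:]:
            common &= other
        count_all += int((common.sum(axis=1) >= observed).sum())
        for i, j in pairs:
            inter = (masks[i] & masks[j]).sum(axis=1)
            count_pair[(i, j)] += int((inter >= pairwise_observed[(i, j)]).sum())
        done += m
    p_all = (1 + count_all) / (reps + 1)
    p_pair = {p: (1 + c) / (reps + 1) for p, c in count_pair.items()}
    return OverlapResult(
        set_sizes=tuple(sizes),
        observed=int(observed),
        pairwise=dict(pairwise_observed or {}),
        p_value=float(p_all),
        pairwise_p=p_pair,
        reps=int(reps),
        seed=int(seed),
    )


def observed_overlaps(lists: Sequence[Sequence[str]]) -> tuple[int, dict]:
    """All-sets and pairwise overlap counts of named feature lists."""
    sets = [set(lst) for lst in lists]
    common = set.intersection(*sets) if sets else set()
    pairwise = {
        (i, j): len(sets[i] & sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    }
    return len(common), pairwise


# --------------------------------------------------------------------------
# Hypergeometric enrichment
# --------------------------------------------------------------------------


def enrich_category(
    prioritized: Sequence[str],
    registry: Sequence[FeatureDef],
) -> list[EnrichmentResult]:
    """Category enrichment of a prioritized list within the manifest.

    Categories are the statistic families (mean/min/max/variance) and the
    constituent families (distance/angle/height/meta/endpoint).  For each,
    the upper-tail hypergeometric p-value of drawing ``k`` members in a
    list of ``n`` from a universe of ``N`` containing ``K`` is reported
    along with the fold enrichment ``(k/n) / (K/N)``.
    """
    by_name = {d.name: d for d in registry}
    unknown = [f for f in prioritized if f not in by_name]
    if unknown:
        raise KeyError(f"prioritized features not in the registry: {unknown[:3]}")
    N = len(registry)
    n = len(prioritized)
    results = []
    categories: dict[str, set[str]] = {}
    for d in registry:
        if d.statistic != "none":
            categories.setdefault(f"statistic:{d.statistic}", set()).add(d.name)
        categories.setdefault(f"family:{d.category}", set()).add(d.name)
    for cat in sorted(categories):
        members = categories[cat]
        K = len(members)
        k = sum(1 for f in prioritized if f in members)
        fold = (k / n) / (K / N) if n and K else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(EnrichmentResult(category=cat, k=k, n=n, K=K, N=N,
                                        fold=float(fold), p_value=p))
    return results


# --------------------------------------------------------------------------
# LDA projection and centroid distances
# --------------------------------------------------------------------------


def lda_project(
    X: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    standardize: bool = False,
) -> np.ndarray:
    """Linear-discriminant projection of all features (SVD solver).

    Two classes give a 1-D projection, three or more a 2-D one (the first
    two discriminants).  ``standardize`` optionally z-scores features
    before projection (off by default; the projection is fitted on raw
    features).
    """
    Xm = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs >= 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"class(es) with fewer than 2 samples: {list(small)}")
    if not np.isfinite(Xm).all():
        raise ValueError("feature matrix contains non-finite values")
    if standardize:
        mu, sd = Xm.mean(axis=0), Xm.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xm = (Xm - mu) / sd
    lda = LinearDiscriminantAnalysis(solver="svd")
    proj = lda.fit_transform(Xm, labels)
    dims = min(len(classes) - 1, 2)
    return proj[:, :dims]


def centroid_distances(
    projection: np.ndarray,
    labels: Sequence[str],
    reference: str,
) -> tuple[np.ndarray, dict]:
    """Euclidean distances to the reference group's centroid.

    ``intra``: distances of reference samples to their own centroid;
    ``inter[g]``: distances of group ``g``'s samples to the reference
    centroid.
    """
    proj = np.atleast_2d(np.asarray(projection, dtype=float))
    if proj.shape[0] == 1 and len(labels) > 1:
        proj = proj.T
    labels = np.asarray(labels)
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} absent from labels")
    centroid = proj[labels == reference].mean(axis=0)
    intra = np.linalg.norm(proj[labels == reference] - centroid, axis=1)
    inter = {}
    for g in np.unique(labels):
        if g == reference:
            continue
        inter[str(g)] = np.linalg.norm(proj[labels == g] - centroid, axis=1)
    return intra, inter
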