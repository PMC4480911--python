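"""Preranked gene-set enrichment: weighted KS enrichment score, NES, FDR q.

Given a gene list ranked by a signed score (here: per-gene correlation with a
principal component), the enrichment score of a set is the extremum of a
running sum that increases by ``|score|^p / sum_hits |score|^p`` at each set
member and decreases by ``1 / (N - N_hits)`` at each non-member.  The null is
gene-label permutation (random member positions with the real score weights);
NES divides the observed ES by the mean magnitude of same-sign null ES values
of the same set size, and FDR q-values follow the sign-stratified
tail-fraction ratio, clipped to [0, 1] and made monotone in |NES| within each
sign.

When the extremum is ambiguous (positive and negative deviations of equal
magnitude) the positive one is reported; ties in scores keep the input order
of the ranked list (stable sort upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detest import DEResult
from .io import GeneSetCollection, ValidationError


@dataclass
class GSEAResult:
    """Per-set size, ES, NES and FDR q for one ranked list."""

    table: pd.DataFrame  # index name; columns size, es, nes, fdr_q

    def significant(self, fdr_q: float = 0.01) -> pd.DataFrame:
        return self.table.loc[self.table["fdr_q"] < fdr_q]


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _es_batch(positions: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """ES for rows of sorted hit positions (B, m) against weights (N,)."""
    n = weights.shape[0]
    m = positions.shape[1]
    if m >= n:
        raise ValidationError("gene set may not cover the entire ranked list")
    w = weights[positions]  # (B, m)
    denom = w.sum(axis=1, keepdims=True)
    # all-zero hit weights degenerate to unweighted steps
    w = np.where(denom > 0, w, 1.0)
    denom = np.where(denom > 0, denom, float(m))
    cum = np.cumsum(w, axis=1) / denom
    miss = (positions - np.arange(m)) / (n - m)
    after = cum - miss
    before = np.concatenate([np.zeros((positions.shape[0], 1)), cum[:, :-1]], axis=1) - miss
    max_c = after.max(axis=1)
    min_c = before.min(axis=1)
    return np.where(np.abs(max_c) >= np.abs(min_c), max_c, min_c)


def _check_ranked(ranked: pd.Series) -> None:
    values = ranked.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("ranked scores must be finite")
    if np.any(np.diff(values) > 0):
        raise ValidationError("ranked list must be sorted by descending score")
    if ranked.index.duplicated().any():
        raise ValidationError("ranked list has duplicate gene ids")


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set on a descending ranked list, plus the running sum.

    ``ranked`` maps gene id to score, sorted descending.  Errors if the set is
    disjoint from the list or covers it entirely.
    """
    _check_ranked(ranked)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=len(ranked))
    m = int(hit.sum())
    if m == 0:
        raise ValidationError("gene set is disjoint from the ranked list")
    if m == len(ranked):
        raise ValidationError("gene set may not cover the entire ranked list")
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight
    w_hit = np.where(hit, weights, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        w_hit = hit.astype(float)
        denom = float(m)
    steps = np.where(hit, w_hit / denom, -1.0 / (len(ranked) - m))
    running = np.cumsum(steps)
    positions = np.flatnonzero(hit)[None, :]
    es = float(_es_batch(positions, weights)[0])
    return es, running


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    weight: float = 1.0,
    seed: int = 0,
) -> GSEAResult:
    """ES/NES/FDR for every set with [min_size, max_size] members in the list.

    The null distribution per set size is obtained from ``n_perm`` random
    member-position draws (gene-label permutation) and shared between sets of
    equal size; NES normalizes by the mean |null ES| of matching sign, and
    q-values follow the sign-stratified GSEA convention.
    """
    _check_ranked(ranked)
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    n = len(ranked)
    pos_of = {g: i for i, g in enumerate(ranked.index)}
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight

    names, sizes, positions_list = [], [], []
    for name, members in collection:
        pos = sorted(pos_of[g] for g in members if g in pos_of)
        if not min_size <= len(pos) <= max_size or len(pos) == n:
            continue
        names.append(name)
        sizes.append(len(pos))
        positions_list.append(np.asarray(pos))
    if not names:
        raise ValidationError(
            f"no gene set has between {min_size} and {max_size} members in the list"
        )

    es_obs = np.array(
        [_es_batch(p[None, :], weights)[0] for p in positions_list]
    )

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    for m in sorted(set(sizes)):
        draws = rng.random((n_perm, n)).argpartition(m - 1, axis=1)[:, :m]
        draws = np.sort(draws, axis=1)
        null_cache[m] = _es_batch(draws, weights)

    nes_obs = np.empty_like(es_obs)
    null_nes_pool = []
    for i, m in enumerate(sizes):
        null = null_cache[m]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.abs(null).mean()
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.abs(null).mean()
        nes_obs[i] = es_obs[i] / (pos_mean if es_obs[i] >= 0 else neg_mean)
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(null_nes)
    pool = np.concatenate(null_nes_pool)

    fdr = np.empty_like(nes_obs)
    n_pool_pos = max((pool >= 0).sum(), 1)
    n_pool_neg = max((pool < 0).sum(), 1)
    n_obs_pos = max((nes_obs >= 0).sum(), 1)
    n_obs_neg = max((nes_obs < 0).sum(), 1)
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            tail_null = (pool >= nes).sum() / n_pool_pos
            tail_obs = (nes_obs >= nes).sum() / n_obs_pos
        else:
            tail_null = (pool <= nes).sum() / n_pool_neg
            tail_obs = (nes_obs <= nes).sum() / n_obs_neg
        fdr[i] = min(tail_null / tail_obs, 1.0) if tail_obs > 0 else 0.0

    # monotone within sign: a more extreme |NES| never has a larger q.
    # Running min from the least extreme set toward the most extreme (as in
    # step-up multiple-testing corrections), so q_i = min of raw q over sets
    # at most as extreme as i — never the other way around.
    for sign_mask in (nes_obs >= 0, nes_obs < 0):
        idx = np.flatnonzero(sign_mask)
        if idx.size:
            order = idx[np.argsort(-np.abs(nes_obs[idx]), kind="stable")]
            fdr[order] = np.minimum.accumulate(fdr[order][::-1])[::-1]

    table = pd.DataFrame(
        {"size": sizes, "es": es_obs, "nes": nes_obs, "fdr_q": fdr},
        index=pd.Index(names, name="name"),
    )
    return GSEAResult(table)


def pc_gsea(pc_cor: DEResult, collection: GeneSetCollection, **kwargs) -> GSEAResult:
    """Preranked GSEA on per-gene PC-correlation scores.

    Genes are ranked by their signed correlation score, descending (ties keep
    input order); positive-NES sets are positively correlated with the
    component.
    """
    scores = pc_cor.table["score"]
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    return preranked_gsea(ranked, collection, **kwargs)
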