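"""SAM-style resampling rank tests with permutation local FDR.

The test family follows the SAMseq lineage adapted to spike-in depth
anchoring: per-sample sequencing depths (spike-in or endogenous sums) are
equalized by Poisson downsampling to the minimum depth, a rank statistic is
computed per gene on each resampled matrix and averaged across resamples, and
significance is calibrated by permuting the response and repeating the whole
computation on the same resampled stacks.  Per-gene local FDR is the
density-ratio estimate ``pi0 * f0(z) / f(z)`` with ``f0`` from the
permutation pool and ``f`` from the observed scores.

Statistics (mid-ranks throughout):

* two-class      — standardized Wilcoxon rank-sum (signed; positive means
  higher ranks in the lexicographically later class);
* multiclass     — Kruskal–Wallis statistic (unsigned), tie-corrected;
* quantitative   — standardized Spearman rank correlation
  ``z = rho * sqrt(n - 1)`` against a continuous per-sample response.

Spike-in features drive depth estimation in spike mode but are excluded from
testing and from the density estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, ValidationError
from .normalization import downsample_stack, estimate_depth

RESPONSE_KINDS = ("two_class", "multiclass", "quantitative")

MIN_PERMUTED_SCORES = 50
_KDE_GRID = 512
_MAX_POOL = 20000


@dataclass
class DEResult:
    """Per-gene score, local FDR and direction for one response test."""

    table: pd.DataFrame  # index gene_id; columns score, local_fdr, direction
    response_kind: str

    def significant(self, local_fdr: float = 0.01) -> pd.DataFrame:
        return self.table.loc[self.table["local_fdr"] < local_fdr]


# ---------------------------------------------------------------------------
# rank statistics (vectorized over genes and response permutations)
# ---------------------------------------------------------------------------


def _rank_center_scatter(ranks: np.ndarray) -> tuple[float, np.ndarray]:
    n = ranks.shape[1]
    rbar = (n + 1) / 2.0
    scatter = ((ranks - rbar) ** 2).sum(axis=1)
    return rbar, scatter


def _two_class_scores(ranks: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """Standardized rank-sum; ranks (G, N), indicators (N, P) booleans for class B."""
    n = ranks.shape[1]
    n1 = indicators[:, 0].sum()
    rbar, scatter = _rank_center_scatter(ranks)
    w = ranks @ indicators  # (G, P)
    # variance of a without-replacement rank-sum; tie-aware via the scatter
    var = n1 * (n - n1) / (n * (n - 1)) * scatter
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - n1 * rbar) / sd[:, None]
    z[sd == 0] = 0.0
    return z


def _multiclass_scores(ranks: np.ndarray, indicators: np.ndarray, n_classes: int) -> np.ndarray:
    """Tie-corrected Kruskal–Wallis; indicators (N, P*k) stacked one-hot blocks."""
    n = ranks.shape[1]
    rbar, scatter = _rank_center_scatter(ranks)
    class_sizes = indicators[:, :n_classes].sum(axis=0)  # same in every block
    sums = ranks @ indicators  # (G, P*k)
    g = ranks.shape[0]
    p = indicators.shape[1] // n_classes
    sums = sums.reshape(g, p, n_classes)
    between = (sums**2 / class_sizes).sum(axis=2) - n * rbar**2  # (G, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (n - 1) * between / scatter[:, None]
    h[scatter == 0] = 0.0
    return h


def _quantitative_scores(ranks: np.ndarray, response_ranks: np.ndarray) -> np.ndarray:
    """Standardized Spearman correlation; response_ranks (N, P)."""
    n = ranks.shape[1]
    rbar, scatter = _rank_center_scatter(ranks)
    q_scatter = ((response_ranks[:, 0] - rbar) ** 2).sum()
    num = (ranks - rbar) @ (response_ranks - rbar)  # (G, P)
    denom = np.sqrt(scatter[:, None] * q_scatter)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / denom
    rho[scatter == 0] = 0.0
    return rho * np.sqrt(n - 1)


def _validate_response(response: np.ndarray, kind: str) -> None:
    if kind not in RESPONSE_KINDS:
        raise ValidationError(f"kind must be one of {RESPONSE_KINDS}")
    if kind == "quantitative":
        values = response.astype(float)
        if not np.isfinite(values).all():
            raise ValidationError("quantitative response must be finite")
        if np.ptp(values) == 0:
            raise ValidationError("quantitative response is constant")
        return
    labels, counts = np.unique(response, return_counts=True)
    if kind == "two_class":
        if len(labels) != 2:
            raise ValidationError(f"two_class response needs exactly 2 classes, got {len(labels)}")
    else:
        if len(labels) < 2:
            raise ValidationError("multiclass response needs >= 2 classes")
    if counts.min() < 2:
        raise ValidationError("each class needs >= 2 samples")


def rank_statistic(values, response, kind: str) -> float:
    """Signed rank statistic of one gene's per-sample values against a response.

    See the module docstring for the statistic family; mid-ranks are used for
    ties, and a constant value vector yields 0.
    """
    values = np.asarray(values, dtype=float)
    response = np.asarray(response)
    if values.shape != response.shape:
        raise ValidationError("values and response must be aligned")
    _validate_response(response, kind)
    ranks = stats.rankdata(values)[None, :]
    if kind == "two_class":
        labels = np.unique(response)
        ind = (response == labels[1]).astype(float)[:, None]
        return float(_two_class_scores(ranks, ind)[0, 0])
    if kind == "multiclass":
        labels = np.unique(response)
        ind = np.stack([(response == lab) for lab in labels], axis=1).astype(float)
        return float(_multiclass_scores(ranks, ind, len(labels))[0, 0])
    q = stats.rankdata(np.asarray(response, dtype=float))[:, None]
    return float(_quantitative_scores(ranks, q)[0, 0])


# ---------------------------------------------------------------------------
# local FDR
# ---------------------------------------------------------------------------


def local_fdr(observed, permuted) -> np.ndarray:
    """Density-ratio local FDR: ``pi0 * f0(z) / f(z)``, clipped to [0, 1].

    ``f0`` is a kernel density over the permutation score pool, ``f`` over the
    observed scores, both evaluated on a shared grid; ``pi0`` is estimated
    from the central region (scores of magnitude below the pooled median
    absolute permuted score).  Identical observed scores receive identical
    local FDR by construction.
    """
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float).ravel()
    if permuted.size < MIN_PERMUTED_SCORES:
        raise ValidationError(
            f"need >= {MIN_PERMUTED_SCORES} permuted scores for a density estimate"
        )
    if not np.isfinite(observed).all() or not np.isfinite(permuted).all():
        raise ValidationError("scores must be finite")
    if permuted.size > _MAX_POOL:
        # deterministic thinning: evenly spaced order statistics
        permuted = np.sort(permuted)[:: permuted.size // _MAX_POOL + 1]
    if observed.std() == 0 or permuted.std() == 0:
        return np.ones_like(observed)

    # shared absolute bandwidth (from the larger, better-estimated null pool)
    # so the ratio f0/f is not biased by unequal smoothing
    kde_null = stats.gaussian_kde(permuted)
    bandwidth = kde_null.factor * permuted.std(ddof=1)
    kde_obs = stats.gaussian_kde(observed, bw_method=bandwidth / observed.std(ddof=1))
    pad = 3 * max(kde_obs.factor * observed.std(), kde_null.factor * permuted.std())
    lo = min(observed.min(), permuted.min()) - pad
    hi = max(observed.max(), permuted.max()) + pad
    grid = np.linspace(lo, hi, _KDE_GRID)
    f = np.interp(observed, grid, kde_obs(grid))
    f0 = np.interp(observed, grid, kde_null(grid))

    center = np.median(np.abs(permuted))
    frac_null_central = np.mean(np.abs(permuted) <= center)
    frac_obs_central = np.mean(np.abs(observed) <= center)
    pi0 = 1.0 if frac_null_central == 0 else frac_obs_central / frac_null_central
    pi0 = float(np.clip(pi0, 1e-3, 1.0))

    tiny = np.finfo(float).tiny
    lfdr = pi0 * f0 / np.maximum(f, tiny)
    return np.clip(lfdr, 0.0, 1.0)


# ---------------------------------------------------------------------------
# the full resampling test
# ---------------------------------------------------------------------------


def sam_test(
    matrix: CountMatrix,
    response,
    kind: str,
    depth_mode: str = "spike",
    n_resamples: int = 20,
    n_perms: int = 100,
    seed: int = 0,
) -> DEResult:
    """Resampling rank test of every endogenous gene against a response.

    Pipeline: depth estimation (``depth_mode``), Poisson downsampling of the
    endogenous counts to the minimum depth (``n_resamples`` stacks), per-gene
    rank statistic averaged over resamples, permutation null from ``n_perms``
    response permutations evaluated on the same stacks, and density-ratio
    local FDR.  Deterministic under a fixed ``seed``.
    """
    if isinstance(response, pd.Series):
        response = response.reindex(matrix.sample_ids).to_numpy()
    response = np.asarray(response)
    if response.shape[0] != matrix.n_samples:
        raise ValidationError("response must have one entry per sample")
    _validate_response(response, kind)

    depths = estimate_depth(matrix, depth_mode)
    factors = (depths.depths.min() / depths.depths.reindex(matrix.sample_ids)).to_numpy()
    endog = matrix.endog_counts
    if endog.shape[0] == 0:
        raise ValidationError("no endogenous genes to test")

    ss = np.random.SeedSequence([int(seed), 0x5A17])
    resample_seed, perm_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    stack = downsample_stack(endog.to_numpy(), factors, n_resamples, seed=resample_seed)

    rng = np.random.default_rng(perm_seed)
    n = matrix.n_samples
    n_cols = n_perms + 1  # column 0 is the observed response

    if kind == "quantitative":
        q_obs = stats.rankdata(response.astype(float))
        q = np.empty((n, n_cols))
        q[:, 0] = q_obs
        for p in range(1, n_cols):
            q[:, p] = q_obs[rng.permutation(n)]
        design = q
        labels = None
    else:
        labels = np.unique(response)
        codes = np.searchsorted(labels, response)
        perm_codes = np.empty((n, n_cols), dtype=np.int64)
        perm_codes[:, 0] = codes
        for p in range(1, n_cols):
            perm_codes[:, p] = codes[rng.permutation(n)]
        if kind == "two_class":
            design = (perm_codes == 1).astype(float)
        else:
            k = len(labels)
            design = np.zeros((n, n_cols * k))
            for p in range(n_cols):
                design[np.arange(n), p * k + perm_codes[:, p]] = 1.0

    scores = np.zeros((endog.shape[0], n_cols))
    for r in range(n_resamples):
        ranks = stats.rankdata(stack[r], axis=1)
        if kind == "two_class":
            scores += _two_class_scores(ranks, design)
        elif kind == "multiclass":
            scores += _multiclass_scores(ranks, design, len(labels))
        else:
            scores += _quantitative_scores(ranks, design)
    scores /= n_resamples

    observed = scores[:, 0]
    pool = scores[:, 1:].ravel()
    lfdr = local_fdr(observed, pool)
    direction = np.sign(observed) if kind != "multiclass" else np.zeros_like(observed)
    table = pd.DataFrame(
        {"score": observed, "local_fdr": lfdr, "direction": direction},
        index=endog.index.rename("gene_id"),
    )
    return DEResult(table=table, response_kind=kind)
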