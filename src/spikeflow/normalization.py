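"""Depth estimation, Poisson resampling, normalization, content estimation, QC.

Two depth conventions are supported and deliberately contrasted:

* ``"spike"``   — per-sample depth = sum of spike-in counts.  Because the
  spike-in input is fixed per sample, this anchors absolute expression per
  unit total RNA and is robust to fluctuations of polyA+ mRNA content.
* ``"endogenous"`` — per-sample depth = sum of endogenous counts (the
  classical total-count normalization).  When the true polyA+ content differs
  between groups this convention silently rescales the difference away and
  makes the (truly constant) spike-ins appear differentially expressed.

Relative polyA+ content per sample is estimated as the ratio of endogenous to
spike-in count sums; outliers in that estimate are screened with a
median-absolute-deviation rule within comparison groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, ValidationError

logger = logging.getLogger("spikeflow")

DEPTH_MODES = ("spike", "endogenous")


@dataclass
class DepthVector:
    """Per-sample sequencing-depth estimates (all positive)."""

    depths: pd.Series
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in DEPTH_MODES:
            raise ValidationError(f"depth mode must be one of {DEPTH_MODES}")
        bad = self.depths[~(self.depths > 0)]
        if len(bad):
            raise ValidationError(f"zero/invalid depth for sample(s): {list(bad.index)[:5]}")


@dataclass
class ContentEstimate:
    """Relative polyA+ content per sample: endogenous sum / spike-in sum."""

    content: pd.Series

    def __post_init__(self) -> None:
        if not (self.content > 0).all():
            raise ValidationError("content estimates must be positive")


def estimate_depth(matrix: CountMatrix, mode: str) -> DepthVector:
    """Per-sample depth as the sum of spike-in or endogenous counts."""
    if mode not in DEPTH_MODES:
        raise ValidationError(f"depth mode must be one of {DEPTH_MODES}")
    if mode == "spike":
        if not matrix.is_spike.any():
            raise ValidationError("spike depth mode requires spike-in features")
        sums = matrix.spike_counts.sum(axis=0)
    else:
        sums = matrix.endog_counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"zero {mode} depth for sample(s): {list(zero.index)[:5]}")
    return DepthVector(sums.astype(float), mode)


def downsample_stack(
    counts: np.ndarray, factors: np.ndarray, n_resamples: int, seed: int = 0
) -> np.ndarray:
    """Poisson-thin ``counts`` columnwise by per-sample ``factors``, ``n_resamples`` times.

    Columns with factor 1 are kept verbatim (no noise added to the reference
    sample); others are replaced by Poisson draws with mean
    ``factor * count``, so zeros stay zero exactly and every entry keeps
    expectation ``factor * count``.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    if not np.isfinite(factors).all():
        raise ValidationError("non-finite depth factor")
    rng = np.random.default_rng(seed)
    stack = np.empty((n_resamples, *counts.shape), dtype=np.int64)
    keep = np.isclose(factors, 1.0)
    means = counts * factors[np.newaxis, :]
    for r in range(n_resamples):
        draw = rng.poisson(means)
        draw[:, keep] = counts[:, keep]
        stack[r] = draw
    return stack


def resample_to_min_depth(
    matrix: CountMatrix, depths: DepthVector, n_resamples: int, seed: int = 0
) -> np.ndarray:
    """Poisson-downsample every sample to the minimum depth, ``n_resamples`` times.

    For sample ``s`` the thinning factor is ``d_s = min(depths)/depth_s``.
    Returns an integer stack of shape ``(n_resamples, genes, samples)``.
    """
    d = depths.depths.reindex(matrix.sample_ids)
    if d.isna().any() or not np.isfinite(d.to_numpy()).all():
        raise ValidationError("depths do not cover all samples or are non-finite")
    factors = (d.min() / d).to_numpy()
    return downsample_stack(matrix.counts.to_numpy(), factors, n_resamples, seed)


def normalize(matrix: CountMatrix, mode: str) -> pd.DataFrame:
    """Depth-normalized expression: count * mean(depths) / depth_s.

    Spike-in features are retained (flags live on the input matrix); under
    spike mode with equal spike input their expected normalized values are
    equal across samples.
    """
    depths = estimate_depth(matrix, mode)
    scale = depths.depths.mean() / depths.depths
    return matrix.counts.astype(float).mul(scale, axis=1)


def estimate_relative_content(matrix: CountMatrix) -> ContentEstimate:
    """Relative polyA+ content per sample = endogenous sum / spike-in sum.

    Invariant to rescaling all counts of a sample by a constant (both sums
    scale together); errors if any sample has a zero spike-in sum.
    """
    spike_sum = matrix.spike_counts.sum(axis=0)
    zero = spike_sum[spike_sum <= 0]
    if len(zero):
        raise ValidationError(f"zero spike-in sum for sample(s): {list(zero.index)[:5]}")
    endo_sum = matrix.endog_counts.sum(axis=0)
    return ContentEstimate((endo_sum / spike_sum).astype(float))


def replicate_concordance(matrix: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of log1p counts for every within-group replicate pair.

    Groups are (donor, sample_type); singleton groups are skipped with a log
    notice.  Returns a table with one row per pair.
    """
    log_counts = np.log1p(matrix.counts.astype(float))
    rows = []
    for (donor, stype), group in meta.groupby(["donor", "sample_type"], sort=True):
        ids = group["sample_id"].tolist()
        if len(ids) < 2:
            logger.info("singleton group (%s, %s) skipped in concordance", donor, stype)
            continue
        for a, b in combinations(ids, 2):
            rho = stats.spearmanr(log_counts[a], log_counts[b]).statistic
            rows.append(
                {
                    "donor": donor,
                    "sample_type": stype,
                    "sample_a": a,
                    "sample_b": b,
                    "spearman": float(rho),
                }
            )
    return pd.DataFrame(rows, columns=["donor", "sample_type", "sample_a", "sample_b", "spearman"])


def flag_outliers(
    content: ContentEstimate,
    meta: pd.DataFrame,
    k_mad: float = 5.0,
    group_col: str = "sample_type",
    rel_floor: float = 0.05,
) -> list[str]:
    """Samples whose relative content deviates > ``k_mad`` MADs from the group median.

    The robust scale is floored at ``rel_floor`` times the group median: with
    a handful of tight replicates the MAD can collapse toward zero, and
    without the floor ordinary sampling noise would be flagged.  At the
    defaults a sample must deviate by at least 25 % of the group median.
    Groups smaller than 3 are skipped with a log notice (no robust scale
    estimate); ``k_mad = inf`` flags nothing.  Returns flagged sample ids.
    """
    flagged: list[str] = []
    for gval, group in meta.groupby(group_col, sort=True):
        ids = group["sample_id"].tolist()
        if len(ids) < 3:
            logger.info("group %s=%s has < 3 samples; outlier screen skipped", group_col, gval)
            continue
        values = content.content.reindex(ids)
        if values.isna().any():
            raise ValidationError(f"content estimate missing for sample(s) in group {gval}")
        if not np.isfinite(k_mad):
            continue
        med = values.median()
        mad = (values - med).abs().median()
        scale = max(mad, rel_floor * abs(med))
        if scale == 0:
            continue
        deviants = values[(values - med).abs() > k_mad * scale]
        flagged.extend(deviants.index.tolist())
    return sorted(flagged)
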