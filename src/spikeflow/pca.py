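"""Scaled, non-centered PCA of normalized expression.

Each gene row is divided by its (population) standard deviation across
samples but the mean is *not* subtracted.  The decomposition is then the SVD
of the preprocessed matrix — equivalently the eigendecomposition of the
uncentered cross-product — so the first component typically captures the
common expression offset shared by all samples, which is exactly the axis on
which samples with different absolute polyA+ content separate.  Contribution
ratios are eigenvalue shares of the total (uncentered) sum of squares.

Per-component gene loadings are standardized into z-scores over all retained
genes; the "three sigma" rule (|z| > 3) extracts the genes that contribute
most to a component.  Correlation of each gene with a component is delegated
to the quantitative-response resampling test with the component's sample
scores as the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detest import DEResult, sam_test
from .io import CountMatrix, ValidationError

logger = logging.getLogger("spikeflow")


@dataclass
class PCAResult:
    """Sample scores, gene loadings, contribution ratios and loading z-scores."""

    sample_scores: pd.DataFrame  # samples x components, columns PC1..PCk
    loadings: pd.DataFrame  # genes x components
    contribution_ratio: pd.Series  # percent of total variance per component
    loading_z: pd.DataFrame  # genes x components, standardized loadings

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)


def scale_noncenter(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene row by its population SD across samples; do NOT center.

    Zero-variance genes are dropped with a log notice; an all-constant matrix
    is an error.  Output rows have SD exactly 1 and keep their (nonzero)
    means.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("scaling needs >= 2 samples")
    sd = matrix.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all genes have zero variance")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d zero-variance gene(s) before PCA", dropped)
    return matrix.loc[keep].div(sd[keep], axis=0)


def fit_pca(preprocessed: pd.DataFrame, n_components: int) -> PCAResult:
    """Uncentered SVD of a genes x samples matrix.

    ``X = U S V^T`` with orthonormal gene loadings ``U`` and sample scores
    ``V S``; contribution ratio of component c is its eigenvalue share of the
    *full* spectrum, so ratios over all components sum to 100 %.  The sign of
    each component is fixed by making its largest-magnitude loading positive.
    """
    g, n = preprocessed.shape
    if n_components < 1 or n_components > min(g, n):
        raise ValidationError("n_components must be in [1, min(genes, samples)]")
    x = preprocessed.to_numpy(dtype=float)
    try:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical failure
        raise ValidationError(f"SVD failed: {exc}") from exc
    total = float((s**2).sum())
    u = u[:, :n_components]
    vt = vt[:n_components]
    s = s[:n_components]
    # deterministic orientation: largest-magnitude loading positive
    for c in range(n_components):
        j = int(np.argmax(np.abs(u[:, c])))
        if u[j, c] < 0:
            u[:, c] = -u[:, c]
            vt[c] = -vt[c]
    names = [f"PC{c + 1}" for c in range(n_components)]
    loadings = pd.DataFrame(u, index=preprocessed.index, columns=names)
    scores = pd.DataFrame((vt.T * s), index=preprocessed.columns, columns=names)
    contribution = pd.Series(s**2 / total * 100.0, index=names, name="contribution_pct")
    try:
        z = loadings.apply(lambda col: _zscores(col.to_numpy()), axis=0)
    except ValidationError as exc:
        logger.info("loading z-scores unavailable (%s); filled with NaN", exc)
        z = pd.DataFrame(np.nan, index=loadings.index, columns=names)
    return PCAResult(scores, loadings, contribution, z)


def _zscores(values: np.ndarray) -> np.ndarray:
    if values.size < 3:
        raise ValidationError("need >= 3 genes for loading z-scores")
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValidationError("loadings are constant; z-scores undefined")
    return (values - values.mean()) / sd


def loading_zscores(result: PCAResult, component: str | int) -> pd.Series:
    """Standardized loadings of one component over all retained genes."""
    name = component if isinstance(component, str) else f"PC{component}"
    if name not in result.loadings.columns:
        raise ValidationError(f"component {name!r} not fitted")
    return pd.Series(
        _zscores(result.loadings[name].to_numpy()), index=result.loadings.index, name=name
    )


def high_loading_genes(
    result: PCAResult, component: str | int, k_sigma: float = 3.0
) -> tuple[pd.Index, pd.Index]:
    """Genes whose loading z-score exceeds +k_sigma (positive) or -k_sigma (negative)."""
    z = loading_zscores(result, component)
    return z.index[z > k_sigma], z.index[z < -k_sigma]


def pc_correlation(
    matrix: CountMatrix,
    result: PCAResult,
    component: str | int,
    depth_mode: str = "spike",
    seed: int = 0,
    n_resamples: int = 20,
    n_perms: int = 100,
) -> DEResult:
    """Correlation of every gene with a component's sample scores.

    Delegates to the quantitative-response resampling test with the PC scores
    as the continuous response; returns per-gene signed scores and local FDR.
    """
    name = component if isinstance(component, str) else f"PC{component}"
    if name not in result.sample_scores.columns:
        raise ValidationError(f"component {name!r} not fitted")
    response = result.sample_scores[name]
    missing = [s for s in matrix.sample_ids if s not in response.index]
    if missing:
        raise ValidationError(f"PC scores missing for sample(s): {missing[:5]}")
    return sam_test(
        matrix,
        response,
        kind="quantitative",
        depth_mode=depth_mode,
        n_resamples=n_resamples,
        n_perms=n_perms,
        seed=seed,
    )
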