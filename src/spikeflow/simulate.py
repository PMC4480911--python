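"""Synthetic tag-count data with spike-in anchoring and known truth.

The generator emulates the statistical structure the downstream analysis
relies on: a fixed amount of spike-in RNA per sample, endogenous polyA+ mRNA
content per unit total RNA that varies by sample type, technical replicates
per biological sample, planted differentially expressed genes with known fold
changes, and Poisson (optionally gamma-Poisson overdispersed) counting noise.

Model
-----
For sample ``s`` of type ``t`` with depth factor ``depth_s`` and content
multiplier ``content_t``:

* endogenous gene ``g``:  E[count] = depth_s * content_t * theta_{g,t}
  where ``theta_{g,t} = theta_g * 2**log2fc_{g,t}`` and the baseline
  ``theta_g`` lies on a simplex;
* spike-in ``k``:          E[count] = depth_s * a_k
  with ``a_k`` constant across samples (fixed input per sample).

The ratio of endogenous to spike-in expectation sums between two sample types
therefore recovers the ratio of their content multipliers (up to the
O(de_fraction) drift from planted fold changes, which have random signs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DEFAULT_SPIKE_PREFIX, CountMatrix, GeneSetCollection, ValidationError

#: Default sample-type content multipliers: early-passage cultured
#: keratinocytes carry about twice the polyA+ mRNA of epidermal tissue
#: (split-thickness grafts); late-passage and immortalized cells sit between.
CONTENT_SG = 1.0
CONTENT_EKC = 2.0
CONTENT_LKC_HACAT = 1.4

#: Fraction of a sample's depth allotted to spike-in reads at content 1.
SPIKE_READ_FRACTION = 0.1

#: Spread of the log-normal library-size (depth) variation across samples.
DEPTH_LOG_SD = 0.1


@dataclass
class ScenarioConfig:
    """Parameters of one simulated study.

    ``sample_plan`` is a list of ``(sample_type, donor, n_replicates)``
    triples; ``content`` maps sample type to its polyA+ content multiplier
    (reference type at 1.0).  ``dispersion`` is the gamma-Poisson
    overdispersion (0 = pure Poisson); ``de_fraction`` of endogenous genes are
    planted as differentially expressed with |log2 fold change| drawn
    uniformly from ``de_log2fc_range`` and applied, with random sign, in one
    randomly chosen sample type.
    """

    n_genes: int
    n_spikes: int
    sample_plan: list[tuple[str, str, int]]
    content: dict[str, float]
    depth_mean: float = 1e6
    dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc_range: tuple[float, float] = (2.0, 2.0)
    seed: int = 0
    spike_prefix: str = DEFAULT_SPIKE_PREFIX
    outlier_sample: str | None = None
    outlier_boost: float = 1.0
    #: optional "tissue" type: DE genes target it with probability
    #: ``tissue_program_weight`` (its program — differentiation in the skin
    #: setting — being the dominant transcriptional axis vs cultured cells),
    #: the remaining genes target one of the other types uniformly.
    tissue_type: str | None = None
    tissue_program_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_spikes < 1:
            raise ValidationError("need at least one endogenous gene and one spike-in")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        plan_types = {t for t, _, _ in self.sample_plan}
        for t in plan_types:
            if t not in self.content:
                raise ValidationError(f"no content multiplier for sample type {t!r}")
            if self.content[t] <= 0:
                raise ValidationError("content multipliers must be positive")
        lo, hi = self.de_log2fc_range
        if lo > hi:
            raise ValidationError("de_log2fc_range must be (low, high)")


@dataclass
class TruthTable:
    """Ground truth of a simulated matrix.

    ``genes``: one row per feature with baseline relative abundance, DE flag
    and per-type log2 fold change columns (``log2fc_<type>``; spike-ins are 0
    everywhere by construction).  ``samples``: one row per sample with the
    true content multiplier and depth factor.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame


def preset(name: str) -> ScenarioConfig:
    """Named study scenarios.

    ``sg_vs_ekc``
        Two groups, 2 donors x 3 technical replicates each: epidermal tissue
        (SG, content 1.0) vs early-passage keratinocytes (EKC, content 2.0 —
        twice the polyA+ mRNA per unit total RNA).
    ``four_types``
        SG / EKC / LKC / HaCaT with contents 1.0 / 2.0 / 1.4 / 1.4
        (EKC > LKC = HaCaT > SG), 2 donors x 3 replicates per type.
    ``outlier_demo``
        The two-group design with one EKC replicate whose endogenous counts
        are boosted 5x (inflated relative polyA+ content), spikes untouched.
    """
    two_group_plan = [
        ("SG", "d1", 3), ("SG", "d2", 3),
        ("EKC", "d1", 3), ("EKC", "d2", 3),
    ]
    if name == "sg_vs_ekc":
        return ScenarioConfig(
            n_genes=2000, n_spikes=50,
            sample_plan=two_group_plan,
            content={"SG": CONTENT_SG, "EKC": CONTENT_EKC},
        )
    if name == "four_types":
        plan = [
            (t, d, 3)
            for t in ("SG", "EKC", "LKC", "HaCaT")
            for d in ("d1", "d2")
        ]
        # pervasive type-specific programs: the study this emulates found the
        # majority of measured genes differential between sample types, with
        # validated fold changes of 2-8x
        return ScenarioConfig(
            n_genes=2000, n_spikes=50,
            sample_plan=plan,
            content={
                "SG": CONTENT_SG,
                "EKC": CONTENT_EKC,
                "LKC": CONTENT_LKC_HACAT,
                "HaCaT": CONTENT_LKC_HACAT,
            },
            de_fraction=0.3,
            de_log2fc_range=(1.0, 3.0),
            tissue_type="SG",
        )
    if name == "outlier_demo":
        return ScenarioConfig(
            n_genes=2000, n_spikes=50,
            sample_plan=two_group_plan,
            content={"SG": CONTENT_SG, "EKC": CONTENT_EKC},
            outlier_sample="EKC_d1_r2",
            outlier_boost=5.0,
        )
    raise ValidationError(
        f"unknown preset {name!r}; available: sg_vs_ekc, four_types, outlier_demo"
    )


def _sample_table(config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for sample_type, donor, n_rep in config.sample_plan:
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{sample_type}_{donor}_r{r}",
                    "donor": donor,
                    "sample_type": sample_type,
                    "replicate": r,
                }
            )
    meta = pd.DataFrame(rows)
    if meta["sample_id"].duplicated().any():
        raise ValidationError("sample_plan yields duplicate sample ids")
    return meta


def simulate(config: ScenarioConfig) -> tuple[CountMatrix, pd.DataFrame, TruthTable]:
    """Draw one count matrix, its metadata table, and the generating truth.

    A single RNG stream (seeded from ``config.seed``) draws the gene-level
    parameters; per-sample sub-streams are spawned deterministically so the
    same seed always yields the identical matrix.
    """
    root = np.random.SeedSequence(config.seed)
    gene_ss, sample_root = root.spawn(2)
    rng = np.random.default_rng(gene_ss)

    meta = _sample_table(config)
    types = sorted({t for t, _, _ in config.sample_plan})

    # baseline endogenous abundances: log-normal, normalized to a simplex
    theta = np.exp(rng.normal(0.0, 1.5, size=config.n_genes))
    theta /= theta.sum()

    # spike abundances span three orders of magnitude in log space
    ladder = np.logspace(0.0, 3.0, config.n_spikes)
    spike_a = SPIKE_READ_FRACTION * ladder / ladder.sum()

    # planted DE genes: one target type each, random sign, |log2fc| from range
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    lo, hi = config.de_log2fc_range
    magnitudes = rng.uniform(lo, hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    if config.tissue_type is not None and config.tissue_type in types and len(types) > 1:
        tissue_j = types.index(config.tissue_type)
        others = [j for j in range(len(types)) if j != tissue_j]
        pick_tissue = rng.random(n_de) < config.tissue_program_weight
        target_types = np.where(
            pick_tissue, tissue_j, rng.choice(others, size=n_de)
        )
    else:
        target_types = rng.choice(len(types), size=n_de)

    log2fc = np.zeros((config.n_genes, len(types)))
    log2fc[de_idx, target_types] = signs * magnitudes

    gene_ids = [f"GENE_{i:05d}" for i in range(config.n_genes)]
    spike_ids = [f"{config.spike_prefix}{k:03d}" for k in range(config.n_spikes)]

    # per-sample depth factors around depth_mean
    sample_streams = sample_root.spawn(len(meta))
    depths = np.empty(len(meta))
    counts = np.empty((config.n_genes + config.n_spikes, len(meta)), dtype=np.int64)
    type_index = {t: j for j, t in enumerate(types)}

    for s, row in meta.iterrows():
        srng = np.random.default_rng(sample_streams[s])
        depth = config.depth_mean * np.exp(srng.normal(0.0, DEPTH_LOG_SD))
        depths[s] = depth
        content = config.content[row.sample_type]
        theta_t = theta * 2.0 ** log2fc[:, type_index[row.sample_type]]
        mean = np.concatenate([depth * content * theta_t, depth * spike_a])
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            mean = srng.gamma(shape, mean / shape)
        counts[:, s] = srng.poisson(mean)

    frame = pd.DataFrame(counts, index=gene_ids + spike_ids, columns=meta["sample_id"].tolist())
    is_spike = pd.Series(
        [False] * config.n_genes + [True] * config.n_spikes, index=frame.index, dtype=bool
    )
    matrix = CountMatrix(frame, is_spike)

    de_flag = np.zeros(config.n_genes, dtype=bool)
    de_flag[de_idx] = True
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids + spike_ids,
            "is_spike": [False] * config.n_genes + [True] * config.n_spikes,
            "baseline": np.concatenate([theta, spike_a]),
            "is_de": np.concatenate([de_flag, np.zeros(config.n_spikes, dtype=bool)]),
        }
    )
    for j, t in enumerate(types):
        gene_truth[f"log2fc_{t}"] = np.concatenate([log2fc[:, j], np.zeros(config.n_spikes)])
    sample_truth = meta.copy()
    sample_truth["content"] = [config.content[t] for t in meta["sample_type"]]
    sample_truth["depth"] = depths
    truth = TruthTable(genes=gene_truth, samples=sample_truth)

    if config.outlier_sample is not None and config.outlier_boost != 1.0:
        outlier_seed = int(root.generate_state(1)[0] % (2**31))
        matrix = inject_outlier(
            matrix, config.outlier_sample, config.outlier_boost, seed=outlier_seed
        )

    return matrix, meta, truth


def inject_outlier(
    matrix: CountMatrix, sample_id: str, content_boost: float, seed: int = 0
) -> CountMatrix:
    """Re-draw one sample's endogenous counts around a boosted expectation.

    Emulates a sample with exceptionally high relative polyA+ transcript
    counts: endogenous counts are replaced by Poisson draws with mean
    ``content_boost`` times the observed count (the observed count standing in
    for the expectation); spike-in rows are untouched.  ``content_boost = 1``
    returns an unchanged copy.
    """
    if sample_id not in matrix.sample_ids:
        raise ValidationError(f"unknown sample {sample_id!r}")
    if content_boost < 1:
        raise ValidationError("content_boost must be >= 1")
    counts = matrix.counts.copy()
    if content_boost > 1.0:
        rng = np.random.default_rng(seed)
        endog = ~matrix.is_spike.to_numpy()
        col = counts[sample_id].to_numpy()
        boosted = rng.poisson(content_boost * col[endog])
        col = col.copy()
        col[endog] = boosted
        counts[sample_id] = col
    return CountMatrix(counts, matrix.is_spike.copy())


def truth_gene_sets(
    truth: TruthTable,
    n_random: int = 50,
    random_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene sets derived from the generator truth, plus random decoys.

    For each sample type, the set of genes planted as upregulated in that type
    (``UP_IN_<type>``); random sets of ``random_size`` endogenous genes act as
    null decoys for enrichment calibration.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    endog = genes.loc[~genes["is_spike"]]
    sets: dict[str, list[str]] = {}
    for col in [c for c in genes.columns if c.startswith("log2fc_")]:
        t = col.removeprefix("log2fc_")
        up = endog.loc[endog[col] > 0, "gene_id"].tolist()
        if up:
            sets[f"UP_IN_{t}"] = up
    pool = endog["gene_id"].to_numpy()
    for i in range(n_random):
        members = rng.choice(pool, size=min(random_size, len(pool)), replace=False)
        sets[f"RANDOM_{i:03d}"] = sorted(members.tolist())
    return GeneSetCollection(sets, {name: "synthetic" for name in sets})
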