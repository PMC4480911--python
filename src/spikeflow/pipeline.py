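"""End-to-end orchestration: QC -> normalization -> DE -> PCA -> PC-GSEA.

A single :class:`PipelineConfig` describes either real inputs (counts +
metadata TSVs, optional GMT collection) or a simulation scenario.  ``run``
executes the full chain and writes one TSV per stage into the output
directory, each carrying a header comment naming the tool version and seed;
re-running with the same seed reproduces every file byte for byte (no
timestamps are recorded).

Samples flagged as content outliers are excluded from all downstream stages
(mirroring exclusion of a replicate with exceptionally high relative polyA+
counts during study QC) unless ``keep_outliers`` is set; the exclusion path
is equivalent to removing the sample from the input matrix by hand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detest import sam_test
from .gsea import pc_gsea
from .io import (
    CountMatrix,
    DEFAULT_SPIKE_PREFIX,
    GeneSetCollection,
    read_counts,
    read_gmt,
    read_metadata,
    validate_metadata,
    write_counts,
    write_metadata,
    write_rnk,
    ValidationError,
)
from .normalization import (
    estimate_relative_content,
    flag_outliers,
    normalize,
    replicate_concordance,
)
from .pca import fit_pca, high_loading_genes, loading_zscores, pc_correlation, scale_noncenter
from .simulate import ScenarioConfig, simulate, truth_gene_sets

logger = logging.getLogger("spikeflow")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Exactly one of (``counts_path`` + ``meta_path``) or ``scenario`` must be
    set.  Thresholds follow the study conventions: local FDR < 1 % for
    significant genes, GSEA q-value FDR < 1 % for significant sets, and the
    three-sigma rule for high-loading genes.
    """

    outdir: str
    counts_path: str | None = None
    meta_path: str | None = None
    gmt_path: str | None = None
    scenario: ScenarioConfig | None = None
    spike_prefix: str = DEFAULT_SPIKE_PREFIX
    depth_mode: str = "spike"
    local_fdr_threshold: float = 0.01
    gsea_fdr_threshold: float = 0.01
    k_sigma: float = 3.0
    n_components: int = 3
    n_resamples: int = 20
    n_perms: int = 100
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    k_mad: float = 5.0
    log_transform: bool = True
    keep_outliers: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None or self.meta_path is not None
        has_scenario = self.scenario is not None
        if has_paths and has_scenario:
            raise ValidationError("set either input paths or a simulation scenario, not both")
        if not has_scenario and (self.counts_path is None or self.meta_path is None):
            raise ValidationError("need counts_path and meta_path, or a scenario")
        for name in ("local_fdr_threshold", "gsea_fdr_threshold"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            scenario = ScenarioConfig(**scenario)
        return cls(scenario=scenario, **raw)


@dataclass
class PipelineReport:
    """Paths written by one run, plus the excluded-sample list."""

    outdir: Path
    paths: dict[str, Path] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def _write_table(frame: pd.DataFrame, path: Path, seed: int, index: bool = True) -> None:
    with open(path, "w") as handle:
        handle.write(f"# spikeflow {__version__} seed={seed}\n")
        frame.to_csv(handle, sep="\t", index=index, float_format="%.10g")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise ValidationError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis chain and write its report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(outdir=outdir)
    seed = config.seed
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ("detest", "pc_correlation", "gsea", "gene_sets"),
            np.random.SeedSequence([seed, 0xF10E]).spawn(4),
        )
    }

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.scenario is not None:
        scenario = replace(config.scenario, seed=seed)
        matrix, meta, truth = _stage("simulate")(simulate)(scenario)
        write_counts(matrix, outdir / "counts.tsv")
        write_metadata(meta, outdir / "meta.tsv")
        _write_table(truth.genes, outdir / "truth_genes.tsv", seed, index=False)
        _write_table(truth.samples, outdir / "truth_samples.tsv", seed, index=False)
        report.paths["counts"] = outdir / "counts.tsv"
    else:
        matrix = _stage("read_counts")(read_counts)(config.counts_path, config.spike_prefix)
        meta = _stage("read_metadata")(read_metadata)(config.meta_path)
    validate_metadata(meta, matrix)

    if config.gmt_path is not None:
        collection = _stage("read_gmt")(read_gmt)(config.gmt_path)
    elif truth is not None:
        collection = truth_gene_sets(truth, seed=stage_seeds["gene_sets"])
    else:
        collection = None

    # ---- QC: concordance, relative content, outlier screen ---------------
    concordance = _stage("qc")(replicate_concordance)(matrix, meta)
    content = _stage("qc")(estimate_relative_content)(matrix)
    flagged = _stage("qc")(flag_outliers)(content, meta, k_mad=config.k_mad)
    qc = meta.set_index("sample_id").copy()
    qc["relative_content"] = content.content
    qc["flagged_outlier"] = qc.index.isin(flagged)
    qc["excluded"] = qc["flagged_outlier"] & (not config.keep_outliers)
    _write_table(qc, outdir / "qc_report.tsv", seed)
    _write_table(concordance, outdir / "concordance_pairs.tsv", seed, index=False)
    report.paths["qc"] = outdir / "qc_report.tsv"

    if flagged and not config.keep_outliers:
        logger.info("excluding outlier sample(s): %s", flagged)
        matrix = matrix.drop_samples(flagged)
        meta = meta.loc[~meta["sample_id"].isin(flagged)].reset_index(drop=True)
        report.excluded = list(flagged)

    # ---- normalization ----------------------------------------------------
    norm = _stage("normalize")(normalize)(matrix, config.depth_mode)
    _write_table(norm.rename_axis("gene_id"), outdir / "norm.tsv", seed)
    report.paths["norm"] = outdir / "norm.tsv"

    # ---- multiclass differential expression -------------------------------
    response = meta.set_index("sample_id")["sample_type"]
    de = _stage("detest")(sam_test)(
        matrix,
        response,
        kind="multiclass",
        depth_mode=config.depth_mode,
        n_resamples=config.n_resamples,
        n_perms=config.n_perms,
        seed=stage_seeds["detest"],
    )
    _write_table(de.table, outdir / "de_multiclass.tsv", seed)
    report.paths["de"] = outdir / "de_multiclass.tsv"

    # ---- non-centered scaled PCA ------------------------------------------
    endog_norm = norm.loc[~matrix.is_spike]
    if config.log_transform:
        endog_norm = np.log1p(endog_norm)
    pre = _stage("pca")(scale_noncenter)(endog_norm)
    pca = _stage("pca")(fit_pca)(pre, config.n_components)
    scores_out = pca.sample_scores.copy()
    scores_out.columns = [
        f"{c} ({pca.contribution_ratio[c]:.1f}%)" for c in scores_out.columns
    ]
    _write_table(scores_out.rename_axis("sample_id"), outdir / "pca_scores.tsv", seed)
    _write_table(pca.loadings.rename_axis("gene_id"), outdir / "pca_loadings.tsv", seed)
    report.paths["pca_scores"] = outdir / "pca_scores.tsv"

    # ---- per-PC correlation, three-sigma loadings, PC-GSEA -----------------
    for c, name in enumerate(pca.components, start=1):
        pc_seed = int(
            np.random.SeedSequence([stage_seeds["pc_correlation"], c]).generate_state(1)[0]
            % 2**31
        )
        cor = _stage("pc_correlation")(pc_correlation)(
            matrix,
            pca,
            name,
            depth_mode=config.depth_mode,
            seed=pc_seed,
            n_resamples=config.n_resamples,
            n_perms=config.n_perms,
        )
        _write_table(cor.table, outdir / f"pc{c}_correlation.tsv", seed)
        write_rnk(cor.table["score"], outdir / f"pc{c}_correlation.rnk")
        report.paths[f"pc{c}_correlation"] = outdir / f"pc{c}_correlation.tsv"

        z = loading_zscores(pca, name)
        pos, neg = high_loading_genes(pca, name, config.k_sigma)
        high = pd.DataFrame(
            {
                "z": pd.concat([z[pos], z[neg]]),
                "side": ["positive"] * len(pos) + ["negative"] * len(neg),
            }
        ).rename_axis("gene_id")
        _write_table(high, outdir / f"high_loading_pc{c}.tsv", seed)

        if collection is not None:
            gsea_seed = int(
                np.random.SeedSequence([stage_seeds["gsea"], c]).generate_state(1)[0] % 2**31
            )
            enr = _stage("gsea")(pc_gsea)(
                cor,
                collection,
                n_perm=config.gsea_n_perm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=gsea_seed,
            )
            _write_table(enr.table, outdir / f"pc{c}_gsea.tsv", seed)
            report.paths[f"pc{c}_gsea"] = outdir / f"pc{c}_gsea.tsv"

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "tool": "spikeflow",
        "version": __version__,
        "seed": seed,
        "config": _config_dict(config),
        "excluded_samples": report.excluded,
        "outputs": sorted(
            p.name
            for p in outdir.iterdir()
            if p.is_file() and p.name != "run_manifest.json"
        ),
    }
    with open(outdir / "run_manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    report.paths["manifest"] = outdir / "run_manifest.json"
    return report


def _config_dict(config: PipelineConfig) -> dict:
    raw = asdict(config)
    if raw.get("scenario") is not None:
        raw["scenario"]["sample_plan"] = [list(t) for t in raw["scenario"]["sample_plan"]]
        raw["scenario"]["de_log2fc_range"] = list(raw["scenario"]["de_log2fc_range"])
    return raw


def summarize(outdir, local_fdr: float = 0.01, gsea_fdr: float = 0.01) -> pd.DataFrame:
    """Count significant genes/sets per stage from a report bundle.

    A pure function of the bundle files: DE genes below the local-FDR
    threshold; per PC, positively/negatively correlated genes, significant
    gene sets by sign of NES, and three-sigma loading genes per side.
    """
    outdir = Path(outdir)
    de_path = outdir / "de_multiclass.tsv"
    if not de_path.exists():
        raise ValidationError(f"missing report file: {de_path}")
    rows = []
    de = pd.read_csv(de_path, sep="\t", comment="#", index_col=0)
    rows.append(("de_multiclass", "significant_genes", int((de["local_fdr"] < local_fdr).sum())))
    for cor_path in sorted(outdir.glob("pc[0-9]*_correlation.tsv")):
        pc = cor_path.name.split("_")[0]
        cor = pd.read_csv(cor_path, sep="\t", comment="#", index_col=0)
        sig = cor["local_fdr"] < local_fdr
        rows.append((pc, "genes_positive", int((sig & (cor["score"] > 0)).sum())))
        rows.append((pc, "genes_negative", int((sig & (cor["score"] < 0)).sum())))
        gsea_path = outdir / f"{pc}_gsea.tsv"
        if gsea_path.exists():
            enr = pd.read_csv(gsea_path, sep="\t", comment="#", index_col=0)
            sig_set = enr["fdr_q"] < gsea_fdr
            rows.append((pc, "sets_positive", int((sig_set & (enr["nes"] > 0)).sum())))
            rows.append((pc, "sets_negative", int((sig_set & (enr["nes"] < 0)).sum())))
        high_path = outdir / f"high_loading_{pc}.tsv"
        if high_path.exists():
            high = pd.read_csv(high_path, sep="\t", comment="#", index_col=0)
            rows.append((pc, "loading_positive", int((high["side"] == "positive").sum())))
            rows.append((pc, "loading_negative", int((high["side"] == "negative").sum())))
    return pd.DataFrame(rows, columns=["stage", "quantity", "count"])
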