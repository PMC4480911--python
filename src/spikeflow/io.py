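"""Core data types and readers/writers.

The central container is :class:`CountMatrix`: an integer gene x sample count
table in which a subset of features are synthetic spike-in RNAs, flagged by an
identifier prefix.  Spike-ins are added in a fixed amount per sample before
library preparation, so their counts anchor absolute (per-sample) depth
estimation; everything downstream (normalization, DE testing, PCA) consumes
this container.

On-disk formats are deliberately minimal: TSV for dense count matrices and
sample metadata, Matrix Market triples for sparse counts, the Broad GMT
dialect for gene-set collections, and two-column RNK files for ranked lists.
Gene identifiers are opaque strings; no genome annotation is bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("spikeflow")

DEFAULT_SPIKE_PREFIX = "RNA_SPIKE_"

METADATA_COLUMNS = ("sample_id", "donor", "sample_type", "replicate")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts with spike-in flags.

    Parameters
    ----------
    counts
        Genes x samples DataFrame of non-negative integer counts; the index
        holds gene identifiers and the columns sample identifiers.
    is_spike
        Boolean Series aligned to ``counts.index`` marking spike-in features.
    """

    counts: pd.DataFrame
    is_spike: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dupes[:5]}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dupes[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0, rtol=0):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        spike = self.is_spike.reindex(counts.index)
        if spike.isna().any():
            raise ValidationError("is_spike must cover every gene id")
        self.is_spike = spike.astype(bool)
        if not self.is_spike.any():
            logger.warning("no spike-in features flagged; spike-mode operations will fail")

    # -- convenience views ------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.is_spike]

    @property
    def endog_counts(self) -> pd.DataFrame:
        return self.counts.loc[~self.is_spike]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order preserved)."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return CountMatrix(self.counts.loc[:, list(sample_ids)].copy(), self.is_spike.copy())

    def drop_samples(self, sample_ids) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return self.subset_samples(keep)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), members unique within each set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_counts(path, spike_prefix: str = DEFAULT_SPIKE_PREFIX) -> CountMatrix:
    """Read a count matrix from TSV or a Matrix Market triple.

    TSV layout: header row of sample ids, first column gene ids.  For sparse
    input pass the ``.mtx`` path; row ids are read from ``<stem>.rows`` and
    column ids from ``<stem>.cols`` (one id per line).

    Features whose id starts with ``spike_prefix`` are flagged as spike-ins.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = path.with_suffix(".rows").read_text().split()
        samples = path.with_suffix(".cols").read_text().split()
        if len(genes) != mat.shape[0] or len(samples) != mat.shape[1]:
            raise ValidationError("row/col sidecar files do not match matrix shape")
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        counts.index = counts.index.astype(str).rename(None)
        counts.columns = counts.columns.astype(str).rename(None)
    is_spike = pd.Series(
        [str(g).startswith(spike_prefix) for g in counts.index],
        index=counts.index,
        dtype=bool,
    )
    return CountMatrix(counts, is_spike)


def write_counts(matrix: CountMatrix, path) -> None:
    """Write a count matrix as TSV (gene ids in the first column)."""
    path = Path(path)
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, donor, sample_type, replicate."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor": str, "sample_type": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame, matrix: CountMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    dup = meta.duplicated(subset=["donor", "sample_type", "replicate"])
    if dup.any():
        raise ValidationError("replicate indices must be unique within (donor, sample_type)")
    if matrix is not None:
        meta_ids = set(meta["sample_id"])
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            raise ValidationError(
                f"metadata/matrix sample mismatch: only-meta={sorted(meta_ids - mat_ids)[:5]}, "
                f"only-matrix={sorted(mat_ids - meta_ids)[:5]}"
            )
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name, description, members... (tab-separated)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT parse error at line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"GMT parse error at line {lineno}: duplicate set {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning("gene set %s: %d duplicate member(s) removed", name, len(members) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, members in collection:
            desc = collection.descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# ranked lists (RNK)
# ---------------------------------------------------------------------------


def write_rnk(scores: pd.Series, path) -> None:
    """Write a two-column RNK file sorted by descending score; ties keep input order."""
    if scores.isna().any():
        raise ValidationError("RNK scores contain NaN")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValidationError("RNK scores must be finite")
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    ordered.to_csv(path, sep="\t", header=False)


def read_rnk(path) -> pd.Series:
    ranked = pd.read_csv(
        path, sep="\t", header=None, index_col=0, float_precision="round_trip"
    ).iloc[:, 0]
    ranked.index = pd.Index(ranked.index.astype(str), name=None)
    ranked.name = "score"
    return ranked
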