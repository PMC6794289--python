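"""Count-matrix container, delimited-text I/O, CPM, and the expressed-gene filter.

The central object is :class:`CountExperiment`: a genes x samples matrix of
non-negative integer read counts together with a sample sheet (species,
tissue, post-mortem interval in hours, replicate) and a gene annotation
table (biotype plus optional simulation ground-truth columns).  Library
size is simply the per-sample column sum; expression is quantified as
counts per million (CPM) and a gene is called expressed when its CPM
reaches a threshold in a minimum number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import LoadError, ValidationError

SAMPLE_SHEET_COLUMNS = ("species", "tissue", "pmi_hours", "replicate")


def _write_table(df: pd.DataFrame, path: Path | str, *, index_label: str,
                 comments: Mapping[str, object] | None = None, sep: str = "\t") -> None:
    """Write a table with leading ``#key: value`` comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"#{key}: {value}\n")
        df.to_csv(fh, sep=sep, index_label=index_label)


def _read_table(path: Path | str, *, sep: str = "\t", index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"input file does not exist: {path}")
    try:
        return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)
    except Exception as exc:  # malformed text
        raise LoadError(f"could not parse {path}: {exc}") from exc


@dataclass
class CountExperiment:
    """Validated bundle of counts, sample sheet, and gene annotations.

    Parameters
    ----------
    counts
        genes x samples matrix; index gene_id, columns sample_id,
        non-negative integers.
    sample_sheet
        One row per sample (index sample_id) with at least the columns
        ``species, tissue, pmi_hours, replicate``.
    gene_annotations
        One row per gene (index gene_id) with at least ``biotype``;
        simulated experiments also carry truth columns.

    Gene rows are normalised to lexicographic order and sample columns to
    sample-sheet order.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    gene_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValidationError("experiment has an empty gene set")
        if self.counts.shape[1] == 0:
            raise ValidationError("experiment has no samples")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample identifiers in count matrix")

        missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.sample_sheet.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet is missing columns: {missing_cols}")

        count_samples = set(map(str, self.counts.columns))
        sheet_samples = set(map(str, self.sample_sheet.index))
        if count_samples != sheet_samples:
            only_counts = sorted(count_samples - sheet_samples)
            only_sheet = sorted(sheet_samples - count_samples)
            raise ValidationError(
                "sample identifiers do not match one-to-one; "
                f"only in counts: {only_counts}; only in sample sheet: {only_sheet}"
            )
        count_genes = set(map(str, self.counts.index))
        ann_genes = set(map(str, self.gene_annotations.index))
        if count_genes != ann_genes:
            only_counts = sorted(count_genes - ann_genes)[:10]
            only_ann = sorted(ann_genes - count_genes)[:10]
            raise ValidationError(
                "gene identifiers do not match one-to-one; "
                f"only in counts: {only_counts}; only in annotations: {only_ann}"
            )

        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            as_float = values.astype(float)
            if np.any(~np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
                bad = self.counts.index[np.any(as_float != np.floor(as_float), axis=1)][:10]
                raise ValidationError(f"counts must be integral; offending genes include {list(bad)}")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

        # canonical ordering: genes lexicographic, samples by sample-sheet order
        gene_order = sorted(self.counts.index.astype(str))
        self.counts.index = self.counts.index.astype(str)
        self.gene_annotations.index = self.gene_annotations.index.astype(str)
        self.counts = self.counts.loc[gene_order]
        self.gene_annotations = self.gene_annotations.loc[gene_order]
        self.counts.columns = self.counts.columns.astype(str)
        self.sample_sheet.index = self.sample_sheet.index.astype(str)
        self.counts = self.counts.loc[:, list(self.sample_sheet.index)]

    # -- convenience -------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def pmi_hours(self) -> pd.Series:
        return self.sample_sheet["pmi_hours"].astype(float)

    def subset_genes(self, genes: Sequence[str]) -> "CountExperiment":
        genes = [str(g) for g in genes]
        missing = sorted(set(genes) - set(self.counts.index))
        if missing:
            raise ValidationError(f"unknown genes in subset: {missing[:10]}")
        return CountExperiment(
            counts=self.counts.loc[genes].copy(),
            sample_sheet=self.sample_sheet.copy(),
            gene_annotations=self.gene_annotations.loc[genes].copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "CountExperiment":
        samples = [str(s) for s in samples]
        missing = sorted(set(samples) - set(self.counts.columns))
        if missing:
            raise ValidationError(f"unknown samples in subset: {missing[:10]}")
        return CountExperiment(
            counts=self.counts.loc[:, samples].copy(),
            sample_sheet=self.sample_sheet.loc[samples].copy(),
            gene_annotations=self.gene_annotations.copy(),
        )

    def cpm(self) -> pd.DataFrame:
        return cpm(self)

    def write(self, counts_path, sample_sheet_path, annotations_path,
              comments: Mapping[str, object] | None = None) -> None:
        _write_table(self.counts, counts_path, index_label="gene_id", comments=comments)
        _write_table(self.sample_sheet, sample_sheet_path, index_label="sample_id", comments=comments)
        _write_table(self.gene_annotations, annotations_path, index_label="gene_id", comments=comments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountExperiment):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.sample_sheet.index.equals(other.sample_sheet.index)
            and np.allclose(self.pmi_hours, other.pmi_hours)
            and self.gene_annotations.index.equals(other.gene_annotations.index)
        )


def read_counts(counts_path, sample_sheet_path, annotations_path) -> CountExperiment:
    """Load a :class:`CountExperiment` from three delimited-text tables.

    Identifier mismatches and non-integral counts raise :class:`LoadError`
    naming the offending IDs.
    """
    counts = _read_table(counts_path)
    sheet = _read_table(sample_sheet_path)
    annotations = _read_table(annotations_path)
    try:
        return CountExperiment(counts=counts, sample_sheet=sheet, gene_annotations=annotations)
    except ValidationError as exc:
        raise LoadError(str(exc)) from exc


def cpm(experiment: CountExperiment) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6`` per sample."""
    lib = experiment.library_sizes
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    return experiment.counts / lib.to_numpy(dtype=float) * 1e6


def filter_expressed(cpm_matrix: pd.DataFrame, min_cpm: float = 1.0,
                     min_samples: int = 4, *,
                     within_timepoint: pd.Series | None = None) -> list[str]:
    """Genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    By default qualifying samples are counted across the whole experiment.
    Passing ``within_timepoint`` (a per-sample group label series aligned to
    the CPM columns) instead requires the quota to be met inside at least
    one group.
    """
    if min_samples > cpm_matrix.shape[1]:
        raise ValidationError(
            f"min_samples={min_samples} exceeds the number of samples ({cpm_matrix.shape[1]})"
        )
    passing = cpm_matrix >= min_cpm
    if within_timepoint is None:
        keep = passing.sum(axis=1) >= min_samples
    else:
        labels = within_timepoint.loc[cpm_matrix.columns]
        keep = pd.Series(False, index=cpm_matrix.index)
        for _, cols in labels.groupby(labels).groups.items():
            keep |= passing.loc[:, list(cols)].sum(axis=1) >= min_samples
    return [str(g) for g in cpm_matrix.index[keep]]
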