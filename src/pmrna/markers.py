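"""Marker-gene selection from Z-score timelines.

Candidate PMI markers are genes whose replicate variability is low (within-
timepoint BCV below a threshold at every timepoint of a reference grid,
0/3/6/12/24 h by default) and whose standardised expression timeline moves
consistently with post-mortem time.  Per gene, the mean log2(CPM + 0.5) at
each timepoint is standardised to a Z-score (mean 0, sample SD 1 across
timepoints), and an ordinary least-squares line of Z on hours provides the
slope and R^2.  "Visually consistent slope" is operationalised as
R^2 >= min_r2 (default 0.8).  The selection returns the requested number of
top positive- and negative-slope genes (9 + 9 by default), with ties broken
by lexicographic gene ID.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountExperiment, cpm as _cpm
from .de import estimate_tagwise_dispersion
from .exceptions import MarkerSelectionError, ValidationError

DEFAULT_BCV_TIMEPOINTS: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 24.0)


def standardize_timeline(means: pd.DataFrame) -> pd.DataFrame:
    """Row-standardise per-timepoint means to Z-scores (sample SD, n-1).

    Constant rows become all-zero rather than NaN.
    """
    values = means.to_numpy(float)
    center = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (values - center) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=means.index, columns=means.columns)


def _ols_slope_r2(z: pd.DataFrame, hours: np.ndarray) -> tuple[pd.Series, pd.Series]:
    hc = hours - hours.mean()
    sxx = float((hc**2).sum())
    zv = z.to_numpy(float)
    slope = zv @ hc / sxx
    sst = (zv**2).sum(axis=1)  # rows have mean 0
    ssr = sst - slope**2 * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / np.where(sst > 0, sst, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return (pd.Series(slope, index=z.index, name="slope"),
            pd.Series(r2, index=z.index, name="r2"))


@dataclass
class ZTimelines:
    """Z-score timelines for a set of genes: Z matrix plus per-gene OLS fit."""

    z: pd.DataFrame          # genes x timepoints
    slope: pd.Series         # Z units per hour
    r2: pd.Series

    @property
    def timepoints(self) -> list[float]:
        return [float(c) for c in self.z.columns]

    def as_frame(self) -> pd.DataFrame:
        out = self.z.copy()
        out.columns = [f"z_{c:g}h" for c in self.z.columns]
        out["slope"] = self.slope
        out["r2"] = self.r2
        return out


def zscore_timeline(experiment: CountExperiment, gene_ids: Sequence[str] | None = None,
                    timepoints: Sequence[float] | None = None) -> ZTimelines:
    """Per-gene Z-score timeline of mean log2(CPM + 0.5) over PMI timepoints."""
    pmi = experiment.pmi_hours
    if timepoints is None:
        timepoints = sorted(set(pmi.tolist()))
    timepoints = [float(t) for t in timepoints]
    if len(timepoints) < 3:
        raise ValidationError("at least 3 timepoints are required for a slope fit")
    if gene_ids is not None:
        experiment = experiment.subset_genes(gene_ids)
    logcpm = np.log2(_cpm(experiment) + 0.5)
    means = {}
    for t in timepoints:
        cols = pmi.index[np.isclose(pmi.to_numpy(float), t)]
        if len(cols) == 0:
            raise ValidationError(f"no samples at pmi_hours={t:g}")
        means[t] = logcpm.loc[:, list(cols)].mean(axis=1)
    means = pd.DataFrame(means)
    z = standardize_timeline(means)
    slope, r2 = _ols_slope_r2(z, np.asarray(timepoints, float))
    return ZTimelines(z=z, slope=slope, r2=r2)


def bcv_filter(experiment: CountExperiment,
               timepoints: Sequence[float] = DEFAULT_BCV_TIMEPOINTS,
               max_bcv: float = 0.075) -> list[str]:
    """Genes whose per-timepoint replicate BCV stays below ``max_bcv``.

    The BCV is the unshrunk (prior_df = 0) tagwise estimate within each
    listed timepoint's replicate group; a gene must pass at every listed
    timepoint.
    """
    pmi = experiment.pmi_hours
    keep = pd.Series(True, index=experiment.counts.index)
    for t in timepoints:
        cols = pmi.index[np.isclose(pmi.to_numpy(float), float(t))]
        if len(cols) == 0:
            raise ValidationError(f"no samples at pmi_hours={t:g}")
        if len(cols) < 2:
            raise ValidationError(f"timepoint {t:g} h has fewer than 2 replicates")
        sub = experiment.subset_samples(list(cols))
        disp = estimate_tagwise_dispersion(sub, group_labels=[0] * len(cols), prior_df=0.0)
        keep &= disp.tagwise_bcv < max_bcv
    return [str(g) for g in experiment.counts.index[keep]]


def select_candidates(timelines: ZTimelines, n_positive: int = 9, n_negative: int = 9,
                      min_r2: float = 0.8) -> pd.DataFrame:
    """Top positive- and negative-slope genes among consistent (R^2) timelines.

    Returns a frame ordered positives (descending slope) then negatives
    (ascending slope) with columns ``slope, r2, sign``; ties on slope break
    by lexicographic gene ID.  Raises when either sign has too few eligible
    genes.
    """
    stats = pd.DataFrame({"slope": timelines.slope, "r2": timelines.r2})
    eligible = stats[stats["r2"] >= min_r2]
    pos = eligible[eligible["slope"] > 0]
    neg = eligible[eligible["slope"] < 0]
    if len(pos) < n_positive or len(neg) < n_negative:
        raise MarkerSelectionError(
            f"insufficient eligible genes: {len(pos)} positive-slope and "
            f"{len(neg)} negative-slope candidates at r2 >= {min_r2} "
            f"(requested {n_positive} + {n_negative})"
        )
    # deterministic tie-break: sort by gene id first (stable sort keeps it on ties)
    pos = pos.sort_index(kind="stable").sort_values("slope", ascending=False, kind="stable")
    neg = neg.sort_index(kind="stable").sort_values("slope", ascending=True, kind="stable")
    chosen = pd.concat([pos.head(n_positive).assign(sign="positive"),
                        neg.head(n_negative).assign(sign="negative")])
    chosen.index.name = "gene_id"
    return chosen


def select_markers(experiment: CountExperiment,
                   bcv_timepoints: Sequence[float] = DEFAULT_BCV_TIMEPOINTS,
                   max_bcv: float = 0.075, n_positive: int = 9, n_negative: int = 9,
                   min_r2: float = 0.8,
                   z_timepoints: Sequence[float] | None = None) -> pd.DataFrame:
    """BCV filter + Z-timeline fit + slope selection in one call."""
    eligible = bcv_filter(experiment, timepoints=bcv_timepoints, max_bcv=max_bcv)
    if not eligible:
        raise MarkerSelectionError(f"no genes pass the BCV < {max_bcv} filter")
    timelines = zscore_timeline(experiment, gene_ids=eligible, timepoints=z_timepoints)
    return select_candidates(timelines, n_positive=n_positive, n_negative=n_negative,
                             min_r2=min_r2)
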