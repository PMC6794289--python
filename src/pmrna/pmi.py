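"""Post-mortem interval estimation from a qRT-PCR marker panel.

Each animal's raw cycle-threshold (Ct) values are internally normalised by
subtracting that animal's mean Ct across the whole panel (delta-Ct), which
removes per-animal template-amount shifts without a housekeeping gene.  An
exhaustive ensemble of ordinary least-squares regressions

    PMI ~ 1 + dCt_g1 + dCt_g2 + dCt_g3

is fitted over every 3-gene combination of the panel (C(18,3) = 816 for an
18-gene panel).  Models are screened on the overall regression F-test
p-value (p <= threshold by default; the opposite direction is available as
a flag) and each retained model's prediction is averaged — the unweighted
mean is the final PMI estimate.  Leave-one-animal-out (LOAO) refitting
provides the evaluation protocol (signed errors, MAE, RMSE).

Entry points follow the model/results convention: :class:`PmiEnsembleModel`
wraps a :class:`CtPanel` and ``fit()`` returns :class:`PmiEnsembleResults`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .counts import _read_table, _write_table
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

CT_COLUMNS = ("gene_id", "animal_id", "pmi_hours", "ct")


class CtPanel:
    """Long-format gene x animal Ct table, optionally internally normalised.

    Every animal must carry a complete panel (one Ct per gene).  After
    :meth:`normalize`, records carry ``delta_ct`` = Ct minus the animal's
    mean Ct over the panel, which is zero-mean within each animal.
    """

    def __init__(self, data: pd.DataFrame, normalized: bool = False):
        data = data.copy().reset_index(drop=True)
        missing = [c for c in CT_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"Ct panel is missing columns: {missing}")
        if normalized and "delta_ct" not in data.columns:
            raise ValidationError("normalized panel must carry a delta_ct column")
        data["gene_id"] = data["gene_id"].astype(str)
        data["animal_id"] = data["animal_id"].astype(str)
        data["pmi_hours"] = data["pmi_hours"].astype(float)

        pivot = data.pivot_table(index="animal_id", columns="gene_id", values="ct", aggfunc="count")
        counts = pivot.fillna(0).to_numpy()
        if (counts != 1).any():
            rows, cols = np.nonzero(counts != 1)
            bad = [(pivot.index[r], pivot.columns[c]) for r, c in zip(rows, cols)][:10]
            raise ValidationError(f"incomplete or duplicated panel records for (animal, gene): {bad}")
        pmi_spread = data.groupby("animal_id")["pmi_hours"].nunique()
        if (pmi_spread != 1).any():
            raise ValidationError(
                f"inconsistent pmi_hours within animals: {list(pmi_spread.index[pmi_spread != 1])}"
            )
        self.data = data
        self.normalized = bool(normalized)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def animals(self) -> list[str]:
        return sorted(self.data["animal_id"].unique())

    def pmi_by_animal(self) -> pd.Series:
        return self.data.groupby("animal_id")["pmi_hours"].first().loc[self.animals]

    def normalize(self) -> "CtPanel":
        """Internal per-animal normalisation; errors on a second call."""
        if self.normalized:
            raise ValidationError("panel is already normalized")
        data = self.data.copy()
        data["delta_ct"] = data["ct"] - data.groupby("animal_id")["ct"].transform("mean")
        return CtPanel(data, normalized=True)

    def wide_delta(self) -> pd.DataFrame:
        """animals x genes matrix of delta-Ct values."""
        if not self.normalized:
            raise ValidationError("panel must be normalized before regression")
        return self.data.pivot(index="animal_id", columns="gene_id", values="delta_ct")

    def subset_animals(self, animals: Sequence[str]) -> "CtPanel":
        animals = set(map(str, animals))
        return CtPanel(self.data[self.data["animal_id"].isin(animals)], normalized=self.normalized)

    def write_csv(self, path, comments: Mapping[str, object] | None = None) -> None:
        _write_table(self.data.set_index("gene_id"), path, index_label="gene_id",
                     comments=comments, sep=",")

    @classmethod
    def from_csv(cls, path) -> "CtPanel":
        data = _read_table(path, sep=",", index_col=None)
        return cls(data, normalized="delta_ct" in data.columns)


def normalize_ct(panel: CtPanel) -> CtPanel:
    """Subtract each animal's panel-mean Ct from its Ct values (delta-Ct)."""
    return panel.normalize()


def enumerate_triples(gene_ids: Sequence[str]) -> list[tuple[str, str, str]]:
    """All C(n,3) unordered 3-gene combinations, lexicographically ordered."""
    gene_ids = sorted(map(str, set(gene_ids)))
    if len(gene_ids) < 3:
        raise ValidationError("at least 3 genes are required")
    return list(itertools.combinations(gene_ids, 3))


@dataclass(frozen=True)
class PmiModel:
    """One 3-gene OLS regression of PMI on delta-Ct values."""

    genes: tuple[str, str, str]
    intercept: float
    coefficients: tuple[float, float, float]  # hours per delta-Ct cycle
    model_p: float
    r2: float

    def predict(self, delta: pd.DataFrame) -> pd.Series:
        x = delta[list(self.genes)].to_numpy(float)
        return pd.Series(self.intercept + x @ np.asarray(self.coefficients),
                         index=delta.index, name="+".join(self.genes))


@dataclass
class PmiEnsemble:
    """Retained 3-gene models plus the mean-aggregation prediction rule."""

    models: list[PmiModel]
    p_threshold: float
    direction: str = "le"
    n_candidates: int = 0
    n_skipped_singular: int = 0
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.direction not in ("le", "ge"):
            raise ValidationError("direction must be 'le' or 'ge'")

    def __len__(self) -> int:
        return len(self.models)


def _fit_one_triple(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, float] | None:
    """OLS fit with intercept; returns (beta, F-test p, r2) or None if singular."""
    n = y.size
    design = np.column_stack([np.ones(n), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return None
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return None
    k = design.shape[1] - 1
    df_resid = n - design.shape[1]
    if df_resid < 1:
        return None
    r2 = 1.0 - rss / tss
    if rss <= 1e-12 * tss:
        p = 0.0
    else:
        f_stat = ((tss - rss) / k) / (rss / df_resid)
        p = float(f_dist.sf(f_stat, k, df_resid))
    return beta, p, r2


def fit_ensemble(panel: CtPanel, p_threshold: float = 0.05,
                 direction: str = "le") -> PmiEnsemble:
    """Fit every 3-gene regression and retain models passing the p filter.

    ``direction='le'`` keeps models with overall F-test p <= threshold (the
    default); ``'ge'`` reproduces the literal >= reading.  Singular designs
    are skipped with a logged warning rather than failing the run.
    """
    if not panel.normalized:
        panel = panel.normalize()
    delta = panel.wide_delta()
    y = panel.pmi_by_animal().loc[delta.index].to_numpy(float)
    if y.size < 5:
        raise ValidationError("at least 5 animals are required (residual df >= 1)")
    if direction not in ("le", "ge"):
        raise ValidationError("direction must be 'le' or 'ge'")

    triples = enumerate_triples(panel.genes)
    models: list[PmiModel] = []
    skipped = 0
    values = delta.to_numpy(float)
    col = {g: i for i, g in enumerate(delta.columns)}
    for triple in triples:
        x = values[:, [col[g] for g in triple]]
        fit = _fit_one_triple(y, x)
        if fit is None:
            skipped += 1
            continue
        beta, p, r2 = fit
        keep = p <= p_threshold if direction == "le" else p >= p_threshold
        if keep:
            models.append(PmiModel(genes=triple, intercept=float(beta[0]),
                                   coefficients=tuple(float(b) for b in beta[1:]),
                                   model_p=p, r2=r2))
    if skipped:
        logger.warning("skipped %d of %d singular 3-gene designs", skipped, len(triples))
    return PmiEnsemble(models=models, p_threshold=float(p_threshold), direction=direction,
                       n_candidates=len(triples), n_skipped_singular=skipped)


@dataclass
class PmiPredictions:
    """Per-animal ensemble estimates with per-model diagnostics."""

    estimates: pd.Series            # final (mean-aggregated) PMI estimate, hours
    per_model: pd.DataFrame         # animals x retained models
    n_models: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate_hours": self.estimates,
                             "n_models": self.n_models})


def predict_pmi(ensemble: PmiEnsemble, panel: CtPanel) -> PmiPredictions:
    """Ensemble PMI estimate per animal: unweighted mean of retained models.

    Estimates are not clipped; negative values are reported as-is.
    """
    if len(ensemble) == 0:
        raise ValidationError("ensemble contains no retained models")
    if not panel.normalized:
        panel = panel.normalize()
    delta = panel.wide_delta()
    needed = sorted({g for m in ensemble.models for g in m.genes})
    missing = sorted(set(needed) - set(delta.columns))
    if missing:
        raise ValidationError(f"panel is missing genes used by the ensemble: {missing}")
    per_model = pd.concat([m.predict(delta) for m in ensemble.models], axis=1)
    if ensemble.aggregation == "median":
        estimates = per_model.median(axis=1)
    else:
        estimates = per_model.mean(axis=1)
    estimates.name = "estimate_hours"
    return PmiPredictions(estimates=estimates, per_model=per_model, n_models=len(ensemble))


@dataclass
class LoaoResult:
    """Leave-one-animal-out evaluation of the ensemble."""

    predictions: pd.DataFrame   # animal_id -> truth_hours, estimate_hours, error_hours, n_models
    mae: float
    rmse: float

    @property
    def errors(self) -> pd.Series:
        return self.predictions["error_hours"]


def evaluate_loao(panel: CtPanel, p_threshold: float = 0.05,
                  direction: str = "le") -> LoaoResult:
    """Leave-one-animal-out cross-validation.

    Normalisation is within-animal, so normalising the full panel first
    leaks nothing between train and test animals.
    """
    if not panel.normalized:
        panel = panel.normalize()
    animals = panel.animals
    if len(animals) < 6:
        raise ValidationError("at least 6 animals are required for LOAO evaluation")
    truth = panel.pmi_by_animal()
    rows = []
    for held_out in animals:
        train = panel.subset_animals([a for a in animals if a != held_out])
        test = panel.subset_animals([held_out])
        ensemble = fit_ensemble(train, p_threshold=p_threshold, direction=direction)
        pred = predict_pmi(ensemble, test)
        est = float(pred.estimates.iloc[0])
        rows.append({"animal_id": held_out, "truth_hours": float(truth[held_out]),
                     "estimate_hours": est, "error_hours": est - float(truth[held_out]),
                     "n_models": pred.n_models})
    frame = pd.DataFrame(rows).set_index("animal_id")
    err = frame["error_hours"].to_numpy()
    return LoaoResult(predictions=frame, mae=float(np.mean(np.abs(err))),
                      rmse=float(np.sqrt(np.mean(err**2))))


# ---------------------------------------------------------------------------
# model/results facade and table I/O

class PmiEnsembleModel:
    """Exhaustive 3-gene regression ensemble over a normalised Ct panel."""

    def __init__(self, panel: CtPanel, p_threshold: float = 0.05, direction: str = "le"):
        self.panel = panel if panel.normalized else panel.normalize()
        self.p_threshold = float(p_threshold)
        self.direction = direction

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PmiEnsembleModel":
        return cls(CtPanel(data), **kwargs)

    def fit(self) -> "PmiEnsembleResults":
        ensemble = fit_ensemble(self.panel, p_threshold=self.p_threshold,
                                direction=self.direction)
        return PmiEnsembleResults(model=self, ensemble=ensemble)


@dataclass
class PmiEnsembleResults:
    model: PmiEnsembleModel
    ensemble: PmiEnsemble

    def predict(self, panel: CtPanel | None = None) -> PmiPredictions:
        return predict_pmi(self.ensemble, panel if panel is not None else self.model.panel)

    def loao(self) -> LoaoResult:
        return evaluate_loao(self.model.panel, p_threshold=self.model.p_threshold,
                             direction=self.model.direction)

    def models_table(self) -> pd.DataFrame:
        rows = [{"gene_1": m.genes[0], "gene_2": m.genes[1], "gene_3": m.genes[2],
                 "intercept": m.intercept, "coef_1": m.coefficients[0],
                 "coef_2": m.coefficients[1], "coef_3": m.coefficients[2],
                 "model_p": m.model_p, "r2": m.r2} for m in self.ensemble.models]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        e = self.ensemble
        lines = [
            "PMI regression ensemble",
            "=" * 47,
            f"panel genes:             {len(self.model.panel.genes)}",
            f"animals:                 {len(self.model.panel.animals)}",
            f"candidate 3-gene models: {e.n_candidates}",
            f"retained models:         {len(e)} (p {'<=' if e.direction == 'le' else '>='} {e.p_threshold:g})",
            f"skipped singular:        {e.n_skipped_singular}",
            f"aggregation:             {e.aggregation}",
        ]
        if e.models:
            r2s = np.array([m.r2 for m in e.models])
            lines.append(f"retained model r2:       median {np.median(r2s):.3f}, "
                         f"range [{r2s.min():.3f}, {r2s.max():.3f}]")
        return "\n".join(lines)


def write_models_tsv(results: PmiEnsembleResults, path, comments=None) -> None:
    table = results.models_table()
    table.insert(0, "model_id", np.arange(len(table)))
    _write_table(table.set_index("model_id"), path, index_label="model_id", comments=comments)


def read_models_tsv(path, p_threshold: float = 0.05, direction: str = "le") -> PmiEnsemble:
    table = _read_table(path)
    models = [PmiModel(genes=(str(r.gene_1), str(r.gene_2), str(r.gene_3)),
                       intercept=float(r.intercept),
                       coefficients=(float(r.coef_1), float(r.coef_2), float(r.coef_3)),
                       model_p=float(r.model_p), r2=float(r.r2))
              for r in table.itertuples()]
    return PmiEnsemble(models=models, p_threshold=p_threshold, direction=direction,
                       n_candidates=len(models))
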