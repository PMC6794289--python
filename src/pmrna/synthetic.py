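"""Synthetic post-mortem transcriptome generator.

Ground truth is a per-gene exponential decay model with no synthesis term:
after death, transcript ``g`` with baseline abundance ``a_g`` (arbitrary
molecule units) decays as ``a_g * exp(-lambda_g * t)``.  Sequencing observes
only the composition: at fixed depth ``L`` the expected count of gene ``g``
at post-mortem time ``t`` is ``L * p_g(t)`` with

    p_g(t) = a_g exp(-lambda_g t) / sum_h a_h exp(-lambda_h t).

Uniform decay is therefore invisible; only decay relative to the
transcriptome average is observable, so slowly decaying genes appear
relatively upregulated ("preserved") and fast ones downregulated
("degraded").  Replicate noise follows a negative-binomial observation
model with variance ``mu + bcv**2 * mu**2`` (gamma-Poisson mixture); a
biological coefficient of variation (BCV) of 0.1 emulates genetically
identical model organisms and 0.4 outbred/human data.

The module also simulates the qRT-PCR side of the study (cycle-threshold
panels with Ct = c0 - log2 abundance + Gaussian noise) and homolog maps
with configurable unmapped/multi-mapped fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CountExperiment
from .exceptions import ValidationError
from .homology import HomologMap
from .pmi import CtPanel

LN2 = float(np.log(2.0))

DECAY_CLASSES = ("stable", "background", "fast")
BIOTYPES = ("protein_coding", "lncRNA", "pseudogene")

#: default class mix: both preserved and degraded calls non-empty by 24 h
DEFAULT_CLASS_PROPORTIONS: tuple[float, float, float] = (0.1, 0.8, 0.1)
#: per-class decay-rate intervals (per hour), ordered stable < background < fast
DEFAULT_RATE_RANGES: Mapping[str, tuple[float, float]] = {
    "stable": (0.0, 0.002),
    "background": (0.02, 0.06),
    "fast": (0.10, 0.30),
}
DEFAULT_BIOTYPE_PROPORTIONS: tuple[float, float, float] = (0.85, 0.10, 0.05)

#: harvest grids used in the study designs this generator emulates
MOUSE_PMI_GRID: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 3.0, 6.0, 12.0, 24.0)
BABOON_PMI_GRID: tuple[float, ...] = (0.0, 3.0, 6.0, 24.0)
CT_PMI_GRID: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)


class DecayModel:
    """Collection of per-gene decay parameters (the simulation ground truth).

    Wraps a table with columns ``gene_id, baseline_abundance, decay_rate,
    decay_class, biotype`` (index gene_id).  ``decay_rate`` is lambda_g in
    1/h, ``baseline_abundance`` is a_g > 0.
    """

    COLUMNS = ("baseline_abundance", "decay_rate", "decay_class", "biotype")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "gene_id" in table.columns:
            table = table.set_index("gene_id")
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"decay model table is missing columns: {missing}")
        if table.index.has_duplicates:
            raise ValidationError("duplicate gene_id in decay model")
        if len(table) < 1:
            raise ValidationError("decay model must contain at least one gene")
        if (table["decay_rate"].to_numpy(float) < 0).any():
            raise ValidationError("decay rates must be non-negative")
        if (table["baseline_abundance"].to_numpy(float) <= 0).any():
            raise ValidationError("baseline abundances must be strictly positive")
        bad_class = set(table["decay_class"]) - set(DECAY_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown decay classes: {sorted(bad_class)}")
        table.index = table.index.astype(str)
        self.table = table.sort_index()

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def decay_rates(self) -> pd.Series:
        return self.table["decay_rate"].astype(float)

    @property
    def baselines(self) -> pd.Series:
        return self.table["baseline_abundance"].astype(float)

    def expected_proportions(self, t: float) -> pd.Series:
        return expected_proportions(self, t)

    def simulate(self, design: "SimDesign") -> CountExperiment:
        return simulate_counts(self, design)

    def annotations(self) -> pd.DataFrame:
        """Gene annotation table carrying the simulation truth columns."""
        ann = pd.DataFrame(index=self.table.index)
        ann["biotype"] = self.table["biotype"]
        ann["true_lambda"] = self.table["decay_rate"]
        ann["true_class"] = self.table["decay_class"]
        ann["true_baseline"] = self.table["baseline_abundance"]
        ann.index.name = "gene_id"
        return ann


@dataclass(frozen=True)
class SimDesign:
    """Design of one simulated sequencing experiment.

    ``pmi_hours`` must contain 0 (the baseline group for contrasts) and
    ``replicates_per_timepoint`` must be at least 2 (dispersion is
    inestimable otherwise).  ``library_size`` is the expected reads per
    sample; ``bcv`` the replicate biological coefficient of variation
    (``bcv == 0`` selects an exact Poisson branch).
    """

    species: str = "mouse"
    tissue: str = "retina"
    pmi_hours: tuple[float, ...] = MOUSE_PMI_GRID
    replicates_per_timepoint: int = 4
    library_size: int = 1_000_000
    bcv: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        hours = np.asarray(self.pmi_hours, dtype=float)
        if hours.size == 0 or (hours < 0).any():
            raise ValidationError("pmi_hours must be non-empty and non-negative")
        if len(set(hours.tolist())) != hours.size:
            raise ValidationError("pmi_hours contains duplicates")
        if not np.any(np.isclose(hours, 0.0)):
            raise ValidationError("pmi_hours must contain 0 (the baseline group)")
        if self.replicates_per_timepoint < 2:
            raise ValidationError("replicates_per_timepoint must be >= 2")
        if self.library_size < 1:
            raise ValidationError("library_size must be a positive integer")
        if self.bcv < 0:
            raise ValidationError("bcv must be non-negative")

    def with_seed(self, seed: int) -> "SimDesign":
        return replace(self, seed=int(seed))


def _check_simplex(p: Sequence[float], name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name} must be a 3-simplex (non-negative, summing to 1)")
    return p


def generate_decay_model(
    n_genes: int,
    class_proportions: Sequence[float] = DEFAULT_CLASS_PROPORTIONS,
    rate_ranges: Mapping[str, tuple[float, float]] = DEFAULT_RATE_RANGES,
    baseline_log_sd: float = 1.0,
    biotype_proportions: Sequence[float] = DEFAULT_BIOTYPE_PROPORTIONS,
    seed: int | None = None,
    gene_prefix: str = "G",
) -> DecayModel:
    """Draw a random :class:`DecayModel`.

    Classes are drawn from ``class_proportions`` (stable, background, fast);
    lambda_g is uniform within its class interval, which must be
    non-negative and non-overlapping in the order stable <= background <=
    fast; a_g is log-normal with the given log-SD.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    class_p = _check_simplex(class_proportions, "class_proportions")
    biotype_p = _check_simplex(biotype_proportions, "biotype_proportions")
    ranges = {c: tuple(map(float, rate_ranges[c])) for c in DECAY_CLASSES}
    for c, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValidationError(f"rate range for class '{c}' must satisfy 0 <= low <= high")
    if ranges["stable"][1] > ranges["background"][0] or ranges["background"][1] > ranges["fast"][0]:
        raise ValidationError("rate ranges must be ordered stable <= background <= fast without overlap")

    rng = np.random.default_rng(seed)
    classes = rng.choice(len(DECAY_CLASSES), size=n_genes, p=class_p)
    lam = np.empty(n_genes)
    for k, c in enumerate(DECAY_CLASSES):
        mask = classes == k
        lo, hi = ranges[c]
        lam[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    baseline = rng.lognormal(mean=0.0, sigma=baseline_log_sd, size=n_genes)
    biotypes = rng.choice(len(BIOTYPES), size=n_genes, p=biotype_p)

    width = max(5, len(str(n_genes)))
    table = pd.DataFrame(
        {
            "gene_id": [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)],
            "baseline_abundance": baseline,
            "decay_rate": lam,
            "decay_class": [DECAY_CLASSES[k] for k in classes],
            "biotype": [BIOTYPES[k] for k in biotypes],
        }
    )
    return DecayModel(table)


def expected_proportions(model: DecayModel, t: float) -> pd.Series:
    """Relative abundance of every gene at post-mortem time ``t`` hours."""
    if t < 0:
        raise ValidationError("t must be non-negative")
    lam = model.decay_rates.to_numpy()
    a = model.baselines.to_numpy()
    w = a * np.exp(-lam * float(t))
    total = w.sum()
    if total <= 0:  # all transcripts decayed below floating point
        raise ValidationError(f"total abundance underflowed to zero at t={t}")
    return pd.Series(w / total, index=model.table.index, name=f"p_{t}h")


def simulate_counts(model: DecayModel, design: SimDesign) -> CountExperiment:
    """Simulate a fixed-depth sequencing experiment from a decay model.

    Per sample at time ``t`` the gene means are ``L * p_g(t)``; counts are
    negative-binomial (gamma-Poisson) with variance ``mu + bcv^2 mu^2``, or
    exactly Poisson when ``bcv == 0``.
    """
    rng = np.random.default_rng(design.seed)
    phi = design.bcv**2
    genes = model.table.index
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for t in design.pmi_hours:
        p = expected_proportions(model, t).to_numpy()
        mu = design.library_size * p
        for rep in range(1, design.replicates_per_timepoint + 1):
            if phi == 0.0:
                counts = rng.poisson(mu)
            else:
                lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
                counts = rng.poisson(lam)
            sid = f"{design.species}_{design.tissue}_{t:g}h_r{rep}"
            columns[sid] = counts.astype(np.int64)
            sheet_rows.append(
                {"sample_id": sid, "species": design.species, "tissue": design.tissue,
                 "pmi_hours": float(t), "replicate": rep}
            )
    counts_df = pd.DataFrame(columns, index=genes)
    counts_df.index.name = "gene_id"
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    return CountExperiment(counts=counts_df, sample_sheet=sheet, gene_annotations=model.annotations())


def simulate_ct_panel(
    model: DecayModel,
    panel_genes: Sequence[str],
    pmi_hours: Sequence[float] = CT_PMI_GRID,
    replicates: int = 4,
    ct_noise_sd: float = 0.25,
    seed: int | None = None,
    baseline_ct: float = 30.0,
) -> CtPanel:
    """Simulate a qRT-PCR cycle-threshold panel over a PMI grid.

    ``Ct = c0 - log2(a_g exp(-lambda_g t)) + N(0, ct_noise_sd)`` with
    amplification efficiency fixed at 2, so a transcript halving per hour
    gains exactly one cycle per hour.  One animal per (PMI, replicate).
    """
    panel_genes = [str(g) for g in panel_genes]
    unknown = sorted(set(panel_genes) - set(model.table.index))
    if unknown:
        raise ValidationError(f"panel genes absent from decay model: {unknown}")
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd must be non-negative")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    a = model.baselines.loc[panel_genes].to_numpy()
    lam = model.decay_rates.loc[panel_genes].to_numpy()
    records = []
    for t in pmi_hours:
        if t < 0:
            raise ValidationError("pmi_hours must be non-negative")
        for rep in range(1, replicates + 1):
            animal = f"A{t:g}h_r{rep}"
            ct = baseline_ct - np.log2(a) + lam * float(t) / LN2
            if ct_noise_sd > 0:
                ct = ct + rng.normal(0.0, ct_noise_sd, size=ct.size)
            for g, c in zip(panel_genes, ct):
                records.append({"gene_id": g, "animal_id": animal,
                                "pmi_hours": float(t), "ct": float(c)})
    return CtPanel(pd.DataFrame(records))


def simulate_homolog_map(
    source_genes: Sequence[str],
    frac_unmapped: float = 0.11,
    frac_multimapped: float = 0.05,
    seed: int | None = None,
    target_prefix: str = "HUM",
) -> HomologMap:
    """Random source -> target homolog map.

    Each source gene maps to 0 targets (probability ``frac_unmapped``),
    2-3 targets (``frac_multimapped``), or exactly 1 otherwise.  Target IDs
    carry a sortable, zero-padded numeric suffix.
    """
    if frac_unmapped < 0 or frac_multimapped < 0 or frac_unmapped + frac_multimapped > 1:
        raise ValidationError("frac_unmapped and frac_multimapped must be non-negative and sum to <= 1")
    source_genes = [str(g) for g in source_genes]
    rng = np.random.default_rng(seed)
    n = len(source_genes)
    cat = rng.choice(3, size=n, p=[frac_unmapped, frac_multimapped, 1 - frac_unmapped - frac_multimapped])
    n_targets_per_gene = np.where(cat == 0, 0, np.where(cat == 1, rng.integers(2, 4, size=n), 1))
    total = int(n_targets_per_gene.sum())
    pool = max(10 * total, 100)
    suffixes = rng.choice(pool, size=total, replace=False)
    rows = []
    k = 0
    for g, m in zip(source_genes, n_targets_per_gene):
        for _ in range(int(m)):
            rows.append({"source_id": g, "target_id": f"{target_prefix}{int(suffixes[k]):07d}"})
            k += 1
    return HomologMap(pd.DataFrame(rows, columns=["source_id", "target_id"]))


def fdr_benchmark_model(
    n_genes: int,
    frac_decayed: float = 0.10,
    fold_change: float = 4.0,
    at_hours: float = 24.0,
    decayed_abundance_scale: float = 0.1,
    baseline_log_sd: float = 1.0,
    seed: int | None = None,
) -> DecayModel:
    """Decay model for false-discovery benchmarking of the classifier.

    A fraction ``frac_decayed`` of genes decays ``fold_change``-fold by
    ``at_hours``; the rest do not decay and are the true nulls.  Decayed
    genes' baseline abundance is scaled by ``decayed_abundance_scale`` so
    they carry only a small share of the fixed sequencing depth: under the
    compositional observation model a large decaying mass genuinely raises
    every other gene's relative abundance, which is a true signal rather
    than a false discovery and would confound a calibration measurement.
    """
    if not 0 < frac_decayed < 1:
        raise ValidationError("frac_decayed must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_fast = int(round(frac_decayed * n_genes))
    lam_fast = np.log(fold_change) / at_hours
    lam = np.zeros(n_genes)
    fast_idx = rng.permutation(n_genes)[:n_fast]
    lam[fast_idx] = lam_fast
    baseline = rng.lognormal(0.0, baseline_log_sd, size=n_genes)
    baseline[fast_idx] *= decayed_abundance_scale
    classes = np.array(["background"] * n_genes, dtype=object)
    classes[fast_idx] = "fast"
    width = max(5, len(str(n_genes)))
    table = pd.DataFrame(
        {
            "gene_id": [f"G{i:0{width}d}" for i in range(n_genes)],
            "baseline_abundance": baseline,
            "decay_rate": lam,
            "decay_class": classes,
            "biotype": "protein_coding",
        }
    )
    return DecayModel(table)
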