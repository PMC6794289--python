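"""End-to-end reproducible pipeline: simulate -> filter -> DE -> markers -> PMI -> overlap.

A single flat :class:`PipelineConfig` (YAML-serialisable, unknown keys
rejected) drives the whole run.  One master seed deterministically derives
per-stage seeds, every output table starts with ``#`` comment lines
recording the seed and a config hash, and a markdown report summarises the
headline numbers (per-PMI preserved/degraded matrix, selected markers,
ensemble size, LOAO MAE, homolog overlap).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, homology, markers, pmi, synthetic
from .counts import CountExperiment, cpm, filter_expressed, _write_table
from .exceptions import PipelineError, ValidationError

logger = logging.getLogger("pmrna.pipeline")


@dataclass
class PipelineConfig:
    """Flat, fully serialisable configuration of a pipeline run."""

    seed: int = 0
    # simulator
    n_genes: int = 15_000
    mouse_pmi_hours: tuple[float, ...] = synthetic.MOUSE_PMI_GRID
    baboon_pmi_hours: tuple[float, ...] = synthetic.BABOON_PMI_GRID
    replicates_per_timepoint: int = 4
    library_size: int = 1_000_000
    bcv: float = 0.1
    stable_prop: float = 0.1
    background_prop: float = 0.8
    fast_prop: float = 0.1
    baseline_log_sd: float = 1.0
    tissue: str = "retina"
    # expression filter
    min_cpm: float = 1.0
    min_samples: int = 4
    # DE
    alpha: float = 0.05
    prior_df: float = 10.0
    # markers
    max_bcv: float = 0.075
    n_pos: int = 9
    n_neg: int = 9
    min_r2: float = 0.8
    marker_timepoints: tuple[float, ...] = markers.DEFAULT_BCV_TIMEPOINTS
    # PMI panel / ensemble
    ct_pmi_hours: tuple[float, ...] = synthetic.CT_PMI_GRID
    ct_replicates: int = 4
    ct_noise_sd: float = 0.25
    p_threshold: float = 0.05
    p_direction: str = "le"
    # homologs
    frac_unmapped_mouse: float = 0.11
    frac_unmapped_baboon: float = 0.07
    frac_multimapped: float = 0.03
    overlap_contrast_hours: tuple[float, ...] = (6.0, 24.0)

    def __post_init__(self) -> None:
        for name in ("mouse_pmi_hours", "baboon_pmi_hours", "marker_timepoints",
                     "ct_pmi_hours", "overlap_contrast_hours"):
            setattr(self, name, tuple(float(t) for t in getattr(self, name)))
        if self.p_direction not in ("le", "ge"):
            raise ValidationError("p_direction must be 'le' or 'ge'")

    def to_yaml(self, path=None) -> str:
        data = {}
        for f in fields(self):
            v = getattr(self, f.name)
            data[f.name] = list(v) if isinstance(v, tuple) else v
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.md5(self.to_yaml().encode()).hexdigest()[:12]


def _setup_logging(run_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler) for h in logger.handlers)
    if not logger.handlers:
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(stream)
    if not have_file:
        fh = logging.FileHandler(run_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(fh)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write all artifacts into ``out_dir``.

    Returns a summary dict (also rendered to ``report.md``).  A stage
    failure raises :class:`PipelineError` with a stage-named message;
    outputs written before the failure are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    meta = {"seed": config.seed, "config_hash": config.config_hash}
    config.to_yaml(out / "config.yaml")
    stage_seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(8)]
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        class_props = (config.stable_prop, config.background_prop, config.fast_prop)
        mouse_model = synthetic.generate_decay_model(
            config.n_genes, class_proportions=class_props,
            baseline_log_sd=config.baseline_log_sd, seed=stage_seeds[0], gene_prefix="MUS")
        baboon_model = synthetic.generate_decay_model(
            config.n_genes, class_proportions=class_props,
            baseline_log_sd=config.baseline_log_sd, seed=stage_seeds[1], gene_prefix="PAP")
        mouse = synthetic.simulate_counts(mouse_model, synthetic.SimDesign(
            species="mouse", tissue=config.tissue, pmi_hours=config.mouse_pmi_hours,
            replicates_per_timepoint=config.replicates_per_timepoint,
            library_size=config.library_size, bcv=config.bcv, seed=stage_seeds[2]))
        baboon = synthetic.simulate_counts(baboon_model, synthetic.SimDesign(
            species="baboon", tissue=config.tissue, pmi_hours=config.baboon_pmi_hours,
            replicates_per_timepoint=config.replicates_per_timepoint,
            library_size=config.library_size, bcv=config.bcv, seed=stage_seeds[3]))
        for name, exp in (("mouse", mouse), ("baboon", baboon)):
            exp.write(out / f"{name}_counts.tsv", out / f"{name}_samples.tsv",
                      out / f"{name}_genes.tsv", comments=meta)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[simulate] {exc}") from exc

    experiments = {}
    try:
        stage("filter")
        for name, exp in (("mouse", mouse), ("baboon", baboon)):
            expressed = filter_expressed(cpm(exp), min_cpm=config.min_cpm,
                                         min_samples=config.min_samples)
            experiments[name] = exp.subset_genes(expressed)
            pd.Series(expressed, name="gene_id").to_frame().set_index("gene_id").pipe(
                _write_table, out / f"{name}_expressed.tsv", index_label="gene_id", comments=meta)
            summary[f"n_expressed_{name}"] = len(expressed)
            logger.info("%s: %d expressed genes", name, len(expressed))
    except Exception as exc:
        raise PipelineError(f"[filter] {exc}") from exc

    de_results = {}
    try:
        stage("de")
        for name, exp in experiments.items():
            model = de.DecayDEModel(exp, alpha=config.alpha, prior_df=config.prior_df,
                                    filter_genes=False)
            res = model.fit()
            de_results[name] = res
            for t, tab in res.contrast_tables.items():
                _write_table(tab, out / f"de_{name}_{t:g}h.tsv", index_label="gene_id",
                             comments=meta)
            _write_table(res.count_table(), out / f"de_summary_{name}.tsv",
                         index_label="pmi_hours", comments=meta)
            summary[f"de_counts_{name}"] = res.count_table().to_dict("index")
            summary[f"common_bcv_{name}"] = round(res.dispersion.bcv, 4)
    except Exception as exc:
        raise PipelineError(f"[de] {exc}") from exc

    try:
        stage("select")
        candidates = markers.select_markers(
            experiments["mouse"], bcv_timepoints=config.marker_timepoints,
            max_bcv=config.max_bcv, n_positive=config.n_pos, n_negative=config.n_neg,
            min_r2=config.min_r2)
        _write_table(candidates, out / "markers.tsv", index_label="gene_id", comments=meta)
        summary["markers"] = list(candidates.index)
        logger.info("selected %d markers", len(candidates))
    except Exception as exc:
        raise PipelineError(f"[select] {exc}") from exc

    try:
        stage("train-pmi")
        panel = synthetic.simulate_ct_panel(
            mouse_model, list(candidates.index), pmi_hours=config.ct_pmi_hours,
            replicates=config.ct_replicates, ct_noise_sd=config.ct_noise_sd,
            seed=stage_seeds[4])
        panel.write_csv(out / "ct_panel.csv", comments=meta)
        fit = pmi.PmiEnsembleModel(panel, p_threshold=config.p_threshold,
                                   direction=config.p_direction).fit()
        pmi.write_models_tsv(fit, out / "pmi_models.tsv", comments=meta)
        summary["n_candidate_models"] = fit.ensemble.n_candidates
        summary["n_retained_models"] = len(fit.ensemble)
    except Exception as exc:
        raise PipelineError(f"[train-pmi] {exc}") from exc

    try:
        stage("eval-pmi")
        loao = fit.loao()
        _write_table(loao.predictions, out / "pmi_loao.tsv", index_label="animal_id",
                     comments=meta)
        summary["loao_mae_hours"] = round(loao.mae, 3)
        summary["loao_rmse_hours"] = round(loao.rmse, 3)
        logger.info("LOAO MAE %.3f h", loao.mae)
    except Exception as exc:
        raise PipelineError(f"[eval-pmi] {exc}") from exc

    try:
        stage("overlap")
        maps = {
            "mouse": synthetic.simulate_homolog_map(
                experiments["mouse"].genes, frac_unmapped=config.frac_unmapped_mouse,
                frac_multimapped=config.frac_multimapped, seed=stage_seeds[5]),
            "baboon": synthetic.simulate_homolog_map(
                experiments["baboon"].genes, frac_unmapped=config.frac_unmapped_baboon,
                frac_multimapped=config.frac_multimapped, seed=stage_seeds[6]),
        }
        for name, hmap in maps.items():
            hmap.write_tsv(out / f"homologs_{name}.tsv", comments=meta)
        overlaps = []
        shared = [t for t in config.overlap_contrast_hours
                  if t in de_results["mouse"].contrast_tables
                  and t in de_results["baboon"].contrast_tables]
        for t in shared:
            for status in ("preserved", "degraded"):
                sets = {}
                for name in ("mouse", "baboon"):
                    tab = de_results[name].contrast_tables[t]
                    genes = tab.index[tab["status"] == status]
                    sets[name] = homology.resolve_homologs(genes, maps[name])
                overlaps.append(homology.overlap_sets(
                    sets["mouse"], sets["baboon"],
                    label_a=f"mouse {status} 0-{t:g}h", label_b=f"baboon {status} 0-{t:g}h"))
        table = homology.overlap_table(overlaps)
        _write_table(table.set_index("label_a"), out / "species_overlap.tsv",
                     index_label="label_a", comments=meta)
        summary["species_overlap"] = table.to_dict("records")
        bt = homology.biotype_breakdown(
            de_results["mouse"].contrast_tables[max(de_results["mouse"].contrasts)],
            experiments["mouse"].gene_annotations)
        _write_table(bt, out / "biotype_breakdown_mouse.tsv", index_label="biotype",
                     comments=meta)
    except Exception as exc:
        raise PipelineError(f"[overlap] {exc}") from exc

    try:
        stage("report")
        report = _render_report(config, summary, de_results, candidates, table)
        (out / "report.md").write_text(report)
    except Exception as exc:
        raise PipelineError(f"[report] {exc}") from exc
    logger.info("pipeline complete: %s", out)
    return summary


def _render_report(config: PipelineConfig, summary: dict, de_results: dict,
                   candidates: pd.DataFrame, overlap_df: pd.DataFrame) -> str:
    lines = [
        "# Post-mortem RNA pipeline report",
        "",
        f"- seed: {config.seed}",
        f"- config hash: {config.config_hash}",
        f"- simulated genes per species: {config.n_genes}",
        "",
        "## Expressed genes",
        "",
    ]
    for name in ("mouse", "baboon"):
        lines.append(f"- {name}: {summary[f'n_expressed_{name}']} "
                     f"(common BCV {summary[f'common_bcv_{name}']})")
    for name, res in de_results.items():
        lines += ["", f"## DE calls vs 0 h ({name})", "", "```",
                  res.count_table().to_string(), "```"]
    lines += ["", "## Selected marker genes", "", "```",
              candidates.to_string(), "```", "",
              "## PMI ensemble", "",
              f"- candidate 3-gene models: {summary['n_candidate_models']}",
              f"- retained models: {summary['n_retained_models']} "
              f"(p {'<=' if config.p_direction == 'le' else '>='} {config.p_threshold:g})",
              f"- LOAO MAE: {summary['loao_mae_hours']} h "
              f"(RMSE {summary['loao_rmse_hours']} h)",
              "", "## Cross-species overlap (human-homolog namespace)", "", "```",
              overlap_df.to_string(index=False), "```", ""]
    return "\n".join(lines)
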