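import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pmrna.counts import CountExperiment

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_experiment(counts: np.ndarray, pmi_hours, species="mouse", tissue="retina",
                    gene_prefix="G") -> CountExperiment:
    """Build a CountExperiment from a raw count array and per-sample PMI labels."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = [f"{gene_prefix}{i:04d}" for i in range(n_genes)]
    reps: dict[float, int] = {}
    sample_ids, rows = [], []
    for j, t in enumerate(pmi_hours):
        reps[t] = reps.get(t, 0) + 1
        sid = f"s{j:02d}_{t:g}h_r{reps[t]}"
        sample_ids.append(sid)
        rows.append({"sample_id": sid, "species": species, "tissue": tissue,
                     "pmi_hours": float(t), "replicate": reps[t]})
    cdf = pd.DataFrame(counts, index=genes, columns=sample_ids)
    sheet = pd.DataFrame(rows).set_index("sample_id")
    ann = pd.DataFrame({"biotype": "protein_coding"}, index=genes)
    return CountExperiment(counts=cdf, sample_sheet=sheet, gene_annotations=ann)


@pytest.fixture(scope="session")
def null_experiment():
    """Global-null simulation: every gene decays at the same rate."""
    from pmrna import synthetic

    model = synthetic.generate_decay_model(
        1000, class_proportions=(0.0, 1.0, 0.0),
        rate_ranges={"stable": (0.0, 0.0), "background": (0.03, 0.03), "fast": (0.03, 0.03)},
        seed=42)
    design = synthetic.SimDesign(pmi_hours=(0.0, 24.0), replicates_per_timepoint=4,
                                 library_size=1_000_000, bcv=0.1, seed=43)
    return synthetic.simulate_counts(model, design)


@pytest.fixture(scope="session")
def marker_panel():
    """Synthetic 18-gene Ct panel with 9 slow and 9 fast decayers, noise 0.25 cycles."""
    from pmrna import benchmarks, synthetic

    model = benchmarks.marker_panel_model(seed=5)
    return synthetic.simulate_ct_panel(model, model.genes, ct_noise_sd=0.25, seed=6)
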