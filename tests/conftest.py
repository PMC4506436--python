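import importlib.resources

import numpy as np
import pandas as pd
import pytest

import emtseq as e


@pytest.fixture(scope="session")
def benchmark_rows() -> pd.DataFrame:
    """Curated TF enrichment/depletion records with printed fold ratios."""
    ref = importlib.resources.files("emtseq.data") / "tf_enrichment_benchmark.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


@pytest.fixture(scope="session")
def sim_default():
    """A moderate six-group simulation shared by read-only tests:
    2000 genes, triplicates, NB dispersion 0.0155, 5% planted DEGs at
    |log2FC| = 1.5."""
    design = e.SimDesign(n_genes=2000, seed=1)
    cm, truth = e.generate_count_matrix(design)
    return design, cm, truth


@pytest.fixture(scope="session")
def fitted_default(sim_default):
    """Filtered + normalized matrix with dispersions and the CM-CE test."""
    _, cm, truth = sim_default
    cm_f, _ = e.filter_unresponsive(cm)
    cm_f.norm_factors = e.compute_scaling_factors(cm_f)
    fit = e.estimate_dispersion(cm_f)
    stats = e.lrt_contrast(fit, cm_f, e.ContrastSpec.pairwise("CM", "CE"))
    return cm_f, fit, stats, truth


@pytest.fixture()
def toy_counts() -> e.CountMatrix:
    """Two groups x 3 replicates, hand-set counts for rule fixtures."""
    counts = pd.DataFrame(
        {
            "A_1": [0, 900, 90, 0, 500, 0, 5, 100, 30, 40],
            "A_2": [0, 800, 80, 0, 450, 0, 0, 110, 25, 35],
            "A_3": [0, 700, 0, 0, 400, 1, 0, 105, 20, 30],
            "B_1": [0, 850, 0, 2, 0, 0, 0, 95, 28, 500],
            "B_2": [0, 750, 0, 1, 0, 0, 0, 100, 22, 480],
            "B_3": [0, 650, 0, 1, 0, 2, 0, 90, 18, 460],
        },
        index=[f"g{i}" for i in range(1, 11)],
    )
    groups = pd.Series(
        {s: s.split("_")[0] for s in counts.columns}, name="group"
    )
    return e.CountMatrix(counts=counts, groups=groups)


def make_expression_blocks(
    sizes: list[int], n_cols: int, separation: float, seed: int = 0
) -> pd.DataFrame:
    """Gaussian rows around well-separated block centers."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, separation, size=(len(sizes), n_cols))
    rows, labels = [], []
    for b, size in enumerate(sizes):
        rows.append(centers[b] + rng.normal(0.0, 1.0, size=(size, n_cols)))
        labels += [b] * size
    df = pd.DataFrame(
        np.vstack(rows),
        index=[f"r{i}" for i in range(sum(sizes))],
    )
    df.attrs["labels"] = labels
    return df
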