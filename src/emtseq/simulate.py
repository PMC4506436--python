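"""Synthetic-data generators with known ground truth.

These generators emulate the three inputs the pipeline consumes:

* a six-group, triplicate negative-binomial count matrix with planted
  mesenchymal-vs-epithelial DEGs (the two-factor EMT/TNF design:
  control epithelial/mesenchymal plus TNF-stimulated pairs at 1 h and
  12 h);
* a TF-experiment target-gene database with planted (K, k) overlap
  structure against a nominated DEG set;
* peak/annotation pairs on a toy chromosome with known true
  peak-to-gene assignments.

Counts follow the gamma-Poisson construction of NB(mean, phi) with
``var = mu + phi*mu**2``, so the planted dispersion is directly
comparable to estimates from the analysis stage.  Gene baseline means
are log-normally spread around ``baseline_mean`` (one decade of sd),
library sizes are log-normal with the stated coefficient of variation,
and planted DEGs scale the mean of every mesenchymal group by
``2**planted_log2fc`` (half up, half down).  All outputs are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg import CountMatrix
from .enrichment import TFExperiment, TFGeneSetDB
from .peaks import GeneModel, Peak

__all__ = [
    "SimDesign",
    "SimTruth",
    "generate_count_matrix",
    "generate_tf_database",
    "generate_peaks_and_annotation",
]

DEFAULT_GROUPS = ("CE", "CM", "T1E", "T1M", "T12E", "T12M")
MESENCHYMAL_GROUPS = frozenset({"CM", "T1M", "T12M"})
#: contrasts along which the planted mesenchymal effect is differential
PLANTED_CONTRASTS = ("CM-CE", "T1M-T1E", "T12M-T12E")


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the synthetic count experiment."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 3
    n_genes: int = 2000
    baseline_mean: float = 500.0
    dispersion: float = 0.0155
    planted_deg_fraction: float = 0.05
    planted_log2fc: float = 1.5
    library_size_cv: float = 0.1
    seed: int = 0
    gene_mean_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if not 0.0 <= self.planted_deg_fraction <= 1.0:
            raise ValueError("planted_deg_fraction must be in [0, 1]")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be nonnegative")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be nonnegative")
        if self.replicates_per_group <= 0:
            raise ValueError("replicates_per_group must be positive")
        if len(set(self.groups)) != len(self.groups) or not self.groups:
            raise ValueError("groups must be unique and nonempty")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.replicates_per_group


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    deg_per_contrast: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_tfs: dict[str, dict] = field(default_factory=dict)
    peak_to_gene: dict[str, str | None] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_count_matrix(design: SimDesign) -> tuple[CountMatrix, SimTruth]:
    """Draw the NB count matrix and record which genes were planted as
    mesenchymal-vs-epithelial DEGs (alternating up/down)."""
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)
    samples = [
        f"{g}_{r + 1}"
        for g in design.groups
        for r in range(design.replicates_per_group)
    ]
    group_of = {
        s: g
        for g, s_list in zip(
            design.groups,
            np.array_split(np.array(samples), len(design.groups)),
        )
        for s in s_list
    }

    base = design.baseline_mean * np.exp(
        rng.normal(0.0, design.gene_mean_log_sd, design.n_genes)
        - design.gene_mean_log_sd**2 / 2.0
    )
    n_planted = int(round(design.planted_deg_fraction * design.n_genes))
    planted_idx = rng.choice(design.n_genes, size=n_planted, replace=False)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1, -1)

    effect = np.ones((design.n_genes, len(design.groups)))
    mes_cols = [
        j for j, g in enumerate(design.groups) if g in MESENCHYMAL_GROUPS
    ]
    for idx, sign in zip(planted_idx, signs):
        effect[idx, mes_cols] = 2.0 ** (sign * design.planted_log2fc)

    if design.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(design.library_size_cv**2))
        lib_factor = np.exp(
            rng.normal(0.0, sigma, design.n_samples) - sigma**2 / 2.0
        )
    else:
        lib_factor = np.ones(design.n_samples)

    counts = np.empty((design.n_genes, design.n_samples), dtype=int)
    for j, s in enumerate(samples):
        gcol = design.groups.index(group_of[s])
        mu = base * effect[:, gcol] * lib_factor[j]
        lam = rng.gamma(
            shape=1.0 / design.dispersion, scale=design.dispersion * mu
        )
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=pd.Series(group_of).reindex(samples),
    )
    deg_map = {
        genes[idx]: int(sign) for idx, sign in zip(planted_idx, signs)
    }
    truth = SimTruth(
        deg_per_contrast={
            name: dict(sorted(deg_map.items())) for name in PLANTED_CONTRASTS
            if all(g in design.groups for g in name.split("-"))
        }
    )
    return cm, truth


def generate_tf_database(
    n_tfs: int,
    universe: list[str],
    planted: list[tuple[str, int, int]],
    deg_set: set[str],
    seed: int = 0,
) -> tuple[TFGeneSetDB, SimTruth]:
    """Build a TF-experiment database with planted overlap structure.

    ``planted`` holds (tf_id, K, k) triples: each planted experiment
    gets exactly ``K`` targets, ``k`` of them drawn from ``deg_set``.
    The remaining ``n_tfs - len(planted)`` null experiments draw their
    targets uniformly from the universe.
    """
    if n_tfs < len(planted):
        raise ValueError("n_tfs smaller than the number of planted TFs")
    universe = list(universe)
    uni_set = set(universe)
    if len(uni_set) != len(universe):
        raise ValueError("universe ids must be unique")
    deg_in = sorted(set(deg_set) & uni_set)
    if set(deg_set) - uni_set:
        raise ValueError("deg_set must be a subset of the universe")
    non_deg = sorted(uni_set - set(deg_in))
    rng = np.random.default_rng(seed)
    experiments: list[TFExperiment] = []
    truth = SimTruth()
    n, N = len(deg_in), len(universe)
    for tf_id, K, k in planted:
        if K > N:
            raise ValueError(f"{tf_id}: K={K} exceeds universe size {N}")
        if not 0 <= k <= min(K, n):
            raise ValueError(
                f"{tf_id}: overlap k={k} impossible for K={K}, |DEG|={n}"
            )
        if K - k > len(non_deg):
            raise ValueError(
                f"{tf_id}: K-k={K - k} exceeds non-DEG universe {len(non_deg)}"
            )
        inside = rng.choice(deg_in, size=k, replace=False)
        outside = rng.choice(non_deg, size=K - k, replace=False)
        targets = frozenset(inside) | frozenset(outside)
        experiments.append(
            TFExperiment(
                experiment_id=tf_id,
                tf_name=tf_id.split("@")[0],
                metadata=f"{tf_id.split('@')[0]}|synthetic|planted",
                targets=targets,
            )
        )
        truth.planted_tfs[tf_id] = {
            "K": K,
            "k": k,
            "fold_ratio": (k / n) / (K / N) if n and K else 0.0,
        }
    max_null_k = max(10, min(1500, N // 4))
    for i in range(n_tfs - len(planted)):
        K = int(rng.integers(50, max_null_k + 1))
        targets = frozenset(rng.choice(universe, size=K, replace=False))
        experiments.append(
            TFExperiment(
                experiment_id=f"NULLTF{i + 1:03d}",
                tf_name=f"NULLTF{i + 1:03d}",
                metadata=f"NULLTF{i + 1:03d}|synthetic|null",
                targets=targets,
            )
        )
    db = TFGeneSetDB(experiments=experiments, universe=frozenset(universe))
    return db, truth


def generate_peaks_and_annotation(
    n_genes: int,
    n_peaks: int,
    seed: int = 0,
    upstream: int = 5000,
    downstream: int = 1000,
) -> tuple[list[Peak], list[GeneModel], SimTruth]:
    """Gene models on a toy chromosome plus peaks at known offsets.

    Peaks cycle through five placement categories — inside the gene
    body, within the upstream promoter window, within the downstream
    window, just beyond the upstream window, and deep intergenic — and
    the truth records the expected target gene (or None) for the stated
    window sizes.  Genes alternate strands and are spaced widely enough
    that windows never overlap neighbours.
    """
    if n_genes <= 0 or n_peaks <= 0:
        raise ValueError("n_genes and n_peaks must be positive")
    rng = np.random.default_rng(seed)
    spacing = 6 * (upstream + downstream) + 12000
    genes: list[GeneModel] = []
    for i in range(n_genes):
        start = 2 * spacing + i * spacing
        length = int(rng.integers(2000, 8001))
        genes.append(
            GeneModel(
                gene_name=f"PG{i + 1:04d}",
                chrom="chrS",
                strand="+" if i % 2 == 0 else "-",
                tx_start=start,
                tx_end=start + length,
            )
        )
    categories = ("body", "upstream_in", "downstream_in", "upstream_out",
                  "intergenic")
    peaks: list[Peak] = []
    truth = SimTruth()
    width = 400
    for j in range(n_peaks):
        g = genes[j % n_genes]
        category = categories[j % len(categories)]
        five_prime = g.tx_start if g.strand == "+" else g.tx_end
        sign = 1 if g.strand == "+" else -1
        if category == "body":
            center = (g.tx_start + g.tx_end) // 2
            expected: str | None = g.gene_name
        elif category == "upstream_in":
            offset = int(rng.integers(width, upstream - width))
            center = five_prime - sign * offset
            expected = g.gene_name
        elif category == "downstream_in":
            three_prime = g.tx_end if g.strand == "+" else g.tx_start
            offset = int(rng.integers(0, max(downstream - width, 1)))
            center = three_prime + sign * offset
            expected = g.gene_name
        elif category == "upstream_out":
            offset = int(rng.integers(upstream + width, 2 * upstream))
            center = five_prime - sign * offset
            expected = None
        else:  # intergenic, far from every window
            center = five_prime - sign * (3 * upstream + 2000)
            expected = None
        name = f"peak{j + 1:05d}"
        peaks.append(
            Peak(
                chrom="chrS",
                start=center - width // 2,
                end=center + width // 2,
                name=name,
            )
        )
        truth.peak_to_gene[name] = expected
    return peaks, genes, truth
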