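"""Gene-set over-representation statistics for TF target sets.

The engine tests a DEG set of size *n* against each target-gene set
(size *K*) from a ChIP-derived database over a fixed gene universe of
size *N*, using the hypergeometric distribution:

* enrichment: upper-tail ``p = P(X >= k)``,
  fold ratio ``(k/n) / (K/N) = k / k_e`` with expected overlap
  ``k_e = n*K/N``;
* depletion: lower-tail ``p = P(X <= k)``, fold ratio ``k_e / k``
  (infinite when ``k = 0``).

Raw p-values are Bonferroni-corrected by the number of experiments *m*
in the database (experiments on the same TF in different cell lines are
deliberately kept separate) and Benjamini–Hochberg q-values are reported
alongside.  The same machinery serves as a generic over-representation
engine (e.g. pathway gene sets), since the ratio-of-enrichment statistic
R = k/k_e coincides with the enriched-mode fold ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "TFExperiment",
    "TFGeneSetDB",
    "EnrichmentRecord",
    "hypergeom_upper_p",
    "hypergeom_lower_p",
    "enrichment_scan",
    "depletion_scan",
    "classify_significant",
    "bimodal_overlap",
]


@dataclass(frozen=True)
class TFExperiment:
    """One ChIP experiment: a TF with its target-gene set in one
    cell line / publication."""

    experiment_id: str
    tf_name: str
    metadata: str
    targets: frozenset[str]


@dataclass
class TFGeneSetDB:
    """A collection of TF-experiment target sets over a declared gene
    universe.  ``m`` (number of experiments) is the Bonferroni multiplier."""

    experiments: list[TFExperiment]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be nonempty")
        for exp in self.experiments:
            if not exp.targets:
                raise ValueError(f"{exp.experiment_id}: empty target set")
            stray = exp.targets - self.universe
            if stray:
                raise ValueError(
                    f"{exp.experiment_id}: {len(stray)} targets outside "
                    "the declared universe"
                )

    @property
    def m(self) -> int:
        return len(self.experiments)

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    @classmethod
    def from_gmt_records(
        cls,
        records: Iterable[tuple[str, str, set[str]]],
        universe: Iterable[str],
    ) -> "TFGeneSetDB":
        """Build from parsed GMT lines; the description field is expected
        to carry ``tf_name|...`` metadata (falls back to the set name)."""
        universe_set = frozenset(universe)
        exps = []
        for name, desc, genes in records:
            tf = desc.split("|")[0] if desc else name
            exps.append(
                TFExperiment(
                    experiment_id=name,
                    tf_name=tf or name,
                    metadata=desc,
                    targets=frozenset(genes) & universe_set,
                )
            )
        return cls(experiments=exps, universe=universe_set)


@dataclass
class EnrichmentRecord:
    """Overlap counts and corrected statistics for one experiment."""

    experiment_id: str
    tf_name: str
    metadata: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_bonferroni: float
    q_bh: float = math.nan
    mode: str = "enriched"
    deg_direction: str = "up"

    @property
    def k_expected(self) -> float:
        return self.n * self.K / self.N

    @property
    def fold_ratio(self) -> float:
        if self.mode == "enriched":
            return (self.k / self.n) / (self.K / self.N) if self.n else 0.0
        return self.k_expected / self.k if self.k else math.inf


def _check_counts(k: np.ndarray, N: int, K: int, n: int) -> None:
    if N <= 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent universe counts N={N}, K={K}, n={n}")
    if ((k < max(0, n + K - N)) | (k > min(K, n))).any():
        raise ValueError(f"overlap k impossible for N={N}, K={K}, n={n}")


def hypergeom_upper_p(k, N: int, K: int, n: int):
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    X counts the overlap between a size-``n`` draw and a size-``K``
    category in a size-``N`` universe.  ``k`` may be a scalar or array.
    Stable down to ~1e-300; the result is floored at the smallest
    positive double so downstream logs/corrections never see an exact
    zero.
    """
    karr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    _check_counts(karr, N, K, n)
    p = np.where(karr <= 0, 1.0, hypergeom.sf(karr - 1, N, K, n))
    p = np.clip(p, 5e-324, 1.0)
    return float(p[0]) if np.isscalar(k) or np.ndim(k) == 0 else p


def hypergeom_lower_p(k, N: int, K: int, n: int):
    """Lower-tail hypergeometric probability ``P(X <= k)``; ``k`` may be
    a scalar or array."""
    karr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    _check_counts(karr, N, K, n)
    p = np.clip(hypergeom.cdf(karr, N, K, n), 5e-324, 1.0)
    return float(p[0]) if np.isscalar(k) or np.ndim(k) == 0 else p


def _scan(
    deg_set: set[str],
    db: TFGeneSetDB,
    deg_direction: str,
    mode: str,
) -> list[EnrichmentRecord]:
    if deg_direction not in ("up", "down"):
        raise ValueError(f"deg_direction must be up/down, got {deg_direction}")
    in_universe = set(deg_set) & db.universe
    dropped = len(set(deg_set)) - len(in_universe)
    if dropped:
        log.info("dropped %d DEG ids absent from the %d-gene universe",
                 dropped, db.universe_size)
    if not in_universe:
        log.warning("empty DEG set after universe restriction; no records")
        return []
    n, N, m = len(in_universe), db.universe_size, db.m
    tail = hypergeom_upper_p if mode == "enriched" else hypergeom_lower_p
    records = []
    for exp in db.experiments:
        k = len(in_universe & exp.targets)
        p = tail(k, N, len(exp.targets), n)
        records.append(
            EnrichmentRecord(
                experiment_id=exp.experiment_id,
                tf_name=exp.tf_name,
                metadata=exp.metadata,
                k=k,
                K=len(exp.targets),
                n=n,
                N=N,
                p_raw=p,
                p_bonferroni=min(1.0, m * p),
                mode=mode,
                deg_direction=deg_direction,
            )
        )
    if records:
        q = multipletests([r.p_raw for r in records], method="fdr_bh")[1]
        for r, qv in zip(records, q):
            r.q_bh = float(qv)
    return records


def enrichment_scan(
    deg_set: set[str], db: TFGeneSetDB, deg_direction: str = "up"
) -> list[EnrichmentRecord]:
    """Upper-tail over-representation of ``deg_set`` in every experiment."""
    return _scan(deg_set, db, deg_direction, "enriched")


def depletion_scan(
    deg_set: set[str], db: TFGeneSetDB, deg_direction: str = "up"
) -> list[EnrichmentRecord]:
    """Lower-tail under-representation of ``deg_set`` in every experiment."""
    return _scan(deg_set, db, deg_direction, "depleted")


def classify_significant(
    records: Sequence[EnrichmentRecord],
    p_cutoff: float = 0.01,
    ratio_cutoff: float = 1.5,
) -> list[EnrichmentRecord]:
    """Keep records with Bonferroni p < ``p_cutoff`` and fold ratio
    strictly > ``ratio_cutoff``, sorted by fold ratio descending (ties
    broken by experiment id)."""
    kept = [
        r
        for r in records
        if r.p_bonferroni < p_cutoff and r.fold_ratio > ratio_cutoff
    ]
    return sorted(kept, key=lambda r: (-r.fold_ratio, r.experiment_id))


def bimodal_overlap(
    enriched_up: set[str],
    enriched_down: set[str],
    tf_universe_size: int,
    tail: str = "ge",
) -> tuple[int, float]:
    """Overlap between the up- and down-enriched experiment sets and its
    hypergeometric significance over the experiment universe.

    ``tail='ge'`` gives P(X >= overlap); ``tail='gt'`` the strict
    P(X > overlap) variant.
    """
    if tf_universe_size < len(enriched_up) or tf_universe_size < len(
        enriched_down
    ):
        raise ValueError("tf_universe_size smaller than an input set")
    if tail not in ("ge", "gt"):
        raise ValueError(f"tail must be 'ge' or 'gt', got {tail}")
    overlap = len(set(enriched_up) & set(enriched_down))
    k = overlap if tail == "ge" else overlap + 1
    if k > min(len(enriched_up), len(enriched_down)):
        # strict tail beyond the support: probability-zero event, floored
        return overlap, 5e-324
    p = hypergeom_upper_p(
        k, tf_universe_size, len(enriched_up), len(enriched_down)
    )
    return overlap, p


def records_to_rows(records: Sequence[EnrichmentRecord]) -> list[dict]:
    """Flatten records for tabular output (Table-style columns)."""
    return [
        {
            "experiment_id": r.experiment_id,
            "tf": r.tf_name,
            "metadata": r.metadata,
            "K": r.K,
            "k": r.k,
            "n": r.n,
            "N": r.N,
            "fold_ratio": r.fold_ratio,
            "p_raw": r.p_raw,
            "p_bonferroni": r.p_bonferroni,
            "q_bh": r.q_bh,
            "mode": r.mode,
            "deg_direction": r.deg_direction,
        }
        for r in records
    ]
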