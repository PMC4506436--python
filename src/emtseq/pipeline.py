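"""End-to-end pipeline wiring: simulate fixtures, run the full analysis.

``run_simulate`` writes a complete, self-consistent fixture bundle
(counts, group map, TF gene sets, peaks, annotation, truth, manifest)
so the whole pipeline can be exercised without any external data.
``run_full`` executes filter → normalize → dispersion → per-contrast
LRT → DEG selection → enrichment/depletion scans → TF-target topology
clustering with permutation significance → program comparison, writing
TSV reports with provenance headers.  With fixed seeds, reruns on the
same inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as eio
from .cluster import (cut_dendrogram, hcluster, permutation_significance,
                      tf_target_matrix)
from .compare import DEGProgram, core_genes, overlap_report
from .deg import (ContrastSpec, CountMatrix, compute_scaling_factors,
                  estimate_dispersion, filter_unresponsive, lrt_contrast,
                  mds_leading_logfc, select_degs)
from .enrichment import (TFGeneSetDB, classify_significant, depletion_scan,
                         enrichment_scan, records_to_rows)
from .peaks import peaks_to_gene_sets
from .simulate import (SimDesign, generate_count_matrix,
                       generate_peaks_and_annotation, generate_tf_database)

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "default_contrasts", "run_simulate", "run_full"]

#: the contrast panel of the two-factor design (treatment-baseline)
DEFAULT_CONTRASTS = (
    "CM-CE",
    "T1E-CE",
    "T12E-CE",
    "T12E-T1E",
    "T1M-T1E",
    "T12M-T12E",
    "T1M-CM",
    "T12M-CM",
    "T12M-T1M",
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""


def default_contrasts(group_order: list[str]) -> list[ContrastSpec]:
    specs = []
    for name in DEFAULT_CONTRASTS:
        a, b = name.split("-")
        if a in group_order and b in group_order:
            specs.append(ContrastSpec.pairwise(a, b))
    return specs


def _config_hash(config: dict) -> str:
    # the output location does not affect the analysis
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _headers(config: dict, seed: int) -> list[str]:
    from . import __version__

    return [
        f"emtseq {__version__}",
        f"config_hash={_config_hash(config)}",
        f"seed={seed}",
    ]


def run_simulate(
    out_dir: str | Path,
    design: SimDesign | None = None,
    n_null_tfs: int = 20,
    n_planted_tfs: int = 3,
    n_peak_genes: int = 40,
    n_peaks: int = 100,
) -> dict:
    """Write a fixture bundle with known ground truth; returns the manifest.

    Planted TF experiments draw most of their targets from the true DEG
    set so the end-to-end pipeline must recover them as significantly
    enriched; null experiments draw targets uniformly.
    """
    design = design or SimDesign()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cm, truth = generate_count_matrix(design)
    deg_truth = next(iter(truth.deg_per_contrast.values()), {})
    deg_genes = set(deg_truth)
    universe = list(cm.gene_ids)
    planted = []
    n_deg, N = len(deg_genes), len(universe)
    for i in range(n_planted_tfs):
        K = max(40, N // 12)
        k = min(n_deg, max(5, int(0.6 * n_deg)))
        k = min(k, K)
        planted.append((f"PLANTED{i + 1:02d}", K, k))
    db, tf_truth = generate_tf_database(
        n_tfs=n_null_tfs + n_planted_tfs,
        universe=universe,
        planted=planted,
        deg_set=deg_genes,
        seed=design.seed + 1,
    )
    peaks, gene_models, peak_truth = generate_peaks_and_annotation(
        n_genes=n_peak_genes, n_peaks=n_peaks, seed=design.seed + 2
    )

    eio.write_counts_tsv(out / "counts.tsv", cm.counts)
    eio.write_group_map(out / "groups.yaml", dict(cm.groups))
    eio.write_gmt(
        out / "tf_sets.gmt",
        [(e.experiment_id, e.metadata, e.targets) for e in db.experiments],
    )
    eio.write_bed(out / "peaks.bed", peaks)
    eio.write_refflat(out / "annotation.refflat", gene_models)
    truth_payload = {
        "deg_per_contrast": truth.deg_per_contrast,
        "planted_tfs": tf_truth.planted_tfs,
        "peak_to_gene": peak_truth.peak_to_gene,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": design.seed,
        "design": {
            "groups": list(design.groups),
            "replicates_per_group": design.replicates_per_group,
            "n_genes": design.n_genes,
            "baseline_mean": design.baseline_mean,
            "dispersion": design.dispersion,
            "planted_deg_fraction": design.planted_deg_fraction,
            "planted_log2fc": design.planted_log2fc,
            "library_size_cv": design.library_size_cv,
        },
        "files": {
            name: eio.file_sha256(out / name)
            for name in sorted(
                p.name for p in out.iterdir()
                if p.is_file() and p.name != "manifest.json"
            )
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def run_full(config: dict) -> dict:
    """Run the complete analysis described by ``config``; returns a
    summary dict of headline numbers.

    Required config keys: ``counts``, ``groups``, ``gene_sets`` (GMT),
    ``out_dir``.  Optional: ``peaks`` + ``annotation``, ``contrasts``
    (list of "A-B"), ``primary_contrast``, ``deg_regime``
    (glm_fwer | fc_q), filter/enrichment/clustering settings, ``seed``.
    """
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    headers = _headers(config, seed)
    summary: dict = {"seed": seed}

    counts = _stage("read_counts")(eio.read_counts_tsv)(config["counts"])
    groups = _stage("read_groups")(eio.read_group_map)(config["groups"])
    cm = _stage("build_matrix")(CountMatrix)(
        counts=counts, groups=pd.Series(groups)
    )
    log.info("input: %d genes x %d samples", *cm.counts.shape)

    cm_f, culled = _stage("filter")(filter_unresponsive)(
        cm,
        min_samples_per_group=int(config.get("min_samples_per_group", 2)),
        cpm_threshold=float(config.get("cpm_threshold", 1.0)),
    )
    summary["genes_in"] = int(cm.counts.shape[0])
    summary["genes_retained"] = int(cm_f.counts.shape[0])
    summary["genes_culled"] = culled

    factors = _stage("normalize")(compute_scaling_factors)(cm_f)
    cm_f.norm_factors = factors
    summary["scaling_factor_mean"] = float(factors.mean())

    fit = _stage("dispersion")(estimate_dispersion)(cm_f)
    summary["common_dispersion"] = fit.common_dispersion

    contrast_names = config.get("contrasts")
    if contrast_names:
        specs = [
            ContrastSpec.pairwise(*name.split("-")) for name in contrast_names
        ]
    else:
        specs = default_contrasts(cm_f.group_order)
    if not specs:
        raise PipelineError("stage 'contrasts' failed: no valid contrasts")
    regime = config.get("deg_regime", "glm_fwer")

    programs: dict[str, DEGProgram] = {}
    for spec in specs:
        stats = _stage(f"lrt[{spec.name}]")(lrt_contrast)(fit, cm_f, spec)
        eio.write_table(
            out / f"gene_stats_{spec.name}.tsv",
            stats.reset_index(),
            headers,
        )
        up, down = _stage(f"select[{spec.name}]")(select_degs)(stats, regime)
        programs[spec.name] = DEGProgram(name=spec.name, up=up, down=down)
        eio.write_deg_program(
            out / f"degs_{spec.name}.tsv", up, down, headers
        )
        log.info("contrast %s: %d up, %d down (%s)",
                 spec.name, len(up), len(down), regime)
    summary["deg_counts"] = {
        name: {"up": len(p.up), "down": len(p.down)}
        for name, p in programs.items()
    }

    mds = _stage("mds")(mds_leading_logfc)(
        cm_f, top_genes=int(config.get("mds_top_genes", 500))
    )
    eio.write_table(out / "mds_coordinates.tsv",
                    mds.rename_axis("sample_id").reset_index(), headers)

    primary = config.get("primary_contrast", specs[0].name)
    if primary not in programs:
        raise PipelineError(
            f"stage 'enrichment' failed: primary contrast {primary!r} "
            "was not analyzed"
        )
    prog = programs[primary]

    gmt = _stage("read_gene_sets")(eio.read_gmt)(config["gene_sets"])
    db = _stage("build_db")(TFGeneSetDB.from_gmt_records)(
        gmt, universe=list(cm.gene_ids)
    )
    p_cut = float(config.get("enrichment_p_cutoff", 0.01))
    r_cut = float(config.get("enrichment_ratio_cutoff", 1.5))
    significant: dict[tuple[str, str], list] = {}
    for direction, deg_set in (("up", prog.up), ("down", prog.down)):
        for mode, scan in (("enriched", enrichment_scan),
                           ("depleted", depletion_scan)):
            records = _stage(f"{mode}[{direction}]")(scan)(
                deg_set, db, direction
            )
            rows = pd.DataFrame(
                records_to_rows(records)
                or {c: [] for c in ("experiment_id", "tf", "fold_ratio")}
            )
            eio.write_table(
                out / f"tf_{mode}_{direction}.tsv", rows, headers
            )
            sig = classify_significant(records, p_cut, r_cut)
            significant[(mode, direction)] = sig
            rows_sig = pd.DataFrame(
                records_to_rows(sig)
                or {c: [] for c in ("experiment_id", "tf", "fold_ratio")}
            )
            eio.write_table(
                out / f"tf_{mode}_{direction}_significant.tsv",
                rows_sig, headers,
            )
            log.info("%s scan (%s DEGs): %d/%d experiments significant",
                     mode, direction, len(sig), len(records))
    summary["significant_tfs"] = {
        f"{mode}_{direction}": [r.experiment_id for r in recs]
        for (mode, direction), recs in significant.items()
    }

    if config.get("peaks") and config.get("annotation"):
        peaks = _stage("read_peaks")(eio.read_bed)(config["peaks"])
        models = _stage("read_annotation")(eio.read_refflat)(
            config["annotation"]
        )
        gene_sets = _stage("annotate_peaks")(peaks_to_gene_sets)(
            peaks,
            models,
            upstream=int(config.get("peak_upstream", 5000)),
            downstream=int(config.get("peak_downstream", 1000)),
        )
        eio.write_gmt(
            out / "peak_gene_sets.gmt",
            [(exp, f"{exp}|peaks", genes)
             for exp, genes in sorted(gene_sets.items())],
        )
        summary["peak_experiments"] = len(gene_sets)

    # TF-target topology: signed membership of DEGs in the enriched
    # experiments' target sets, clustered over TF columns
    enriched_ids = {
        r.experiment_id
        for key in (("enriched", "up"), ("enriched", "down"))
        for r in significant[key]
    }
    targets = {
        e.experiment_id: set(e.targets)
        for e in db.experiments
        if e.experiment_id in enriched_ids
    }
    if len(targets) >= 2 and (prog.up or prog.down):
        topo = _stage("topology_matrix")(tf_target_matrix)(
            prog.up, prog.down, targets
        )
        if topo.shape[0] >= 3 and topo.shape[1] >= 2:
            dend = _stage("cluster")(hcluster)(
                topo, axis="columns",
                linkage=config.get("cluster_linkage", "ward.d2"),
            )
            k = min(int(config.get("cluster_k", 3)), dend.n_leaves)
            labels = cut_dendrogram(dend, k)
            eio.write_table(
                out / "tf_clusters.tsv",
                labels.rename("cluster").rename_axis("experiment_id")
                .reset_index(),
                headers,
            )
            sig = _stage("cluster_significance")(permutation_significance)(
                topo, axis="columns",
                linkage=config.get("cluster_linkage", "ward.d2"),
                B=int(config.get("cluster_permutations", 1000)),
                seed=seed,
            )
            with open(out / "cluster_significance.txt", "w") as fh:
                for line in headers:
                    fh.write(f"# {line}\n")
                fh.write(f"n_permutations\t{sig.n_permutations}\n")
                for name in sorted(sig.observed):
                    fh.write(
                        f"observed_{name}\t{sig.observed[name]:.6g}\n"
                    )
                    fh.write(f"p_{name}\t{sig.p_values[name]:.6g}\n")
            summary["cluster_p_values"] = sig.p_values

    venn_names = [
        n for n in (primary, "T1E-CE", "T12E-CE") if n in programs
    ]
    venn_programs = [programs[n] for n in dict.fromkeys(venn_names)]
    if len(venn_programs) >= 2:
        regions = _stage("venn")(overlap_report)(venn_programs)
        eio.write_table(
            out / "venn_regions.tsv",
            pd.DataFrame(
                sorted(regions.items()), columns=["region", "count"]
            ),
            headers,
        )
        core = _stage("core")(core_genes)(venn_programs)
        eio.write_deg_program(
            out / "core_genes.tsv",
            sorted(core & venn_programs[0].up),
            sorted(core & venn_programs[0].down),
            headers,
        )
        summary["core_gene_count"] = len(core)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
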