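"""Differential-expression stage: filtering, TMM, dispersion, LRT, MDS."""

import numpy as np
import pandas as pd
import pytest

import emtseq as e
from emtseq.deg import select_degs

# ---------------------------------------------------------------------------
# filtering


def test_filter_matches_hand_evaluation(toy_counts):
    """10-gene toy table evaluated by hand against the rule: keep a gene
    iff some group has CPM >= 1 in at least 2 of its 3 samples.

    Library sizes are ~1665-1765, so CPM 1 is ~0.002 counts: any
    nonzero count passes the CPM bar and the rule reduces to 'at least
    two nonzero samples in some group'.
    """
    kept, culled = e.filter_unresponsive(toy_counts)
    # g1 all zero; g4 zero in A, counts in 2 of 3 B samples -> kept;
    # g6 single positive sample per group -> culled; g7 one sample -> culled
    assert list(kept.gene_ids) == ["g2", "g3", "g4", "g5", "g8", "g9", "g10"]
    assert culled == 3


def test_filter_boundary_two_of_three_in_one_group_only(toy_counts):
    kept, _ = e.filter_unresponsive(toy_counts)
    assert "g3" in set(kept.gene_ids)  # 2/3 in group A, zero in B
    assert "g5" in set(kept.gene_ids)  # 3/3 in A only


def test_filter_all_zero_gene_is_culled(toy_counts):
    kept, _ = e.filter_unresponsive(toy_counts)
    assert "g1" not in set(kept.gene_ids)


def test_filter_min_samples_above_group_size_raises(toy_counts):
    with pytest.raises(ValueError):
        e.filter_unresponsive(toy_counts, min_samples_per_group=4)


def test_tested_genes_are_exactly_the_retained_genes(fitted_default):
    cm_f, _, stats, _ = fitted_default
    assert list(stats.index) == list(cm_f.gene_ids)
    assert stats["p_raw"].notna().all()


# ---------------------------------------------------------------------------
# TMM scaling


def _naive_tmm(counts: np.ndarray, ref: int, trim_m=0.30, trim_a=0.05):
    """Straightforward per-sample TMM: trim M and A tails, weight kept
    M-values by inverse asymptotic variance (plain loops)."""
    lib = counts.sum(axis=0)
    logf = []
    for s in range(counts.shape[1]):
        ms, was = [], []
        for g in range(counts.shape[0]):
            ys, yr = counts[g, s], counts[g, ref]
            if ys <= 0 or yr <= 0:
                continue
            ms.append(np.log2((ys / lib[s]) / (yr / lib[ref])))
            was.append(
                (lib[s] - ys) / (lib[s] * ys)
                + (lib[ref] - yr) / (lib[ref] * yr)
            )
        ms, was = np.array(ms), np.array(was)
        a_vals = np.array(
            [
                0.5
                * np.log2(
                    (counts[g, s] / lib[s]) * (counts[g, ref] / lib[ref])
                )
                for g in range(counts.shape[0])
                if counts[g, s] > 0 and counts[g, ref] > 0
            ]
        )
        lo_m, hi_m = np.quantile(ms, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a_vals, [trim_a, 1 - trim_a])
        keep = (ms >= lo_m) & (ms <= hi_m) & (a_vals >= lo_a) & (a_vals <= hi_a)
        logf.append(np.sum(ms[keep] / was[keep]) / np.sum(1.0 / was[keep]))
    f = 2.0 ** np.array(logf)
    return f / np.exp(np.mean(np.log(f)))


def test_tmm_identical_columns_give_unit_factors():
    col = np.arange(1, 101) * 3
    counts = pd.DataFrame(
        {f"s{i}": col for i in range(6)}, index=[f"g{i}" for i in range(100)]
    )
    groups = pd.Series({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
    cm = e.CountMatrix(counts=counts, groups=groups)
    f = e.compute_scaling_factors(cm)
    assert np.allclose(f.to_numpy(), 1.0)


def test_tmm_factors_have_unit_geometric_mean():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(rng.gamma(2, 50, size=(300, 1)), size=(300, 6)),
        index=[f"g{i}" for i in range(300)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
    cm = e.CountMatrix(counts=counts, groups=groups)
    f = e.compute_scaling_factors(cm)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_removes_depth_and_matches_naive_recipe():
    """Doubling one sample's depth is absorbed by the library size, not
    the composition factor; factors agree with a loop-based recipe."""
    rng = np.random.default_rng(5)
    base = rng.gamma(2.0, 100.0, size=500)
    counts = np.column_stack(
        [rng.poisson(base) for _ in range(5)] + [rng.poisson(2.0 * base)]
    )
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(500)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
    cm = e.CountMatrix(counts=df, groups=groups)
    f = e.compute_scaling_factors(cm)
    assert abs(np.log2(f.iloc[-1]) - np.log2(f.iloc[:-1]).mean()) < 0.05
    # oracle comparison with the same reference column
    uq = np.quantile(counts / counts.sum(axis=0), 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    expected = _naive_tmm(counts.astype(float), ref)
    assert np.allclose(f.to_numpy(), expected, rtol=1e-8)


def test_tmm_zero_library_raises():
    counts = pd.DataFrame(
        {"s0": [0, 0], "s1": [5, 5]}, index=["g1", "g2"]
    )
    cm = e.CountMatrix(
        counts=counts, groups=pd.Series({"s0": "A", "s1": "A"})
    )
    with pytest.raises(ValueError):
        e.compute_scaling_factors(cm)


# ---------------------------------------------------------------------------
# dispersion estimation


def test_common_dispersion_recovered_within_twenty_percent(fitted_default):
    _, fit, _, _ = fitted_default
    assert fit.common_dispersion == pytest.approx(0.0155, rel=0.20)


def test_poisson_data_yields_near_zero_common_dispersion():
    design = e.SimDesign(
        n_genes=500, dispersion=1e-9, baseline_mean=1000,
        planted_deg_fraction=0.0, seed=4,
    )
    cm, _ = e.generate_count_matrix(design)
    cm_f, _ = e.filter_unresponsive(cm)
    fit = e.estimate_dispersion(cm_f)
    assert fit.common_dispersion <= 0.01


def test_tagwise_dispersion_lies_between_genewise_and_common(fitted_default):
    _, fit, _, _ = fitted_default
    lo = np.minimum(fit.genewise_dispersion, fit.common_dispersion)
    hi = np.maximum(fit.genewise_dispersion, fit.common_dispersion)
    assert ((fit.tagwise_dispersion >= lo * (1 - 1e-9)) &
            (fit.tagwise_dispersion <= hi * (1 + 1e-9))).all()


def test_dispersion_requires_replication():
    counts = pd.DataFrame(
        {"s0": [10, 20], "s1": [12, 18]}, index=["g1", "g2"]
    )
    cm = e.CountMatrix(
        counts=counts, groups=pd.Series({"s0": "A", "s1": "B"})
    )
    with pytest.raises(ValueError, match="replicates"):
        e.estimate_dispersion(cm)


# ---------------------------------------------------------------------------
# likelihood-ratio tests


def test_contrast_validation():
    with pytest.raises(ValueError):
        e.ContrastSpec(name="null", coefficients={"CM": 0.0, "CE": 0.0})
    with pytest.raises(ValueError):
        e.ContrastSpec(name="bad", coefficients={"CM": 1.0, "CE": -0.5})


def test_lrt_unknown_group_raises(fitted_default):
    cm_f, fit, _, _ = fitted_default
    with pytest.raises(ValueError, match="unknown"):
        e.lrt_contrast(fit, cm_f, e.ContrastSpec.pairwise("CM", "XX"))


def test_null_gene_type_one_error_near_nominal(fitted_default):
    _, _, stats, truth = fitted_default
    null = stats.drop(index=list(truth.deg_per_contrast["CM-CE"]))
    frac = float((null["p_raw"] < 0.05).mean())
    assert 0.03 <= frac <= 0.08


def test_planted_deg_power_above_ninety_percent(fitted_default):
    """Planted |log2FC|=1.5 DEGs under the FC>=2 then FWER<1e-5 regime."""
    _, _, stats, truth = fitted_default
    planted = truth.deg_per_contrast["CM-CE"]
    up, down = select_degs(stats, "glm_fwer")
    hits = sum(
        (g in up) if s > 0 else (g in down) for g, s in planted.items()
    )
    assert hits / len(planted) > 0.9
    false = (up | down) - set(planted)
    assert len(false) <= 0.001 * len(stats) + 2


def test_bonferroni_is_m_times_raw_capped(fitted_default):
    _, _, stats, _ = fitted_default
    m = len(stats)
    expected = np.minimum(1.0, m * stats["p_raw"])
    assert np.allclose(stats["p_bonferroni"], expected)
    assert (stats["p_bonferroni"] >= stats["p_raw"]).all()


def test_bh_q_values_match_brute_force_step_up():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=200) ** 2
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    # brute force: q_(i) = min_{j>=i} m p_(j) / j
    order = np.argsort(p)
    m = len(p)
    scaled = m * p[order] / np.arange(1, m + 1)
    brute_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    brute = np.empty(m)
    brute[order] = np.minimum(brute_sorted, 1.0)
    assert np.allclose(q, brute)


# ---------------------------------------------------------------------------
# DEG selection rules


def test_select_degs_hand_evaluated_toy_table():
    table = pd.DataFrame(
        {
            "log2fc": [1.3, -1.6, 0.85, 2.5, -3.0, 1.0],
            "p_bonferroni": [1e-6, 2e-7, 1e-12, 0.5, 9e-6, 1e-5],
            "q_bh": [0.001, 0.5, 0.001, 0.005, 0.02, 0.01],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    up, down = select_degs(table, "glm_fwer")
    # g1: passes both; g2: down; g3 fails FC pre-filter despite tiny p;
    # g4 fails FWER; g5 down; g6 p == cutoff -> excluded (strict <)
    assert up == {"g1"} and down == {"g2", "g5"}
    up_q, down_q = select_degs(table, "fc_q")
    # q <= 0.01 inclusive: g1, g4, g6 up; g5 fails (q=0.02); g2 (q=0.5)
    assert up_q == {"g1", "g4", "g6"} and down_q == set()


def test_select_degs_sets_disjoint_and_union_complete(fitted_default):
    _, _, stats, _ = fitted_default
    up, down = select_degs(stats, "fc_q")
    assert not up & down
    assert len(up | down) == len(up) + len(down)


def test_select_degs_unknown_regime_raises(fitted_default):
    _, _, stats, _ = fitted_default
    with pytest.raises(ValueError):
        select_degs(stats, "bogus")


# ---------------------------------------------------------------------------
# MDS on leading log fold changes


def test_mds_duplicate_samples_coincide():
    rng = np.random.default_rng(3)
    base = rng.poisson(100, size=(300,))
    counts = pd.DataFrame(
        {
            "s0": base, "s1": base,
            "s2": rng.poisson(100, 300), "s3": rng.poisson(100, 300),
        },
        index=[f"g{i}" for i in range(300)],
    )
    groups = pd.Series({s: "A" for s in counts.columns})
    cm = e.CountMatrix(counts=counts, groups=groups)
    coords = e.mds_leading_logfc(cm, top_genes=100)
    assert np.allclose(
        coords.loc["s0"].to_numpy(), coords.loc["s1"].to_numpy(), atol=1e-9
    )


def test_mds_first_dimension_separates_cell_states(fitted_default):
    """Planted mesenchymal effect dominates dimension 1 (positive
    silhouette of the E/M split on that axis)."""
    cm_f, _, _, _ = fitted_default
    coords = e.mds_leading_logfc(cm_f)
    is_m = cm_f.groups.str.endswith("M").to_numpy()
    from sklearn.metrics import silhouette_score

    score = silhouette_score(
        coords[["dim1"]].to_numpy(), is_m.astype(int)
    )
    assert score > 0


def test_mds_top_genes_clamped_with_warning(fitted_default, caplog):
    cm_f, _, _, _ = fitted_default
    small = cm_f.subset_genes(cm_f.gene_ids[:50])
    with caplog.at_level("WARNING"):
        coords = e.mds_leading_logfc(small, top_genes=500)
    assert coords.shape[0] == len(small.sample_ids)
    assert any("clamp" in r.message for r in caplog.records)
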