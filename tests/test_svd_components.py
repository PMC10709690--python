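"""SVD genotype-effect attribution: decomposition identities, model
selection, loading partition, and planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest

import th1regnet.synthetic_data as sd
from th1regnet.io_formats import SampleDesign
from th1regnet.normalize_de import regularized_log
from th1regnet.svd_components import (
    attribute_genotype_effect,
    center_and_decompose,
    fit_component_models,
    foldchange_cluster,
    partition_left_vectors,
    select_component,
)


def _design(conditions, genotypes, day=3):
    n = len(conditions)
    return SampleDesign(pd.DataFrame({
        "condition": conditions,
        "day": [day] * n,
        "genotype": genotypes,
        "replicate": list(range(n)),
    }, index=[f"s{i}" for i in range(n)]))


def _balanced_design(n_rep=2):
    conditions, genotypes = [], []
    for geno in ("flox", "cre"):
        for cond in ("Medium", "IL12", "IL12_IL27", "IL27"):
            conditions += [cond] * n_rep
            genotypes += [geno] * n_rep
    return _design(conditions, genotypes)


def _frame(m, columns):
    return pd.DataFrame(m, index=[f"g{i}" for i in range(m.shape[0])],
                        columns=columns)


# --- decomposition ---------------------------------------------------------


def test_rank_one_matrix_has_single_variance_component():
    design = _balanced_design()
    u = np.arange(1.0, 11.0)[:, None]
    v = np.linspace(-1, 1, 16)[None, :]
    m = _frame(u @ v, design.sample_ids)
    decomp = center_and_decompose(m, design)
    assert decomp.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)
    assert np.all(decomp.variance_fraction[1:] < 1e-10)


def test_svd_reconstruction_and_centering():
    rng = np.random.default_rng(0)
    design = _balanced_design()
    m = _frame(rng.normal(size=(100, 16)), design.sample_ids)
    decomp = center_and_decompose(m, design)
    centered = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
    rel_err = (np.linalg.norm(decomp.reconstruct() - centered)
               / np.linalg.norm(centered))
    assert rel_err < 1e-8
    assert np.allclose(centered.mean(axis=1), 0.0, atol=1e-12)
    assert decomp.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(decomp.singular_values) <= 1e-12)


def test_orientation_rule_flox_mean_at_least_cre_mean():
    rng = np.random.default_rng(1)
    design = _balanced_design()
    m = _frame(rng.normal(size=(50, 16)), design.sample_ids)
    decomp = center_and_decompose(m, design)
    genotypes = design.column("genotype", decomp.sample_ids)
    for j in range(decomp.n_components):
        v = decomp.right_vectors[:, j]
        assert v[genotypes == "flox"].mean() >= v[genotypes == "cre"].mean() - 1e-12


def test_constant_matrix_rejected():
    design = _balanced_design()
    m = _frame(np.ones((5, 16)), design.sample_ids)
    with pytest.raises(ValueError, match="constant"):
        center_and_decompose(m, design)


# --- component model fits --------------------------------------------------


def _planted_decomposition(signal, design, noise_sd=0.01, seed=0):
    """Matrix whose dominant component carries the given sample signal."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(200, 1))
    m = u @ signal[None, :] + rng.normal(0, noise_sd, (200, len(signal)))
    return center_and_decompose(_frame(m, design.sample_ids), design)


def test_genotype_component_is_identified_by_models():
    design = _balanced_design()
    genotypes = design.column("genotype")
    signal = np.where(genotypes == "cre", -1.0, 1.0)
    decomp = _planted_decomposition(signal, design)
    fits = fit_component_models(decomp, design)
    top = fits[0]
    assert top.anova_p_vs_condition_only < 1e-6
    assert top.aic_genotype_only < top.aic_full
    assert top.sign_divergent


def test_condition_component_is_not_sign_divergent():
    design = _balanced_design()
    conditions = design.column("condition")
    signal = np.where(conditions == "IL27", 1.0, -1.0 / 3.0)
    decomp = _planted_decomposition(signal, design)
    fits = fit_component_models(decomp, design)
    assert not fits[0].sign_divergent
    assert fits[0].anova_p_vs_genotype_only < 1e-6


def test_pure_noise_component_rarely_reaches_significance():
    # on pure-noise data the leading component is itself noise; its
    # BH-adjusted genotype p should stay above 0.05 in >= 90% of replicates
    design = _balanced_design()
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        m = _frame(rng.normal(size=(60, 16)), design.sample_ids)
        fits = fit_component_models(center_and_decompose(m, design), design)
        if fits[0].padj < 0.05:
            hits += 1
    assert hits <= n_seeds // 10


def test_empty_design_cell_is_reported():
    conditions = ["Medium"] * 8 + ["IL27"] * 8
    genotypes = (["flox"] * 8) + (["cre"] * 8)  # IL27 only in cre
    design = _design(conditions, genotypes)
    rng = np.random.default_rng(2)
    m = _frame(rng.normal(size=(30, 16)), design.sample_ids)
    decomp = center_and_decompose(m, design)
    with pytest.raises(ValueError, match="empty design cell"):
        fit_component_models(decomp, design)


# --- selection and partition -----------------------------------------------


def test_selection_recovers_planted_ko_effect(ko_dataset):
    cm, design, truth = ko_dataset
    sel = attribute_genotype_effect(regularized_log(cm), design, seed=0)
    planted = truth["affected_up"] | truth["affected_down"]
    recovered = sel.positive_gene_set | sel.negative_gene_set
    jaccard = len(planted & recovered) / len(planted | recovered)
    assert jaccard > 0.5
    assert 0.5 * 0.03 <= sel.variance_fraction <= 2.0 * 0.03


def test_stronger_of_two_planted_effects_wins():
    design = _balanced_design()
    genotypes = design.column("genotype")
    rng = np.random.default_rng(3)
    geno_sig = np.where(genotypes == "cre", -1.0, 1.0)
    u_strong = np.zeros((300, 1)); u_strong[:30] = rng.normal(2.0, 0.2, (30, 1))
    u_weak = np.zeros((300, 1)); u_weak[200:210] = rng.normal(0.2, 0.02, (10, 1))
    m = (u_strong @ geno_sig[None, :] + u_weak @ geno_sig[None, :]
         + rng.normal(0, 0.3, (300, 16)))
    sel = attribute_genotype_effect(_frame(m, design.sample_ids), design, seed=0)
    recovered = sel.positive_gene_set | sel.negative_gene_set
    strong_members = {f"g{i}" for i in range(30)}
    assert len(recovered & strong_members) / len(strong_members) > 0.8


def test_null_effect_selection_is_weak_or_fails():
    spec = sd.KoSimSpec(
        base=sd.KineticsSimSpec(n_genes=500, days=(3,), n_replicates=3, seed=9),
        genotype_log2fc=0.0, seed=9,
    )
    cm, design, _ = sd.simulate_ko(spec)
    try:
        sel = attribute_genotype_effect(regularized_log(cm), design, seed=0)
        assert sel.weak
    except ValueError:
        pass  # no genotype-divergent component also counts as a null outcome


def test_partition_keeps_most_extreme_cluster_per_sign():
    from th1regnet.svd_components import SvdDecomposition

    loadings = np.array([0.9, 0.85, 0.01, 0.02, -0.7, -0.02])
    decomp = SvdDecomposition(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=["s1", "s2"],
        left_vectors=loadings[:, None],
        singular_values=np.array([1.0]),
        right_vectors=np.array([[1.0], [-1.0]]),
    )
    pos, neg = partition_left_vectors(decomp, 0, seed=0)
    assert pos == {"g0", "g1"}
    assert neg == {"g4"}


def test_partition_symmetric_loadings_give_equal_sets():
    from th1regnet.svd_components import SvdDecomposition

    vals = np.array([0.9, 0.8, 0.1, 0.05, -0.9, -0.8, -0.1, -0.05])
    decomp = SvdDecomposition(
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=["s1", "s2"],
        left_vectors=vals[:, None],
        singular_values=np.array([1.0]),
        right_vectors=np.array([[1.0], [-1.0]]),
    )
    pos, neg = partition_left_vectors(decomp, 0, seed=0)
    assert len(pos) == len(neg) == 2


def test_selection_invariant_to_sample_order(ko_dataset):
    cm, design, _ = ko_dataset
    m = regularized_log(cm)
    sel1 = attribute_genotype_effect(m, design, seed=0)
    rng = np.random.default_rng(11)
    perm = list(rng.permutation(m.columns))
    sel2 = attribute_genotype_effect(m[perm], design, seed=0)
    assert sel1.positive_gene_set == sel2.positive_gene_set
    assert sel1.negative_gene_set == sel2.negative_gene_set


# --- fold-change clustering ------------------------------------------------


def test_foldchange_identical_rows_cocluster():
    fc = pd.DataFrame(
        np.vstack([np.tile([1.0, 2.0, 0.5], (5, 1)),
                   np.tile([-2.0, -1.0, 0.0], (5, 1))]),
        index=[f"g{i}" for i in range(10)],
        columns=["Prdm1", "Maf", "Prdm1xMaf"],
    )
    cr, means = foldchange_cluster(fc, k=2, seed=0)
    labels = cr.assignments
    assert labels.iloc[:5].nunique() == 1
    assert labels.iloc[5:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[5]
    assert means.shape == (2, 3)


def test_foldchange_recovers_three_archetypes():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(4)
    archetypes = np.array([[2.0, 2.0, 3.0], [-2.0, -2.0, -3.0], [0.0, 2.0, -2.0]])
    truth = rng.integers(0, 3, 300)
    fc = pd.DataFrame(archetypes[truth] + rng.normal(0, 0.2, (300, 3)),
                      index=[f"g{i}" for i in range(300)],
                      columns=["Prdm1", "Maf", "Prdm1xMaf"])
    cr, _ = foldchange_cluster(fc, k=3, seed=0)
    assert adjusted_rand_score(truth, cr.assignments.to_numpy()) > 0.9
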