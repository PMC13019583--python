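"""Generator, bag-assembly and split tests against direct oracles."""

import numpy as np
import pytest

from cellmil.simdata import (
    BagDataset,
    SimulationSpec,
    assemble_bags,
    generate_cell_pool,
    inject_label_noise,
    select_hvgs,
    simulate_dataset,
    split_dataset,
    true_log2fc,
)


def small_spec(**kw):
    base = dict(n_genes=100, n_de_genes_per_signature=10, cells_per_sample=50,
                n_control_samples=6, n_case_samples=6,
                perturb_fractions=(0.2,), de_log2fc=2.0, seed=0)
    base.update(kw)
    return SimulationSpec(**base)


# ---------------------------------------------------------------------------
# NB generator moments
# ---------------------------------------------------------------------------
def test_nb_variance_matches_moment_formula():
    # single gene, mu=4, theta=2: Var = mu + mu^2/theta = 12
    spec = SimulationSpec(n_genes=1, n_de_genes_per_signature=0,
                          mean_log_mu=np.log(4.0), mean_log_sigma=0.0,
                          disp_log_mu=np.log(2.0), disp_log_sigma=0.0,
                          cells_per_sample=10, n_control_samples=1,
                          n_case_samples=1, perturb_fractions=(0.0,), seed=3)
    pool = generate_cell_pool(spec, n_control=50_000, n_perturbed=0)
    x = pool.counts[:, 0]
    assert x.mean() == pytest.approx(4.0, rel=0.05)
    assert x.var() == pytest.approx(12.0, rel=0.05)


def test_zero_effect_means_agree_between_groups():
    spec = small_spec(de_log2fc=0.0, seed=5)
    pool = generate_cell_pool(spec, n_control=5000, n_perturbed=5000)
    ctrl = pool.counts[np.asarray(pool.truth_label_of_cell) == "control"]
    pert = pool.counts[np.asarray(pool.truth_label_of_cell) == "perturbA"]
    diff = ctrl.mean(0) - pert.mean(0)
    se = np.sqrt(ctrl.var(0) / len(ctrl) + pert.var(0) / len(pert))
    assert np.all(np.abs(diff) <= 3.2 * np.maximum(se, 1e-12))


def test_planted_fold_change_recovered_in_expectation():
    spec = small_spec(seed=8)
    pool = generate_cell_pool(spec, n_control=8000, n_perturbed=8000)
    lfc = true_log2fc(spec)[0]
    de = np.flatnonzero(lfc != 0)
    ctrl = pool.counts[np.asarray(pool.truth_label_of_cell) == "control"]
    pert = pool.counts[np.asarray(pool.truth_label_of_cell) == "perturbA"]
    est = np.log2(pert[:, de].mean(0) / ctrl[:, de].mean(0))
    assert np.allclose(est, 2.0, atol=0.3)


def test_generator_deterministic_given_seed():
    spec = small_spec(seed=11)
    a = generate_cell_pool(spec)
    b = generate_cell_pool(spec)
    np.testing.assert_array_equal(a.counts, b.counts)
    np.testing.assert_array_equal(a.truth_label_of_cell, b.truth_label_of_cell)


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        small_spec(perturb_fractions=(0.6, 0.5))
    with pytest.raises(ValueError):
        small_spec(n_de_genes_per_signature=60, perturb_fractions=(0.1, 0.1))
    with pytest.raises(ValueError):
        small_spec(library_size_cv=-1.0)


def test_library_size_cv_scales_cell_totals():
    spec = small_spec(library_size_cv=0.5, seed=2)
    pool = generate_cell_pool(spec, n_control=4000, n_perturbed=0)
    totals = pool.counts.sum(axis=1).astype(float)
    cv = totals.std() / totals.mean()
    # observed CV combines the planted CV with NB noise, so it exceeds 0.4
    assert cv > 0.4


# ---------------------------------------------------------------------------
# bag assembly
# ---------------------------------------------------------------------------
def test_case_bag_composition_matches_fraction():
    spec = SimulationSpec(n_genes=60, n_de_genes_per_signature=5,
                          cells_per_sample=400, n_control_samples=14,
                          n_case_samples=14, perturb_fractions=(0.2,), seed=1)
    ds = assemble_bags(generate_cell_pool(spec), spec)
    truth = np.asarray(ds.cells.truth_label_of_cell)
    sample = np.asarray(ds.cells.sample_of_cell)
    for s, label in ds.bag_labels.items():
        members = truth[sample == s]
        assert len(members) == 400
        n_pert = (members != "control").sum()
        assert n_pert == (80 if label == 1 else 0)


def test_mixture_bag_composition():
    spec = SimulationSpec(n_genes=60, n_de_genes_per_signature=5,
                          cells_per_sample=400, n_control_samples=4,
                          n_case_samples=4, perturb_fractions=(0.1, 0.1),
                          seed=2)
    ds = assemble_bags(generate_cell_pool(spec), spec)
    truth = np.asarray(ds.cells.truth_label_of_cell)
    sample = np.asarray(ds.cells.sample_of_cell)
    for s, label in ds.bag_labels.items():
        if label == 1:
            members = truth[sample == s]
            assert (members == "perturbA").sum() == 40
            assert (members == "perturbB").sum() == 40
            assert (members == "control").sum() == 320


def test_zero_fraction_gives_null_dataset():
    spec = small_spec(perturb_fractions=(0.0,))
    ds = assemble_bags(generate_cell_pool(spec), spec)
    assert (np.asarray(ds.cells.truth_label_of_cell) == "control").all()


def test_round_half_up_composition():
    # 15% of 50 = 7.5 -> 8 perturbed cells per case bag
    spec = small_spec(perturb_fractions=(0.15,))
    assert spec.perturbed_per_bag() == [8]


def test_insufficient_pool_raises_with_label_name():
    spec = small_spec()
    pool = generate_cell_pool(spec)
    pert_rows = np.flatnonzero(np.asarray(pool.truth_label_of_cell) == "perturbA")
    starved = pool.subset_cells(np.setdiff1d(np.arange(pool.n_cells),
                                             pert_rows[:5]))
    with pytest.raises(ValueError, match="perturbA"):
        assemble_bags(starved, spec)


def test_every_cell_in_exactly_one_bag():
    spec = small_spec()
    ds = assemble_bags(generate_cell_pool(spec), spec)
    sample = np.asarray(ds.cells.sample_of_cell)
    assert (sample != "").all()
    sizes = [len(ds.bag_cell_indices(s)) for s in ds.samples]
    assert sum(sizes) == ds.cells.n_cells
    assert set(sizes) == {spec.cells_per_sample}


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------
def test_split_sizes_and_stratification():
    spec = SimulationSpec(n_genes=40, n_de_genes_per_signature=4,
                          cells_per_sample=20, n_control_samples=14,
                          n_case_samples=14, perturb_fractions=(0.2,), seed=4)
    ds = split_dataset(assemble_bags(generate_cell_pool(spec), spec),
                       (0.5, 0.25, 0.25), seed=0)
    sizes = {p: len(ds.samples_in(p)) for p in ("train", "val", "test")}
    assert sizes == {"train": 14, "val": 7, "test": 7}
    # class balance within one sample of the global 50:50
    for p in sizes:
        labels = [ds.bag_labels[s] for s in ds.samples_in(p)]
        assert abs(sum(labels) - len(labels) / 2) <= 0.5 + 1e-9
    # disjoint cover
    all_assigned = sum((ds.samples_in(p) for p in sizes), [])
    assert sorted(all_assigned) == ds.samples


def test_split_rejects_bad_fractions_and_empty_classes():
    spec = small_spec()
    ds = assemble_bags(generate_cell_pool(spec), spec)
    with pytest.raises(ValueError):
        split_dataset(ds, (0.5, 0.2, 0.2), seed=0)
    tiny = SimulationSpec(n_genes=40, n_de_genes_per_signature=4,
                          cells_per_sample=20, n_control_samples=2,
                          n_case_samples=2, perturb_fractions=(0.2,), seed=4)
    tiny_ds = assemble_bags(generate_cell_pool(tiny), tiny)
    with pytest.raises(ValueError):
        split_dataset(tiny_ds, (0.5, 0.25, 0.25), seed=0)


# ---------------------------------------------------------------------------
# label noise
# ---------------------------------------------------------------------------
def test_label_noise_flips_exactly_k_train_labels():
    ds = simulate_dataset(small_spec(n_control_samples=14, n_case_samples=14))
    for k in range(6):
        noisy = inject_label_noise(ds, k, seed=3)
        train = noisy.samples_in("train")
        flips = [s for s in noisy.samples
                 if noisy.noisy_labels[s] != noisy.bag_labels[s]]
        assert len(flips) == k
        assert all(s in train for s in flips)
    same1 = inject_label_noise(ds, 3, seed=9).noisy_labels
    same2 = inject_label_noise(ds, 3, seed=9).noisy_labels
    assert same1 == same2
    with pytest.raises(ValueError):
        inject_label_noise(ds, len(ds.samples_in("train")) + 1, seed=0)


def test_noisy_labels_on_val_rejected_by_container():
    ds = simulate_dataset(small_spec())
    val_sample = ds.samples_in("val")[0]
    bad = dict(ds.bag_labels)
    bad[val_sample] = 1 - bad[val_sample]
    with pytest.raises(ValueError):
        BagDataset(cells=ds.cells, bag_labels=ds.bag_labels,
                   partition=ds.partition, noisy_labels=bad)


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------
def test_hvg_identity_and_planted_recovery():
    spec = small_spec(seed=6, mean_log_sigma=0.0)  # homogeneous background
    pool = generate_cell_pool(spec, n_control=2000, n_perturbed=500)
    assert select_hvgs(pool, pool.n_genes) is pool
    lfc = true_log2fc(spec)[0]
    planted = set(np.flatnonzero(lfc != 0))
    top = select_hvgs(pool, 20)
    kept = {int(g.split("_")[1]) for g in top.gene_ids}
    assert planted <= kept
    # cell order preserved
    np.testing.assert_array_equal(top.cell_ids, pool.cell_ids)
    with pytest.raises(ValueError):
        select_hvgs(pool, 0)


def test_simulate_dataset_pipeline_determinism():
    spec = small_spec(seed=13)
    a = simulate_dataset(spec, n_label_noise=2)
    b = simulate_dataset(spec, n_label_noise=2)
    np.testing.assert_array_equal(a.cells.counts, b.cells.counts)
    assert a.partition == b.partition
    assert a.noisy_labels == b.noisy_labels
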