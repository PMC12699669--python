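"""Synthetic-data generators: determinism, truth recovery, K80 calibration."""

import filecmp
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import homoeokit as hk
from homoeokit.simulate import (
    DivergenceMode,
    SimulationConfig,
    branch_length_for_4dtv,
    branch_length_for_ks,
    expected_ng86_ks,
    k80_rate_matrix,
    k80_transition_matrix,
    simulate_codon_pairs,
    simulate_gene_orders,
    simulate_retention,
    simulate_triads_expression,
)


def _write_all(config, outdir: Path) -> list[Path]:
    paths = []
    for sim in (
        simulate_retention(config),
        simulate_triads_expression(config),
        simulate_codon_pairs(config),
        simulate_gene_orders(config),
    ):
        paths.extend(sim.write(outdir).values())
    return paths


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = dict(seed=123, n_groups=50, n_triads=30, n_pairs=10, codons_per_pair=30)
    files1 = _write_all(SimulationConfig(**cfg), tmp_path / "a")
    files2 = _write_all(SimulationConfig(**cfg), tmp_path / "b")
    for f1, f2 in zip(files1, files2):
        assert filecmp.cmp(f1, f2, shallow=False), f1.name
    # and a different seed actually changes the data
    files3 = _write_all(SimulationConfig(**{**cfg, "seed": 124}), tmp_path / "c")
    assert any(
        not filecmp.cmp(f1, f3, shallow=False) for f1, f3 in zip(files1, files3)
    )


def test_config_validation():
    with pytest.raises(hk.InputError):
        SimulationConfig(seed=1, retention_mixture={"triad": 1.0})  # missing keys
    with pytest.raises(hk.InputError):
        SimulationConfig(seed=1, not_expressed_fraction=1.5)
    with pytest.raises(hk.InputError):
        SimulationConfig(seed=1, divergence_modes=())
    with pytest.raises(hk.InputError):
        SimulationConfig(seed="nope")


def test_retention_truth_recovered_exactly():
    config = SimulationConfig(seed=9, n_groups=300)
    sim = simulate_retention(config)
    groups = hk.groups_from_catalog(sim.catalog)
    by_id = {g.group_id: g for g in groups}
    for row in sim.truth.itertuples():
        group = by_id[row.group_id]
        assert group.copy_vector == (row.n_A, row.n_B, row.n_C)
        assert hk.classify_group(group) == row.truth_class
    assigned = hk.classify_all(groups, sim.catalog)
    truth_class = dict(zip(sim.truth["group_id"], sim.truth["truth_class"]))
    group_of = dict(zip(sim.catalog.frame["gene_id"], sim.catalog.frame["group_id"]))
    assert all(assigned[g] == truth_class[group_of[g]] for g in assigned.index)


def test_retention_mixture_within_binomial_ci():
    config = SimulationConfig(seed=31, n_groups=10_000)
    sim = simulate_retention(config)
    frac = sim.truth["truth_class"].value_counts(normalize=True)
    n = len(sim.truth)
    for cls, p in config.retention_mixture.items():
        half = 2.576 * math.sqrt(p * (1 - p) / n)  # 99% CI
        assert abs(frac.get(cls, 0.0) - p) <= half, cls


def test_simulated_catalog_roundtrips_through_parser(tmp_path):
    sim = simulate_retention(SimulationConfig(seed=3, n_groups=40))
    paths = sim.write(tmp_path)
    loaded = hk.load_gene_catalog(paths["catalog"])
    pd.testing.assert_frame_equal(loaded.frame, sim.catalog.frame)


def _run_bias_pipeline(sim):
    tissue = hk.aggregate_replicates(sim.expression, sim.design)
    te = hk.triad_tpm(sim.triads, tissue)
    assignments = hk.classify_triads(te)
    return assignments.merge(sim.truth, on=["triad_id", "tissue"])


def test_noise_free_limit_recovers_categories_exactly():
    config = SimulationConfig(
        seed=7, n_triads=200, dirichlet_concentration=None, replicate_cv=0.0,
        not_expressed_fraction=0.0,
    )
    merged = _run_bias_pipeline(simulate_triads_expression(config))
    assert (merged["status"] == "expressed").all()
    assert (merged["category"] == merged["truth_category"]).all()


def test_noisy_simulation_recovery_and_filter_path():
    config = SimulationConfig(seed=42, n_triads=500)
    merged = _run_bias_pipeline(simulate_triads_expression(config))
    ne = merged[merged["truth_status"] == "not_expressed"]
    assert len(ne) > 0
    assert (ne["status"] == "not_expressed").all()
    both = merged[(merged["status"] == "expressed") & (merged["truth_status"] == "expressed")]
    acc = (both["category"] == both["truth_category"]).mean()
    assert acc >= 0.95


def test_expression_matrix_roundtrips_at_six_significant_digits(tmp_path):
    sim = simulate_triads_expression(SimulationConfig(seed=8, n_triads=20))
    paths = sim.write(tmp_path)
    loaded = hk.load_expression(paths["expression"])
    assert list(loaded.columns) == list(sim.expression.columns)
    np.testing.assert_allclose(
        loaded.to_numpy(), sim.expression.to_numpy(), rtol=1e-5, atol=1e-12
    )
    design = hk.load_design(paths["design"])
    assert len(design) == len(sim.design)


# ------------------------------- K80 ---------------------------------------


@pytest.mark.parametrize("d", [0.0, 0.05, 0.3, 1.0])
@pytest.mark.parametrize("kappa", [0.5, 2.0, 5.0])
def test_k80_transition_matrix_against_expm_oracle(d, kappa):
    P = k80_transition_matrix(d, kappa)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(P, expm(k80_rate_matrix(kappa) * d), atol=1e-10)


def test_4dtv_branch_inversion_closed_form():
    for target in (0.01, 0.056, 0.208, 0.4):
        d = branch_length_for_4dtv(target, kappa=2.0)
        P = k80_transition_matrix(d, 2.0)
        # transversion probability from any base = two transversion cells
        assert 2 * P[0, 1] == pytest.approx(target, rel=1e-10)
    assert branch_length_for_4dtv(0.0, 2.0) == 0.0
    with pytest.raises(hk.InputError, match="unattainable"):
        branch_length_for_4dtv(0.5, 2.0)


def test_ks_branch_inversion_is_consistent():
    for target in (0.05, 0.15, 0.516):
        d = branch_length_for_ks(target, kappa=2.0)
        assert expected_ng86_ks(d, 2.0) == pytest.approx(target, abs=1e-6)


def test_zero_divergence_mode_gives_identical_pairs():
    config = SimulationConfig(
        seed=5, n_pairs=5, codons_per_pair=20,
        divergence_modes=(DivergenceMode(0.0, 1.0, 2.0),),
    )
    sim = simulate_codon_pairs(config)
    for row in sim.pairs.itertuples():
        assert sim.sequences[row.gene1] == sim.sequences[row.gene2]
        pair = hk.CodonPair(row.pair_id, sim.sequences[row.gene1], sim.sequences[row.gene2])
        assert hk.four_dtv(pair)[2] == 0.0


def test_single_mode_mean_4dtv_hits_target():
    config = SimulationConfig(
        seed=11, n_pairs=500, codons_per_pair=300,
        divergence_modes=(DivergenceMode(0.208, 1.0, 2.0),),
    )
    sim = simulate_codon_pairs(config)
    values = []
    for row in sim.pairs.itertuples():
        pair = hk.CodonPair(row.pair_id, sim.sequences[row.gene1], sim.sequences[row.gene2])
        values.append(hk.four_dtv(pair)[2])
    assert np.mean(values) == pytest.approx(0.208, abs=0.01)


def test_k80_ks_parameter_recovery():
    """Pairs simulated at kappa=2 with expected Ks 0.15: the median NG86
    estimate must land within 15% of the simulated expectation."""
    config = SimulationConfig(
        seed=13, n_pairs=500, codons_per_pair=300, divergence_statistic="ks",
        divergence_modes=(DivergenceMode(0.15, 1.0, 2.0),),
    )
    sim = simulate_codon_pairs(config)
    ks = []
    for row in sim.pairs.itertuples():
        pair = hk.CodonPair(row.pair_id, sim.sequences[row.gene1], sim.sequences[row.gene2])
        ks.append(hk.ng86(pair)["Ks"])
    assert abs(np.median(ks) - 0.15) <= 0.15 * 0.15


def test_simulated_fasta_roundtrips_through_reader(tmp_path):
    sim = simulate_codon_pairs(SimulationConfig(seed=2, n_pairs=5, codons_per_pair=30))
    paths = sim.write(tmp_path)
    pairs = hk.read_pairs(paths["fasta"], paths["pairs"])
    assert len(pairs) == 5
    assert pairs[0].seq1 == sim.sequences[sim.pairs.iloc[0]["gene1"]]


def test_gene_orders_reject_overflowing_blocks():
    with pytest.raises(hk.InputError, match="genes per chromosome"):
        simulate_gene_orders(
            SimulationConfig(seed=1, synteny_genes_per_chrom=20,
                             planted_blocks=((15, 3, "same"),))
        )


def test_gene_order_truth_has_one_row_per_pair(tmp_path):
    sim = simulate_gene_orders(SimulationConfig(seed=6, synteny_noise_pairs=5))
    assert len(sim.truth) == len(sim.pairs)
    assert (sim.truth["truth_block"] == -1).sum() == 5
    paths = sim.write(tmp_path)
    assert len(hk.load_gene_orders(paths["orders1"])) == 300
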