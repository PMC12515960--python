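import numpy as np
import pytest

from pecircuit import (
    ConnectivitySpec,
    ModelParams,
    PopulationSpec,
    assign_preferred_stimuli,
    grouped_weight_matrix,
    homogenize_plastic_weights,
    perturb_connectivity,
    sample_connectivity,
)
from pecircuit.connectivity import (
    PATHWAY_ENDPOINTS,
    PathwaySpec,
    _template_of,
    default_pathways,
)
from pecircuit._numerics import softplus


def test_invalid_probability_rejected():
    with pytest.raises(ValueError, match="probability"):
        PathwaySpec(prob=1.4, mean_weight=1.0)


def test_population_invariants():
    pop = PopulationSpec()
    assert pop.n_martinotti + pop.n_nonmartinotti == pop.n_som
    assert pop.n_martinotti == 28 and pop.n_nonmartinotti == 12
    counts = np.bincount(pop.group_assignment)
    assert (counts == 70).all()
    with pytest.raises(ValueError, match="divisible"):
        PopulationSpec(n_pc=281)


def test_sampling_deterministic_and_nonnegative():
    pop, spec = PopulationSpec(), ConnectivitySpec()
    a = sample_connectivity(pop, spec, seed=3)
    b = sample_connectivity(pop, spec, seed=3)
    for key in a.weights:
        np.testing.assert_array_equal(a.weights[key], b.weights[key])
        assert (a.weights[key] >= 0).all()
        assert not a.weights[key][~a.masks[key]].any()  # zeros off the mask


def test_realized_in_degree_matches_binomial_expectation():
    """Per-neuron afferent counts stay within 4 binomial SDs of p * N_pre."""
    pop = PopulationSpec()
    conn = sample_connectivity(pop, ConnectivitySpec(), seed=0)
    sizes = {"E": 280, "P": 40, "S": 40, "M": 28, "nM": 12, "V": 40}
    for key, mask in conn.masks.items():
        template = _template_of(key)
        p = conn.spec.pathways[template].prob
        n_pre = mask.shape[1]
        counts = mask.sum(axis=1)
        mean = p * n_pre - (template in ("EE", "PP")) * p  # self-connection excluded
        sd = np.sqrt(n_pre * p * (1 - p))
        assert np.all(np.abs(counts - mean) <= 4 * sd + 1e-9), key
    # worked case: each SOM cell receives ~ 0.35 * 280 = 98 PC afferents
    assert abs(conn.masks["SE"].sum(axis=1).mean() - 98) < 4 * np.sqrt(280 * 0.35 * 0.65)


def test_zero_probability_pathway_is_all_zero():
    pathways = default_pathways()
    pathways["DE"] = PathwaySpec(0.0, 0.42)
    conn = sample_connectivity(PopulationSpec(), ConnectivitySpec(pathways=pathways), seed=1)
    assert not conn.weights["D1E"].any()


def test_mean_total_afferent_strength_matches_table():
    conn = sample_connectivity(PopulationSpec(), ConnectivitySpec(), seed=5)
    for key, w in conn.weights.items():
        wbar = conn.spec.pathways[_template_of(key)].mean_weight
        totals = w.sum(axis=1)
        # uniform init divided by the realized count keeps the mean total at wbar
        assert abs(totals.mean() - wbar) < 0.05 * wbar, key


def test_plastic_weights_track_softplus_parameters():
    conn = sample_connectivity(PopulationSpec(), ConnectivitySpec(), seed=2)
    for key in conn.plastic_keys():
        mask = conn.masks[key]
        np.testing.assert_allclose(
            conn.weights[key][mask], softplus(conn.v_params[key][mask]), rtol=1e-12
        )
    assert set(conn.plastic_keys()) == {"EP", "EnM", "D1M", "PS", "PV"}


def test_homogenize_sets_pathway_means_exactly():
    conn = homogenize_plastic_weights(
        sample_connectivity(PopulationSpec(), ConnectivitySpec(), seed=2)
    )
    for key in conn.plastic_keys():
        totals = conn.weights[key].sum(axis=1)
        wbar = conn.spec.pathways[_template_of(key)].mean_weight
        present = conn.masks[key].sum(axis=1) > 0
        np.testing.assert_allclose(totals[present], wbar, rtol=1e-10)


class TestPerturbation:
    def test_zero_range_is_identity(self, conn_small):
        out = perturb_connectivity(conn_small, 0.0, seed=4)
        for key in conn_small.weights:
            np.testing.assert_array_equal(out.weights[key], conn_small.weights[key])

    def test_bounds_and_masks(self, conn_small):
        out = perturb_connectivity(conn_small, 0.1, seed=4)
        for key in conn_small.weights:
            w0, w1 = conn_small.weights[key], out.weights[key]
            nz = w0 > 0
            assert np.all(w1[nz] >= 0.9 * w0[nz] - 1e-12)
            assert np.all(w1[nz] <= 1.1 * w0[nz] + 1e-12)
            np.testing.assert_array_equal(out.masks[key], conn_small.masks[key])

    def test_negative_range_rejected(self, conn_small):
        with pytest.raises(ValueError):
            perturb_connectivity(conn_small, -0.2, seed=1)

    def test_mean_preserved_over_many_draws(self, conn_small):
        """Law of large numbers: the perturbation is unbiased."""
        w0 = conn_small.weights["EE"]
        i, j = np.argwhere(w0 > 0)[0]
        draws = np.array(
            [perturb_connectivity(conn_small, 0.3, seed=s).weights["EE"][i, j]
             for s in range(2000)]
        )
        se = 0.3 * w0[i, j] / np.sqrt(3 * len(draws))
        assert abs(draws.mean() - w0[i, j]) < 4 * se


class TestGroupedMatrix:
    def test_block_row_sums_match_direct_summation(self, params):
        pop = PopulationSpec()
        conn = sample_connectivity(pop, ConnectivitySpec(), seed=9)
        bank = assign_preferred_stimuli(pop)
        grouped = grouped_weight_matrix(conn, pop, params, bank.som_groups)
        # E<-E block row sums (undo leak factor and the -1 diagonal)
        n = pop.n_groups
        c = grouped.matrix + np.eye(len(grouped.labels))
        ee = c[:n, :n] / (1 - params.lambda_e)
        direct = np.array(
            [conn.weights["EE"][pop.group_assignment == g].sum(axis=1).mean()
             for g in range(n)]
        )
        np.testing.assert_allclose(ee.sum(axis=1), direct, rtol=1e-10)

    def test_pathway_scaling_scales_blocks(self, params):
        pop = PopulationSpec()
        conn = sample_connectivity(pop, ConnectivitySpec(), seed=9)
        bank = assign_preferred_stimuli(pop)
        g0 = grouped_weight_matrix(conn, pop, params, bank.som_groups)
        conn2 = conn.copy()
        conn2.weights["SE"] *= 2.0
        g1 = grouped_weight_matrix(conn2, pop, params, bank.som_groups)
        n, nd = pop.n_groups, pop.n_dendrites
        som_rows = slice(n * (1 + nd) + 1, n * (1 + nd) + 1 + 8)
        e_cols = slice(0, n)
        np.testing.assert_allclose(
            g1.matrix[som_rows, e_cols], 2.0 * g0.matrix[som_rows, e_cols], rtol=1e-12
        )

    def test_no_negative_entries_without_inhibition(self, params):
        pop = PopulationSpec()
        conn = sample_connectivity(pop, ConnectivitySpec(), seed=9)
        for key in ("EP", "EnM", "D1M", "PS", "PV", "PP", "SV", "VS"):
            conn.weights[key][...] = 0.0
        bank = assign_preferred_stimuli(pop)
        grouped = grouped_weight_matrix(conn, pop, params, bank.som_groups)
        off_diag = grouped.matrix + np.eye(len(grouped.labels))
        assert (off_diag >= 0).all()

    def test_single_group_soma_block_matches_hand_build(self, params):
        """1-group network: the soma diagonal entry is (1-lambda_E) wbar^EE - 1."""
        pop = PopulationSpec(n_pc=40, n_pv=8, n_som=10, n_vip=8, n_groups=1)
        conn = sample_connectivity(pop, ConnectivitySpec(), seed=3)
        bank = assign_preferred_stimuli(pop, feature_space=((0.0,),))
        grouped = grouped_weight_matrix(conn, pop, params, bank.som_groups)
        mean_ee = conn.weights["EE"].sum(axis=1).mean()
        expected = (1 - params.lambda_e) * mean_ee - 1.0
        assert grouped.labels[0] == "E0"
        np.testing.assert_allclose(grouped.matrix[0, 0], expected, rtol=1e-12)

    def test_empty_group_rejected(self, params):
        pop = PopulationSpec(n_pc=40, n_pv=8, n_som=10, n_vip=8, n_groups=4)
        conn = sample_connectivity(pop, ConnectivitySpec(), seed=3)
        bad_groups = np.zeros(pop.n_som, dtype=int)  # no SOM cells in groups 1..3
        bank = assign_preferred_stimuli(pop)
        # PC groups are fine but restricting SOM to one preference while
        # martinotti cells exist in every PC group is allowed; force a truly
        # empty PC group instead
        class Broken(PopulationSpec):
            @property
            def group_assignment(self):
                return np.zeros(self.n_pc, dtype=int)

        broken = Broken(n_pc=40, n_pv=8, n_som=10, n_vip=8, n_groups=4)
        with pytest.raises(ValueError, match="singular grouping"):
            grouped_weight_matrix(conn, broken, params, bank.som_groups)


def test_roundtrip_serialization(tmp_path, conn_small):
    conn_small.to_dir(tmp_path / "conn")
    loaded = type(conn_small).from_dir(tmp_path / "conn")
    for key in conn_small.weights:
        np.testing.assert_allclose(loaded.weights[key], conn_small.weights[key],
                                   atol=1e-12)
    assert loaded.plastic_keys() == conn_small.plastic_keys()
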