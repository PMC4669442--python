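"""Generator contracts: determinism, planted effects, marginal fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secretracer.simulate import (
    ConfigError,
    NetworkSimConfig,
    PlantedCluster,
    SecretomeSimConfig,
    StudySimConfig,
    TracerSimConfig,
    simulate_network,
    simulate_secretome,
    simulate_study,
    simulate_tracer,
)


class TestSecretomeGenerator:
    def test_determinism(self):
        cfg = SecretomeSimConfig(n_proteins=50, n_exclusive_diseased=5,
                                 n_exclusive_healthy=5, n_planted_up=3, seed=11)
        a = simulate_secretome(cfg)[0]
        b = simulate_secretome(cfg)[0]
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.lengths, b.lengths)

    def test_null_effect_means_indistinguishable(self):
        cfg = SecretomeSimConfig(n_proteins=300, n_planted_up=0, planted_log2fc=0.0,
                                 n_exclusive_diseased=0, n_exclusive_healthy=0,
                                 n_replicates=4, seed=5)
        scm, _, _ = simulate_secretome(cfg)
        d = scm.counts[scm.samples_for("diseased")].to_numpy()
        h = scm.counts[scm.samples_for("healthy")].to_numpy()
        p = stats.ttest_ind(d, h, axis=1, equal_var=False).pvalue
        assert np.mean(p >= 0.05) >= 0.95

    def test_planted_fold_change_recovered(self):
        hits = total = 0
        for seed in range(20):
            cfg = SecretomeSimConfig(n_proteins=200, n_planted_up=10, planted_log2fc=2.0,
                                     mean_count=50.0, n_exclusive_diseased=0,
                                     n_exclusive_healthy=0, seed=seed)
            scm, _, truth = simulate_secretome(cfg)
            d = scm.counts[scm.samples_for("diseased")].mean(axis=1)
            h = scm.counts[scm.samples_for("healthy")].mean(axis=1)
            ratio = np.log2(d / h).loc[sorted(truth.planted_up_proteins)]
            hits += int((np.abs(ratio - 2.0) <= 0.5).sum())
            total += len(ratio)
        assert hits / total >= 0.8

    def test_exclusives_structurally_zero_and_detected(self):
        cfg = SecretomeSimConfig(n_proteins=100, n_exclusive_diseased=10,
                                 n_exclusive_healthy=8, n_planted_up=2, seed=3)
        scm, _, truth = simulate_secretome(cfg)
        excl_d = truth.exclusive_proteins["diseased"]
        excl_h = truth.exclusive_proteins["healthy"]
        assert (scm.counts.loc[excl_d, scm.samples_for("healthy")] == 0).all().all()
        assert (scm.counts.loc[excl_h, scm.samples_for("diseased")] == 0).all().all()
        assert (scm.counts.loc[excl_d, scm.samples_for("diseased")].sum(axis=1) > 0).all()

    def test_ground_truth_ids_resolve(self):
        scm, annot, truth = simulate_secretome(SecretomeSimConfig(seed=7))
        ids = set(scm.counts.index)
        assert truth.planted_up_proteins <= ids
        assert annot.loc[sorted(truth.planted_up_proteins)].eq(1).all()

    def test_marginal_mean_and_dispersion_within_10pct(self):
        cfg = SecretomeSimConfig(n_proteins=2000, n_planted_up=0, n_exclusive_diseased=0,
                                 n_exclusive_healthy=0, mean_count=50.0, dispersion=0.1,
                                 n_replicates=6, seed=9)
        scm, _, _ = simulate_secretome(cfg)
        x = scm.counts.to_numpy(dtype=float)
        assert abs(x.mean() - 50.0) / 50.0 < 0.10
        # within-protein moments: E[s2 - xbar] = disp*mu^2, E[xbar^2 - s2/n] = mu^2
        for cond in ("diseased", "healthy"):
            sub = scm.counts[scm.samples_for(cond)].to_numpy(dtype=float)
            xbar = sub.mean(axis=1)
            s2 = sub.var(axis=1, ddof=1)
            disp_hat = (s2 - xbar).sum() / (xbar**2 - s2 / sub.shape[1]).sum()
            assert abs(disp_hat - 0.1) / 0.1 < 0.10

    @pytest.mark.parametrize("field,value", [
        ("frac_secreted", 1.5),
        ("n_replicates", 1),
        ("mean_count", 0.0),
        ("n_planted_up", 1000),
    ])
    def test_invalid_config_rejected(self, field, value):
        cfg = SecretomeSimConfig(**{field: value})
        with pytest.raises(ConfigError):
            simulate_secretome(cfg)


class TestTracerGenerator:
    def test_determinism(self):
        cfg = TracerSimConfig(n_reporters=6, planted_clusters=[], seed=2)
        a, _ = simulate_tracer(cfg)
        b, _ = simulate_tracer(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_null_amplitudes_give_flat_ratios(self):
        cfg = TracerSimConfig(n_reporters=20, planted_clusters=[], noise_log_sd=0.1,
                              n_replicates=4, seed=4)
        plates, _ = simulate_tracer(cfg)
        assay = plates.assay_wells
        rep = assay[assay["reporter"] != "TA"]
        logf = np.log2(rep["flux"])
        means = rep.assign(logf=logf).groupby(["reporter", "condition"])["logf"].mean().unstack()
        ratio = means["treated"] - means["control"]
        bound = 3.0 * cfg.noise_log_sd / np.sqrt(cfg.n_replicates)
        assert (ratio.abs() <= bound).all()

    def test_planted_ramp_separates_members(self):
        members = tuple(range(5))
        for seed in range(20):
            cfg = TracerSimConfig(
                n_reporters=15, noise_log_sd=0.15, n_replicates=4,
                planted_clusters=[PlantedCluster(members, "ramp", 2.0)], seed=seed)
            plates, truth = simulate_tracer(cfg)
            assay = plates.assay_wells
            rep = assay[(assay["reporter"] != "TA")
                        & (assay["time_h"] == assay["time_h"].max())]
            means = (rep.assign(logf=np.log2(rep["flux"]))
                     .groupby(["reporter", "condition"])["logf"].mean().unstack())
            ratio = means["treated"] - means["control"]
            in_m = ratio.loc[sorted(truth.planted_active_reporters)].mean()
            out_m = ratio.drop(sorted(truth.planted_active_reporters)).mean()
            assert in_m - out_m >= 1.0

    def test_no_background_wells_is_hard_error(self):
        with pytest.raises(ConfigError, match="background"):
            simulate_tracer(TracerSimConfig(n_background_wells=0))

    def test_overlapping_cluster_membership_rejected(self):
        clusters = [PlantedCluster((0, 1), "ramp", 1.0), PlantedCluster((1, 2), "flat", 1.0)]
        with pytest.raises(ConfigError, match="disjoint"):
            simulate_tracer(TracerSimConfig(n_reporters=5, planted_clusters=clusters))

    def test_all_fluxes_positive(self):
        plates, _ = simulate_tracer(TracerSimConfig(n_reporters=5, seed=1, planted_clusters=[
            PlantedCluster((0, 1), "decline", -3.0)]))
        assert (plates.data["flux"] > 0).all()


class TestNetworkGenerator:
    def test_planted_chain_only(self):
        cfg = NetworkSimConfig(n_ligands=3, n_receptors=3, n_signaling=2, n_tfs=3,
                               edge_density=0.0,
                               planted_chains=[("L000", "R001", "T002")], seed=0)
        net = simulate_network(cfg)
        assert sorted(net.graph.edges) == [("L000", "R001"), ("R001", "T002")]

    def test_full_density_matches_admissible_count(self):
        cfg = NetworkSimConfig(n_ligands=2, n_receptors=2, n_signaling=0, n_tfs=2,
                               edge_density=1.0, seed=0)
        net = simulate_network(cfg)
        # L->R (4) + R->T (4) + T->T without self-loops (2) = 10
        assert net.graph.number_of_edges() == 10

    def test_determinism(self):
        cfg = NetworkSimConfig(edge_density=0.05, seed=13)
        a = simulate_network(cfg)
        b = simulate_network(cfg)
        assert sorted(a.graph.edges) == sorted(b.graph.edges)

    def test_chain_with_missing_node_rejected(self):
        cfg = NetworkSimConfig(planted_chains=[("nope", "R000", "T000")])
        with pytest.raises(ConfigError, match="nope"):
            simulate_network(cfg)

    def test_edge_types_admissible(self):
        net = simulate_network(NetworkSimConfig(edge_density=0.2, seed=3))
        allowed = {("ligand", "receptor"), ("receptor", "signaling"),
                   ("receptor", "tf"), ("signaling", "tf"), ("tf", "tf")}
        for u, v in net.graph.edges:
            assert (net.node_type(u), net.node_type(v)) in allowed


class TestStudyGenerator:
    def test_chains_link_planted_proteins_to_active_reporters(self):
        cfg = StudySimConfig(
            secretome=SecretomeSimConfig(n_proteins=80, n_planted_up=4,
                                         n_exclusive_diseased=8, n_exclusive_healthy=8),
            tracer=TracerSimConfig(n_reporters=10, planted_clusters=[
                PlantedCluster((0, 1, 2), "ramp", 2.0)]),
            network=NetworkSimConfig(n_receptors=5, n_signaling=3),
            n_planted_chains=2, seed=21)
        scm, annot, plates, net, truth = simulate_study(cfg)
        assert len(truth.planted_chains) == 2
        for lig, rec, tf in truth.planted_chains:
            assert lig in truth.planted_up_proteins
            assert tf in truth.planted_active_reporters
            assert net.graph.has_edge(lig, rec) and net.graph.has_edge(rec, tf)
        assert set(annot.index) == set(scm.counts.index)
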