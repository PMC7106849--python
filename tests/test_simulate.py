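"""The synthetic study generator: panel composition, ground truth, forward
probe model, platform views, Ct tables, and end-to-end identities."""

import numpy as np
import pandas as pd
import pytest

from isopanel import (
    SimulationConfig,
    ct_to_proportions,
    gene_view,
    simulate_ct,
    simulate_panel,
    simulate_probe_counts,
    simulate_platform_views,
    simulate_study,
    simulate_truth,
)
from isopanel.quantify import collapse_replicates, housekeeping_normalize, quantify_panel
from isopanel.simulate import probe_capture_view


def _noiseless(**kw) -> SimulationConfig:
    return SimulationConfig(
        noise_sd=0.0, background=0.0, sample_scale_sd=0.0, replicate_sd=0.0,
        n_replicates=1, **kw,
    )


class TestSimulatePanel:
    def test_default_category_mix_is_exact_in_proportional_mode(self):
        cfg = SimulationConfig()
        genes, probes = simulate_panel(cfg)
        endo = [g for g in genes if g.n_isoforms >= 2]
        by_size = pd.Series([g.n_isoforms for g in endo]).value_counts()
        assert by_size.to_dict() == {2: 79, 3: 37, 4: 18, 5: 21}
        assert len(endo) == 155
        # 10 housekeeping single-isoform genes + 14 spike-in probes
        assert sum(1 for g in genes if g.n_isoforms == 1) == 10
        assert sum(1 for p in probes if p.probe_class == "spike_in") == 14
        assert sum(1 for p in probes if p.probe_class == "housekeeping") == 10
        # max-probe design: one probe per isoform per gene
        n_endo_probes = sum(1 for p in probes if p.probe_class == "endogenous")
        assert n_endo_probes == sum(g.n_isoforms for g in endo)

    def test_single_category_single_gene(self):
        cfg = SimulationConfig(
            n_genes=1, category_weights={2: 1.0}, n_housekeeping=0, n_spike_in=0
        )
        genes, probes = simulate_panel(cfg)
        assert len(genes) == 1 and genes[0].n_isoforms == 2
        assert len(probes) == 2

    def test_fixed_seed_reproduces_panel(self):
        cfg = SimulationConfig(allocation="multinomial", seed=5)
        a = simulate_panel(cfg)
        b = simulate_panel(cfg)
        assert [g.isoform_ids for g in a[0]] == [g.isoform_ids for g in b[0]]
        assert a[1] == b[1]

    def test_multinomial_mode_respects_total(self):
        cfg = SimulationConfig(allocation="multinomial", n_genes=40, seed=9)
        genes, _ = simulate_panel(cfg)
        assert sum(1 for g in genes if g.n_isoforms >= 2) == 40


class TestSimulateTruth:
    def test_zero_spread_gives_identical_samples(self, small_cfg):
        cfg = SimulationConfig(
            n_genes=10, n_samples=4, tissue_weights=(2, 2), biological_sd=0.0,
            de_fraction=0.0, seed=1,
        )
        genes, _ = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        vals = truth.expression.values.to_numpy()
        assert np.allclose(vals, vals[:, [0]])

    def test_housekeeping_constant_across_samples(self, small_cfg):
        genes, _ = simulate_panel(small_cfg)
        truth = simulate_truth(genes, small_cfg)
        hk_isos = [g.isoform_ids[0] for g in truth.housekeeping]
        vals = truth.expression.values.loc[hk_isos].to_numpy()
        assert np.allclose(vals, vals[:, [0]])
        cv = vals.std(axis=1) / vals.mean(axis=1)
        assert (cv < 1e-12).all()

    def test_de_genes_carry_configured_shift(self):
        cfg = SimulationConfig(
            n_genes=10, n_samples=8, tissue_weights=(4, 4), biological_sd=0.0,
            de_fraction=0.5, de_effect=2.0, seed=3,
        )
        genes, _ = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        assert len(truth.de_genes) == 5
        for gid, tissue in truth.de_genes.items():
            gene = next(g for g in truth.genes if g.gene_id == gid)
            vals = truth.expression.values.loc[list(gene.isoform_ids)]
            inside = vals.loc[:, truth.labels == tissue].mean(axis=1)
            outside = vals.loc[:, truth.labels != tissue].mean(axis=1)
            np.testing.assert_allclose(inside / outside, 4.0, rtol=1e-9)

    def test_tissue_allocation_matches_weights(self):
        cfg = SimulationConfig(n_samples=46, tissue_weights=(12, 12, 11, 10, 4, 2))
        genes, _ = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        counts = truth.labels.value_counts()
        assert counts.sum() == 46
        assert counts["prostate"] == 2  # smallest tissue kept at its weight share


class TestForwardProbeModel:
    def test_noiseless_probe_signal_is_incidence_times_truth(self, fli1_gene):
        cfg = _noiseless(n_genes=1, category_weights={4: 1.0}, n_samples=2,
                         tissue_weights=(1, 1), biological_sd=0.0, de_fraction=0.0)
        genes, probes = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        counts, _ = simulate_probe_counts(truth, probes, cfg)
        gene = truth.genes[0]
        x = truth.expression.values.loc[list(gene.isoform_ids)].iloc[:, 0]
        max_probe = counts.counts.loc[f"{gene.gene_id}_max"].iloc[0]
        assert max_probe == pytest.approx(x.sum(), rel=1e-12)
        for k, iso in enumerate(gene.isoform_ids[:-1], start=1):
            assert counts.counts.loc[f"{gene.gene_id}_p{k}"].iloc[0] == pytest.approx(
                x[iso], rel=1e-12
            )

    def test_noiseless_pipeline_recovers_truth_exactly(self, small_cfg):
        cfg = _noiseless(n_genes=12, n_samples=4, tissue_weights=(2, 2), seed=2)
        genes, probes = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        iso, gene = probe_capture_view(truth, probes, cfg)
        recovered = iso.values
        expected = truth.expression.values.loc[recovered.index]
        np.testing.assert_allclose(
            recovered.to_numpy(), expected.to_numpy(), rtol=1e-6, atol=1e-8
        )

    def test_sample_scale_alone_removed_by_normalization(self):
        cfg = _noiseless(n_genes=8, n_samples=4, tissue_weights=(2, 2), seed=4)
        cfg.sample_scale_sd = 0.5  # global per-sample scale, no other noise
        genes, probes = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        iso, _ = probe_capture_view(truth, probes, cfg)
        expected = truth.expression.values.loc[iso.values.index]
        # normalization anchors to the cohort geometric mean, so recovery is
        # exact up to one factor shared by every entry
        ratio = iso.values.to_numpy() / expected.to_numpy()
        np.testing.assert_allclose(ratio, ratio.mean(), rtol=1e-6)

    def test_replicate_correlation_increases_as_noise_shrinks(self):
        cfg_by_sd = {}
        for sd in (0.05, 0.4):
            cfg = SimulationConfig(
                n_genes=40, n_samples=4, tissue_weights=(2, 2), noise_sd=sd,
                replicate_sd=0.0, n_replicates=2, seed=10,
            )
            genes, probes = simulate_panel(cfg)
            truth = simulate_truth(genes, cfg)
            counts, rep_map = simulate_probe_counts(truth, probes, cfg)
            log = np.log1p(counts.counts)
            rs = []
            for s in truth.expression.sample_ids:
                reps = [c for c, m in rep_map.items() if m == s]
                rs.append(np.corrcoef(log[reps[0]], log[reps[1]])[0, 1])
            cfg_by_sd[sd] = np.mean(rs)
        assert cfg_by_sd[0.05] > cfg_by_sd[0.4]
        assert cfg_by_sd[0.05] > 0.99


class TestPlatformViews:
    def test_near_limit_views_agree_almost_perfectly(self):
        cfg = _noiseless(
            n_genes=20, n_samples=4, tissue_weights=(2, 2), seed=6,
            ambiguity=0.0, array_background=0.0, array_noise_sd=0.0,
            seq_depth=2000.0,
        )
        genes, probes = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        views = simulate_platform_views(truth, probes, cfg)
        from isopanel import log_transform, pooled_correlation

        logs = {k: log_transform(v) for k, v in views.items()}
        for a, b in [("seq", "array"), ("seq", "probe"), ("array", "probe")]:
            assert pooled_correlation(logs[a], logs[b]) > 0.99

    def test_ambiguity_preserves_gene_totals(self, small_cfg):
        genes, probes = simulate_panel(small_cfg)
        truth = simulate_truth(genes, small_cfg)
        from isopanel.simulate import _mix_within_gene

        mixed = _mix_within_gene(truth, 0.7)
        for gene in truth.genes[:5]:
            isos = list(gene.isoform_ids)
            np.testing.assert_allclose(
                mixed.loc[isos].sum(axis=0),
                truth.expression.values.loc[isos].sum(axis=0),
                rtol=1e-12,
            )

    def test_gene_view_sums_isoforms(self, small_cfg):
        genes, probes = simulate_panel(small_cfg)
        truth = simulate_truth(genes, small_cfg)
        G = gene_view(truth.expression, truth.annotation)
        g0 = truth.genes[0]
        np.testing.assert_allclose(
            G.values.loc[g0.gene_id],
            truth.expression.values.loc[list(g0.isoform_ids)].sum(axis=0),
        )


class TestSimulateCt:
    def test_noiseless_ct_inverts_to_true_proportions(self, small_cfg):
        cfg = SimulationConfig(
            n_genes=6, n_samples=4, tissue_weights=(2, 2), ct_noise_sd=0.0, seed=8
        )
        genes, _ = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        gene = truth.genes[0]
        ct = simulate_ct(truth, [gene.gene_id], cfg)
        sample = truth.expression.sample_ids[0]
        sub = ct[ct["sample_id"] == sample].set_index("isoform_id")["ct"]
        sub = sub.loc[list(gene.isoform_ids)]
        p = ct_to_proportions(sub.to_numpy())
        x = truth.expression.values.loc[list(gene.isoform_ids), sample].to_numpy()
        np.testing.assert_allclose(p, x / x.sum(), rtol=1e-9)

    def test_per_sample_ct_offset_cancels(self):
        ct = np.array([18.0, 21.5, 23.0])
        np.testing.assert_allclose(
            ct_to_proportions(ct + 4.2), ct_to_proportions(ct), rtol=1e-9
        )

    def test_zero_expression_yields_missing_ct(self):
        cfg = SimulationConfig(n_genes=2, n_samples=2, tissue_weights=(1, 1), seed=9)
        genes, _ = simulate_panel(cfg)
        truth = simulate_truth(genes, cfg)
        gene = truth.genes[0]
        truth.expression.values.loc[gene.isoform_ids[0]] = 0.0
        ct = simulate_ct(truth, [gene.gene_id], cfg)
        assert ct[ct["isoform_id"] == gene.isoform_ids[0]]["ct"].isna().all()


def test_fixed_seed_gives_byte_identical_study(tmp_path, small_cfg):
    from isopanel import io as iio

    for sub in ("a", "b"):
        genes, probes, truth, views, gene_views = simulate_study(small_cfg)
        d = tmp_path / sub
        d.mkdir()
        iio.write_expression_matrix(truth.expression, d / "truth.tsv")
        for name, M in views.items():
            iio.write_expression_matrix(M, d / f"{name}.tsv")
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
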