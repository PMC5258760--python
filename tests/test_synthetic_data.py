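import numpy as np
import pandas as pd
import pytest

from oracles import naive_site_score
from mirqtl.synthetic_data import (
    SimulationConfig,
    SimulationError,
    _check_planted_sites,
    simulate_annotation_and_targets,
    simulate_counts,
    simulate_expression_profiles,
    simulate_plant_records,
    simulate_sssl_panel,
)
from mirqtl.target_scoring import ScoringScheme


SMALL = SimulationConfig(seed=7, n_mirnas=60, n_de=6, n_genes=20)


class TestDeterminism:
    def test_counts_identical_on_rerun(self):
        a, b = simulate_counts(SMALL), simulate_counts(SMALL)
        assert np.array_equal(a.counts.counts, b.counts.counts)
        assert a.truth.equals(b.truth)

    def test_panel_identical_on_rerun(self):
        a, b = simulate_sssl_panel(SMALL), simulate_sssl_panel(SMALL)
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        assert a.phenotypes.equals(b.phenotypes)

    def test_targets_identical_on_rerun(self):
        ca = simulate_counts(SMALL)
        pa = simulate_sssl_panel(SMALL)
        a = simulate_annotation_and_targets(SMALL, ca.truth, pa.qtl_intervals)
        b = simulate_annotation_and_targets(SMALL, ca.truth, pa.qtl_intervals)
        assert a.transcript_records == b.transcript_records
        assert a.truth_pairs.equals(b.truth_pairs)


class TestCounts:
    def test_null_config_has_equal_heat_and_control_means(self):
        cfg = SimulationConfig(seed=1, n_mirnas=50, n_de=0, dispersion=0.0)
        sim = simulate_counts(cfg)
        heat = [c for c in sim.expected_means.columns if c.endswith("T")]
        ctrl = [c.replace("T", "C") for c in heat]
        assert np.allclose(sim.expected_means[heat].values, sim.expected_means[ctrl].values)
        assert sim.truth.empty

    def test_spiked_cells_match_truth_table(self):
        sim = simulate_counts(SMALL)
        for _, row in sim.truth.iterrows():
            heat_lib = f"{row.genotype}-{row.timepoint_hours}hT"
            ctrl_lib = f"{row.genotype}-{row.timepoint_hours}hC"
            ratio = (
                sim.expected_means.loc[row.mirna_id, heat_lib]
                / sim.expected_means.loc[row.mirna_id, ctrl_lib]
            )
            assert np.log2(ratio) == pytest.approx(row.log2fc)

    def test_first_genotype_always_spiked(self):
        sim = simulate_counts(SMALL)
        per_mirna = sim.truth.groupby("mirna_id")["genotype"].unique()
        assert all("GXN" in genos for genos in per_mirna)

    def test_zero_depth_rejected(self):
        with pytest.raises(SimulationError):
            simulate_counts(SimulationConfig(library_depth=0))

    def test_generated_matrix_passes_reader_invariants(self, tmp_path):
        from mirqtl import io_formats

        sim = simulate_counts(SMALL)
        io_formats.write_count_table(sim.counts, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = io_formats.read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert np.array_equal(back.counts, sim.counts.counts)


class TestPanel:
    def test_no_qtls_and_no_noise_gives_parent_phenotype_everywhere(self):
        cfg = SimulationConfig(seed=3, planted_qtls=(), phenotype_sd=0.0)
        panel = simulate_sssl_panel(cfg)
        assert np.allclose(panel.phenotypes["value"], cfg.parent_mean)
        assert panel.truth.empty

    def test_carrier_mean_shift_is_twice_the_additive_effect(self):
        cfg = SimulationConfig(seed=4, phenotype_sd=0.0)
        panel = simulate_sssl_panel(cfg)
        means = panel.phenotypes.groupby("line_id")["value"].mean()
        for _, row in panel.truth.iterrows():
            shift = means[row.line_id] - means[cfg.parent_id]
            assert shift == pytest.approx(2.0 * row.additive_effect)

    def test_each_planted_qtl_covered_by_exactly_one_line(self):
        panel = simulate_sssl_panel(SimulationConfig(seed=5))
        for chrom, start, end, _ in panel.qtl_intervals:
            cidx = panel.markers.chrom_indices(chrom)
            covering = []
            for line, row in zip(panel.genotypes.line_ids, panel.genotypes.codes):
                donor_pos = [
                    panel.markers.positions_mb[i] for i in cidx if row[i] == "D"
                ]
                if donor_pos and min(donor_pos) <= start and max(donor_pos) >= end:
                    covering.append(line)
            assert covering == [panel.truth.set_index("chromosome").loc[chrom, "line_id"]]

    def test_more_qtls_than_lines_rejected(self):
        qtls = tuple(
            SimulationConfig().planted_qtls[0].__class__(str(i + 1), 1.0) for i in range(5)
        )
        with pytest.raises(SimulationError):
            simulate_sssl_panel(SimulationConfig(n_lines=3, planted_qtls=qtls))


class TestTargets:
    def _sim(self, **kwargs):
        cfg = SimulationConfig(seed=9, n_mirnas=60, n_de=6, n_genes=20, **kwargs)
        counts = simulate_counts(cfg)
        panel = simulate_sssl_panel(cfg)
        return cfg, simulate_annotation_and_targets(cfg, counts.truth, panel.qtl_intervals), panel

    def test_planted_sites_score_their_mismatch_count(self):
        cfg, targets, _ = self._sim()
        _check_planted_sites(targets)
        scheme = ScoringScheme()
        tx = dict(targets.transcript_records)
        mir = dict(targets.mirna_records)
        for _, row in targets.truth_pairs.iterrows():
            site = tx[row.gene_id][row.site_start : row.site_start + cfg.mirna_length_nt]
            score = naive_site_score(mir[row.mirna_id], site, "none", 0, scheme)
            assert score == pytest.approx(float(row.n_mismatches))

    def test_all_targets_inside_qtls_when_fraction_is_one(self):
        _, targets, panel = self._sim(fraction_targets_in_qtl=1.0)
        assert targets.truth_pairs["in_qtl"].all()
        by_chrom = {}
        for chrom, s, e, _ in panel.qtl_intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        genes = {g.gene_id: g for g in targets.genes}
        for gid in targets.truth_pairs["gene_id"]:
            g = genes[gid]
            assert any(
                g.start_mb < e and g.end_mb > s for s, e in by_chrom.get(g.chromosome, [])
            )

    def test_out_of_qtl_genes_avoid_all_qtl_intervals(self):
        _, targets, panel = self._sim(fraction_targets_in_qtl=0.5)
        by_chrom = {}
        for chrom, s, e, _ in panel.qtl_intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        in_qtl_ids = set(targets.truth_pairs.loc[targets.truth_pairs.in_qtl, "gene_id"])
        for g in targets.genes:
            if g.gene_id in in_qtl_ids:
                continue
            assert all(
                g.end_mb <= s or g.start_mb >= e
                for s, e in by_chrom.get(g.chromosome, [])
            )


class TestProfilesAndPlants:
    def test_true_target_profiles_anticorrelate_with_spike(self):
        cfg = SMALL
        counts = simulate_counts(cfg)
        panel = simulate_sssl_panel(cfg)
        targets = simulate_annotation_and_targets(cfg, counts.truth, panel.qtl_intervals)
        profiles, abundance = simulate_expression_profiles(cfg, counts.truth, targets.truth_pairs)
        spike = {
            (r.mirna_id, r.genotype, r.timepoint_hours): r.log2fc
            for _, r in counts.truth.iterrows()
        }
        for _, row in targets.truth_pairs.iterrows():
            prof = profiles[row.gene_id]
            planted = np.array(
                [spike.get((row.mirna_id, g, t), 0.0) for g, t in prof.cells]
            )
            if planted.std() > 0:
                r = np.corrcoef(planted, prof.values)[0, 1]
                assert r < -0.5
            assert abundance[row.gene_id] == (50.0 if row.expressed else 0.0)

    def test_plant_records_reproduce_requested_fertility(self):
        cfg = SimulationConfig(seed=2, plants_per_line=10)
        records = simulate_plant_records(cfg, {"HJX": (76.6, 15.3)})
        df = pd.DataFrame(
            {"cond": [r.condition for r in records], "sfp": [r.fsp / r.tsp * 100 for r in records]}
        )
        means = df.groupby("cond")["sfp"].mean()
        assert means["control"] == pytest.approx(76.6, abs=5.0)
        assert means["heat"] == pytest.approx(15.3, abs=5.0)
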