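"""Seeded generators: determinism, planted-truth recovery, sampling laws."""

import numpy as np
import pandas as pd
import pytest

from dndscape.dnd_detect import assign_dnd_genes
from dndscape.fitness import CompetitionSeries, relative_fitness
from dndscape.genome_io import ProphageRegion
from dndscape.prophage_profile import assign_family
from dndscape.pt_sites import deg_pt_coupling, scan_motifs
from dndscape.synthetic_data import (
    PanelSpec,
    hits_from_frame,
    simulate_competition,
    simulate_de_table,
    simulate_hit_table,
    simulate_panel,
    simulate_prophage_proteins,
    simulate_sequence_with_motifs,
)


class TestDeterminism:
    def test_panel_identical_across_runs(self):
        a = simulate_panel(PanelSpec(seed=11, genomes_per_genus=40))
        b = simulate_panel(PanelSpec(seed=11, genomes_per_genus=40))
        assert a.truth.to_csv() == b.truth.to_csv()
        assert a.taxonomy.to_csv() == b.taxonomy.to_csv()
        assert a.assignments.to_csv() == b.assignments.to_csv()
        assert [g.features for g in a.genomes] == [g.features for g in b.genomes]

    def test_light_panel_matches_full_panel_truth(self):
        full = simulate_panel(PanelSpec(seed=11, genomes_per_genus=40))
        light = simulate_panel(
            PanelSpec(seed=11, genomes_per_genus=40), include_genomes=False
        )
        assert full.truth.to_csv() == light.truth.to_csv()

    def test_other_generators_byte_identical(self):
        panel = simulate_panel(PanelSpec(seed=5, genomes_per_genus=20))
        h1, _ = simulate_hit_table(panel.assignments, seed=7, decoy_rate=1.0)
        h2, _ = simulate_hit_table(panel.assignments, seed=7, decoy_rate=1.0)
        assert h1.to_csv() == h2.to_csv()
        s1 = simulate_sequence_with_motifs(5000, 0.01, 0.5, seed=9)
        s2 = simulate_sequence_with_motifs(5000, 0.01, 0.5, seed=9)
        assert s1[0] == s2[0] and s1[1].to_csv() == s2[1].to_csv()
        c1 = simulate_competition(1.04, seed=13)
        c2 = simulate_competition(1.04, seed=13)
        assert c1.to_csv() == c2.to_csv()
        d1 = simulate_de_table(100, 10, seed=17)
        d2 = simulate_de_table(100, 10, seed=17)
        assert d1[0].to_csv() == d2[0].to_csv() and d1[1].to_csv() == d2[1].to_csv()


class TestHitTables:
    def test_zero_noise_perfect_recovery(self):
        panel = simulate_panel(PanelSpec(seed=21, genomes_per_genus=50))
        df, fam_map = simulate_hit_table(panel.assignments, seed=22, decoy_rate=0.0)
        recovered = assign_dnd_genes(hits_from_frame(df, fam_map))
        assert {a.gene_id for a in recovered} == set(panel.assignments["gene_id"])
        fam_of = dict(zip(panel.assignments["gene_id"], panel.assignments["family"]))
        assert all(a.family == fam_of[a.gene_id] for a in recovered)

    def test_recovery_robust_to_decoys(self):
        panel = simulate_panel(PanelSpec(seed=21, genomes_per_genus=50))
        df, fam_map = simulate_hit_table(panel.assignments, seed=23, decoy_rate=3.0)
        recovered = assign_dnd_genes(hits_from_frame(df, fam_map))
        assert {a.gene_id for a in recovered} == set(panel.assignments["gene_id"])

    def test_decoys_only_yield_no_assignments(self):
        panel = simulate_panel(PanelSpec(seed=21, genomes_per_genus=30))
        df, fam_map = simulate_hit_table(panel.assignments, seed=24, decoy_rate=2.0)
        decoys = df.iloc[len(panel.assignments):]
        assert assign_dnd_genes(hits_from_frame(decoys, fam_map)) == []

    def test_decoy_evalues_never_survive_default_filter(self):
        panel = simulate_panel(PanelSpec(seed=21, genomes_per_genus=30))
        df, _ = simulate_hit_table(panel.assignments, seed=25, decoy_rate=2.0)
        decoys = df.iloc[len(panel.assignments):]
        passing = (decoys["evalue"] < 1e-10) & (
            decoys["length"] / decoys["qlen"] >= 0.5
        )
        assert not passing.any()


class TestPanel:
    def test_prevalence_zero_plants_nothing(self):
        panel = simulate_panel(
            PanelSpec(seed=31, genomes_per_genus=100,
                      dnd_cluster_prevalence={"dndBCDE": 0.0})
        )
        assert not panel.truth["dnd_any"].any()
        assert len(panel.assignments) == 0

    def test_planted_prevalence_within_binomial_error(self):
        n = 500
        panel = simulate_panel(
            PanelSpec(seed=32, genomes_per_genus=n), include_genomes=False
        )
        prev = panel.truth["dndBCDE"].mean()
        se = np.sqrt(0.18 * 0.82 / n)
        assert abs(prev - 0.18) < 3 * se

    def test_independence_under_beta_zero(self):
        taus = []
        for seed in range(40):
            panel = simulate_panel(
                PanelSpec(seed=1000 + seed, genomes_per_genus=300,
                          dependence_beta=0.0),
                include_genomes=False,
            )
            x = panel.truth["dnd_any"].astype(int)
            y = panel.truth["n_prophages"]
            if x.nunique() < 2 or y.nunique() < 2:
                continue
            from dndscape.cooccur_stats import within_taxon_association

            taus.append(within_taxon_association(x, y).statistic)
        mean_tau = np.mean(taus)
        se = np.std(taus, ddof=1) / np.sqrt(len(taus))
        assert abs(mean_tau) < 3 * se + 1e-9

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ValueError, match="plant"):
            simulate_panel(PanelSpec(seed=1, genes_per_genome=10,
                                     dnd_cluster_prevalence={
                                         "dndCD": 1.0, "dndBCDE": 1.0,
                                         "dndFGH": 1.0}))


class TestProphageProteins:
    def _region(self, n=10):
        return ProphageRegion("G1", "chrom", 0, 1000,
                              protein_ids=[f"p{i}" for i in range(n)])

    @pytest.mark.parametrize(
        "purity,expected", [(1.0, "Siphoviridae"), (0.5, "Siphoviridae"),
                            (0.4, "unclassified"), (0.0, "unclassified")]
    )
    def test_purity_controls_classification(self, purity, expected):
        region = self._region(10)
        hits = simulate_prophage_proteins(region, "Siphoviridae", purity, seed=41)
        assert assign_family(region, hits).family == expected


class TestSequences:
    def test_scan_recovers_exactly_planted_motifs(self):
        seq, _, planted = simulate_sequence_with_motifs(20000, 0.01, 0.3, seed=51)
        found = scan_motifs(seq)
        assert len(found) == len(planted)
        assert [p for p, _ in found] == sorted(planted["position"])

    def test_modified_fraction_recoverable(self):
        seq, sites, planted = simulate_sequence_with_motifs(
            40000, 0.01, 0.0405, seed=52
        )
        from dndscape.pt_sites import MOTIF_CLASS, modified_fraction, motif_totals

        totals = motif_totals(seq)["reference_strand"]
        for motif in ("GAAC", "GTTC"):
            cls = MOTIF_CLASS[motif]
            n_mod = (sites["motif_class"] == cls).sum()
            n_tot = (planted["motif_class"] == cls).sum()
            assert totals[motif] == n_tot
            pct = modified_fraction(int(n_mod), int(n_tot))
            assert pct == pytest.approx(100 * round(0.0405 * n_tot) / n_tot)

    def test_zero_modified_fraction_empty_sites(self):
        _, sites, planted = simulate_sequence_with_motifs(5000, 0.005, 0.0, seed=53)
        assert len(sites) == 0 and len(planted) > 0

    def test_too_dense_raises(self):
        with pytest.raises(ValueError, match="density"):
            simulate_sequence_with_motifs(100, 0.5, 0.1, seed=54)


class TestCompetition:
    def test_neutral_w_estimated_near_one(self):
        ws = []
        for seed in range(60):
            counts = simulate_competition(1.0, f0=0.5, n_transfers=2,
                                          replicates=1, seed=seed)
            series = CompetitionSeries.from_counts(counts)
            ws.append(relative_fitness(series, (0, 2)).mean_w)
        mean_w = np.mean(ws)
        se = np.std(ws, ddof=1) / np.sqrt(len(ws))
        assert abs(mean_w - 1.0) < 3 * se + 1e-6

    def test_large_samples_converge_to_true_w(self):
        counts = simulate_competition(
            1.04, f0=0.52, n_transfers=5, colonies_per_sample=10**5,
            replicates=1, seed=61,
        )
        series = CompetitionSeries.from_counts(counts)
        w = relative_fitness(series, (0, 5)).mean_w
        assert w == pytest.approx(1.04, abs=0.003)

    def test_fixation_horizon_rejected(self):
        with pytest.raises(ValueError, match="fixation|horizon"):
            simulate_competition(3.0, f0=0.05, n_transfers=40, seed=62)


class TestDeTables:
    def test_planted_degs_recovered_exactly(self):
        de, counts = simulate_de_table(1000, 57, seed=71)
        rep = deg_pt_coupling(de, counts)
        assert rep["n_deg"] == 57

    def test_enrichment_shifts_deg_proportion(self):
        de, counts = simulate_de_table(4000, 2000, seed=72, pt_prob=0.3,
                                       pt_enrichment=0.3)
        rep = deg_pt_coupling(de, counts)
        assert rep["deg_with_pt_percent"] > rep["non_deg_with_pt_percent"] + 10
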