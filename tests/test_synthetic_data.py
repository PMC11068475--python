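import numpy as np
import pandas as pd
import pytest

from gmebiome import synthetic_data as sd


class TestStudyDesign:
    def test_default_design_counts(self):
        d = sd.StudyDesign()
        assert d.n_combinations == 72
        assert d.n_pots == 144

    def test_rejects_duplicate_levels(self):
        with pytest.raises(ValueError):
            sd.StudyDesign(genotypes=("a", "a"))

    def test_term_df_for_printed_levels(self):
        d = sd.StudyDesign(inoculants=("F5C", "F5S", "MIX"))
        assert d.term_df() == {"G": 8, "M": 2, "E": 1, "GxM": 16,
                               "GxE": 8, "MxE": 2, "GxMxE": 16}


class TestGenerateReference:
    def test_seeded_determinism(self, tmp_path):
        a = sd.generate_reference(10, seed=1, outdir=tmp_path / "a")
        b = sd.generate_reference(10, seed=1, outdir=tmp_path / "b")
        assert a["reference"] == b["reference"]
        for fname in ("reference.fasta", "lineage.tsv", "accepted_names.tsv",
                      "host.fasta"):
            assert (tmp_path / "a" / fname).read_bytes() == \
                   (tmp_path / "b" / fname).read_bytes()

    def test_dimension_contract(self):
        out = sd.generate_reference(2, lineage_depth=6, seed=0)
        assert len(out["reference"]) == 2
        rank_cols = [c for c in out["lineage"].columns if c != "reference_id"]
        assert len(rank_cols) == 6

    def test_withheld_name_count(self):
        out = sd.generate_reference(20, seed=3, withheld_fraction=0.1)
        accepted = set(zip(out["accepted_names"]["rank"],
                           out["accepted_names"]["name"]))
        genera = set(out["lineage"]["genus"])
        missing = {g for g in genera if ("genus", g) not in accepted}
        assert len(missing) == 2

    def test_sequences_pairwise_distinct(self):
        out = sd.generate_reference(12, seed=5)
        seqs = list(out["reference"].values())
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                ident = np.mean([a == b for a, b in zip(seqs[i], seqs[j])])
                assert ident < 0.5

    def test_invalid_n_taxa(self):
        with pytest.raises(ValueError):
            sd.generate_reference(1)


class TestSimulateCommunities:
    def test_rows_sum_to_one_and_metadata_shape(self, tiny_design):
        model = sd.default_community_model(n_taxa=10, seed=0)
        comp, meta = sd.simulate_communities(tiny_design, model, seed=1,
                                             samples_per_pot=2)
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        assert len(meta) == len(comp) == tiny_design.n_pots * 2
        assert set(meta.columns) == {"sample", "G", "M", "E", "pot"}

    def test_null_model_gives_shared_composition(self, tiny_design):
        scales = {t: 0.0 for t in sd.TERMS}
        model = sd.CommunityModel(n_taxa=6,
                                  baseline_logabundance=np.arange(6.0),
                                  effect_scales=scales, overdispersion=1e-9)
        comp, _ = sd.simulate_communities(tiny_design, model, seed=2)
        assert np.allclose(comp.to_numpy(), comp.to_numpy()[0], atol=1e-6)

    def test_seeded_determinism(self, tiny_design):
        model = sd.default_community_model(n_taxa=10, seed=0)
        a, _ = sd.simulate_communities(tiny_design, model, seed=9)
        b, _ = sd.simulate_communities(tiny_design, model, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateReads:
    def test_fresh_umis_without_duplication(self, tiny_design, tiny_reference,
                                            tmp_path):
        model = sd.default_community_model(n_taxa=8, seed=2)
        comp, _ = sd.simulate_communities(tiny_design, model, seed=3,
                                          samples_per_pot=1)
        cfg = sd.ReadSimConfig(per_base_error=0.0, mean_pcr_duplicates=0.0,
                               reads_per_sample=30, seed=5)
        _, _, log = sd.simulate_reads(comp, tiny_reference["reference"], cfg,
                                      tmp_path)
        for sample in log["samples"].values():
            mols = sample["molecules"]
            umis = {m["umi"] for m in mols}
            assert len(umis) == len(mols)        # fresh UMI per molecule
            assert all(m["copies"] == 1 for m in mols)

    def test_pcr_duplicates_share_umis(self, tiny_design, tiny_reference,
                                       tmp_path):
        model = sd.default_community_model(n_taxa=8, seed=2)
        comp, _ = sd.simulate_communities(tiny_design, model, seed=3,
                                          samples_per_pot=1)
        cfg = sd.ReadSimConfig(per_base_error=0.0, mean_pcr_duplicates=4.0,
                               reads_per_sample=30, seed=5)
        r1, _, log = sd.simulate_reads(comp, tiny_reference["reference"], cfg,
                                       tmp_path)
        n_molecules = sum(len(s["molecules"]) for s in log["samples"].values())
        n_reads = sum(1 for line in open(r1) if line.startswith("@"))
        assert n_reads > n_molecules
        for sample in log["samples"].values():
            assert len({m["umi"] for m in sample["molecules"]}) == \
                len(sample["molecules"])

    def test_umi_respects_pattern(self, tiny_design, tiny_reference, tmp_path):
        model = sd.default_community_model(n_taxa=8, seed=2)
        comp, _ = sd.simulate_communities(tiny_design, model, seed=3,
                                          samples_per_pot=1)
        cfg = sd.ReadSimConfig(reads_per_sample=20, seed=6)
        _, _, log = sd.simulate_reads(comp, tiny_reference["reference"], cfg,
                                      tmp_path)
        for sample in log["samples"].values():
            for m in sample["molecules"]:
                for base, pat in zip(m["umi"], cfg.umi_pattern):
                    assert base in sd.IUPAC[pat]

    def test_byte_identical_under_seed(self, tiny_design, tiny_reference,
                                       tmp_path):
        model = sd.default_community_model(n_taxa=8, seed=2)
        comp, _ = sd.simulate_communities(tiny_design, model, seed=3,
                                          samples_per_pot=1)
        cfg = sd.ReadSimConfig(reads_per_sample=25, seed=7,
                               per_base_error=0.01, mean_pcr_duplicates=1.0)
        r1a, r2a, _ = sd.simulate_reads(comp, tiny_reference["reference"],
                                        cfg, tmp_path / "a")
        r1b, r2b, _ = sd.simulate_reads(comp, tiny_reference["reference"],
                                        cfg, tmp_path / "b")
        assert r1a.read_bytes() == r1b.read_bytes()
        assert r2a.read_bytes() == r2b.read_bytes()

    def test_empty_composition_rejected(self, tiny_reference, tmp_path):
        cfg = sd.ReadSimConfig()
        with pytest.raises(ValueError):
            sd.simulate_reads(pd.DataFrame(), tiny_reference["reference"],
                              cfg, tmp_path)


class TestSimulatePhenotypes:
    def test_individual_count_without_death(self):
        design = sd.StudyDesign()
        model = sd.default_pheno_model(design)
        model.death_rate = 0.0
        table = sd.simulate_phenotypes(design, model, seed=1)
        assert len(table) == 72 * 2 * 6

    def test_death_rate_drops_individuals(self):
        design = sd.StudyDesign()
        table = sd.simulate_phenotypes(design, sd.default_pheno_model(design),
                                       seed=1)
        assert 0.85 * 864 < len(table) < 0.97 * 864

    def test_genotype_mean_recovery_without_effects(self):
        # law-of-large-numbers check: no effects, no pot/vigor variation
        design = sd.StudyDesign(genotypes=("a", "b"), inoculants=("x",),
                                environments=("u",), pots_per_combination=1,
                                plants_per_pot=2500)
        model = sd.PhenoModel(genotype_means={"a": 5.0, "b": 9.0},
                              factor_effects={}, pot_sd=0.0, vigor_sd=0.0,
                              gamma_shape=12.0, death_rate=0.0)
        table = sd.simulate_phenotypes(design, model, seed=2)
        means = table.groupby("G")["SL"].mean()
        assert means["a"] == pytest.approx(5.0, rel=0.02)
        assert means["b"] == pytest.approx(9.0, rel=0.02)

    def test_traits_positively_correlated(self, pheno_table):
        corr = pheno_table[["SL", "RL", "NOL", "NOB"]].corr()
        assert (corr.to_numpy() > 0).all()

    def test_seeded_determinism(self, tiny_design):
        model = sd.default_pheno_model(tiny_design)
        a = sd.simulate_phenotypes(tiny_design, model, seed=3)
        b = sd.simulate_phenotypes(tiny_design, model, seed=3)
        pd.testing.assert_frame_equal(a, b)
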