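"""Generator contracts: determinism, round-trips, NB moments, planted truth."""

import filecmp
import json

import numpy as np
import pytest

from cernet import io as cio
from cernet.annotation import classify_all
from cernet.models import rng_from_seed
from cernet.simulate import (
    CATEGORY_CYCLE,
    PlacementError,
    SimulationConfig,
    generate_counts,
    generate_gene_models,
    plan_truth,
    simulate,
    write_fixture,
)
from cernet.targets import SITE_RANK, find_seed_sites

from conftest import read_tsv


class TestConfigValidation:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "kw",
        [
            {"nb_dispersion": 0.0},
            {"nb_dispersion": -1.0},
            {"n_mrna": -2},
            {"n_mrna": 2.5},
            {"n_planted_triads": 50},
            {"triad_correlation_strength": 1.5},
            {"de_fraction": -0.1},
            {"utr_length": 10},
            {"n_replicates_per_group": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_triad_mirna_budget(self):
        with pytest.raises(ValueError, match="mirnas_per_triad"):
            SimulationConfig(n_mirna=5, n_planted_triads=3, mirnas_per_triad=3)


class TestGeneModels:
    def test_five_categories_with_five_lncrnas(self):
        cfg = SimulationConfig(n_lncrna=5, n_planted_triads=0)
        _, _, categories = generate_gene_models(cfg)
        assert sorted(categories.values()) == sorted(CATEGORY_CYCLE)

    def test_coding_genes_have_multiple_exons(self):
        genes, _, _ = generate_gene_models(SimulationConfig())
        assert all(len(g.exons) >= 2 for g in genes)

    def test_genome_too_small_names_region(self):
        with pytest.raises(PlacementError, match="chr1"):
            generate_gene_models(SimulationConfig(genome_length=1000))

    def test_crowded_cassette_error(self):
        cfg = SimulationConfig(
            n_mrna=1, n_lncrna=30, n_mirna=1, n_planted_triads=0
        )
        with pytest.raises(PlacementError, match="crowded"):
            generate_gene_models(cfg)

    def test_classifier_roundtrip(self):
        cfg = SimulationConfig(n_lncrna=15, n_planted_triads=0)
        genes, lncrnas, categories = generate_gene_models(cfg)
        assert classify_all(lncrnas, genes) == categories


class TestSequences:
    def test_mirna_length_mode_22(self):
        cfg = SimulationConfig(n_mirna=200, n_planted_triads=0, n_lncrna=0)
        ds = simulate(cfg)
        lengths = [len(s) for s in ds.mirna_seqs.values()]
        values, counts = np.unique(lengths, return_counts=True)
        assert values[np.argmax(counts)] == 22
        assert set(values) <= {21, 22, 23}

    def test_planted_sites_scanner_roundtrip(self, small_dataset):
        seqs = dict(small_dataset.utr_seqs, **small_dataset.lnc_seqs)
        for mid, tid, pos, site_type in small_dataset.truth.planted_sites:
            sites = find_seed_sites(small_dataset.mirna_seqs[mid], seqs[tid], mid, tid)
            assert (pos, site_type) in {(s.start, s.site_type) for s in sites}

    def test_background_free_of_7mer_sites(self, small_dataset):
        planted = {(m, t) for m, t, _, _ in small_dataset.truth.planted_sites}
        seqs = dict(small_dataset.utr_seqs, **small_dataset.lnc_seqs)
        for mid, mseq in small_dataset.mirna_seqs.items():
            for tid, tseq in seqs.items():
                if (mid, tid) in planted:
                    continue
                sites = find_seed_sites(mseq, tseq, mid, tid)
                assert all(SITE_RANK[s.site_type] < 1 for s in sites), (mid, tid)


class TestCounts:
    def test_nb_moments_match_oracle(self):
        # oracle: NB mean mu, variance mu + mu^2 * dispersion
        cfg = SimulationConfig(
            seed=3,
            n_mrna=1,
            n_lncrna=0,
            n_mirna=1,
            n_planted_triads=0,
            de_fraction=0.0,
            library_size_cv=0.0,
            nb_dispersion=0.1,
            base_mean_log_range=(2.0, 2.0),  # mu = 100 exactly
            n_replicates_per_group=500,  # 1000 samples
        )
        rng = rng_from_seed(cfg.seed)
        truth = plan_truth(cfg, rng)
        counts = generate_counts(cfg, truth, rng)["mrna"].counts.to_numpy().ravel()
        mu, disp = 100.0, 0.1
        se_mean = np.sqrt((mu + mu**2 * disp) / counts.size)
        assert abs(counts.mean() - mu) < 3 * se_mean
        var = counts.var(ddof=1)
        assert var == pytest.approx(mu + mu**2 * disp, rel=0.25)

    def test_noise_free_limit_pearson(self):
        # strength 1, dispersion -> 0: lncRNA and mRNA counts proportional
        from cernet.cerna import pearson

        vals = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed,
                n_mrna=3,
                n_lncrna=3,
                n_mirna=9,
                n_planted_triads=1,
                nb_dispersion=1e-6,
                base_mean_log_range=(2.5, 3.0),
                de_fraction=0.0,
            )
            rng = rng_from_seed(seed)
            truth = plan_truth(cfg, rng)
            counts = generate_counts(cfg, truth, rng)
            vals.append(
                pearson(
                    counts["lncrna"].counts.loc["lnc_0000"],
                    counts["mrna"].counts.loc["mrna_0000"],
                )
            )
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)

    def test_null_features_symmetric_log2fc(self):
        # planted nulls: empirical mean log2FC ~ 0
        from cernet.expression import differential_test

        lfcs = []
        for seed in range(60):
            cfg = SimulationConfig(
                seed=seed, n_mrna=30, n_lncrna=0, n_mirna=1,
                n_planted_triads=0, de_fraction=0.0,
            )
            rng = rng_from_seed(seed)
            truth = plan_truth(cfg, rng)
            counts = generate_counts(cfg, truth, rng)
            lfcs.extend(differential_test(counts["mrna"])["log2fc"])
        assert abs(np.mean(lfcs)) < 0.1

    def test_triad_members_flagged_de(self, small_dataset):
        small_dataset.truth.validate()  # raises on violation

    def test_decoys_present(self, small_config, small_dataset):
        used = small_config.n_planted_triads * small_config.mirnas_per_triad
        site_mirnas = {m for m, _, _, _ in small_dataset.truth.planted_sites}
        decoy_sites = small_config.mirna_ids[used]
        decoy_corr = small_config.mirna_ids[used + 1]
        assert decoy_sites in site_mirnas
        assert decoy_corr not in site_mirnas
        assert small_dataset.truth.de_flags["mirna"][decoy_corr] != "null"


class TestFixtureIO:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_mrna=10, n_lncrna=5, n_mirna=10,
                               n_planted_triads=2, mirnas_per_triad=2)
        a, b = tmp_path / "a", tmp_path / "b"
        write_fixture(simulate(cfg), a)
        write_fixture(simulate(cfg), b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_truth_triad_rows(self, small_config, fixture_dir):
        triads = read_tsv(fixture_dir / "truth_triads.tsv")
        expected = small_config.n_planted_triads * small_config.mirnas_per_triad
        assert len(triads) == expected

    def test_manifest_reproduces(self, fixture_dir, tmp_path):
        from cernet.simulate import load_fixture_config

        cfg = load_fixture_config(fixture_dir)
        out = tmp_path / "regen"
        write_fixture(simulate(cfg), out)
        for name in ("counts_mrna.tsv", "models.gtf", "mirna.fa", "truth_de.tsv"):
            assert (out / name).read_bytes() == (fixture_dir / name).read_bytes()

    def test_gtf_roundtrip(self, small_dataset, fixture_dir):
        genes, transcripts = cio.read_gtf(fixture_dir / "models.gtf")
        assert [g.id for g in genes] == [g.id for g in small_dataset.genes]
        assert [g.exons for g in genes] == [g.exons for g in small_dataset.genes]
        lncs = [t for t in transcripts if t.biotype == "lncRNA"]
        assert [(t.id, t.exons, t.strand) for t in lncs] == [
            (t.id, t.exons, t.strand) for t in small_dataset.lncrnas
        ]

    def test_manifest_contents(self, fixture_dir, small_config):
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        assert manifest["seed"] == small_config.seed
        assert manifest["config"]["n_mrna"] == small_config.n_mrna
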