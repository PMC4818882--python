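"""Synthetic-data generator: determinism, stated design, round-trips."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from dataclasses import replace

from blastodyn import (
    SimConfig,
    SyntheticDataset,
    simulate_experiment,
    simulate_transcripts,
    write_dataset,
)
from blastodyn.io import (
    read_counts,
    read_go_map,
    read_hit_table,
    read_transcript_truth,
    read_transcripts,
)
from blastodyn.synthetic_data import ORF_CLASSES, STOP_CODONS


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"library_size": 0},
            {"de_fraction": -0.1},
            {"de_fraction": 0.8},  # exceeds the cyclic-design bound 2/P
            {"log2fc_range": (0.0, 2.0)},
            {"phases": ("MC",)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_comparisons_are_cyclic(self):
        assert SimConfig().comparisons == [
            ("preTO", "MC"), ("TO", "preTO"), ("MC", "TO"),
        ]


class TestSimulateExperiment:
    def test_no_de_world_is_all_null(self):
        ds = simulate_experiment(SimConfig(n_genes=100, de_fraction=0.0, seed=5))
        assert (ds.truth_de["status"] == "null").all()
        assert (ds.truth_de["log2fc"] == 0).all()

    def test_determinism(self):
        a = simulate_experiment(SimConfig(n_genes=150, seed=7))
        b = simulate_experiment(SimConfig(n_genes=150, seed=7))
        assert a.counts.counts.equals(b.counts.counts)
        assert a.truth_de.equals(b.truth_de)
        assert a.go_map.equals(b.go_map)
        assert [r.sequence for r in a.transcripts] == [r.sequence for r in b.transcripts]

    def test_de_fraction_within_binomial_bounds(self, default_dataset):
        # per transition the number of non-null genes is Binomial(n, 0.1);
        # the observed fraction must sit inside the central 99% interval
        cfg = default_dataset.config
        lo = scipy.stats.binom.ppf(0.005, cfg.n_genes, cfg.de_fraction)
        hi = scipy.stats.binom.ppf(0.995, cfg.n_genes, cfg.de_fraction)
        for comparison, group in default_dataset.truth_de.groupby("comparison"):
            n_de = (group["status"] != "null").sum()
            assert lo <= n_de <= hi, comparison

    def test_cyclic_effects_sum_to_zero(self, small_dataset):
        sums = small_dataset.truth_de.groupby("gene_id")["log2fc"].sum()
        assert np.allclose(sums, 0.0)

    def test_null_gene_mean_converges(self):
        # 1e4 replicate samples per phase-free world: empirical mean within
        # 5% of library_size * theta (colony effect is mean ~1.005)
        cfg = SimConfig(
            n_genes=40, n_colonies=3334, de_fraction=0.0,
            library_size=1e5, colony_sigma=0.1, seed=13,
        )
        ds = simulate_experiment(cfg)
        mc_cols = ds.counts.samples.loc[
            ds.counts.samples["phase"] == "MC", "sample_id"
        ]
        means = ds.counts.counts[mc_cols].mean(axis=1)
        expected = cfg.library_size * ds.theta
        rel = np.abs(means / expected - 1.0)
        assert (rel < 0.05).all()

    def test_coherent_terms_share_direction(self, default_dataset):
        # among a coherent term's truly-DE members, every comparison must be
        # single-direction; incoherent terms are free to mix
        truth = default_dataset.truth_de
        de = truth[truth["status"] != "null"]
        merged = default_dataset.go_map.merge(de, on="gene_id")
        n_coherent = round(
            default_dataset.config.coherent_term_fraction
            * default_dataset.config.n_go_terms
        )
        coherent_codes = {f"GO:{i + 1:07d}" for i in range(n_coherent)}
        mixing = (
            merged[merged["go_code"].isin(coherent_codes)]
            .groupby(["go_code", "comparison"])["status"]
            .nunique()
        )
        assert (mixing <= 1).all()

    def test_every_term_has_a_member(self, small_dataset):
        assert small_dataset.go_map["go_code"].nunique() == small_dataset.config.n_go_terms


class TestSimulateTranscripts:
    def test_class_counts(self):
        records, truth = simulate_transcripts(SimConfig(transcripts_per_class=10, seed=1))
        assert len(records) == 50
        assert truth["true_class"].value_counts().eq(10).all()
        assert set(truth["true_class"]) == set(ORF_CLASSES)

    def test_complete_record_structure(self):
        records, truth = simulate_transcripts(SimConfig(seed=3))
        by_id = {r.transcript_id: r.sequence for r in records}
        complete = truth.loc[truth["true_class"] == "complete", "transcript_id"]
        min_aa = SimConfig().orf_min_aa
        for tid in complete:
            seq = by_id[tid]
            # some ATG must open a stop-terminated in-frame run >= min_aa
            found = False
            for start in range(len(seq) - 2):
                if seq[start : start + 3] != "ATG":
                    continue
                stops = [
                    i
                    for i in range(start, len(seq) - 2, 3)
                    if seq[i : i + 3] in STOP_CODONS
                ]
                if stops and stops[0] - start >= 3 * min_aa:
                    found = True
                    break
            assert found, tid

    def test_seeded_fasta_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            ds = simulate_experiment(SimConfig(n_genes=50, seed=21))
            manifest = write_dataset(ds, tmp_path / run)
            paths.append(manifest["transcripts"])
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestWriteDataset:
    def test_round_trip(self, small_dataset, tmp_path):
        manifest = write_dataset(small_dataset, tmp_path)
        assert sorted(manifest) == [
            "counts", "go_map", "hits", "samples", "transcripts", "truth_de",
        ]
        assert all(p.stat().st_size > 0 for p in manifest.values())
        experiment = read_counts(manifest["counts"], manifest["samples"])
        assert experiment.counts.equals(small_dataset.counts.counts)
        assert experiment.samples.equals(small_dataset.counts.samples)
        go_map = read_go_map(manifest["go_map"])
        assert go_map.equals(small_dataset.go_map)
        hits = read_hit_table(manifest["hits"])
        assert list(hits["query"]) == list(small_dataset.hit_table["query"])
        records = read_transcripts(manifest["transcripts"])
        assert [r.sequence for r in records] == [
            r.sequence for r in small_dataset.transcripts
        ]
        truth = read_transcript_truth(manifest["transcripts"])
        assert truth.equals(small_dataset.truth_orf)

    def test_empty_dataset_writes_headers(self, small_dataset, tmp_path):
        from blastodyn.pairwise_de import CountExperiment

        empty = SyntheticDataset(
            config=small_dataset.config,
            counts=CountExperiment(
                counts=small_dataset.counts.counts.iloc[0:0],
                samples=small_dataset.counts.samples,
            ),
            truth_de=small_dataset.truth_de.iloc[0:0],
            go_map=small_dataset.go_map.iloc[0:0],
            transcripts=[],
            truth_orf=small_dataset.truth_orf.iloc[0:0],
            hit_table=small_dataset.hit_table.iloc[0:0],
            truth_taxon=small_dataset.truth_taxon.iloc[0:0],
        )
        manifest = write_dataset(empty, tmp_path)
        counts = pd.read_csv(manifest["counts"], sep="\t", index_col=0)
        assert counts.empty and list(counts.columns) == list(
            small_dataset.counts.counts.columns
        )
        truth = pd.read_csv(manifest["truth_de"], sep="\t")
        assert truth.empty and list(truth.columns) == [
            "gene_id", "comparison", "status", "log2fc",
        ]
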