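"""Generator contracts: determinism, planted effects, missingness, round-trips."""

import numpy as np
import pandas as pd
import pytest

import cortexatlas as ca
from cortexatlas.abundance import count_theoretical_peptides
from cortexatlas.synthetic_data import CONCORDANCE_CATEGORIES, default_category_plan


class TestGenerateProteome:
    def test_determinism(self):
        cfg = ca.AtlasConfig(n_regions=13, n_clusters=4, n_proteins=100, seed=5)
        t1, truth1 = ca.generate_proteome(cfg)
        t2, truth2 = ca.generate_proteome(ca.AtlasConfig(n_regions=13, n_clusters=4, n_proteins=100, seed=5))
        assert truth1.region_cluster == truth2.region_cluster
        pd.testing.assert_frame_equal(truth1.true_log2_matrix, truth2.true_log2_matrix)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.intensities, b.intensities)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="cluster_sizes"):
            ca.AtlasConfig(n_regions=13, n_clusters=4, cluster_sizes=(4, 4, 4, 4))
        with pytest.raises(ValueError, match="missing_rate"):
            ca.AtlasConfig(missing_rate=1.5)

    def test_reference_in_every_batch(self, default_atlas):
        cfg, tables, _ = default_atlas
        for t in tables:
            assert cfg.reference_region in t.channel_design.values()

    def test_noiseless_limit_recovers_true_matrix(self):
        """With zero noise and no dropout, merge+normalize equals the
        median-polished truth to 1e-9."""
        cfg = ca.AtlasConfig(n_regions=13, n_clusters=4, n_proteins=200,
                             noise_sd=0.0, missing_rate=0.0, seed=3)
        tables, truth = ca.generate_proteome(cfg)
        bts = [
            ca.compute_reference_ratios(
                t.intensities, t.channel_design, t.reference_region, t.batch_id, t.replicate_id
            )
            for t in tables
        ]
        norm = ca.median_normalize(ca.merge_batches(bts))
        truth_norm = ca.median_normalize(ca.RatioMatrix(truth.true_log2_matrix))
        diff = (norm.values - truth_norm.values.loc[norm.values.index, norm.values.columns]).abs()
        assert diff.to_numpy().max() <= 1e-9

    def test_planted_effect_size(self, default_atlas, merged):
        """Average elevation of planted cluster signatures matches the
        configured effect within 3*noise_sd/sqrt(n_regions)."""
        cfg, _, truth = default_atlas
        vals = merged.values
        cluster_regions = truth.cluster_regions
        diffs = []
        for c, members in truth.cluster_signature_proteins.items():
            target = [r for r in cluster_regions[c] if r != cfg.reference_region]
            other = [
                r for r in vals.columns
                if r not in target and r != cfg.reference_region
            ]
            for p in members & set(vals.index):
                diffs.append(vals.loc[p, target].mean() - vals.loc[p, other].mean())
        tol = 3 * cfg.noise_sd / np.sqrt(cfg.n_regions)
        assert abs(np.mean(diffs) - cfg.signature_effect) <= tol

    def test_missingness_rate_within_binomial_bounds(self, default_atlas):
        cfg, tables, _ = default_atlas
        n_missing = sum(int(t.intensities.isna().all(axis=1).sum()) for t in tables)
        n_rows = len(tables) * cfg.n_proteins
        p = cfg.missing_rate
        half_width = 2.576 * np.sqrt(p * (1 - p) / n_rows)
        assert abs(n_missing / n_rows - p) <= half_width

    def test_signature_sets_disjoint(self, default_atlas):
        _, _, truth = default_atlas
        assert not (truth.all_cluster_signatures & truth.all_ba_signatures)
        assert set(truth.region_cluster) == set(truth.true_log2_matrix.columns)


class TestGenerateSequences:
    def test_deterministic_and_canonical(self):
        s1 = ca.generate_sequences(5, (30, 60), seed=9)
        s2 = ca.generate_sequences(5, (30, 60), seed=9)
        assert s1 == s2
        for seq in s1.values():
            assert set(seq) <= set("ACDEFGHIKLMNPQRSTVWY")
            assert 30 <= len(seq) <= 60

    def test_no_cleavage_sites_single_peptide(self):
        """A K/R-free sequence digests to exactly one peptide, countable iff
        its length is inside the window."""
        seq = "A" * 12
        assert count_theoretical_peptides(seq, (7, 30)) == 1
        assert count_theoretical_peptides("A" * 40, (7, 30)) == 0

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            ca.generate_sequences(2, (5, 8), seed=0)


class TestGenerateTranscriptome:
    def test_unknown_category_rejected(self, tiny_atlas):
        _, _, truth = tiny_atlas
        with pytest.raises(ValueError, match="unknown"):
            ca.generate_transcriptome(truth, plan={"sideways": 3}, seed=0)

    def test_no_change_gene_classified_no_change_at_zero_noise(self, tiny_atlas):
        """Planted flat genes produce 'no change' for every region pair when
        noise and dispersion are off."""
        _, _, truth = tiny_atlas
        truth = _fresh_truth(truth)
        plan = {c: 4 for c in CONCORDANCE_CATEGORIES}
        counts, meta, _ = ca.generate_transcriptome(
            truth, plan=plan, seed=1, noise_sd=0.0, dispersion=0.0, n_qc_fail=0
        )
        _, norm = ca.median_of_ratios(ca.detection_filter(counts))
        profile = ca.region_profile(ca.log2_counts(norm), meta)
        table = ca.classify_all(ca.RatioMatrix(truth.true_log2_matrix), profile)
        no_change = [g for (g, _), cat in truth.concordance_category.items() if cat == "no change"]
        sub = table.entries[table.entries["gene"].isin(no_change)]
        assert (sub["category"] == "no change").all()

    def test_qc_failures_flagged_and_excluded(self, transcriptome_bundle):
        _, meta, _ = transcriptome_bundle
        qc = ca.qc_filter(meta)
        assert len(qc.failing) == 8  # default stated world: 21 of 29 pass
        assert len(qc.passing) == 21
        assert set(qc.passing["sample_id"]).isdisjoint(qc.failing["sample_id"])
        assert (qc.failing["qc_fail_reason"] != "").all()

    def test_planted_pairs_use_six_labels(self, default_atlas, transcriptome_bundle):
        _, _, truth = default_atlas
        cats = set(truth.concordance_category.values())
        assert cats == set(CONCORDANCE_CATEGORIES)
        per = pd.Series(list(truth.concordance_category.values())).value_counts()
        assert (per == 60).all()  # default plan


class TestWriteFixture:
    def test_round_trip(self, tmp_path, tiny_atlas):
        cfg, tables, truth = tiny_atlas
        truth = _fresh_truth(truth)
        seqs = ca.generate_sequences(
            cfg.n_proteins, seed=1, protein_ids=list(truth.true_log2_matrix.index)
        )
        counts, meta, lengths = ca.generate_transcriptome(
            truth, plan={"no change": 3, "agree": 3}, seed=2
        )
        paths = ca.write_fixture(
            {
                "proteome_tables": tables,
                "truth": truth,
                "sequences": seqs,
                "counts": counts,
                "sample_meta": meta,
                "gene_lengths": lengths,
            },
            tmp_path,
        )
        assert all(p.exists() for p in paths)
        from cortexatlas import io as caio

        back = caio.read_matrix_tsv(tmp_path / f"intensities_{tables[0].batch_id}_rep1.tsv")
        pd.testing.assert_frame_equal(back, tables[0].intensities, check_names=False)
        assert caio.read_fasta(tmp_path / "sequences.fasta") == seqs
        truth2 = caio.read_truth_json(tmp_path / "truth.json")
        assert truth2.region_cluster == truth.region_cluster
        assert truth2.concordance_category == truth.concordance_category
        pd.testing.assert_frame_equal(truth2.true_log2_matrix, truth.true_log2_matrix)

    def test_empty_bundle_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty bundle"):
            ca.write_fixture({}, tmp_path)
        assert not list(tmp_path.iterdir())


def _fresh_truth(truth):
    """Copy a session-scoped truth so a test can plant its own categories."""
    import copy

    out = copy.copy(truth)
    out.concordance_category = {}
    return out
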