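"""Synthetic-data generator: determinism, planted truth and postconditions."""

import numpy as np
import pytest

from srnapipe.hairpin import apply_criteria
from srnapipe.simulate import (
    SimulationConfig,
    generate_reference_set,
    sample_libraries,
)
from srnapipe.tags import EmptyLibraryError
from srnapipe.targets import scan_targets


class TestConfig:
    def test_fraction_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_fraction=0.8, ncrna_fraction=0.3)
        with pytest.raises(ValueError):
            SimulationConfig(noise_fraction=-0.1)

    def test_depth_and_ratio_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(fp_depth=0)
        with pytest.raises(ValueError):
            SimulationConfig(fold_change_map={"*": -2.0})

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(loop_len=1)


class TestReferences:
    def test_known_mirna_fasta_has_at_least_one_record_per_family(self, small_experiment):
        config, bundle, _, _ = small_experiment
        families = {r.family for r in bundle.mirna}
        assert len(bundle.mirna) >= config.n_conserved_families
        assert len(families) == config.n_conserved_families

    def test_novel_loci_embedded_and_fold_passing(self, small_experiment):
        config, bundle, truth, _ = small_experiment
        genome_seq = dict(bundle.genome)["toygenome1"]
        for locus in truth.novel_loci:
            embedded = genome_seq[locus.precursor_start : locus.precursor_end]
            assert embedded == locus.precursor_seq
            cand = apply_criteria(
                locus.precursor_seq,
                locus.mature_start - locus.precursor_start,
                locus.mature_end - locus.precursor_start - 1,
            )
            assert cand.passes

    def test_planted_target_sites_score_as_recorded(self, small_experiment):
        config, bundle, truth, _ = small_experiment
        tx = dict(bundle.transcripts)
        mature_of = {r.id: r.seq for r in bundle.mirna}
        mature_of.update({l.locus_id: l.mature_seq for l in truth.novel_loci})
        checked = 0
        for row in truth.target_sites.itertuples():
            hits = scan_targets(row.mirna, mature_of[row.mirna], [(row.gene, tx[row.gene])])
            planted = [
                h for h in hits if not (h.end < row.site_start or h.start > row.site_end)
            ]
            assert planted, f"planted site for {row.mirna} not recovered"
            assert min(h.expectation for h in planted) == pytest.approx(row.expectation)
            checked += 1
        assert checked == len(bundle.mirna) + len(truth.novel_loci)

    def test_go_mapping_covers_transcripts_with_valid_ontologies(self, small_experiment):
        _, bundle, _, _ = small_experiment
        assert set(bundle.go_mapping["ontology"]).issubset(
            {"biological_process", "molecular_function", "cellular_component"}
        )
        assert set(bundle.go_mapping["gene"]).issubset({g for g, _ in bundle.transcripts})

    def test_bundle_writes_standard_files(self, small_experiment, tmp_path):
        _, bundle, _, _ = small_experiment
        paths = bundle.write(tmp_path)
        assert all(p.exists() for p in paths.values())
        from srnapipe.seqio import read_reference_fasta

        assert len(read_reference_fasta(paths["mirna"])) == len(bundle.mirna)


class TestSampling:
    def test_identical_seed_identical_output(self, small_config, tmp_path):
        outs = []
        for sub in ("a", "b"):
            bundle, truth = generate_reference_set(small_config)
            libs = sample_libraries(small_config, truth)
            d = tmp_path / sub
            libs.write(d)
            outs.append((d / "fp_collapsed.fasta").read_bytes())
        assert outs[0] == outs[1]

    def test_zero_depth_rejected(self, small_config):
        bundle, truth = generate_reference_set(small_config)
        bad = SimulationConfig(seed=1)
        bad.fp_depth = 0  # bypasses construction-time validation
        with pytest.raises(EmptyLibraryError):
            sample_libraries(bad, truth)

    def test_read_totals_match_depths_and_truth_categories(self, small_experiment):
        config, _, truth, libs = small_experiment
        assert sum(libs.counts_fp.values()) == config.fp_depth
        assert sum(libs.counts_sp.values()) == config.sp_depth
        category = truth.tags.set_index("sequence")["category"]
        by_cat = {}
        for seq, c in libs.counts_fp.items():
            by_cat[category[seq]] = by_cat.get(category[seq], 0) + c
        assert sum(by_cat.values()) == config.fp_depth

    def test_null_mirna_counts_agree_within_binomial_error(self):
        """With a unit fold-change the two libraries' expected counts are
        equal; over many sampling seeds the mean difference stays within
        5 SD of the binomial expectation."""
        from dataclasses import replace

        config = SimulationConfig(
            seed=77, n_conserved_families=3, n_novel_loci=1, n_noise_tags=200,
            n_ncrna_fragments=20, fp_depth=20_000, sp_depth=20_000,
            fold_change_map={"*": 1.0},
        )
        _, truth = generate_reference_set(config)
        target = truth.tags[truth.tags.category == "known_miRNA"].iloc[0]
        var = 2 * config.fp_depth * target.prob_fp * (1 - target.prob_fp)
        diffs = []
        for seed in range(100):
            libs = sample_libraries(replace(config, seed=seed), truth)
            diffs.append(
                libs.counts_fp.get(target.sequence, 0) - libs.counts_sp.get(target.sequence, 0)
            )
        sd_of_mean = np.sqrt(var / len(diffs))
        assert abs(np.mean(diffs)) < 5 * sd_of_mean

    def test_planted_fourfold_ratio_recovered(self):
        """A single planted 4-fold change is recovered empirically within
        the binomial confidence band for expected counts >= 200."""
        from dataclasses import replace

        probe = SimulationConfig(seed=5)
        _, truth0 = generate_reference_set(probe)
        t0 = truth0.tags[truth0.tags.category == "known_miRNA"]
        # a well-covered member that is still a minor share of the pool, so
        # the compositional constraint barely distorts its realized ratio
        expected = t0.prob_fp * probe.fp_depth
        mid = t0[(expected >= 250) & (expected <= 1500)].iloc[0].ref_id
        cfg = replace(probe, fold_change_map={mid: 4.0})
        _, truth = generate_reference_set(cfg)
        row = truth.tags[truth.tags.ref_id == mid].iloc[0]
        assert row.prob_fp * cfg.fp_depth >= 200
        fp_tot = sp_tot = 0
        for seed in range(10):
            libs = sample_libraries(replace(cfg, seed=seed), truth)
            fp_tot += libs.counts_fp.get(row.sequence, 0)
            sp_tot += libs.counts_sp.get(row.sequence, 0)
        assert 3.2 <= sp_tot / fp_tot <= 4.8
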