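import numpy as np
import pytest

from dichot.model import Localization, SegmentLabel, SiteKind
from dichot.segment import SegmenterConfig, segment_proteome
from dichot.simulate import (
    GeneratorConfig,
    SiteModel,
    emit_evidence,
    emit_pfam_hits,
    place_feature_sites,
    sample_proteome,
)
from dichot.stats import residue_class_fractions
from dichot.pfam_scop import pfam_coverage_by_class

KD, CD, ID = SegmentLabel.KD, SegmentLabel.CD, SegmentLabel.ID


def single_stratum_config(**kwargs):
    """All proteins in one localization, for clean closed-form checks."""
    weights = {loc: 0.0 for loc in Localization}
    weights[Localization.NUCLEUS] = 1.0
    defaults = dict(
        n_proteins=200,
        localization_weights=weights,
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


class TestSampleProteome:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_proteins=50)
        p1, t1 = sample_proteome(cfg, 99)
        p2, t2 = sample_proteome(cfg, 99)
        assert [p.sequence for p in p1] == [p.sequence for p in p2]
        assert all(np.array_equal(t1.labels[p.id], t2.labels[p.id]) for p in p1)
        assert t1.localizations == t2.localizations

    def test_id_target_zero_gives_all_domain(self):
        cfg = single_stratum_config(
            id_targets={loc: 0.0 for loc in Localization}, n_proteins=30
        )
        _, truth = sample_proteome(cfg, 0)
        assert truth.id_fraction() == 0.0

    def test_localization_targets_recovered(self):
        """Realized per-stratum ID fractions concentrate on their targets."""
        cfg = GeneratorConfig(n_proteins=800)
        _, truth = sample_proteome(cfg, 123)
        assert truth.id_fraction(Localization.NUCLEUS) == pytest.approx(0.47, abs=0.02)
        assert truth.id_fraction(Localization.MITOCHONDRION) == pytest.approx(0.13, abs=0.02)

    def test_infeasible_target_with_mandatory_domains(self):
        with pytest.raises(ValueError, match="infeasible"):
            single_stratum_config(
                id_targets={loc: 1.0 for loc in Localization}, min_domain_segments=1
            )

    def test_labels_tile_protein(self):
        cfg = GeneratorConfig(n_proteins=40)
        proteins, truth = sample_proteome(cfg, 4)
        for p in proteins:
            assert truth.labels[p.id].size == p.length
            assert set(truth.labels[p.id]) <= {"KD", "CD", "ID"}


class TestEmitEvidence:
    def test_zero_noise_exact_reconstruction(self):
        """The module's central oracle: with all noise rates zero the
        segmenter reconstructs the true label vector of every protein."""
        cfg = GeneratorConfig(n_proteins=250)
        proteins, truth = sample_proteome(cfg, 21)
        bundles = emit_evidence(truth, cfg, 22)
        for seg in segment_proteome(proteins, bundles):
            assert np.array_equal(seg.labels(), truth.labels[seg.protein_id])

    def test_missed_hits_give_zero_kd_recall(self):
        cfg = single_stratum_config(missed_hit_rate=1.0, region_kd_rate=0.0, n_proteins=40)
        proteins, truth = sample_proteome(cfg, 5)
        bundles = emit_evidence(truth, cfg, 6)
        segs = segment_proteome(proteins, bundles)
        assert residue_class_fractions(segs).counts[KD] == 0

    def test_short_subject_artifacts_defer_to_stage_two(self):
        """With every hit an artifact, true KD segments are re-judged from
        tracks (SD/unassigned) and come back as CDs or short-run IDs."""
        cfg = single_stratum_config(short_subject_rate=1.0, region_kd_rate=0.0, n_proteins=40)
        proteins, truth = sample_proteome(cfg, 7)
        bundles = emit_evidence(truth, cfg, 8)
        segs = segment_proteome(proteins, bundles)
        counts = residue_class_fractions(segs).counts
        assert counts[KD] == 0 and counts[CD] > 0

    def test_false_call_leakage_matches_binomial_expectation(self):
        """Per-residue track noise r moves a CD residue off the candidate
        state with probability 1-(1-r)^2; realized leakage (before the
        run-length correction, measured on candidate residues) lies within
        3 sigma of the binomial expectation."""
        r = 0.05
        cfg = single_stratum_config(false_call_rate=r, region_kd_rate=0.0, n_proteins=150)
        proteins, truth = sample_proteome(cfg, 9)
        bundles = emit_evidence(truth, cfg, 10)
        n_cd = 0
        still_candidate = 0
        for p in proteins:
            vec = truth.labels[p.id]
            cd_mask = vec == "CD"
            n_cd += int(cd_mask.sum())
            b = bundles[p.id]
            cand = (b.track_a.calls != "ID") & (b.track_b.calls == "SD")
            still_candidate += int((cd_mask & cand).sum())
        p_keep = (1 - r) ** 2
        sigma = np.sqrt(n_cd * p_keep * (1 - p_keep))
        assert abs(still_candidate - n_cd * p_keep) < 3 * sigma

    def test_noisy_pipeline_matches_oracle_and_binomial_bound(self):
        """Under flip noise the pipeline still equals the per-residue
        brute-force oracle on the emitted evidence, and CD retention after
        the run-length correction cannot exceed the binomial (per-residue)
        expectation: run-breaking only removes candidates."""
        from dichot.segment import SegmenterConfig
        from oracle import brute_force_labels

        r = 0.03
        cfg = single_stratum_config(false_call_rate=r, n_proteins=100)
        proteins, truth = sample_proteome(cfg, 31)
        bundles = emit_evidence(truth, cfg, 32)
        segs = segment_proteome(proteins, bundles)
        scfg = SegmenterConfig()
        n_cd = retained = 0
        for p, seg in zip(proteins, segs):
            assert list(seg.labels()) == brute_force_labels(p, bundles[p.id], scfg)
            cd_mask = truth.labels[p.id] == "CD"
            n_cd += int(cd_mask.sum())
            retained += int((cd_mask & (seg.labels() == "CD")).sum())
        p_keep = (1 - r) ** 2
        sigma = np.sqrt(n_cd * p_keep * (1 - p_keep))
        assert retained <= n_cd * p_keep + 3 * sigma


class TestPlaceFeatureSites:
    def test_enrichment_odds_closed_form(self):
        """Odds 3 against an ID background f gives site-in-ID probability
        q = 3f/(3f+1-f); at f = 0.35 that is about 0.617."""
        cfg = single_stratum_config(
            n_proteins=300,
            id_targets={loc: 0.35 for loc in Localization},
            site_models={SiteKind.PHOSPHORYLATION: SiteModel(34.0, 3.0)},
        )
        _, truth = sample_proteome(cfg, 13)
        sites = place_feature_sites(truth, cfg, 14)
        f = truth.id_fraction()
        q = 3 * f / (3 * f + (1 - f))
        placed = [s for lst in sites.values() for s in lst]
        n = len(placed)
        assert n > 8000
        in_id = sum(
            truth.labels[pid][s.positions[0]] == "ID"
            for pid, lst in sites.items() for s in lst
        )
        sigma = np.sqrt(q * (1 - q) / n)
        assert in_id / n == pytest.approx(q, abs=3 * sigma)
        assert in_id / n == pytest.approx(0.617, abs=0.02)

    def test_odds_one_is_uniform_null(self):
        cfg = single_stratum_config(
            n_proteins=200, site_models={SiteKind.PHOSPHORYLATION: SiteModel(20.0, 1.0)}
        )
        _, truth = sample_proteome(cfg, 15)
        sites = place_feature_sites(truth, cfg, 16)
        f = truth.id_fraction()
        placed = [(pid, s) for pid, lst in sites.items() for s in lst]
        frac = np.mean([truth.labels[pid][s.positions[0]] == "ID" for pid, s in placed])
        assert frac == pytest.approx(f, abs=3 * np.sqrt(f * (1 - f) / len(placed)))

    def test_odds_zero_never_in_id(self):
        cfg = single_stratum_config(
            n_proteins=60, site_models={SiteKind.PHOSPHORYLATION: SiteModel(5.0, 0.0)}
        )
        _, truth = sample_proteome(cfg, 17)
        sites = place_feature_sites(truth, cfg, 18)
        for pid, lst in sites.items():
            for s in lst:
                assert truth.labels[pid][s.positions[0]] != "ID"

    def test_kind_with_no_eligible_proteins_warns(self):
        cfg = single_stratum_config(  # nucleus only; glycosylation is extracellular
            n_proteins=20, site_models={SiteKind.N_GLYCOSYLATION: SiteModel(2.0, 1.0)}
        )
        _, truth = sample_proteome(cfg, 19)
        with pytest.warns(UserWarning, match="n_glycosylation"):
            sites = place_feature_sites(truth, cfg, 20)
        assert sum(len(v) for v in sites.values()) == 0

    def test_determinism(self):
        cfg = GeneratorConfig(n_proteins=60)
        _, t1 = sample_proteome(cfg, 1)
        _, t2 = sample_proteome(cfg, 1)
        assert place_feature_sites(t1, cfg, 2) == place_feature_sites(t2, cfg, 2)


class TestEmitPfamHits:
    def test_coverage_probabilities_recovered(self):
        cfg = GeneratorConfig(n_proteins=600)
        proteins, truth = sample_proteome(cfg, 23)
        bundles = emit_evidence(truth, cfg, 24)
        hits = emit_pfam_hits(truth, cfg, 25)
        segs = segment_proteome(proteins, bundles)
        table = pfam_coverage_by_class(segs, hits)
        assert table.coverage(KD) == pytest.approx(0.606, abs=0.02)
        assert table.coverage(CD) == pytest.approx(0.266, abs=0.02)
        assert table.coverage(ID) == pytest.approx(0.085, abs=0.02)

    def test_zero_probability_class_uncovered(self):
        cfg = GeneratorConfig(
            n_proteins=100,
            pfam_coverage={KD: 0.5, CD: 0.5, ID: 0.0},
        )
        proteins, truth = sample_proteome(cfg, 26)
        hits = emit_pfam_hits(truth, cfg, 27)
        table = pfam_coverage_by_class(truth.segmentations(), hits)
        assert table.covered[ID] == 0

    def test_pool_size_one_gives_single_unique_domain(self):
        cfg = GeneratorConfig(
            n_proteins=100, pfam_pool_sizes={KD: 1, CD: 1, ID: 1}
        )
        _, truth = sample_proteome(cfg, 28)
        hits = emit_pfam_hits(truth, cfg, 29)
        table = pfam_coverage_by_class(truth.segmentations(), hits)
        for lab in SegmentLabel:
            assert table.unique_domains[lab] <= 1


class TestAsVsExonEnrichment:
    def test_as_boundaries_exceed_uniform_exon_fraction(self):
        """Enriched splice boundaries land in ID more often than uniformly
        placed exon boundaries in the same synthetic proteome."""
        cfg = GeneratorConfig(
            n_proteins=500,
            site_models={
                SiteKind.AS_BOUNDARY: SiteModel(4.0, 3.0),
                SiteKind.EXON_BOUNDARY: SiteModel(8.0, 1.0),
            },
        )
        _, truth = sample_proteome(cfg, 33)
        sites = place_feature_sites(truth, cfg, 34)

        def fraction(kind):
            hits = total = 0
            for pid, lst in sites.items():
                for s in lst:
                    if s.kind != kind:
                        continue
                    for pos in s.positions:
                        total += 1
                        hits += truth.labels[pid][pos] == "ID"
            return hits / total

        assert fraction(SiteKind.AS_BOUNDARY) > fraction(SiteKind.EXON_BOUNDARY)
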