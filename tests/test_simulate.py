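"""Generator determinism, planted-structure consistency, self-checks."""

import numpy as np
import pytest

from dreamtargets.genome import load_gene_models, overlap_fraction
from dreamtargets.motifs import scan_peak_sequences
from dreamtargets.simulate import (
    ScenarioConfig,
    builtin_pwms,
    generate_annotation,
    generate_chip,
    generate_counts,
    plant_motifs,
    simulate_scenario,
)

CFG = ScenarioConfig(seed=5, n_genes=60, chrom_length=200_000,
                     n_lin36_shared=12, n_lin15b_shared=6, n_lin35_only=8)


class TestAnnotation:
    def test_gene_count_and_determinism(self):
        g1, p1, s1, c1 = generate_annotation(CFG)
        g2, p2, s2, c2 = generate_annotation(CFG)
        assert len(g1) == 60
        assert s1 == s2
        assert c1 == c2
        assert [(g.gene_id, g.span.start, g.span.end) for g in g1] == [
            (g.gene_id, g.span.start, g.span.end) for g in g2
        ]

    def test_genes_non_overlapping_and_invariants(self):
        genes, _, seq, classes = generate_annotation(CFG)
        spans = sorted((g.span.start, g.span.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for g in genes:
            assert all(g.span.start <= t < g.span.end for t in g.tss_list)
            assert all(g.span.start <= t < g.span.end for t in g.tts_list)
        assert len(seq) == CFG.chrom_length
        assert sorted(classes) == sorted(g.gene_id for g in genes)

    def test_class_sizes(self):
        _, _, _, classes = generate_annotation(CFG)
        from collections import Counter

        sizes = Counter(classes.values())
        assert sizes["LIN36_shared"] == 12
        assert sizes["LIN15B_shared"] == 6
        assert sizes["LIN35_only"] == 8

    def test_roundtrip_through_gff3(self, tmp_path):
        from dreamtargets.genome import write_gene_models

        genes, _, _, _ = generate_annotation(CFG)
        write_gene_models(genes, tmp_path / "g.gff3")
        reloaded = load_gene_models(tmp_path / "g.gff3")
        assert len(reloaded) == len(genes)

    def test_insufficient_space_error(self):
        cfg = ScenarioConfig(n_genes=100, chrom_length=100_000,
                             n_lin36_shared=5, n_lin15b_shared=5, n_lin35_only=5)
        with pytest.raises(ValueError, match="insufficient space"):
            generate_annotation(cfg)


class TestChip:
    def test_class_peaks_cobind_lin35(self):
        genes, _, _, classes = generate_annotation(CFG)
        _, true_peaks, _ = generate_chip(CFG, genes, classes)
        # every LIN-36 class peak coincides with a LIN-35 peak by construction
        assert overlap_fraction(true_peaks["LIN-36"], true_peaks["LIN-35"]) >= CFG.cobinding_rate["LIN-36"] - 0.15

    def test_full_cobinding_rate(self):
        cfg = ScenarioConfig(seed=5, n_genes=60, chrom_length=200_000,
                             n_lin36_shared=12, n_lin15b_shared=6, n_lin35_only=8,
                             cobinding_rate={"LIN-36": 1.0, "LIN-15B": 1.0})
        genes, _, _, classes = generate_annotation(cfg)
        _, true_peaks, _ = generate_chip(cfg, genes, classes)
        assert overlap_fraction(true_peaks["LIN-36"], true_peaks["LIN-35"]) == 1.0
        assert overlap_fraction(true_peaks["LIN-15B"], true_peaks["LIN-35"]) == 1.0

    def test_planted_decrease_lowers_mutant_coverage(self):
        genes, _, _, classes = generate_annotation(CFG)
        tracks, true_peaks, changes = generate_chip(CFG, genes, classes)
        decreased = [c for c in changes if c["fold"] < 1 and c["factor"] == "LIN-35"]
        assert decreased
        peak_of = {iv.name: iv for iv in true_peaks["LIN-35"]}
        for c in decreased[:10]:
            iv = peak_of[c["peak_id"]]
            wt = np.mean([tracks[("LIN-35", "N2", r)].values[iv.start:iv.end]
                          for r in (1, 2)])
            mut = np.mean([tracks[("LIN-35", c["mutant"], r)].values[iv.start:iv.end]
                           for r in (1, 2)])
            assert mut < wt


class TestCounts:
    def test_determinism(self):
        genes, _, _, classes = generate_annotation(CFG)
        rna1, gb1, k91, tpm1, _ = generate_counts(CFG, genes, classes)
        rna2, gb2, k92, tpm2, _ = generate_counts(CFG, genes, classes)
        assert rna1.counts.equals(rna2.counts)
        assert gb1.counts.equals(gb2.counts)
        assert k91.counts.equals(k92.counts)
        assert tpm1.equals(tpm2)

    def test_planted_effect_visible_in_raw_means(self):
        genes, _, _, classes = generate_annotation(CFG)
        rna, _, _, _, truth = generate_counts(CFG, genes, classes)
        up35 = truth["planted_up"]["lin-35"]
        n2 = [s for s in rna.counts if rna.conditions[s] == "N2"]
        mut = [s for s in rna.counts if rna.conditions[s] == "lin-35"]
        ratio = (rna.counts[mut].mean(axis=1) + 1) / (rna.counts[n2].mean(axis=1) + 1)
        assert ratio[up35].median() > 3.0
        others = [g for g in rna.counts.index if g not in set(up35)]
        assert 0.7 < ratio[others].median() < 1.4

    def test_germline_specificity_planted_high(self):
        genes, _, _, classes = generate_annotation(CFG)
        _, _, _, tpm, _ = generate_counts(CFG, genes, classes)
        score = tpm["germline"] / tpm.sum(axis=1)
        planted = [g for g, c in classes.items() if c == "LIN15B_shared"]
        assert (score[planted] > 0.5).all()
        null_genes = [g for g, c in classes.items() if c == "null"]
        assert score[null_genes].median() < 0.3

    def test_mark_loss_flags_consistent_with_classes(self):
        genes, _, _, classes = generate_annotation(CFG)
        _, _, _, _, truth = generate_counts(CFG, genes, classes)
        for g in truth["gbhtz_loss"]["lin-36"]:
            assert classes[g] == "LIN36_shared"
        for g in truth["k9_loss"]["lin-15B"]:
            assert classes[g] == "LIN15B_shared"


class TestPlantMotifs:
    def test_full_rate_plants_in_every_peak(self):
        cfg = ScenarioConfig(
            seed=9, motif_plant_rates={"LIN36_shared": {"E2F-a1": 1.0}}
        )
        rng = np.random.default_rng(1)
        seqs = {
            f"pk{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 200)) for i in range(20)
        }
        classes = {p: "LIN36_shared" for p in seqs}
        out, planted = plant_motifs(cfg, seqs, classes)
        assert len(planted) == 20
        hits = scan_peak_sequences(out, [p for p in builtin_pwms() if p.motif_id == "E2F-a1"])
        assert {h.peak_id for h in hits} == set(seqs)

    def test_planted_offsets_recoverable(self):
        cfg = ScenarioConfig(seed=9, motif_plant_rates={"LIN36_shared": {"LONG-a": 1.0}})
        rng = np.random.default_rng(2)
        seqs = {f"pk{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 200)) for i in range(10)}
        classes = {p: "LIN36_shared" for p in seqs}
        out, planted = plant_motifs(cfg, seqs, classes)
        hits = scan_peak_sequences(out, [p for p in builtin_pwms() if p.motif_id == "LONG-a"])
        found = {(h.peak_id, h.offset, h.strand) for h in hits}
        for rec in planted:
            assert (rec["peak_id"], rec["offset"], rec["strand"]) in found

    def test_zero_rate_only_chance_hits(self):
        cfg = ScenarioConfig(seed=9, motif_plant_rates={})
        rng = np.random.default_rng(3)
        seqs = {f"pk{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 200)) for i in range(50)}
        out, planted = plant_motifs(cfg, seqs, {p: "LIN36_shared" for p in seqs})
        assert planted == []
        assert out == seqs
        hits = scan_peak_sequences(out, builtin_pwms())
        # expected chance hits: ~2 windows/peak/motif/strand at p<=1e-4
        n_expected = 50 * 200 * 2 * len(builtin_pwms()) * 1e-4
        assert len(hits) <= max(3 * n_expected, 10)


class TestScenario:
    def test_scenario_determinism(self):
        s1 = simulate_scenario(CFG)
        s2 = simulate_scenario(CFG)
        assert s1.sequence == s2.sequence
        assert s1.rna.counts.equals(s2.rna.counts)
        assert s1.truth.classes == s2.truth.classes
        assert s1.truth.planted_motifs == s2.truth.planted_motifs

    def test_ground_truth_consistent_with_files(self, small_scenario):
        truth = small_scenario.truth
        # planted peaks exist in the emitted peak sets
        for factor, recs in truth.true_peaks.items():
            names = {iv.name for iv in small_scenario.true_peaks[factor]}
            assert {r[3] for r in recs} == names
        # planted motif instances are present in the genome sequence
        from dreamtargets.simulate import builtin_pwms as bp

        cons = {p.motif_id: p.consensus for p in bp()}
        rc = str.maketrans("ACGT", "TGCA")
        for rec in truth.planted_motifs[:25]:
            expected = cons[rec["motif_id"]]
            if rec["strand"] == "-":
                expected = expected.translate(rc)[::-1]
            start = rec["genomic_offset"]
            assert small_scenario.sequence[start : start + len(expected)] == expected
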