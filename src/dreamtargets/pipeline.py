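"""End-to-end pipeline: files in, classification report out.

Stage order mirrors the analysis flow: peak calling -> merging/rescaling ->
gene assignment -> differential expression -> target taxonomy -> histone
marks -> differential binding -> germline specificity -> motifs.  Every
stage is deterministic, and when a ground_truth.json is present the report
gains sensitivity/precision per planted class.

All thresholds are surfaced as named config keys defaulting to the
published rules (fdr_de=0.01, lfc_up=0.5849, lfc_down=-1, padj_htz=0.001,
padj_k9=0.01, padj_binding=0.001, motif_p=1e-4, motif_fraction=0.30,
quantile_keep=0.90, rescale_halfwidth=100, promoter_upstream=500,
genebody_offset=500, min_gene_length=500).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, motifs as motifmod, targets as targetmod
from .diffexp import CountMatrix
from .genome import (
    PeakSet,
    load_coverage,
    load_fasta,
    load_gene_models,
    load_intervals,
    merge_intervals,
    overlap_any,
    overlap_fraction,
    rescale_to_midpoint,
    write_intervals,
)
from .peakcalling import SmoothingConfig, call_concave_peaks, reproducible_peaks
from .quantify import peak_windows, quantify, to_pseudocounts, top_quantile_filter
from .simulate import FACTORS, GroundTruth

log = logging.getLogger("dreamtargets")

__all__ = ["PipelineConfig", "run_pipeline"]

FACTOR_MUTANT = {"LIN-35": "lin-35", "LIN-36": "lin-36", "LIN-15B": "lin-15B"}


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    indir: str
    outdir: str
    # published threshold defaults
    fdr_de: float = 0.01
    lfc_up: float = 0.5849
    lfc_down: float = -1.0
    padj_htz: float = 0.001
    padj_k9: float = 0.01
    padj_binding: float = 0.001
    motif_p: float = 1e-4
    motif_fraction: float = 0.30
    quantile_keep: float = 0.90
    rescale_halfwidth: int = 100
    promoter_upstream: int = 500
    genebody_offset: int = 500
    min_gene_length: int = 500
    # peak calling
    bandwidth: float = 75.0
    min_height: float = 2.0
    min_support: int = 2
    # divisor converting summed coverage to counts for the binding test:
    # 1 when track noise is independent per base (the synthetic tracks), the
    # mean fragment length for fragment-correlated real coverage
    fragment_length: int = 1
    # stage toggles
    run_marks: bool = True
    run_binding: bool = True
    run_specificity: bool = True
    run_motifs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_de", "padj_htz", "padj_k9", "padj_binding", "motif_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0 < self.quantile_keep <= 1):
            raise ValueError("quantile_keep must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _read_counts(prefix: Path) -> CountMatrix:
    counts = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    return CountMatrix(counts, pd.Series(meta["condition"].values, index=meta["sample"].values))


def _call_factor_peaks(indir: Path, manifest: dict, cfg: PipelineConfig) -> dict[str, PeakSet]:
    """Concave peaks per replicate, then the replicate-support filter."""
    smoothing = SmoothingConfig(bandwidth=cfg.bandwidth)
    chrom = manifest["chrom"]
    length = manifest["chrom_length"]
    out: dict[str, PeakSet] = {}
    for factor in manifest["factors"]:
        rep_files = manifest["chip_files"][factor]["N2"]
        rep_sets = []
        for rel in rep_files:
            track = load_coverage(indir / rel, chrom, length)
            rep_sets.append(call_concave_peaks(track, smoothing, cfg.min_height))
        peaks = (
            reproducible_peaks(rep_sets, cfg.min_support)
            if len(rep_sets) > 1
            else rep_sets[0]
        )
        named = PeakSet(
            [
                iv.__class__(iv.chrom, iv.start, iv.end, iv.strand, f"{factor}_pk{i}", iv.score)
                for i, iv in enumerate(peaks)
            ]
        )
        out[factor] = named
        log.info("peaks[%s]: %d reproducible peaks from %d replicates", factor, len(named), len(rep_sets))
    return out


def _de_results(rna: CountMatrix, cfg: PipelineConfig) -> tuple[dict, dict]:
    """Per-mutant DE tables and up-gene sets."""
    results, up = {}, {}
    for cond in sorted(set(rna.conditions) - {"N2"}):
        res = diffexp.nb_test(rna, cond, "N2")
        labels = diffexp.classify_de(res, cfg.fdr_de, cfg.lfc_up, cfg.lfc_down)
        results[cond] = res.assign(label=labels)
        up[cond] = set(res.index[labels == "up"])
    return results, up


def _mark_loss(cm: CountMatrix, padj: float, cfg: PipelineConfig,
               filter_top: bool = False) -> dict[str, set]:
    """Per-mutant signal-loss gene sets from a mark count table."""
    counts = cm.counts
    if filter_top:
        n2 = [s for s in counts.columns if cm.conditions[s] == "N2"]
        ref = counts[n2].mean(axis=1)
        cutoff = np.quantile(ref.to_numpy(), 1.0 - cfg.quantile_keep)
        counts = counts.loc[ref >= cutoff]
        cm = CountMatrix(counts, cm.conditions)
    loss = {}
    for cond in sorted(set(cm.conditions) - {"N2"}):
        res = diffexp.nb_test(cm, cond, "N2")
        loss[cond] = set(res.index[diffexp.call_signal_loss(res, padj)])
    return loss, set(counts.index)


def _binding_stage(indir: Path, manifest: dict, factor_peaks: dict, cfg: PipelineConfig):
    """NB test of mutant vs wild-type factor signal in rescaled peak windows."""
    chrom, length = manifest["chrom"], manifest["chrom_length"]
    out = {}
    for contrast in manifest.get("binding_contrasts", []):
        factor, mutant = contrast["factor"], contrast["mutant"]
        windows = peak_windows(rescale_to_midpoint(factor_peaks[factor], cfg.rescale_halfwidth))
        tracks = {}
        cond_of = {}
        for cond in ("N2", mutant):
            for rel in manifest["chip_files"][factor][cond]:
                sample = Path(rel).stem
                tracks[sample] = load_coverage(indir / rel, chrom, length)
                cond_of[sample] = cond
        table = quantify(tracks, windows, mode="sum")
        counts = to_pseudocounts(table, cfg.fragment_length)
        cm = CountMatrix(counts, pd.Series(cond_of))
        res = diffexp.nb_test(cm, mutant, "N2")
        labels = diffexp.classify_binding_change(res, cfg.padj_binding)
        out[(factor, mutant)] = res.assign(label=labels)
    return out


def _motif_stage(indir: Path, manifest: dict, class_peaks: dict[str, PeakSet],
                 cfg: PipelineConfig):
    """Scan shared-class peak sequences, resolve overlaps, filter, associate."""
    genome = load_fasta(indir / "genome.fa")
    seq = genome[manifest["chrom"]]
    seqs, ids_by_class = {}, {}
    for cls, ps in class_peaks.items():
        ids = []
        for iv in ps:
            seqs[iv.name] = seq[iv.start : iv.end]
            ids.append(iv.name)
        ids_by_class[cls] = ids
    pwms = motifmod.read_meme(indir / "motifs.meme")
    hits = motifmod.scan_peak_sequences(seqs, pwms, cfg.motif_p)
    resolved = motifmod.resolve_overlaps(hits)
    kept = motifmod.inclusion_filter(resolved, class_peaks, cfg.motif_fraction)
    kept_hits = [h for h in resolved if h.motif_id in kept]
    assoc = motifmod.association_test(
        class_peaks["LIN36_shared"], class_peaks["LIN15B_shared"], kept_hits
    )
    return resolved, kept, assoc


def _recovery_metrics(recovered: set, truth_set: set) -> dict:
    tp = len(recovered & truth_set)
    sens = tp / len(truth_set) if truth_set else float("nan")
    prec = tp / len(recovered) if recovered else float("nan")
    return {
        "n_true": len(truth_set),
        "n_recovered": len(recovered),
        "tp": tp,
        "sensitivity": sens,
        "precision": prec,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and write report.json plus stage TSVs."""
    indir, outdir = Path(config.indir), Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    genes = load_gene_models(indir / "genes.gff3", indir / "promoters.bed")
    report: dict = {"config": asdict(config)}

    # --- peaks, merging, assignment
    factor_peaks = _call_factor_peaks(indir, manifest, config)
    merged = merge_intervals(PeakSet([iv for ps in factor_peaks.values() for iv in ps]))
    rescaled = rescale_to_midpoint(merged, config.rescale_halfwidth)
    rescaled = PeakSet(
        [iv.__class__(iv.chrom, iv.start, iv.end, iv.strand, f"mrg_pk{i}", iv.score)
         for i, iv in enumerate(rescaled)]
    )
    peak_factors = {
        iv.name: [f for f in manifest["factors"]
                  if bool(overlap_any(PeakSet([iv]), factor_peaks[f])[0])]
        for iv in rescaled
    }
    assignments_all = targetmod.assign_peaks_to_genes(rescaled, genes)
    assignments = {
        f: [a for a in assignments_all if f in peak_factors[a.peak_id]]
        for f in manifest["factors"]
    }
    write_intervals(rescaled, outdir / "peaks_rescaled.bed")
    pd.DataFrame([asdict(a) for a in assignments_all]).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    report["peaks"] = {
        "per_factor": {f: len(ps) for f, ps in factor_peaks.items()},
        "merged_rescaled": len(rescaled),
        "overlap_fraction": {
            f"{q}_vs_LIN-35": overlap_fraction(factor_peaks[q], factor_peaks["LIN-35"])
            for q in ("LIN-36", "LIN-15B")
        },
    }

    # --- differential expression and the target taxonomy
    rna = _read_counts(indir / "counts_rna")
    de_results, up = _de_results(rna, config)
    for cond, res in de_results.items():
        res.to_csv(outdir / f"de_{cond}.tsv", sep="\t")
    up_by_factor = {f: up.get(FACTOR_MUTANT[f], set()) for f in FACTORS}
    classifications = targetmod.classify_targets(up_by_factor, assignments)
    direct = targetmod.direct_targets(up_by_factor, assignments)
    lin36_shared = {c.gene_id for c in classifications if c.shared_class == "LIN36_shared"}
    lin15b_shared = {c.gene_id for c in classifications if c.shared_class == "LIN15B_shared"}
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classifications],
            "direct_for": [",".join(sorted(c.direct_for)) for c in classifications],
            "shared_class": [c.shared_class for c in classifications],
        }
    ).to_csv(outdir / "target_classes.tsv", sep="\t", index=False)
    universe = set(rna.counts.index[rna.counts.sum(axis=1) > 0])
    enr = {}
    for name, dset in (("LIN-36", direct["LIN-36"]), ("LIN-15B", direct["LIN-15B"])):
        fold, p = targetmod.overlap_enrichment(dset, direct["LIN-35"], universe)
        enr[f"{name}_vs_LIN-35"] = {"fold": fold, "pvalue": p}
    report["targets"] = {
        "up_per_mutant": {c: len(g) for c, g in up.items()},
        "direct_per_factor": {f: len(g) for f, g in direct.items()},
        "n_lin36_shared": len(lin36_shared),
        "n_lin15b_shared": len(lin15b_shared),
        "overlap_enrichment": enr,
    }

    # --- histone marks
    if config.run_marks:
        gbhtz = _read_counts(indir / "counts_gbhtz")
        # exclude genes shorter than the minimum and keep the top quantile
        long_enough = {
            gm.gene_id for gm in genes if gm.span.length >= config.min_gene_length
        }
        gbhtz = CountMatrix(
            gbhtz.counts.loc[gbhtz.counts.index.intersection(sorted(long_enough))],
            gbhtz.conditions,
        )
        htz_loss, htz_universe = _mark_loss(gbhtz, config.padj_htz, config, filter_top=True)
        k9 = _read_counts(indir / "counts_k9")
        k9_loss, k9_universe = _mark_loss(k9, config.padj_k9, config)
        mark_block: dict = {"gbhtz_loss_counts": {c: len(s) for c, s in htz_loss.items()},
                            "k9_loss_counts": {c: len(s) for c, s in k9_loss.items()}}
        for cls_name, cls_set in (("LIN36_shared", lin36_shared), ("LIN15B_shared", lin15b_shared)):
            for cond in sorted(htz_loss):
                inter = cls_set & htz_universe
                if inter:
                    fold, p = targetmod.overlap_enrichment(
                        inter, htz_loss[cond] & htz_universe, htz_universe
                    )
                    mark_block[f"gbhtz_enrichment_{cls_name}_{cond}"] = {
                        "fraction_lost": len(cls_set & htz_loss[cond]) / len(inter),
                        "fold": fold,
                        "pvalue": p,
                    }
        report["marks"] = mark_block
        loss_frames = []
        for cond, s in sorted(htz_loss.items()):
            loss_frames += [("gbHTZ-1", cond, g) for g in sorted(s)]
        for cond, s in sorted(k9_loss.items()):
            loss_frames += [("H3K9me2", cond, g) for g in sorted(s)]
        pd.DataFrame(loss_frames, columns=["mark", "mutant", "feature_id"]).to_csv(
            outdir / "mark_loss.tsv", sep="\t", index=False
        )
    else:
        htz_loss, k9_loss = {}, {}

    # --- differential binding
    if config.run_binding:
        binding = _binding_stage(indir, manifest, factor_peaks, config)
        bind_block = {}
        for (factor, mutant), res in binding.items():
            res.to_csv(outdir / f"binding_{factor}_{mutant}.tsv", sep="\t")
            counts = res["label"].value_counts().to_dict()
            bind_block[f"{factor}_in_{mutant}"] = {
                "increased": int(counts.get("increased", 0)),
                "decreased": int(counts.get("decreased", 0)),
                "unchanged": int(counts.get("unchanged", 0)),
            }
        report["binding"] = bind_block
    else:
        binding = {}

    # --- germline specificity
    if config.run_specificity:
        tpm = pd.read_csv(indir / "celltype_tpm.tsv", sep="\t", index_col=0)
        spec = targetmod.germline_specificity(tpm, "germline")
        spec.to_csv(outdir / "germline_specificity.tsv", sep="\t")
        groups = {
            "LIN36_shared": lin36_shared,
            "LIN15B_shared": lin15b_shared,
            "LIN35_only": direct["LIN-35"] - lin36_shared - lin15b_shared,
        }
        med = {
            k: float(spec.loc[spec.index.intersection(sorted(v)), "score"].median())
            for k, v in groups.items() if v
        }
        spec_block = {"median_score": med}
        a = spec.loc[spec.index.intersection(sorted(lin15b_shared)), "score"].dropna()
        b = spec.loc[spec.index.intersection(sorted(lin36_shared)), "score"].dropna()
        if len(a) and len(b):
            spec_block["wilcoxon_p_15B_vs_36"] = targetmod.compare_specificity(a, b)
        report["specificity"] = spec_block

    # --- motifs
    if config.run_motifs:
        class_peaks = {}
        for cls_name, cls_set in (("LIN36_shared", lin36_shared), ("LIN15B_shared", lin15b_shared)):
            ivs = []
            gene_of = {a.peak_id: a.gene_id for a in assignments_all
                       if a.gene_id in cls_set}
            for iv in rescaled:
                if iv.name in gene_of:
                    ivs.append(iv)
            class_peaks[cls_name] = PeakSet(ivs)
        if all(len(ps) for ps in class_peaks.values()):
            resolved, kept, assoc = _motif_stage(indir, manifest, class_peaks, config)
            pd.DataFrame([asdict(h) for h in resolved]).to_csv(
                outdir / "motif_hits.tsv", sep="\t", index=False
            )
            assoc.to_csv(outdir / "motif_association.tsv", sep="\t")
            report["motifs"] = {
                "n_hits_resolved": len(resolved),
                "kept_motifs": sorted(kept),
                "association": {
                    m: {"odds_ratio": row["odds_ratio"], "padj": row["padj"]}
                    for m, row in assoc.iterrows()
                },
            }

    # --- ground-truth validation
    gt_path = indir / "ground_truth.json"
    if gt_path.exists():
        truth = GroundTruth.from_json(gt_path)
        validation = {
            "LIN36_shared": _recovery_metrics(lin36_shared, truth.genes_of("LIN36_shared")),
            "LIN15B_shared": _recovery_metrics(lin15b_shared, truth.genes_of("LIN15B_shared")),
            "classes_disjoint": not (lin36_shared & lin15b_shared),
        }
        if config.run_marks:
            for mark, loss, truth_loss in (
                ("gbhtz", htz_loss, truth.gbhtz_loss),
                ("k9", k9_loss, truth.k9_loss),
            ):
                for cond in sorted(loss):
                    t = set(truth_loss.get(cond, []))
                    if t:
                        validation[f"{mark}_loss_{cond}"] = _recovery_metrics(loss[cond], t)
        report["validation"] = validation

    report_json = json.dumps(report, indent=1, sort_keys=True, default=float)
    (outdir / "report.json").write_text(report_json)
    return report
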