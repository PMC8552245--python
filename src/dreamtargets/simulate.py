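"""Synthetic scenario generator with planted, machine-readable ground truth.

Emulates the full input set of the integrative analysis on a toy genome:

* non-overlapping genes with 1-3 transcripts and (usually) an annotated
  promoter, on a single chromosome;
* three-factor ChIP coverage (LIN-35, LIN-36, LIN-15B) with class-driven
  co-binding at promoters, Poisson replicate noise, and planted
  binding-change multipliers in mutants;
* negative-binomial RNA count matrices with planted derepression: the
  LIN36_shared class goes up in *lin-35* and *lin-36* mutants only, the
  LIN15B_shared class in *lin-35*, *lin-15B* and *met-2*, LIN35_only in
  *lin-35* only;
* gene-body H2A.Z and promoter H3K9me2 count tables with planted wild-type
  enrichment and mutant-specific loss;
* a germline-vs-soma cell-type TPM table concentrating germline signal on
  the LIN15B_shared class;
* promoter-peak sequences with planted PWM consensus instances at
  class-specific rates.

Every generator draws from its own RNG stream seeded from
(scenario seed, CRC32 of the stage name), so stages are independently
reproducible and reordering them never changes outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import CountMatrix
from .genome import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    PeakSet,
    write_coverage,
    write_fasta,
    write_gene_models,
    write_intervals,
)
from .motifs import PWM, write_meme

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_annotation",
    "generate_chip",
    "generate_counts",
    "plant_motifs",
    "builtin_pwms",
    "simulate_scenario",
    "write_scenario",
]

FACTORS = ("LIN-35", "LIN-36", "LIN-15B")
CLASSES = ("LIN36_shared", "LIN15B_shared", "LIN35_only", "null")
SOMA_TYPES = ("neurons", "muscle", "hypodermis", "intestine", "pharynx")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode()) & 0x7FFFFFFF])


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 1000
    chrom: str = "chrI"
    chrom_length: int = 3_000_000
    n_lin36_shared: int = 150
    n_lin15b_shared: int = 50
    n_lin35_only: int = 100
    # expression
    n_replicates: int = 4
    effect_lfc: float = 2.0
    nb_dispersion: float = 0.1
    base_expression_mean: float = 150.0
    base_expression_sigma: float = 0.7
    include_met2: bool = True
    # ChIP coverage
    n_chip_replicates: int = 2
    background_rate: float = 0.25
    peak_sigma: float = 75.0
    amp_lin36_class: float = 25.0
    amp_lin15b_class: float = 12.0
    amp_lin35_only: float = 20.0
    amp_decoy: float = 15.0
    decoy_peak_rate: float = 0.10
    cobinding_rate: dict = field(
        default_factory=lambda: {"LIN-36": 0.95, "LIN-15B": 0.72}
    )
    binding_changes: tuple = (
        ("LIN-35", "lin-36", "LIN36_shared", 0.5, 0.6),
        ("LIN-15B", "lin-35", "LIN15B_shared", 2.0, 0.6),
    )
    promoter_prob: float = 0.9
    # histone-mark count tables (deep-coverage pseudo-counts)
    mark_count_mean: float = 800.0
    mark_dispersion: float = 0.02
    gbhtz_enrichment_fold: float = 3.0
    gbhtz_loss_fold: float = 0.5
    gbhtz_loss_rate: float = 0.7
    gbhtz_loss_rate_15b: float = 0.2
    k9_enrichment_fold: float = 4.0
    k9_loss_fold: float = 0.5
    k9_loss_rate: float = 0.6
    k9_loss_rate_lin35: float = 0.4
    # germline specificity
    germline_fraction: float = 0.8
    tpm_mean: float = 50.0
    # motifs
    motif_plant_rates: dict = field(
        default_factory=lambda: {
            "LIN36_shared": {"CDE-CHR-a": 0.6, "E2F-a1": 0.5, "E2F-a2": 0.3},
            "LIN15B_shared": {"CDE-CHR-b": 0.4, "LONG-a": 0.7, "E2F-b": 0.6},
        }
    )

    def __post_init__(self) -> None:
        planted = self.n_lin36_shared + self.n_lin15b_shared + self.n_lin35_only
        if planted > self.n_genes:
            raise ValueError("planted classes exceed n_genes")
        for rate in (self.decoy_peak_rate, self.promoter_prob, self.germline_fraction):
            if not (0 <= rate <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.gbhtz_enrichment_fold, self.k9_enrichment_fold,
               self.gbhtz_loss_fold, self.k9_loss_fold) <= 0:
            raise ValueError("fold parameters must be positive")


@dataclass
class GroundTruth:
    """Planted structure, serialized alongside the generated files."""

    classes: dict  # gene_id -> class
    planted_up: dict  # condition -> sorted list of gene ids
    gbhtz_loss: dict  # mutant -> sorted list of gene ids
    k9_loss: dict  # mutant -> sorted list of gene ids
    binding_changes: list  # dicts: peak_id, factor, mutant, fold
    planted_motifs: list  # dicts: peak_id, motif_id, offset (genomic), strand
    true_peaks: dict  # factor -> list of [chrom, start, end, name]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def genes_of(self, cls_name: str) -> set:
        return {g for g, c in self.classes.items() if c == cls_name}


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: ScenarioConfig):
    """Toy genome: gene models, promoter set, random sequence, class labels.

    Genes are laid out on a fixed pitch (chrom_length / n_genes, >= 3 kb so
    promoters and peak windows never collide across neighbours).
    """
    pitch = config.chrom_length // config.n_genes
    if pitch < 3000:
        raise ValueError(
            f"insufficient space: need >= 3 kb per gene, have {pitch} bp "
            f"({config.chrom_length} bp / {config.n_genes} genes)"
        )
    rng = _stage_rng(config.seed, "annotation")
    margin = 700
    usable = pitch - 2 * margin
    genes: list[GeneModel] = []
    promoters: list[GenomicInterval] = []
    for i in range(config.n_genes):
        gid = f"gene{i:04d}"
        length = int(rng.integers(700, min(1601, usable + 1)))
        start = i * pitch + margin + int(rng.integers(0, usable - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval(config.chrom, start, end, strand)
        n_tx = int(rng.integers(1, 4))
        tss_list, tts_list = [], []
        for t in range(n_tx):
            j5 = 0 if t == 0 else int(rng.integers(0, 100))
            j3 = 0 if t == 0 else int(rng.integers(0, 100))
            if strand == "+":
                tss_list.append(start + j5)
                tts_list.append(end - 1 - j3)
            else:
                tss_list.append(end - 1 - j5)
                tts_list.append(start + j3)
        gm = GeneModel(gid, span, strand, tss_list, tts_list)
        if rng.random() < config.promoter_prob:
            tss = gm.tss_5prime
            if strand == "+":
                prom = GenomicInterval(config.chrom, max(0, tss - 500), tss, strand, name=gid)
            else:
                prom = GenomicInterval(config.chrom, tss + 1, tss + 501, strand, name=gid)
            gm.promoters = [prom]
            promoters.append(prom)
        genes.append(gm)
    # class labels partition the gene list
    order = rng.permutation(config.n_genes)
    classes: dict[str, str] = {}
    cursor = 0
    for cls, n in (
        ("LIN36_shared", config.n_lin36_shared),
        ("LIN15B_shared", config.n_lin15b_shared),
        ("LIN35_only", config.n_lin35_only),
    ):
        for j in order[cursor : cursor + n]:
            classes[genes[j].gene_id] = cls
        cursor += n
    for gm in genes:
        classes.setdefault(gm.gene_id, "null")
    sequence = rng.integers(0, 4, size=config.chrom_length).astype(np.uint8)
    sequence = _BASES[sequence].tobytes().decode()
    return genes, PeakSet(promoters), sequence, classes


def _peak_center(gm: GeneModel) -> int:
    """Binding summit: promoter midpoint, or just inside the gene 5' end."""
    if gm.promoters:
        p = gm.promoters[0]
        return (p.start + p.end) // 2
    return gm.tss_5prime + (150 if gm.strand == "+" else -150)


# ---------------------------------------------------------------------------
# ChIP coverage


def generate_chip(config: ScenarioConfig, genes: list[GeneModel], classes: dict):
    """Factor coverage tracks, true peak sets, and planted binding changes.

    Returns (tracks, true_peaks, binding_changes) where tracks maps
    (factor, condition, replicate) -> CoverageTrack, true_peaks maps
    factor -> PeakSet, and binding_changes lists planted multipliers.
    """
    rng = _stage_rng(config.seed, "chip")
    amp_by_class = {
        "LIN36_shared": config.amp_lin36_class,
        "LIN15B_shared": config.amp_lin15b_class,
        "LIN35_only": config.amp_lin35_only,
    }
    factor_by_class = {
        "LIN36_shared": ("LIN-35", "LIN-36"),
        "LIN15B_shared": ("LIN-35", "LIN-15B"),
        "LIN35_only": ("LIN-35",),
    }
    # planted peaks: (factor, gene_id, center, amplitude)
    peaks: list[tuple[str, str, int, float]] = []
    for gm in genes:
        cls = classes[gm.gene_id]
        center = _peak_center(gm)
        if cls in factor_by_class:
            for f in factor_by_class[cls]:
                peaks.append((f, gm.gene_id, center, amp_by_class[cls]))
        elif rng.random() < config.decoy_peak_rate:
            f = "LIN-36" if rng.random() < 0.5 else "LIN-15B"
            peaks.append((f, gm.gene_id, center, config.amp_decoy))
            if rng.random() < config.cobinding_rate.get(f, 1.0):
                peaks.append(("LIN-35", gm.gene_id, center, config.amp_decoy))
    true_peaks = {
        f: PeakSet(
            [
                GenomicInterval(
                    config.chrom, max(0, c - 100), c + 100, name=f"{f}:{g}", score=a
                )
                for (pf, g, c, a) in peaks
                if pf == f
            ]
        )
        for f in FACTORS
    }
    # planted binding changes in mutants
    changes: list[dict] = []
    multiplier: dict[tuple[str, str, str], float] = {}  # (factor, mutant, gene) -> fold
    for factor, mutant, cls, fold, rate in config.binding_changes:
        for pf, g, c, a in peaks:
            if pf == factor and classes[g] == cls and rng.random() < rate:
                multiplier[(factor, mutant, g)] = fold
                changes.append(
                    {"peak_id": f"{factor}:{g}", "factor": factor, "mutant": mutant, "fold": fold}
                )
    conditions = {"N2": list(FACTORS)}
    for factor, mutant, *_ in config.binding_changes:
        conditions.setdefault(mutant, [])
        if factor not in conditions[mutant]:
            conditions[mutant].append(factor)
    sigma = config.peak_sigma
    half = int(4 * sigma)
    offsets = np.arange(-half, half + 1)
    bump = np.exp(-0.5 * (offsets / sigma) ** 2)
    tracks: dict[tuple[str, str, int], CoverageTrack] = {}
    for cond, factors in conditions.items():
        for factor in factors:
            signal = np.full(config.chrom_length, config.background_rate)
            for pf, g, c, a in peaks:
                if pf != factor:
                    continue
                fold = multiplier.get((factor, cond, g), 1.0) if cond != "N2" else 1.0
                lo, hi = max(0, c - half), min(config.chrom_length, c + half + 1)
                signal[lo:hi] += a * fold * bump[lo - (c - half) : hi - (c - half)]
            for rep in range(1, config.n_chip_replicates + 1):
                tracks[(factor, cond, rep)] = CoverageTrack(
                    config.chrom, rng.poisson(signal).astype(float)
                )
    return tracks, true_peaks, changes


# ---------------------------------------------------------------------------
# count matrices + TPM


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2) via numpy's (n, p) parameterization."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_counts(config: ScenarioConfig, genes: list[GeneModel], classes: dict):
    """RNA, gene-body H2A.Z and promoter H3K9me2 count tables plus TPM table.

    Returns (rna, gbhtz, k9, tpm, truth_parts) with CountMatrix instances
    and a dict of planted flags.
    """
    rng = _stage_rng(config.seed, "counts")
    gene_ids = [gm.gene_id for gm in genes]
    n = len(gene_ids)
    cls_arr = np.array([classes[g] for g in gene_ids])

    # --- RNA-seq
    conditions = ["N2", "lin-35", "lin-36", "lin-15B"] + (["met-2"] if config.include_met2 else [])
    up_in = {
        "LIN36_shared": {"lin-35", "lin-36"},
        "LIN15B_shared": {"lin-35", "lin-15B"} | ({"met-2"} if config.include_met2 else set()),
        "LIN35_only": {"lin-35"},
        "null": set(),
    }
    base = rng.lognormal(np.log(config.base_expression_mean), config.base_expression_sigma, n)
    base = np.clip(base, 20.0, 5000.0)
    effect = 2.0**config.effect_lfc
    rna_cols, rna_names, rna_cond = [], [], []
    planted_up = {c: [] for c in conditions if c != "N2"}
    for cond in conditions:
        fold = np.ones(n)
        if cond != "N2":
            planted = np.array([cond in up_in[c] for c in cls_arr])
            fold[planted] = effect
            planted_up[cond] = sorted(np.array(gene_ids)[planted].tolist())
        for rep in range(1, config.n_replicates + 1):
            rna_cols.append(_nb_draw(rng, base * fold, config.nb_dispersion))
            rna_names.append(f"{cond}_r{rep}")
            rna_cond.append(cond)
    rna = CountMatrix(
        pd.DataFrame(np.column_stack(rna_cols), index=pd.Index(gene_ids, name="feature_id"),
                     columns=rna_names),
        pd.Series(rna_cond, index=rna_names),
    )

    # --- gene-body H2A.Z pseudo-counts
    mark_conditions = ["N2", "lin-35", "lin-36", "lin-15B"]
    gb_base = config.mark_count_mean * rng.lognormal(0.0, 0.5, n)
    gb_base[cls_arr == "LIN36_shared"] *= config.gbhtz_enrichment_fold
    lose36 = (cls_arr == "LIN36_shared") & (rng.random(n) < config.gbhtz_loss_rate)
    lose15 = (cls_arr == "LIN15B_shared") & (rng.random(n) < config.gbhtz_loss_rate_15b)
    gbhtz_loss = {
        "lin-35": sorted(np.array(gene_ids)[lose36 | lose15].tolist()),
        "lin-36": sorted(np.array(gene_ids)[lose36].tolist()),
        "lin-15B": sorted(np.array(gene_ids)[lose15].tolist()),
    }
    gb_cols, gb_names, gb_cond = [], [], []
    for cond in mark_conditions:
        fold = np.ones(n)
        if cond in ("lin-35", "lin-36"):
            fold[lose36] = config.gbhtz_loss_fold
        if cond in ("lin-35", "lin-15B"):
            fold[lose15] = config.gbhtz_loss_fold
        for rep in range(1, config.n_replicates + 1):
            gb_cols.append(_nb_draw(rng, gb_base * fold, config.mark_dispersion))
            gb_names.append(f"{cond}_r{rep}")
            gb_cond.append(cond)
    gbhtz = CountMatrix(
        pd.DataFrame(np.column_stack(gb_cols), index=pd.Index(gene_ids, name="feature_id"),
                     columns=gb_names),
        pd.Series(gb_cond, index=gb_names),
    )

    # --- promoter H3K9me2 pseudo-counts (one promoter-peak feature per
    # promoter-bearing gene; feature id = gene id)
    has_prom = np.array([bool(gm.promoters) for gm in genes])
    k9_ids = list(np.array(gene_ids)[has_prom])
    k9_cls = cls_arr[has_prom]
    m = len(k9_ids)
    k9_base = config.mark_count_mean * rng.lognormal(0.0, 0.5, m)
    k9_base[k9_cls == "LIN15B_shared"] *= config.k9_enrichment_fold
    k9_lose = (k9_cls == "LIN15B_shared") & (rng.random(m) < config.k9_loss_rate)
    k9_lose35 = k9_lose & (rng.random(m) < config.k9_loss_rate_lin35 / max(config.k9_loss_rate, 1e-9))
    k9_loss = {
        "lin-15B": sorted(np.array(k9_ids)[k9_lose].tolist()),
        "lin-35": sorted(np.array(k9_ids)[k9_lose35].tolist()),
        "lin-36": [],
    }
    k9_cols, k9_names, k9_cond = [], [], []
    for cond in mark_conditions:
        fold = np.ones(m)
        if cond == "lin-15B":
            fold[k9_lose] = config.k9_loss_fold
        if cond == "lin-35":
            fold[k9_lose35] = config.k9_loss_fold
        for rep in range(1, config.n_replicates + 1):
            k9_cols.append(_nb_draw(rng, k9_base * fold, config.mark_dispersion))
            k9_names.append(f"{cond}_r{rep}")
            k9_cond.append(cond)
    k9 = CountMatrix(
        pd.DataFrame(np.column_stack(k9_cols), index=pd.Index(k9_ids, name="feature_id"),
                     columns=k9_names),
        pd.Series(k9_cond, index=k9_names),
    )

    # --- cell-type TPM table
    total = rng.lognormal(np.log(config.tpm_mean), 1.0, n)
    germ_share = rng.beta(1.0, 9.0, n)
    is15b = cls_arr == "LIN15B_shared"
    germ_share[is15b] = config.germline_fraction
    soma_split = rng.dirichlet(np.ones(len(SOMA_TYPES)), n)
    tpm = pd.DataFrame(
        np.column_stack(
            [total * germ_share]
            + [total * (1 - germ_share) * soma_split[:, j] for j in range(len(SOMA_TYPES))]
        ),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=["germline", *SOMA_TYPES],
    )

    truth_parts = {"planted_up": planted_up, "gbhtz_loss": gbhtz_loss, "k9_loss": k9_loss}
    return rna, gbhtz, k9, tpm, truth_parts


# ---------------------------------------------------------------------------
# motifs


def _pwm_from_consensus(name: str, consensus: str, family: str, strong: float = 0.94) -> PWM:
    """Near-consensus PWM; 'N' positions are uniform."""
    rows = []
    for b in consensus:
        if b == "N":
            rows.append([0.25] * 4)
        else:
            row = [(1 - strong) / 3] * 4
            row["ACGT".index(b)] = strong
            rows.append(row)
    return PWM(name, np.array(rows), family=family)


def builtin_pwms() -> list[PWM]:
    """Synthetic stand-in PWMs for the seven motif variants (consensus-based).

    These are constructed motifs, not the published matrices: an E2F-like
    GCGC core family, a bipartite CDE-CHR-like family (E2F-like half plus a
    TTTGAA CHR half), and a long 18-bp family.
    """
    return [
        _pwm_from_consensus("CDE-CHR-a", "TTGGCGGGANTTTGAA", "CDE-CHR"),
        _pwm_from_consensus("CDE-CHR-b", "ATGGCGGCANTTTGAA", "CDE-CHR"),
        _pwm_from_consensus("LONG-a", "TAGCATCGGCATTCGATC", "LONG"),
        _pwm_from_consensus("LONG-b", "TAGCATCGGCATTCGTAG", "LONG"),
        _pwm_from_consensus("E2F-a1", "TTTCGCGC", "E2F"),
        _pwm_from_consensus("E2F-a2", "TTTGGCGC", "E2F"),
        _pwm_from_consensus("E2F-b", "TTCCCGCC", "E2F"),
    ]


_RC = str.maketrans("ACGT", "TGCA")


def plant_motifs(
    config: ScenarioConfig,
    peak_seqs: dict[str, str],
    peak_classes: dict[str, str],
    pwms: list[PWM] | None = None,
    rng: np.random.Generator | None = None,
    edge_margin: int = 30,
):
    """Insert PWM consensus instances into peak sequences at class rates.

    Returns (new_seqs, planted) where planted lists dicts with peak_id,
    motif_id, offset (within the peak sequence) and strand.  Insertions
    within one peak never overlap; peaks shorter than a motif are skipped
    with the motif unplanted.
    """
    rng = rng if rng is not None else _stage_rng(config.seed, "motifs")
    pwms = pwms if pwms is not None else builtin_pwms()
    by_id = {p.motif_id: p for p in pwms}
    out = dict(peak_seqs)
    planted: list[dict] = []
    for peak_id in sorted(peak_seqs):
        cls = peak_classes.get(peak_id, "null")
        rates = config.motif_plant_rates.get(cls, {})
        used: list[tuple[int, int]] = []
        seq = out[peak_id]
        for motif_id in sorted(rates):
            if rng.random() >= rates[motif_id]:
                continue
            cons = by_id[motif_id].consensus
            lo, hi = edge_margin, len(seq) - edge_margin - len(cons)
            if hi < lo:
                continue
            for _ in range(20):  # rejection-sample a collision-free offset
                off = int(rng.integers(lo, hi + 1))
                if all(off >= e or off + len(cons) <= s for s, e in used):
                    break
            else:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            ins = cons if strand == "+" else cons.translate(_RC)[::-1]
            seq = seq[:off] + ins + seq[off + len(cons):]
            used.append((off, off + len(cons)))
            planted.append(
                {"peak_id": peak_id, "motif_id": motif_id, "offset": off, "strand": strand}
            )
        out[peak_id] = seq
    return out, planted


# ---------------------------------------------------------------------------
# scenario assembly


@dataclass
class Scenario:
    config: ScenarioConfig
    genes: list[GeneModel]
    promoters: PeakSet
    sequence: str
    tracks: dict  # (factor, condition, replicate) -> CoverageTrack
    true_peaks: dict  # factor -> PeakSet
    rna: CountMatrix
    gbhtz: CountMatrix
    k9: CountMatrix
    tpm: pd.DataFrame
    pwms: list[PWM]
    truth: GroundTruth


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a complete scenario: annotation, ChIP, counts, motifs, truth."""
    genes, promoters, sequence, classes = generate_annotation(config)
    tracks, true_peaks, binding_changes = generate_chip(config, genes, classes)
    rna, gbhtz, k9, tpm, truth_parts = generate_counts(config, genes, classes)
    pwms = builtin_pwms()
    # plant motif instances into the genome at the shared-class promoter peaks
    windows: dict[str, tuple[int, int]] = {}
    peak_classes: dict[str, str] = {}
    for iv in true_peaks["LIN-35"]:
        gid = iv.name.split(":", 1)[1]
        cls = classes[gid]
        if cls in ("LIN36_shared", "LIN15B_shared"):
            windows[iv.name] = (iv.start, iv.end)
            peak_classes[iv.name] = cls
    peak_seqs = {pid: sequence[s:e] for pid, (s, e) in windows.items()}
    new_seqs, planted = plant_motifs(config, peak_seqs, peak_classes, pwms)
    seq_arr = bytearray(sequence.encode())
    for pid, (s, e) in windows.items():
        seq_arr[s:e] = new_seqs[pid].encode()
    for rec in planted:
        rec["genomic_offset"] = windows[rec["peak_id"]][0] + rec["offset"]
    truth = GroundTruth(
        classes=classes,
        planted_up=truth_parts["planted_up"],
        gbhtz_loss=truth_parts["gbhtz_loss"],
        k9_loss=truth_parts["k9_loss"],
        binding_changes=binding_changes,
        planted_motifs=planted,
        true_peaks={
            f: [[iv.chrom, iv.start, iv.end, iv.name] for iv in ps]
            for f, ps in true_peaks.items()
        },
    )
    return Scenario(
        config, genes, promoters, seq_arr.decode(), tracks, true_peaks,
        rna, gbhtz, k9, tpm, pwms, truth,
    )


def _write_count_matrix(cm: CountMatrix, prefix: Path) -> None:
    cm.counts.to_csv(f"{prefix}.tsv", sep="\t")
    meta = pd.DataFrame(
        {"sample": cm.counts.columns,
         "condition": [cm.conditions[s] for s in cm.counts.columns]}
    )
    meta["replicate"] = meta.groupby("condition").cumcount() + 1
    meta.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def write_scenario(scenario: Scenario, outdir) -> None:
    """Serialize a scenario to plain-text files plus ground_truth.json."""
    out = Path(outdir)
    (out / "chip").mkdir(parents=True, exist_ok=True)
    cfg = scenario.config
    write_gene_models(scenario.genes, out / "genes.gff3")
    write_intervals(scenario.promoters, out / "promoters.bed")
    write_fasta({cfg.chrom: scenario.sequence}, out / "genome.fa")
    chip_files = {}
    for (factor, cond, rep), track in scenario.tracks.items():
        name = f"chip/{factor}_{cond}_rep{rep}.bedgraph"
        write_coverage(track, out / name)
        chip_files.setdefault(factor, {}).setdefault(cond, []).append(name)
    for factor, ps in scenario.true_peaks.items():
        write_intervals(ps, out / f"true_peaks_{factor}.bed")
    _write_count_matrix(scenario.rna, out / "counts_rna")
    _write_count_matrix(scenario.gbhtz, out / "counts_gbhtz")
    _write_count_matrix(scenario.k9, out / "counts_k9")
    scenario.tpm.to_csv(out / "celltype_tpm.tsv", sep="\t")
    write_meme(scenario.pwms, out / "motifs.meme")
    scenario.truth.to_json(out / "ground_truth.json")
    manifest = {
        "chrom": cfg.chrom,
        "chrom_length": cfg.chrom_length,
        "factors": list(FACTORS),
        "chip_files": chip_files,
        "binding_contrasts": [
            {"factor": f, "mutant": m} for f, m, *_ in cfg.binding_changes
        ],
        "seed": cfg.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
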