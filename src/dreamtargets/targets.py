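"""Peak-to-gene assignment and the target taxonomy.

A gene is a *direct target* of a factor when it is upregulated in that
factor's mutant and carries an assigned ChIP peak for the factor.  The two
shared classes are then:

* LIN-36-shared: direct targets of both LIN-35 and LIN-36, not upregulated
  in the *lin-15B* mutant;
* LIN-15B-shared: direct targets of both LIN-35 and LIN-15B, not
  upregulated in the *lin-36* mutant.

Peaks are assigned to a gene when they overlap the window running from the
gene's furthest-upstream annotated promoter (strand-aware) through the
gene's 3' end; genes without promoter annotation fall back to the gene
span.  Overlap enrichment between gene sets uses the upper-tail
hypergeometric test; germline expression specificity is germline TPM over
summed TPM across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, PeakSet
from .stats import hypergeom_upper_tail, wilcoxon_rank_sum

__all__ = [
    "Assignment",
    "TargetClassification",
    "assign_peaks_to_genes",
    "bound_genes",
    "direct_targets",
    "shared_targets",
    "classify_targets",
    "overlap_enrichment",
    "germline_specificity",
    "compare_specificity",
]

FACTORS = ("LIN-35", "LIN-36", "LIN-15B")


@dataclass(frozen=True)
class Assignment:
    peak_id: str
    gene_id: str
    rule_fired: str  # {promoter_window, gene_span_fallback}


@dataclass
class TargetClassification:
    gene_id: str
    direct_for: frozenset
    shared_class: str  # {LIN36_shared, LIN15B_shared, none}
    provenance: tuple[str, ...] = ()


def _assignment_window(gm: GeneModel) -> tuple[GenomicInterval, str]:
    """Window from the 5'-most promoter start through the gene 3' end.

    Only promoters on the 5' side extend the window; a promoter-less gene
    falls back to its span.
    """
    span = gm.span
    if not gm.promoters:
        return span, "gene_span_fallback"
    if gm.strand == "+":
        start = min(min(p.start for p in gm.promoters), span.start)
        return GenomicInterval(span.chrom, start, span.end, gm.strand), "promoter_window"
    end = max(max(p.end for p in gm.promoters), span.end)
    return GenomicInterval(span.chrom, span.start, end, gm.strand), "promoter_window"


def assign_peaks_to_genes(peaks: PeakSet, genes: list[GeneModel]) -> list[Assignment]:
    """All (peak, gene) assignments with >= 1 bp overlap of the gene window.

    A peak may map to multiple genes; each assignment records the rule that
    fired.
    """
    windows = [(gm, *_assignment_window(gm)) for gm in genes]
    out = []
    for i, pk in enumerate(peaks):
        pid = pk.name if pk.name else f"peak_{i}"
        for gm, win, rule in windows:
            if pk.overlaps(win):
                out.append(Assignment(pid, gm.gene_id, rule))
    return out


def bound_genes(assignments: list[Assignment]) -> set[str]:
    return {a.gene_id for a in assignments}


def direct_targets(
    up_genes: dict[str, set], assignments: dict[str, list[Assignment]]
) -> dict[str, set]:
    """direct(F) = up(mutant of F) intersect genes bound by an F peak."""
    unknown = set(up_genes) ^ set(assignments)
    if unknown:
        raise KeyError(f"factors not present in both inputs: {sorted(unknown)}")
    return {f: set(up_genes[f]) & bound_genes(assignments[f]) for f in up_genes}


def shared_targets(
    direct35: set, direct36: set, direct15b: set, up36: set, up15b: set
) -> tuple[set, set]:
    """(LIN36_shared, LIN15B_shared) per the exclusion rule.

    LIN36_shared = (direct35 & direct36) - up15B;
    LIN15B_shared = (direct35 & direct15B) - up36.
    """
    lin36_shared = (set(direct35) & set(direct36)) - set(up15b)
    lin15b_shared = (set(direct35) & set(direct15b)) - set(up36)
    return lin36_shared, lin15b_shared


def classify_targets(
    up_genes: dict[str, set], assignments: dict[str, list[Assignment]]
) -> list[TargetClassification]:
    """Full per-gene classification with rule provenance."""
    direct = direct_targets(up_genes, assignments)
    lin36_shared, lin15b_shared = shared_targets(
        direct["LIN-35"], direct["LIN-36"], direct["LIN-15B"],
        up_genes["LIN-36"], up_genes["LIN-15B"],
    )
    genes = sorted(set().union(*direct.values()))
    out = []
    for g in genes:
        dfor = frozenset(f for f in FACTORS if g in direct[f])
        if g in lin36_shared:
            cls, prov = "LIN36_shared", ("direct LIN-35 & LIN-36", "not up in lin-15B")
        elif g in lin15b_shared:
            cls, prov = "LIN15B_shared", ("direct LIN-35 & LIN-15B", "not up in lin-36")
        else:
            cls, prov = "none", ()
        out.append(TargetClassification(g, dfor, cls, prov))
    return out


def overlap_enrichment(setA: set, setB: set, universe: set) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p of |A & B|.

    fold = |A & B| / (|A||B|/|U|).  With an empty A or B the fold is
    undefined (nan) and p = 1.
    """
    U = set(universe)
    A, B = set(setA) & U, set(setB) & U
    if not U:
        raise ValueError("universe must be non-empty")
    if (setA - U) or (setB - U):
        raise ValueError("setA and setB must be subsets of the universe")
    k = len(A & B)
    if len(A) == 0 or len(B) == 0:
        return float("nan"), 1.0
    expected = len(A) * len(B) / len(U)
    fold = k / expected
    p = hypergeom_upper_tail(len(U), len(A), len(B), k)
    return fold, p


def germline_specificity(expr: pd.DataFrame, germline_label: str = "germline") -> pd.DataFrame:
    """Per-gene germline specificity from a gene x cell-type TPM table.

    score = TPM(germline) / sum over cell types; genes with zero total TPM
    are flagged undefined (score NaN) so downstream tests can exclude them.
    """
    if germline_label not in expr.columns:
        raise KeyError(f"no column {germline_label!r} in expression table")
    arr = expr.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = expr.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = expr[germline_label] / total
    return pd.DataFrame(
        {"score": score.where(total > 0), "defined": total > 0},
        index=expr.index,
    )


def compare_specificity(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two specificity score samples."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty after dropping undefined")
    _, p = wilcoxon_rank_sum(a, b)
    return p
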