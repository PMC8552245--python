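"""Peak detection from coverage tracks.

Two callers are provided:

* :func:`call_concave_peaks` — candidate transcription-factor peaks as
  maximal runs where the smoothed coverage is concave (negative central
  second difference) and at least ``min_height`` high.  Concavity isolates
  individual binding summits even when neighbouring peaks sit on a shared
  shoulder, which simple thresholding cannot do.
* :func:`call_enriched_domains` — broad enriched regions (e.g. repressive
  histone-mark domains) via a sliding window tested against a local/global
  Poisson background.

Replicate agreement is enforced by :func:`reproducible_peaks`, a simple
overlap-support filter: a merged candidate is kept when peaks from at least
``min_support`` distinct replicates overlap it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .genome import CoverageTrack, GenomicInterval, PeakSet, merge_intervals, overlap_any

__all__ = [
    "SmoothingConfig",
    "DomainCallConfig",
    "smooth_coverage",
    "call_concave_peaks",
    "reproducible_peaks",
    "call_enriched_domains",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian smoothing: sigma in bp and kernel half-width in sigmas.

    The 75 bp default sigma is of the order of the sonication fragment size
    (~250 bp), so smoothing integrates signal over roughly one fragment.
    """

    bandwidth: float = 75.0
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.truncation < 2:
            raise ValueError("truncation must be >= 2 sigmas")


@dataclass(frozen=True)
class DomainCallConfig:
    """Broad-domain caller parameters (local Poisson background model).

    ``window`` is the local-background scale; it must be several times the
    largest domain expected, otherwise a broad domain dominates its own
    background and can never reach the fold threshold.
    """

    window: int = 20_000
    fold_threshold: float = 2.0
    min_length: int = 500
    pvalue_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.window, self.fold_threshold, self.min_length, self.pvalue_threshold) <= 0:
            raise ValueError("all domain-call parameters must be positive")


def smooth_coverage(track: CoverageTrack, config: SmoothingConfig) -> CoverageTrack:
    """Discrete Gaussian convolution with reflective boundary handling."""
    sigma_bins = config.bandwidth / track.resolution
    smoothed = ndimage.gaussian_filter1d(
        track.values, sigma=sigma_bins, mode="reflect", truncate=config.truncation
    )
    # tiny negative round-off is possible; coverage is non-negative by contract
    np.clip(smoothed, 0.0, None, out=smoothed)
    return CoverageTrack(track.chrom, smoothed, track.resolution)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def call_concave_peaks(
    track: CoverageTrack, config: SmoothingConfig, min_height: float
) -> PeakSet:
    """Concave regions of the smoothed track as candidate peaks.

    A base belongs to a candidate run when the central second difference of
    the smoothed signal is negative and the smoothed value is >= min_height.
    Runs shorter than 3 bins are discarded; each surviving run becomes one
    peak scored by its maximum smoothed height.
    """
    smoothed = smooth_coverage(track, config).values
    if smoothed.size < 3:
        return PeakSet()
    d2 = smoothed[2:] - 2.0 * smoothed[1:-1] + smoothed[:-2]
    mask = np.zeros(smoothed.size, dtype=bool)
    mask[1:-1] = (d2 < 0) & (smoothed[1:-1] >= min_height)
    r = track.resolution
    peaks = []
    for i, (s, e) in enumerate(_runs(mask), 1):
        if e - s < 3:
            continue
        peaks.append(
            GenomicInterval(
                track.chrom,
                int(s * r),
                int(e * r),
                name=f"{track.chrom}_peak{i}",
                score=float(smoothed[s:e].max()),
            )
        )
    return PeakSet(peaks)


def reproducible_peaks(replicate_sets: list[PeakSet], min_support: int) -> PeakSet:
    """Keep merged candidates supported by >= min_support replicates.

    Candidates are the merged union of all replicate peaks; support is the
    number of distinct replicates contributing >= 1 bp of overlap.
    """
    if len(replicate_sets) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    if not (1 <= min_support <= len(replicate_sets)):
        raise ValueError(
            f"min_support must be in [1, {len(replicate_sets)}], got {min_support}"
        )
    union = PeakSet([iv for ps in replicate_sets for iv in ps])
    candidates = merge_intervals(union)
    if len(candidates) == 0:
        return PeakSet()
    support = np.zeros(len(candidates), dtype=int)
    for ps in replicate_sets:
        support += overlap_any(candidates, ps).astype(int)
    return PeakSet([iv for iv, s in zip(candidates, support) if s >= min_support])


def call_enriched_domains(track: CoverageTrack, config: DomainCallConfig) -> PeakSet:
    """Broad enriched domains against a max(local, global) Poisson background.

    The signal in sliding windows of ``min_length`` is treated as a Poisson
    count with expectation max(global mean, local flank mean over
    ``window``) x window size; the scan window itself is excluded from the
    local background so that enrichment does not mask itself.  Window
    centres passing both the upper-tail p-value and the fold threshold are
    merged (each centre extends half a scan window to either side) and
    domains shorter than ``min_length`` are dropped.
    """
    v = track.values
    if v.size == 0 or not np.any(v > 0):
        return PeakSet()
    r = track.resolution
    scan = max(1, config.min_length // r)
    local_w = max(2 * scan, config.window // r)
    global_mean = float(v.mean())
    local_sum = ndimage.uniform_filter1d(v, size=local_w, mode="reflect") * local_w
    scan_sum = ndimage.uniform_filter1d(v, size=scan, mode="reflect") * scan
    flank_mean = (local_sum - scan_sum) / (local_w - scan)
    bg_mean = np.maximum(flank_mean, global_mean)
    win_mean = ndimage.uniform_filter1d(v, size=scan, mode="reflect")
    # per-window Poisson test on the (rounded) window sum
    lam = bg_mean * scan * r
    counts = np.rint(win_mean * scan * r)
    pvals = sps.poisson.sf(counts - 1, lam)
    fold = win_mean / np.maximum(bg_mean, 1e-12)
    hit = (pvals < config.pvalue_threshold) & (fold >= config.fold_threshold)
    if not hit.any():
        return PeakSet()
    # dilate centre hits to full scan windows, then take maximal runs
    dilated = ndimage.binary_dilation(hit, structure=np.ones(scan, dtype=bool))
    domains = []
    for i, (s, e) in enumerate(_runs(dilated), 1):
        if (e - s) * r < config.min_length:
            continue
        domains.append(
            GenomicInterval(
                track.chrom,
                int(s * r),
                int(e * r),
                name=f"{track.chrom}_domain{i}",
                score=float(v[s:e].mean()),
            )
        )
    return PeakSet(domains)
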