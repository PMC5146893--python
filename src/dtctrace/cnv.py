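"""Single-cell copy-number profiling from binned read counts.

Turns one cell's binned read counts into a GC-corrected logR track,
segments it by penalized least squares (piecewise constant fitting, PCF),
scales segments to absolute copy number via the cell ploidy, and scores
per-cell noise with the median absolute pairwise difference (MAPD).

The logR of bin *i* is ``log2(count_i / mean(count))``; a segment with
mean logR *r* in a cell of ploidy |Psi| has copy number ``2**r * Psi``.
MAPD is the median of ``|logR_{i+1} - logR_i|`` over consecutive
within-chromosome bin pairs and scales with the per-bin noise SD
(for i.i.d. Gaussian noise, MAPD ~= 0.954 sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinnedCounts",
    "LogRProfile",
    "SegmentProfile",
    "QcResult",
    "compute_logr",
    "gc_correct",
    "segment_pcf",
    "pcf_segment_series",
    "estimate_cn",
    "estimate_ploidy",
    "compute_mapd",
    "profile_cell",
]

#: Zero-count bins are floored to this many reads before taking logs.
ZERO_COUNT_FLOOR = 0.5

#: Default PCF penalty (applied per breakpoint, on the noise-normalized scale).
DEFAULT_GAMMA = 25.0

#: Default MAPD pass threshold on GC-corrected logR.
DEFAULT_MAPD_THRESHOLD = 0.45

#: Ploidy grid searched by :func:`estimate_ploidy`.
PLOIDY_GRID = np.round(np.arange(1.5, 5.0 + 1e-9, 0.05), 2)

# MAPD of i.i.d. Gaussian noise with unit SD: sqrt(2) * Phi^-1(0.75).
_MAPD_PER_SIGMA = 0.9539


@dataclass
class BinnedCounts:
    """Per-bin read counts for one cell.

    ``bins`` holds one row per genomic bin with columns ``chrom``,
    ``start``, ``end`` (1-based inclusive), ``gc`` (fraction in [0, 1])
    and ``count`` (non-negative integer). Bins must be sorted by
    chromosome then start and non-overlapping.
    """

    cell_id: str
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc", "count"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"bins missing columns: {sorted(missing)}")
        if (self.bins["count"] < 0).any():
            raise ValueError("negative bin counts")
        if ((self.bins["gc"] < 0) | (self.bins["gc"] > 1)).any():
            raise ValueError("gc fraction outside [0, 1]")
        for _, chrom_bins in self.bins.groupby("chrom", sort=False):
            starts = chrom_bins["start"].to_numpy()
            ends = chrom_bins["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError("bins not sorted by start within chromosome")
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError("overlapping bins")

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class LogRProfile:
    """Per-bin logR track (log2 ratio to cell-average coverage)."""

    cell_id: str
    bins: pd.DataFrame  # chrom, start, end, gc, logr
    gc_corrected: bool = False

    @property
    def logr(self) -> np.ndarray:
        return self.bins["logr"].to_numpy()


@dataclass
class SegmentProfile:
    """Segmented, copy-number-scaled profile for one cell.

    ``segments`` has one row per segment: ``chrom``, ``start``, ``end``
    (genomic, 1-based inclusive), ``start_bin``, ``end_bin`` (0-based
    bin indices into the source profile, inclusive), ``n_bins``,
    ``mean_logr``, and, once scaled, ``cn_real`` and ``cn_state``.
    """

    cell_id: str
    segments: pd.DataFrame
    ploidy: float | None = None
    gamma: float = DEFAULT_GAMMA


@dataclass
class QcResult:
    """Per-cell noise QC based on MAPD."""

    mapd: float
    threshold: float = DEFAULT_MAPD_THRESHOLD
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.mapd < 0:
            raise ValueError("MAPD must be non-negative")
        self.passed = self.mapd <= self.threshold


def compute_logr(counts: BinnedCounts) -> LogRProfile:
    """Compute per-bin logR = log2(count / mean count).

    Zero counts are floored to :data:`ZERO_COUNT_FLOOR` reads before the
    log so the track stays finite.

    Raises
    ------
    ValueError
        If every bin has zero reads (empty library).
    """
    c = counts.bins["count"].to_numpy(dtype=float)
    if not np.any(c > 0):
        raise ValueError(f"cell {counts.cell_id}: all bin counts are zero (empty library)")
    mean = c.mean()
    c = np.maximum(c, ZERO_COUNT_FLOOR)
    logr = np.log2(c / mean)
    bins = counts.bins[["chrom", "start", "end", "gc"]].copy()
    bins["logr"] = logr
    return LogRProfile(cell_id=counts.cell_id, bins=bins, gc_corrected=False)


def gc_correct(profile: LogRProfile, gc: np.ndarray | None = None) -> LogRProfile:
    """Remove the quadratic GC trend from a logR profile.

    Fits logR on bin GC fraction by quadratic least squares with one
    round of outlier trimming at 3 MADs (so large CNAs do not drag the
    curve), subtracts the fit, and re-centers the track so the
    coverage-weighted mean of ``2**logR`` is 1 again.

    A constant GC track makes the fit degenerate; the profile is
    returned re-centered but otherwise untouched, with a warning.
    """
    logr = profile.logr
    if gc is None:
        gc = profile.bins["gc"].to_numpy(dtype=float)
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(logr):
        raise ValueError("gc track not aligned to bins")

    if np.ptp(gc) < 1e-9:
        warnings.warn("constant GC across bins; GC correction is a no-op", stacklevel=2)
        corrected = logr.copy()
    else:
        coef = np.polyfit(gc, logr, 2)
        resid = logr - np.polyval(coef, gc)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad > 0:
            keep = np.abs(resid - np.median(resid)) <= 3 * mad / 0.6745
        else:
            keep = np.ones_like(resid, dtype=bool)
        coef = np.polyfit(gc[keep], logr[keep], 2)
        corrected = logr - np.polyval(coef, gc)

    # re-center: mean of 2^logR back to 1
    corrected -= np.log2(np.mean(2.0 ** corrected))
    bins = profile.bins.copy()
    bins["logr"] = corrected
    return LogRProfile(cell_id=profile.cell_id, bins=bins, gc_corrected=True)


def _pcf_series(y: np.ndarray, gamma: float, tol: float = 1e-9) -> list[int]:
    """Exact PCF on one series: breakpoints minimizing RSS + gamma * (#breaks).

    Dynamic program over all segmentations; returns the 0-based start
    indices of each segment (first is always 0). Cost ties are broken
    toward fewer breakpoints, then toward longer final segments.
    """
    n = len(y)
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def rss(i: int, j: int) -> float:
        # RSS of y[i:j] around its mean
        m = j - i
        s = s1[j] - s1[i]
        return max((s2[j] - s2[i]) - s * s / m, 0.0)

    best = np.empty(n + 1)
    nseg = np.zeros(n + 1, dtype=int)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # so the first segment carries no penalty
    for j in range(1, n + 1):
        bc, bn, bi = np.inf, 0, 0
        for i in range(j):
            cost = best[i] + rss(i, j) + gamma
            segs = nseg[i] + 1
            if cost < bc - tol or (abs(cost - bc) <= tol and (segs < bn or (segs == bn and i < bi))):
                bc, bn, bi = cost, segs, i
        best[j], nseg[j], prev[j] = bc, bn, bi
    starts: list[int] = []
    j = n
    while j > 0:
        starts.append(prev[j])
        j = prev[j]
    return starts[::-1]


def pcf_segment_series(y: np.ndarray, gamma: float) -> list[tuple[int, int]]:
    """Segment one numeric series with exact PCF.

    Returns ``(start, end)`` index pairs (0-based, end exclusive) of the
    optimal segmentation minimizing ``sum of within-segment squared
    deviations + gamma * (number of breakpoints)``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        return []
    starts = _pcf_series(y, gamma)
    bounds = starts + [len(y)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(starts))]


def segment_pcf(
    profile: LogRProfile, gamma: float = DEFAULT_GAMMA, normalize: bool = True
) -> SegmentProfile:
    """Segment a logR profile per chromosome with exact PCF.

    With ``normalize=True`` (the default used by the pipeline) the
    penalty is applied on the noise-normalized scale: the per-bin noise
    SD is estimated from the MAPD of the profile and the effective
    penalty on raw RSS becomes ``gamma * sigma_hat**2``, so one value of
    gamma behaves consistently across cells of different noise levels.
    With ``normalize=False`` the penalty applies to RSS in raw logR
    units, matching the plain definition of the objective.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    eff_gamma = gamma
    if normalize:
        diffs = _within_chrom_diffs(profile)
        sigma_hat = np.median(np.abs(diffs)) / _MAPD_PER_SIGMA if len(diffs) else 0.0
        sigma_hat = max(sigma_hat, 1e-6)
        eff_gamma = gamma * sigma_hat**2

    rows = []
    all_bins = profile.bins.reset_index(drop=True)
    for chrom, chrom_bins in all_bins.groupby("chrom", sort=False):
        y = chrom_bins["logr"].to_numpy()
        if len(y) == 0:
            warnings.warn(f"chromosome {chrom} has no bins; skipped", stacklevel=2)
            continue
        offset = chrom_bins.index[0]
        for s, e in pcf_segment_series(y, eff_gamma):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(chrom_bins["start"].iloc[s]),
                    "end": int(chrom_bins["end"].iloc[e - 1]),
                    "start_bin": int(offset + s),
                    "end_bin": int(offset + e - 1),
                    "n_bins": e - s,
                    "mean_logr": float(y[s:e].mean()),
                }
            )
    segments = pd.DataFrame(rows)
    return SegmentProfile(cell_id=profile.cell_id, segments=segments, gamma=gamma)


def estimate_cn(mean_logr: float | np.ndarray, ploidy: float) -> tuple[np.ndarray, np.ndarray]:
    """Scale segment logR to copy number: cn = 2**logR * Psi.

    Returns the real-valued copy number and the integer state
    (conventional rounding, floored at 0).
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    cn = 2.0 ** np.asarray(mean_logr, dtype=float) * ploidy
    state = np.maximum(np.floor(cn + 0.5), 0).astype(int)
    return cn, state


def estimate_ploidy(profile: SegmentProfile) -> float:
    """Grid-search the cell ploidy Psi.

    Minimizes the bin-length-weighted absolute distance of
    ``2**mean_logr * Psi`` to the nearest non-negative integer over
    Psi in [1.5, 5.0] (step 0.05); ties go to the smallest Psi. Note
    logR carries no absolute scale, so a perfectly flat genome-doubled
    cell is indistinguishable from a diploid one and resolves to the
    smallest consistent ploidy.
    """
    seg = profile.segments
    if len(seg) == 0:
        raise ValueError("empty segment profile")
    logr = seg["mean_logr"].to_numpy()
    w = seg["n_bins"].to_numpy(dtype=float)
    best_psi, best_obj = None, np.inf
    for psi in PLOIDY_GRID:
        cn = 2.0**logr * psi
        obj = float(np.sum(w * np.abs(cn - np.maximum(np.round(cn), 0))))
        if obj < best_obj - 1e-12:
            best_psi, best_obj = float(psi), obj
    return best_psi


def _within_chrom_diffs(profile: LogRProfile) -> np.ndarray:
    diffs = []
    for _, chrom_bins in profile.bins.groupby("chrom", sort=False):
        y = chrom_bins["logr"].to_numpy()
        if len(y) >= 2:
            diffs.append(np.diff(y))
    return np.concatenate(diffs) if diffs else np.array([])


def compute_mapd(profile: LogRProfile, threshold: float = DEFAULT_MAPD_THRESHOLD) -> QcResult:
    """Median absolute pairwise difference of consecutive logR bins.

    Consecutive pairs never span a chromosome boundary. A cell passes QC
    iff MAPD <= threshold.
    """
    if len(profile.bins) < 2:
        raise ValueError("MAPD undefined for fewer than 2 bins")
    diffs = _within_chrom_diffs(profile)
    if len(diffs) == 0:
        raise ValueError("no consecutive within-chromosome bin pairs")
    return QcResult(mapd=float(np.median(np.abs(diffs))), threshold=threshold)


def profile_cell(
    counts: BinnedCounts,
    gamma: float = DEFAULT_GAMMA,
    mapd_threshold: float = DEFAULT_MAPD_THRESHOLD,
    ploidy: float | None = None,
) -> tuple[SegmentProfile, QcResult, LogRProfile]:
    """Full per-cell profiling: logR -> GC correction -> PCF -> CN scaling.

    Returns the copy-number-scaled segment profile, the MAPD QC result,
    and the corrected logR track. If ``ploidy`` is not given it is
    estimated by :func:`estimate_ploidy`.
    """
    logr = gc_correct(compute_logr(counts))
    qc = compute_mapd(logr, threshold=mapd_threshold)
    seg = segment_pcf(logr, gamma=gamma, normalize=True)
    psi = ploidy if ploidy is not None else estimate_ploidy(seg)
    cn, state = estimate_cn(seg.segments["mean_logr"].to_numpy(), psi)
    seg.segments["cn_real"] = cn
    seg.segments["cn_state"] = state
    seg.ploidy = psi
    return seg, qc, logr
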