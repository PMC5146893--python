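"""Classify single cells as DTC / AU / N against the bulk tumor architecture.

A cell whose segmented copy-number landscape reproduces (nearly) all of
the bulk tumor's clonal CNAs is a disseminated tumor cell (DTC); a cell
with sizeable CNAs that do not match the tumor is an aberrant cell of
unknown origin (AU); a flat cell is normal (N). Aberrant cells whose
read-depth profile failed noise QC cannot be assigned unambiguously and
are reported as QC_FAIL.

Two CNAs "match" when they overlap, change copy number in the same
direction, and every identifiable breakpoint pair lies within a
tolerance (default 5 Mb); breakpoints at centromeres or telomeres are
treated as unidentifiable and excluded from the distance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import QcResult, SegmentProfile

__all__ = [
    "CnaEvent",
    "BulkProfile",
    "CellLabel",
    "events_from_segments",
    "annotate_breakpoints",
    "match_events",
    "classify_cell",
    "au_recurrence",
    "au_age_regression",
    "morphology_concordance",
]

#: Minimum CNA size considered anywhere (bp); smaller events are noise.
MIN_EVENT_SIZE = 5_000_000

#: Breakpoint tolerance for event matching (bp).
BREAKPOINT_TOL = 5_000_000

#: Fraction of bulk clonal events a DTC must share.
SHARE_FRACTION = 0.8


@dataclass(frozen=True)
class CnaEvent:
    """One copy-number aberration.

    ``kind`` is ``gain``, ``loss`` or ``cnLOH``; ``cn_state`` the total
    copy number of the segment. ``start_identifiable``/
    ``end_identifiable`` are False when the breakpoint coincides with a
    centromere or telomere and therefore cannot anchor a distance test.
    """

    chrom: str
    start: int
    end: int
    kind: str
    cn_state: int | None = None
    start_identifiable: bool = True
    end_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must precede end")
        if self.kind not in ("gain", "loss", "cnLOH"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "CnaEvent") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class BulkProfile:
    """Bulk tumor (sub)clonal CNA architecture (consumed, not computed).

    Clonal events carry an implicit cancer cell fraction (CCF) of 1;
    subclonal events each carry a CCF in (0, 1).
    """

    clonal: list[CnaEvent]
    subclonal: list[tuple[CnaEvent, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, ccf in self.subclonal:
            if not 0 < ccf < 1:
                raise ValueError("subclonal CCF must be in (0, 1)")


@dataclass
class CellLabel:
    """Classification outcome for one cell."""

    cell_id: str
    label: str  # DTC | AU | N | QC_FAIL
    events: list[CnaEvent] = field(default_factory=list)
    shared_clonal: list[CnaEvent] = field(default_factory=list)
    shared_subclonal: list[tuple[CnaEvent, float]] = field(default_factory=list)
    private_events: list[CnaEvent] = field(default_factory=list)
    n_clonal_matched: int = 0
    n_clonal_total: int = 0
    doublet_suspect: bool = False
    notes: str = ""


def events_from_segments(
    profile: SegmentProfile,
    min_size: int = MIN_EVENT_SIZE,
    baseline: int | None = None,
) -> list[CnaEvent]:
    """Extract gain/loss events from a copy-number-scaled segment profile.

    Adjacent segments with the same integer state are merged; runs whose
    state differs from the baseline (rounded cell ploidy by default) and
    whose genomic span is at least ``min_size`` become events. Total
    copy number alone cannot reveal cnLOH, so cell-side events are
    gains/losses only.
    """
    seg = profile.segments
    if "cn_state" not in seg.columns:
        raise ValueError("segment profile not copy-number scaled")
    if baseline is None:
        baseline = int(np.floor((profile.ploidy or 2.0) + 0.5))
    events: list[CnaEvent] = []
    for chrom, rows in seg.groupby("chrom", sort=False):
        cur = None  # (state, start, end)
        for r in rows.itertuples():
            if cur is not None and r.cn_state == cur[0]:
                cur = (cur[0], cur[1], r.end)
                continue
            if cur is not None and cur[0] != baseline:
                events.append(_mk_event(str(chrom), cur, baseline))
            cur = (r.cn_state, r.start, r.end)
        if cur is not None and cur[0] != baseline:
            events.append(_mk_event(str(chrom), cur, baseline))
    return [e for e in events if e.size >= min_size]


def _mk_event(chrom: str, run: tuple, baseline: int) -> CnaEvent:
    state, start, end = run
    kind = "gain" if state > baseline else "loss"
    return CnaEvent(chrom=chrom, start=int(start), end=int(end), kind=kind, cn_state=int(state))


def annotate_breakpoints(
    events: list[CnaEvent],
    chrom_lengths: dict[str, int],
    centromeres: dict[str, tuple[int, int]] | None = None,
    edge_tol: int = 1_000_000,
) -> list[CnaEvent]:
    """Mark breakpoints at centromeres/telomeres as unidentifiable.

    A breakpoint is unidentifiable if it lies within ``edge_tol`` of a
    chromosome end (telomere) or inside/within ``edge_tol`` of the
    centromere interval of its chromosome.
    """
    centromeres = centromeres or {}

    def identifiable(chrom: str, pos: int) -> bool:
        length = chrom_lengths.get(chrom)
        if length is not None and (pos <= edge_tol or pos >= length - edge_tol):
            return False
        cen = centromeres.get(chrom)
        if cen is not None and cen[0] - edge_tol <= pos <= cen[1] + edge_tol:
            return False
        return True

    return [
        replace(
            e,
            start_identifiable=identifiable(e.chrom, e.start),
            end_identifiable=identifiable(e.chrom, e.end),
        )
        for e in events
    ]


def match_events(e1: CnaEvent, e2: CnaEvent, tol: int = BREAKPOINT_TOL) -> bool:
    """Decide whether two CNAs are the same event.

    They match iff they overlap, have the same direction, and every
    breakpoint pair in which both breakpoints are identifiable lies
    within ``tol``. The relation is symmetric.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not e1.overlaps(e2) or e1.kind != e2.kind:
        return False
    if e1.start_identifiable and e2.start_identifiable and abs(e1.start - e2.start) > tol:
        return False
    if e1.end_identifiable and e2.end_identifiable and abs(e1.end - e2.end) > tol:
        return False
    return True


def _half_integer_fraction(profile: SegmentProfile) -> float:
    """Length-weighted fraction of the genome whose real CN sits near x.5."""
    seg = profile.segments
    if "cn_real" not in seg.columns or len(seg) == 0:
        return 0.0
    cn = seg["cn_real"].to_numpy()
    w = seg["n_bins"].to_numpy(dtype=float)
    near_half = np.abs(cn - np.floor(cn) - 0.5) < 0.15
    return float(np.sum(w[near_half]) / np.sum(w))


def classify_cell(
    profile: SegmentProfile,
    qc: QcResult,
    bulk: BulkProfile | None,
    min_size: int = MIN_EVENT_SIZE,
    tol: int = BREAKPOINT_TOL,
    share_fraction: float = SHARE_FRACTION,
) -> CellLabel:
    """Assign a DTC / AU / N / QC_FAIL label to one cell.

    Aberrant cells failing noise QC get QC_FAIL (false positive CNAs
    cannot be excluded); event-free cells are N; cells matching at least
    ``share_fraction`` of the bulk clonal events are DTC; the rest are
    AU. Bulk cnLOH events are excluded from the clonal-match denominator
    since total copy number in the cell cannot reveal them. A mixed
    doublet-like profile (much of the genome near half-integer copy
    number) raises an advisory flag only.
    """
    events = events_from_segments(profile, min_size=min_size)
    doublet_suspect = _half_integer_fraction(profile) >= 0.2

    if not qc.passed and events:
        return CellLabel(
            cell_id=profile.cell_id,
            label="QC_FAIL",
            events=events,
            doublet_suspect=doublet_suspect,
            notes=f"noisy profile (MAPD {qc.mapd:.3f} > {qc.threshold}); "
            "aberrations cannot be unambiguously assigned",
        )
    if not events:
        return CellLabel(cell_id=profile.cell_id, label="N", doublet_suspect=doublet_suspect)

    if bulk is None or not (bulk.clonal or bulk.subclonal):
        warnings.warn(
            "empty bulk profile: only the N/AU distinction is possible", stacklevel=2
        )
        return CellLabel(
            cell_id=profile.cell_id,
            label="AU",
            events=events,
            private_events=list(events),
            doublet_suspect=doublet_suspect,
            notes="no bulk profile available",
        )

    clonal = [e for e in bulk.clonal if e.kind != "cnLOH"]
    shared_clonal = []
    matched_cell_events: set[int] = set()
    for be in clonal:
        for i, ce in enumerate(events):
            if match_events(ce, be, tol=tol):
                shared_clonal.append(be)
                matched_cell_events.add(i)
                break
    shared_sub = []
    for be, ccf in bulk.subclonal:
        if be.kind == "cnLOH":
            continue
        for i, ce in enumerate(events):
            if match_events(ce, be, tol=tol):
                shared_sub.append((be, ccf))
                matched_cell_events.add(i)
                break
    private = [e for i, e in enumerate(events) if i not in matched_cell_events]

    n_total = len(clonal)
    n_matched = len(shared_clonal)
    frac = n_matched / n_total if n_total else 0.0
    label = "DTC" if n_total and frac >= share_fraction else "AU"
    return CellLabel(
        cell_id=profile.cell_id,
        label=label,
        events=events,
        shared_clonal=shared_clonal,
        shared_subclonal=shared_sub,
        private_events=private,
        n_clonal_matched=n_matched,
        n_clonal_total=n_total,
        doublet_suspect=doublet_suspect,
    )


def au_recurrence(
    au_labels: list[CellLabel],
    arms: pd.DataFrame,
) -> pd.DataFrame:
    """Per-arm recurrence of aberrations among AU cells.

    ``arms`` needs columns ``chrom``, ``arm``, ``start``, ``end``. For
    every arm and event kind, reports the fraction of AU cells with an
    event of that kind covering at least half of the arm.
    """
    if not au_labels:
        raise ValueError("need at least one AU cell")
    rows = []
    for arm in arms.itertuples():
        arm_len = arm.end - arm.start + 1
        for kind in ("gain", "loss", "cnLOH"):
            n_hit = 0
            for lab in au_labels:
                covered = 0
                for e in lab.events:
                    if e.kind != kind or e.chrom != arm.chrom:
                        continue
                    ov = min(e.end, arm.end) - max(e.start, arm.start) + 1
                    covered += max(ov, 0)
                if covered >= 0.5 * arm_len:
                    n_hit += 1
            rows.append(
                {
                    "chrom": arm.chrom,
                    "arm": arm.arm,
                    "kind": kind,
                    "n_cells": n_hit,
                    "fraction": n_hit / len(au_labels),
                }
            )
    return pd.DataFrame(rows)


def au_age_regression(points: list[tuple[float, float, int]]) -> dict:
    """OLS of aberrant-cell fraction on patient age.

    ``points`` are ``(age_years, aberrant_fraction, n_cells)`` tuples.
    Returns slope, slope SE, two-sided p-value (t-test on the slope),
    intercept, and the per-point proportion SEs sqrt(f(1-f)/n) used as
    error bars.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for the regression")
    age = np.array([p[0] for p in points], dtype=float)
    frac = np.array([p[1] for p in points], dtype=float)
    n = np.array([p[2] for p in points], dtype=float)
    fit = stats.linregress(age, frac)
    prop_se = np.sqrt(frac * (1 - frac) / n)
    pvalue = float(fit.pvalue)
    if not np.isfinite(pvalue):  # zero residual variance: t-statistic degenerates
        pvalue = 1.0 if fit.slope == 0 else 0.0
    return {
        "slope": float(fit.slope),
        "slope_se": float(fit.stderr),
        "p_value": pvalue,
        "intercept": float(fit.intercept),
        "point_se": prop_se,
    }


def morphology_concordance(crosstab: pd.DataFrame) -> dict:
    """Concordance of sequencing-based and morphologic classification.

    ``crosstab`` has sequencing classes as rows (must include ``DTC``)
    and morphologic classes as columns (``TC`` plus any of
    ``uncertain``/``PHC``/``HC``); doublets and control cells must
    already be excluded. Reports the true positive rate (fraction of
    morphologic tumor cells confirmed as DTC) and the rate at which
    cells morphologically called uncertain/hematopoietic turn out to be
    DTCs, each with the binomial SE sqrt(p(1-p)/n).
    """
    tab = crosstab.drop(index=[i for i in crosstab.index if str(i).lower().startswith("doublet")])
    if (tab.to_numpy() < 0).any() or not np.issubdtype(tab.to_numpy().dtype, np.number):
        raise ValueError("crosstab must hold non-negative counts")

    def rate(num: float, den: float) -> tuple[float, float]:
        if den == 0:
            return float("nan"), float("nan")
        p = num / den
        return p, float(np.sqrt(p * (1 - p) / den))

    n_tc = float(tab["TC"].sum())
    tpr, tpr_se = rate(float(tab.loc["DTC", "TC"]), n_tc)
    non_tc_cols = [c for c in tab.columns if c != "TC"]
    n_non_tc = float(tab[non_tc_cols].to_numpy().sum())
    dtc_non_tc = float(tab.loc["DTC", non_tc_cols].sum())
    fnr, fnr_se = rate(dtc_non_tc, n_non_tc)
    return {
        "tpr": tpr,
        "tpr_se": tpr_se,
        "n_tc": int(n_tc),
        "fnr": fnr,
        "fnr_se": fnr_se,
        "n_non_tc": int(n_non_tc),
        "undefined": n_tc == 0 or n_non_tc == 0,
    }
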