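"""Synthetic single-cell cohorts with the statistical structure the
DTC analysis assumes.

The generator emulates low-coverage sequencing of whole-genome-amplified
single cells from bone marrow, alongside the bulk tumor's (sub)clonal
architecture:

* a clone tree with CNA events and cancer cell fractions (CCFs); the
  emitted bulk profile is written from this truth, so bulk CCFs equal
  the generating mixture fractions by construction;
* per-bin read counts that are negative-binomially dispersed (WGA
  overdispersion is exactly the phenomenon MAPD QC is for) with a
  multiplicative quadratic GC-bias curve;
* sparse SNV read counts with locus dropout, allelic dropout and false
  positive alternative alleles at locus level, at the rates typical of
  GenomePlex-amplified single cells (locus dropout ~0.69, allelic
  dropout ~0.44, false positives ~0.0017 per covered locus);
* four cell classes: DTC (carries all CNA/SNV events on the path from
  the MRCA to its clone), AU (aberrations absent from the tumor tree),
  N (flat diploid), and doublets (bin-wise average of a DTC and an N
  cell's expected coverage).

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import BulkProfile, CnaEvent
from .cnv import BinnedCounts
from .genotype import GenotypeMatrix
from .phylogeny import Subclone

__all__ = [
    "CnaSpec",
    "CloneSpec",
    "SimConfig",
    "SimCell",
    "SyntheticCohort",
    "simulate_cell_counts",
    "simulate_genotype_reads",
    "simulate_cohort",
    "random_clone_tree",
    "default_clone_tree",
    "default_genome",
    "toy_arms",
    "toy_chrom_lengths",
]

MB = 1_000_000


@dataclass(frozen=True)
class CnaSpec:
    """A generative CNA: copy-number change ``delta`` over a region."""

    chrom: str
    start: int
    end: int
    delta: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNA start must precede end")
        if self.delta == 0:
            raise ValueError("CNA delta must be non-zero")

    def to_event(self, baseline: int = 2) -> CnaEvent:
        return CnaEvent(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            kind="gain" if self.delta > 0 else "loss",
            cn_state=baseline + self.delta,
        )


@dataclass(frozen=True)
class CloneSpec:
    """One clone in the generating tree (``parent is None`` = MRCA)."""

    name: str
    parent: str | None
    ccf: float
    events: tuple[CnaSpec, ...] = ()


def default_genome() -> list[tuple[str, int]]:
    """Toy genome: six 50-Mb chromosomes of 100 bins each."""
    return [(f"chr{i}", 100) for i in range(1, 7)]


def toy_chrom_lengths() -> dict[str, int]:
    """Chromosome lengths (bp) of the default toy genome."""
    cfg = SimConfig()
    return {chrom: n * cfg.bin_size for chrom, n in cfg.genome_spec}


def toy_arms() -> pd.DataFrame:
    """Chromosome-arm table for the default toy genome (split at 25 Mb),
    for use with per-arm recurrence summaries."""
    rows = []
    for chrom, length in toy_chrom_lengths().items():
        mid = length // 2
        rows.append({"chrom": chrom, "arm": chrom.replace("chr", "") + "p",
                     "start": 1, "end": mid})
        rows.append({"chrom": chrom, "arm": chrom.replace("chr", "") + "q",
                     "start": mid + 1, "end": length})
    return pd.DataFrame(rows)


def default_clone_tree() -> list[CloneSpec]:
    """Default tumor: 5 clonal events, two nested subclones (CCF 0.5, 0.3)."""
    return [
        CloneSpec(
            name="MRCA",
            parent=None,
            ccf=1.0,
            events=(
                CnaSpec("chr1", 25 * MB + 1, 50 * MB, +1),
                CnaSpec("chr4", 1, 50 * MB, -1),
                CnaSpec("chr6", 25 * MB + 1, 50 * MB, +1),
                CnaSpec("chr2", 1, 15 * MB, -1),
                CnaSpec("chr3", 30 * MB + 1, 50 * MB, +1),
            ),
        ),
        CloneSpec(
            name="S1", parent="MRCA", ccf=0.5, events=(CnaSpec("chr2", 30 * MB + 1, 50 * MB, +1),)
        ),
        CloneSpec(
            name="S2", parent="S1", ccf=0.3, events=(CnaSpec("chr6", 1, 12 * MB, -1),)
        ),
    ]


#: Aberrations available to AU cells; disjoint from the default tree's
#: regions (whole-chromosome-scale events, as typically seen in
#: clonally expanding hematopoietic cells).
AU_EVENT_POOL = (
    CnaSpec("chr5", 1, 50 * MB, +1),
    CnaSpec("chr3", 1, 20 * MB, -1),
    CnaSpec("chr1", 1, 20 * MB, -1),
)


@dataclass
class SimConfig:
    """Generative settings for one synthetic patient cohort.

    Defaults are the study conditions the downstream analysis expects:
    genotyping error rates at the values measured in GenomePlex
    single-cell data, read-count dispersion giving MAPD around 0.3
    (comfortably inside the 0.45 QC pass band), and a quadratic GC
    curve of about +/-10% amplitude.
    """

    genome_spec: list[tuple[str, int]] = field(default_factory=default_genome)
    bin_size: int = 500_000
    base_depth: float = 300.0
    overdispersion: float = 0.04
    gc_bias_coefficients: tuple[float, float, float] = (0.35, 3.0, -3.4)
    clone_tree_spec: list[CloneSpec] = field(default_factory=default_clone_tree)
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {"DTC": 6, "AU": 5, "N": 5, "doublet": 2}
    )
    n_somatic_snvs: int = 35
    n_germline_het_snvs: int = 200
    n_germline_hom_snvs: int = 500
    locus_dropout_rate: float = 0.6907
    allelic_dropout_rate: float = 0.4405
    fp_rate: float = 0.0017
    mean_locus_depth: float = 1.7
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("locus_dropout_rate", "allelic_dropout_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")
        names = {c.name for c in self.clone_tree_spec}
        ccf = {c.name: c.ccf for c in self.clone_tree_spec}
        for clone in self.clone_tree_spec:
            if clone.parent is None:
                continue
            if clone.parent not in names:
                raise ValueError(f"clone {clone.name}: unknown parent {clone.parent}")
            if clone.ccf > ccf[clone.parent] + 1e-12:
                raise ValueError(
                    f"clone {clone.name}: CCF {clone.ccf} exceeds parent's {ccf[clone.parent]}"
                )

    @property
    def total_bins(self) -> int:
        return sum(n for _, n in self.genome_spec)


@dataclass
class SimCell:
    """One simulated cell with its ground truth."""

    cell_id: str
    true_class: str  # DTC | AU | N | doublet
    true_clone: str | None
    morphology: str
    counts: BinnedCounts
    true_cn: np.ndarray
    true_events: tuple[CnaSpec, ...] = ()


@dataclass
class SyntheticCohort:
    """A full synthetic patient: cells, genotypes, bulk truth."""

    config: SimConfig
    bins: pd.DataFrame  # chrom, start, end, gc
    clones: list[CloneSpec]
    cells: list[SimCell]
    genotypes: GenotypeMatrix
    variant_table: pd.DataFrame  # locus, role, clone, per-cell truth implied
    truth_genotypes: pd.DataFrame  # loci x cells, 0 hom-ref / 1 het
    bulk: BulkProfile
    bulk_df: pd.DataFrame

    def clone_path(self, name: str) -> list[str]:
        by_name = {c.name: c for c in self.clones}
        path, cur = [], name
        while cur is not None:
            path.append(cur)
            cur = by_name[cur].parent
        return path[::-1]


def _gc_factor(gc: np.ndarray, coef: tuple[float, float, float]) -> np.ndarray:
    c0, c1, c2 = coef
    return np.maximum(c0 + c1 * gc + c2 * gc**2, 1e-6)


def simulate_cell_counts(
    cn_track: np.ndarray,
    gc: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample per-bin read counts for one cell.

    The expected count of a bin is ``base_depth * (cn / 2) * gc_factor``
    with a quadratic multiplicative GC curve. Counts are
    negative-binomial with variance ``mu * (1 + alpha * mu)``
    (gamma-Poisson mixture); ``alpha = 0`` degenerates to Poisson and
    ``noise_free`` yields the rounded expectation itself.
    """
    cn_track = np.asarray(cn_track, dtype=float)
    if len(cn_track) != len(gc):
        raise ValueError("cn_track length must equal number of bins")
    if (cn_track < 0).any():
        raise ValueError("negative copy number")
    mu = config.base_depth * (cn_track / 2.0) * _gc_factor(np.asarray(gc), config.gc_bias_coefficients)
    if config.noise_free:
        return np.rint(mu).astype(int)
    alpha = config.overdispersion
    if alpha == 0:
        return rng.poisson(mu).astype(int)
    lam = np.where(mu > 0, rng.gamma(1.0 / alpha, alpha * mu, size=len(mu)), 0.0)
    return rng.poisson(lam).astype(int)


def simulate_genotype_reads(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample sparse single-cell ref/alt read counts from truth genotypes.

    ``truth`` is loci x cells with 0 (homozygous reference) or 1
    (heterozygous). Per locus and cell: the locus is uncovered with
    probability ``locus_dropout_rate``; covered loci get depth
    ``1 + Poisson(mean_locus_depth - 1)``. A covered het locus loses
    its alternative allele with probability ``allelic_dropout_rate``
    (allelic dropout and the low-coverage miss are modeled together at
    locus level); otherwise at least one read is alternative. A covered
    hom-ref locus shows one alternative read with probability
    ``fp_rate``.
    """
    n_loci, n_cells = truth.shape
    shape = (n_loci, n_cells)
    covered = rng.random(shape) >= config.locus_dropout_rate
    depth = 1 + rng.poisson(max(config.mean_locus_depth - 1.0, 0.0), size=shape)
    depth = np.where(covered, depth, 0)

    is_het = truth.to_numpy() == 1
    ado = rng.random(shape) < config.allelic_dropout_rate
    fp = rng.random(shape) < config.fp_rate

    alt = np.zeros(shape, dtype=int)
    het_detected = covered & is_het & ~ado
    alt[het_detected] = 1 + rng.binomial(
        np.maximum(depth[het_detected] - 1, 0), 0.5
    )
    hom_fp = covered & ~is_het & fp
    alt[hom_fp] = 1
    ref = depth - alt
    return (
        pd.DataFrame(ref, index=truth.index, columns=truth.columns),
        pd.DataFrame(alt, index=truth.index, columns=truth.columns),
    )


_MORPH_PROBS = {
    "DTC": (("TC", 0.9), ("HC", 0.1)),
    "AU": (("TC", 0.17), ("uncertain", 0.22), ("PHC", 0.44), ("HC", 0.17)),
    "N": (("TC", 0.37), ("uncertain", 0.32), ("PHC", 0.31)),
    "doublet": (("TC", 0.5), ("uncertain", 0.3), ("PHC", 0.1), ("HC", 0.1)),
}


def _make_bins(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, n_bins in config.genome_spec:
        gc = np.clip(rng.normal(0.45, 0.07, size=n_bins), 0.3, 0.65)
        for i in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "start": i * config.bin_size + 1,
                    "end": (i + 1) * config.bin_size,
                    "gc": gc[i],
                }
            )
    return pd.DataFrame(rows)


def _events_to_cn(events: list[CnaSpec], bins: pd.DataFrame) -> np.ndarray:
    cn = np.full(len(bins), 2, dtype=int)
    chrom = bins["chrom"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()
    for e in events:
        # a bin belongs to an event if its midpoint falls inside
        mid = (start + end) / 2
        mask = (chrom == e.chrom) & (mid >= e.start) & (mid <= e.end)
        cn[mask] += e.delta
    if (cn < 0).any():
        raise ValueError("event stack drives copy number below zero")
    return cn


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one synthetic patient cohort. Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    bins = _make_bins(config, rng)
    gc = bins["gc"].to_numpy()
    clones = list(config.clone_tree_spec)
    by_name = {c.name: c for c in clones}

    def path_events(name: str) -> list[CnaSpec]:
        out, cur = [], name
        chain = []
        while cur is not None:
            chain.append(cur)
            cur = by_name[cur].parent
        for n in chain[::-1]:
            out.extend(by_name[n].events)
        return out

    # bulk profile straight from truth
    root = next(c for c in clones if c.parent is None)
    clonal = [e.to_event() for e in root.events]
    subclonal = [
        (e.to_event(), c.ccf) for c in clones if c.parent is not None for e in c.events
    ]
    bulk = BulkProfile(clonal=clonal, subclonal=subclonal)
    bulk_rows = [
        {"chrom": e.chrom, "start": e.start, "end": e.end, "total_cn": e.cn_state,
         "ccf": 1.0, "clone": root.name}
        for e in clonal
    ] + [
        {"chrom": e.chrom, "start": e.start, "end": e.end, "total_cn": e.cn_state,
         "ccf": ccf, "clone": next(c.name for c in clones if c.parent is not None
                                    and any(s.to_event() == e for s in c.events))}
        for e, ccf in subclonal
    ]
    bulk_df = pd.DataFrame(bulk_rows)

    # cells
    cells: list[SimCell] = []
    clone_cycle = [c.name for c in clones]
    counts_cols = {}

    def add_cell(cid: str, cls: str, clone: str | None, events: list[CnaSpec]) -> SimCell:
        cn = _events_to_cn(events, bins)
        raw = simulate_cell_counts(cn, gc, config, rng)
        morph_names, morph_p = zip(*_MORPH_PROBS[cls])
        morph = str(rng.choice(morph_names, p=morph_p))
        bc = BinnedCounts(cell_id=cid, bins=bins.assign(count=raw))
        cell = SimCell(
            cell_id=cid, true_class=cls, true_clone=clone, morphology=morph,
            counts=bc, true_cn=cn, true_events=tuple(events),
        )
        cells.append(cell)
        counts_cols[cid] = raw
        return cell

    for i in range(config.n_cells_per_class.get("DTC", 0)):
        clone = clone_cycle[i % len(clone_cycle)]
        add_cell(f"DTC{i + 1:02d}", "DTC", clone, path_events(clone))
    for i in range(config.n_cells_per_class.get("AU", 0)):
        n_ev = int(rng.integers(1, min(2, len(AU_EVENT_POOL)) + 1))
        idx = rng.choice(len(AU_EVENT_POOL), size=n_ev, replace=False)
        add_cell(f"AU{i + 1:02d}", "AU", None, [AU_EVENT_POOL[j] for j in sorted(idx)])
    for i in range(config.n_cells_per_class.get("N", 0)):
        add_cell(f"N{i + 1:02d}", "N", None, [])
    for i in range(config.n_cells_per_class.get("doublet", 0)):
        # bin-wise average of a tumor (MRCA) cell and a normal cell
        cn_t = _events_to_cn(path_events(root.name), bins)
        cn_n = np.full(len(bins), 2, dtype=int)
        cn_mix = (cn_t + cn_n) / 2.0
        raw = simulate_cell_counts(cn_mix, gc, config, rng)
        morph_names, morph_p = zip(*_MORPH_PROBS["doublet"])
        morph = str(rng.choice(morph_names, p=morph_p))
        cid = f"D{i + 1:02d}"
        bc = BinnedCounts(cell_id=cid, bins=bins.assign(count=raw))
        cells.append(
            SimCell(cell_id=cid, true_class="doublet", true_clone=root.name,
                    morphology=morph, counts=bc, true_cn=cn_mix,
                    true_events=tuple(path_events(root.name)))
        )
        counts_cols[cid] = raw

    # variants: somatic SNVs assigned to clones, germline gold sets
    clone_names = [c.name for c in clones]
    weights = np.array([0.6] + [0.4 / max(len(clone_names) - 1, 1)] * (len(clone_names) - 1))
    weights = weights / weights.sum()
    somatic_clone = rng.choice(clone_names, size=config.n_somatic_snvs, p=weights)
    loci = (
        [f"som{i + 1:03d}" for i in range(config.n_somatic_snvs)]
        + [f"het{i + 1:03d}" for i in range(config.n_germline_het_snvs)]
        + [f"hom{i + 1:03d}" for i in range(config.n_germline_hom_snvs)]
    )
    roles = (
        ["somatic"] * config.n_somatic_snvs
        + ["germline_het_gold"] * config.n_germline_het_snvs
        + ["germline_hom_gold"] * config.n_germline_hom_snvs
    )
    variant_table = pd.DataFrame(
        {
            "locus": loci,
            "role": roles,
            "clone": list(somatic_clone) + [""] * (len(loci) - config.n_somatic_snvs),
        }
    ).set_index("locus")

    cell_ids = [c.cell_id for c in cells]
    truth = pd.DataFrame(0, index=loci, columns=cell_ids, dtype=int)
    truth.loc[variant_table["role"] == "germline_het_gold", :] = 1
    for cell in cells:
        if cell.true_clone is None:
            continue
        carried = {
            n for n in clone_names if n in set(_path_names(by_name, cell.true_clone))
        }
        som_mask = (variant_table["role"] == "somatic") & variant_table["clone"].isin(carried)
        truth.loc[som_mask[som_mask].index, cell.cell_id] = 1

    ref, alt = simulate_genotype_reads(truth, config, rng)
    genotypes = GenotypeMatrix(ref=ref, alt=alt, roles=variant_table["role"])

    return SyntheticCohort(
        config=config,
        bins=bins,
        clones=clones,
        cells=cells,
        genotypes=genotypes,
        variant_table=variant_table,
        truth_genotypes=truth,
        bulk=bulk,
        bulk_df=bulk_df,
    )


def _path_names(by_name: dict[str, CloneSpec], name: str) -> list[str]:
    out, cur = [], name
    while cur is not None:
        out.append(cur)
        cur = by_name[cur].parent
    return out[::-1]


def random_clone_tree(
    rng: np.random.Generator,
    max_nodes: int = 6,
    min_ccf_gap: float = 0.03,
) -> tuple[dict[str, str], list[Subclone], dict[str, frozenset[str]]]:
    """Random subclonal tree plus one cell per node spanning its path.

    Generates a rooted tree of 2..max_nodes subclones under an implicit
    MRCA with CCFs satisfying the mixture constraints (children of a
    node sum below its CCF, so no incomparable pair is falsely
    pigeonhole-forced) and pairwise CCF gaps above ``min_ccf_gap`` (so
    nesting directions are unambiguous). Returns the true parent map
    (parent of top-level subclones is "MRCA"), the subclone list, and
    per-node cells carrying the full event path — the evidence needed to
    resolve every pigeonhole-ambiguous ancestor pair.
    """
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        labels = [f"E{i + 1}" for i in range(n)]
        parent: dict[str, str] = {}
        for i, lab in enumerate(labels):
            parent[lab] = "MRCA" if i == 0 else str(rng.choice(["MRCA"] + labels[:i]))
        children: dict[str, list[str]] = {}
        for lab, p in parent.items():
            children.setdefault(p, []).append(lab)
        ccf: dict[str, float] = {"MRCA": 1.0}
        ok = True

        def assign(node: str) -> None:
            nonlocal ok
            kids = children.get(node, [])
            if not kids or not ok:
                return
            w = rng.dirichlet(np.ones(len(kids)))
            s = ccf[node] * rng.uniform(0.5, 0.9)
            for kid, wi in zip(kids, w):
                ccf[kid] = float(s * wi)
                if ccf[kid] < 0.05:
                    ok = False
                    return
            for kid in kids:
                assign(kid)

        assign("MRCA")
        if not ok:
            continue
        vals = [ccf[lab] for lab in labels]
        if any(abs(a - b) < min_ccf_gap for a, b in combinations(vals, 2)):
            continue
        if any(abs(ccf[lab] - ccf[parent[lab]]) < min_ccf_gap for lab in labels):
            continue
        subclones = [Subclone(label=lab, ccf=ccf[lab]) for lab in labels]
        cells = {}
        for lab in labels:
            path, cur = [], lab
            while cur != "MRCA":
                path.append(cur)
                cur = parent[cur]
            cells[f"cell_{lab}"] = frozenset(path)
        return parent, subclones, cells
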