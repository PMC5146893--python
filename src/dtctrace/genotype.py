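"""Per-cell genotyping error models and beta-binomial lineage tests.

Whole-genome-amplified single cells genotype poorly: loci drop out
entirely, one allele of a heterozygous site may vanish (allelic
dropout), and amplification/sequencing artifacts occasionally fabricate
an alternative allele. Gold-standard germline SNPs — loci whose true
genotype is known from matched bulk data — let us estimate, per cell,

* the false positive rate p_fp: fraction of covered homozygous-reference
  gold SNPs showing at least one alternative read,
* the false negative rate p_fn: fraction of covered heterozygous gold
  SNPs showing no alternative read,
* the locus dropout rate: fraction of heterozygous gold SNPs with no
  coverage at all.

Given a cell covering n somatic loci of which k show the variant
allele, two one-sided tests ask how surprising the pattern is: under
the *false positive model* the cell is assumed unrelated to the tumor
and every detection is an artifact (p-value P(X >= k)); under the
*false negative model* the cell is assumed tumor-derived and every
miss is a dropout (p-value P(Y >= n-k)). To propagate the uncertainty
of the per-cell rate estimates, X and Y are beta-binomial: the success
probability follows Beta(a, b) with moments matched to (p_hat,
var(p_hat)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "GenotypeMatrix",
    "GoldStandardCriteria",
    "ErrorRateEstimate",
    "LineageTest",
    "select_gold_standard",
    "estimate_error_rates",
    "beta_from_moments",
    "betabinom_tail",
    "lineage_pvalues",
    "filter_somatic_calls",
]

LOCUS_ROLES = ("somatic", "germline_het_gold", "germline_hom_gold", "germline_other")

#: Minimum allelic fraction for a somatic call to survive filtering.
AF_THRESHOLD = 0.15

#: Region classes in which somatic calls are discarded.
BLACKLIST_REGIONS = ("centromere", "intergenic", "repeat")


@dataclass
class GenotypeMatrix:
    """Ref/alt read counts per locus per cell.

    ``ref`` and ``alt`` are loci x cells integer DataFrames sharing
    index (locus ids) and columns (cell ids); ``roles`` labels each
    locus with one of :data:`LOCUS_ROLES`. A locus is *covered* in a
    cell iff ref + alt >= 1; a locus counts as a variant *detection*
    with >= 1 alt read.
    """

    ref: pd.DataFrame
    alt: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        if not self.ref.index.equals(self.alt.index) or not self.ref.columns.equals(
            self.alt.columns
        ):
            raise ValueError("ref and alt matrices must be aligned")
        if (self.ref.to_numpy() < 0).any() or (self.alt.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        unknown = set(self.roles.unique()) - set(LOCUS_ROLES)
        if unknown:
            raise ValueError(f"unknown locus roles: {sorted(unknown)}")

    @property
    def cells(self) -> list[str]:
        return list(self.ref.columns)

    def coverage(self) -> pd.DataFrame:
        return (self.ref + self.alt) >= 1

    def detections(self) -> pd.DataFrame:
        return self.alt >= 1


@dataclass
class GoldStandardCriteria:
    """Selection windows for gold-standard germline SNPs."""

    het_baf_window: tuple[float, float] = (0.3, 0.7)
    hom_baf_max: float = 0.1
    hom_baf_min: float = 0.9
    min_exome_coverage: int = 10
    allowed_hom_cn: tuple[str, ...] = ("1+1", "2+2")

    def __post_init__(self) -> None:
        lo, hi = self.het_baf_window
        if not (0 <= lo < hi <= 1):
            raise ValueError("het BAF window must be within [0, 1]")
        if not (0 <= self.hom_baf_max < self.hom_baf_min <= 1):
            raise ValueError("hom BAF cutoffs must be within [0, 1]")


@dataclass
class ErrorRateEstimate:
    """Per-cell genotyping error rates with binomial variances."""

    cell_id: str
    p_fp: float
    var_fp: float
    p_fn: float
    var_fn: float
    locus_dropout: float
    n_hom_covered: int
    n_het_covered: int
    n_het_total: int
    n_fp_events: int
    n_fn_events: int
    fp_pseudocall: bool = False
    fn_pseudocall: bool = False
    undefined: bool = False


@dataclass
class LineageTest:
    """Beta-binomial lineage-assignment test for one cell."""

    cell_id: str
    n: int
    k: int
    p_fp_model: float
    p_fn_model: float
    fp_beta: tuple[float, float] | None = None
    fn_beta: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


def select_gold_standard(
    array_baf: pd.Series,
    blood_exome: pd.DataFrame,
    tumor_exome: pd.DataFrame,
    bulk_cn: pd.Series,
    criteria: GoldStandardCriteria | None = None,
) -> pd.Series:
    """Label loci as het/hom gold-standard germline SNPs.

    ``blood_exome``/``tumor_exome`` need columns ``genotype`` (``het``,
    ``hom_ref`` or ``hom_alt``) and ``coverage``; ``bulk_cn`` holds the
    allele-specific bulk copy number as "major+minor" strings. A locus
    is heterozygous gold iff its array BAF falls in the het window and
    both exomes call it het at sufficient coverage; homozygous gold
    additionally requires a normal 1+1 (or genome-doubled 2+2) copy
    number so allelic imbalance cannot mimic an error. Loci missing
    from any source are excluded (role ``germline_other``).
    """
    crit = criteria or GoldStandardCriteria()
    roles = pd.Series("germline_other", index=array_baf.index, dtype=object)
    lo, hi = crit.het_baf_window
    for locus in array_baf.index:
        if locus not in blood_exome.index or locus not in tumor_exome.index:
            continue
        baf = array_baf[locus]
        b, t = blood_exome.loc[locus], tumor_exome.loc[locus]
        if b["coverage"] < crit.min_exome_coverage or t["coverage"] < crit.min_exome_coverage:
            continue
        if lo <= baf <= hi and b["genotype"] == "het" and t["genotype"] == "het":
            roles[locus] = "germline_het_gold"
        elif (baf <= crit.hom_baf_max or baf >= crit.hom_baf_min) and (
            b["genotype"].startswith("hom") and t["genotype"].startswith("hom")
        ):
            if bulk_cn.get(locus) in crit.allowed_hom_cn:
                roles[locus] = "germline_hom_gold"
    return roles


def estimate_error_rates(matrix: GenotypeMatrix, cell_id: str) -> ErrorRateEstimate:
    """Estimate p_fp, p_fn and locus dropout for one cell from gold SNPs.

    Rates are per covered locus; variances are binomial p(1-p)/n. If a
    cell shows zero errors of a kind, a worst-case pseudocall is applied:
    one error is added to the numerator and one trial to the denominator,
    giving p_hat = 1/(n+1).
    """
    ref = matrix.ref[cell_id]
    alt = matrix.alt[cell_id]
    covered = (ref + alt) >= 1
    detected = alt >= 1
    hom = matrix.roles == "germline_hom_gold"
    het = matrix.roles == "germline_het_gold"

    n_hom_cov = int((hom & covered).sum())
    n_het_cov = int((het & covered).sum())
    n_het_tot = int(het.sum())
    n_fp = int((hom & covered & detected).sum())
    n_fn = int((het & covered & ~detected).sum())

    if n_hom_cov == 0 or n_het_cov == 0:
        return ErrorRateEstimate(
            cell_id=cell_id,
            p_fp=float("nan"),
            var_fp=float("nan"),
            p_fn=float("nan"),
            var_fn=float("nan"),
            locus_dropout=float((het & ~covered).sum() / n_het_tot) if n_het_tot else float("nan"),
            n_hom_covered=n_hom_cov,
            n_het_covered=n_het_cov,
            n_het_total=n_het_tot,
            n_fp_events=n_fp,
            n_fn_events=n_fn,
            undefined=True,
        )

    def rate(events: int, n: int) -> tuple[float, float, bool]:
        pseudo = events == 0
        p = 1.0 / (n + 1) if pseudo else events / n
        return p, p * (1 - p) / n, pseudo

    p_fp, var_fp, fp_pseudo = rate(n_fp, n_hom_cov)
    p_fn, var_fn, fn_pseudo = rate(n_fn, n_het_cov)
    dropout = float((het & ~covered).sum()) / n_het_tot

    return ErrorRateEstimate(
        cell_id=cell_id,
        p_fp=p_fp,
        var_fp=var_fp,
        p_fn=p_fn,
        var_fn=var_fn,
        locus_dropout=dropout,
        n_hom_covered=n_hom_cov,
        n_het_covered=n_het_cov,
        n_het_total=n_het_tot,
        n_fp_events=n_fp,
        n_fn_events=n_fn,
        fp_pseudocall=fp_pseudo,
        fn_pseudocall=fn_pseudo,
    )


def beta_from_moments(mu: float, var: float) -> tuple[float, float]:
    """Invert the Beta(a, b) moments: mu = a/(a+b), var = ab/((a+b)^2 (a+b+1)).

    Requires 0 < mu < 1 and 0 < var < mu(1-mu); the round trip through
    the Beta moments recovers the inputs to machine precision.
    """
    if not 0 < mu < 1:
        raise ValueError("mu must be in (0, 1)")
    if not 0 < var < mu * (1 - mu):
        raise ValueError("var must be in (0, mu(1-mu)) for a Beta to exist")
    nu = mu * (1 - mu) / var - 1.0
    return mu * nu, (1 - mu) * nu


def betabinom_tail(k: int, n: int, a: float, b: float) -> float:
    """P(X >= k) for X ~ BetaBinomial(n, a, b), by exact summation.

    The pmf is written with rising factorials,
    ``pmf(j) = C(n, j) * a^(j) * b^(n-j) / (a+b)^(n)``, and summed in
    log space. Unlike beta-function formulations this stays accurate
    for arbitrarily large a and b (the near-degenerate Beta limit),
    where it converges to the binomial tail at p = a / (a + b).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 1.0
    j = np.arange(n + 1)
    # cumulative log rising factorials: [0, log a, log a + log(a+1), ...]
    rise_a = np.concatenate([[0.0], np.cumsum(np.log(a + np.arange(n)))])
    rise_b = np.concatenate([[0.0], np.cumsum(np.log(b + np.arange(n)))])
    rise_ab = np.sum(np.log(a + b + np.arange(n)))
    logpmf = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + rise_a[j]
        + rise_b[n - j]
        - rise_ab
    )
    return float(np.exp(logsumexp(logpmf[k:])))


def _tail_at_least(successes: int, n: int, mu: float, var: float) -> tuple[float, tuple | None, list[str]]:
    """P(successes or more in n trials), beta-binomial or binomial fallback."""
    flags: list[str] = []
    if successes <= 0:
        return 1.0, None, flags
    if var <= 0 or var >= mu * (1 - mu):
        # no proper Beta (tiny n or degenerate variance): plain binomial
        flags.append("binomial_fallback")
        return float(stats.binom.sf(successes - 1, n, mu)), None, flags
    a, b = beta_from_moments(mu, var)
    return betabinom_tail(successes, n, a, b), (a, b), flags


def lineage_pvalues(
    n: int, k: int, fp_estimate: ErrorRateEstimate, fn_estimate: ErrorRateEstimate | None = None
) -> LineageTest:
    """Tail probabilities for the false positive and false negative models.

    ``n`` is the number of somatic loci covered in the cell, ``k`` the
    number showing the variant allele. The FP model assumes the cell is
    unrelated to the tumor, so the k detections are all errors:
    p = P(X >= k) with X ~ BetaBinomial(n, a_fp, b_fp). The FN model
    assumes the cell is tumor-derived, so the n-k misses are all
    dropouts: p = P(Y >= n-k) with Y ~ BetaBinomial(n, a_fn, b_fn).
    A small FP-model p-value marks a likely tumor-lineage cell; a small
    FN-model p-value marks a likely unrelated cell. Tails are exact
    beta-binomial sums; a cell whose variance estimate admits no Beta
    falls back to the binomial and is flagged.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    fn_estimate = fn_estimate or fp_estimate
    if n == 0:
        return LineageTest(
            cell_id=fp_estimate.cell_id, n=0, k=0, p_fp_model=1.0, p_fn_model=1.0,
            flags=["no_covered_loci"],
        )
    p_fp, fp_beta, f1 = _tail_at_least(k, n, fp_estimate.p_fp, fp_estimate.var_fp)
    p_fn, fn_beta, f2 = _tail_at_least(n - k, n, fn_estimate.p_fn, fn_estimate.var_fn)
    flags = [f"fp_{x}" for x in f1] + [f"fn_{x}" for x in f2]
    return LineageTest(
        cell_id=fp_estimate.cell_id,
        n=n,
        k=k,
        p_fp_model=p_fp,
        p_fn_model=p_fn,
        fp_beta=fp_beta,
        fn_beta=fn_beta,
        flags=flags,
    )


def filter_somatic_calls(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-call filtering of candidate somatic substitutions.

    ``candidates`` needs columns ``allelic_fraction``, ``alt_fwd``,
    ``alt_rev`` (per-strand alt read counts), ``in_panel`` (seen in any
    panel of normals) and ``region`` (e.g. ``exonic``, ``intronic``,
    ``intergenic``, ``centromere``, ``repeat``). A variant is discarded
    if it is present in a panel normal, falls in a centromere /
    intergenic / repeat region, has allelic fraction < 0.15, or shows
    complete strand bias (all alt reads on one strand). Variants with
    missing annotations are held out and reported, never passed
    silently.

    Returns the retained variants and a per-rule report with columns
    ``rule`` and ``n``.
    """
    required = ["allelic_fraction", "alt_fwd", "alt_rev", "in_panel", "region"]
    missing_cols = [c for c in required if c not in candidates.columns]
    if missing_cols:
        raise ValueError(f"candidates missing columns: {missing_cols}")

    df = candidates.copy()
    held = df[required].isna().any(axis=1)
    report_rows = [{"rule": "held_out_missing_annotation", "n": int(held.sum())}]
    df = df[~held]

    panel = df["in_panel"].astype(bool)
    region = df["region"].isin(BLACKLIST_REGIONS)
    low_af = df["allelic_fraction"] < AF_THRESHOLD
    alt_total = df["alt_fwd"] + df["alt_rev"]
    strand = (alt_total > 0) & ((df["alt_fwd"] == 0) | (df["alt_rev"] == 0))

    drop = panel | region | low_af | strand
    for rule, mask in [
        ("panel_of_normals", panel),
        ("blacklist_region", region),
        ("allelic_fraction_lt_0.15", low_af),
        ("complete_strand_bias", strand),
    ]:
        report_rows.append({"rule": rule, "n": int(mask.sum())})
    retained = df[~drop]
    report_rows.append({"rule": "retained", "n": int(len(retained))})
    return retained, pd.DataFrame(report_rows)
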