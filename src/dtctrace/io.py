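"""Plain-text readers and writers for the pipeline's file formats.

All outputs are TSV-family text formats: BED-like binned counts,
SEG-style segment tables, bedGraph logR tracks, Battenberg-style bulk
profiles, loci x cells "ref,alt" genotype matrices, a minimal VCF with
per-cell allelic depths, Newick trees, and JSON truth/summary files.
Every file starts with a comment header recording the package version
and a hash of the run configuration, so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import BulkProfile, CnaEvent
from .cnv import BinnedCounts, LogRProfile, SegmentProfile
from .genotype import GenotypeMatrix

__all__ = [
    "config_hash",
    "write_binned_counts",
    "read_binned_counts",
    "write_segments",
    "write_bedgraph",
    "write_bulk_profile",
    "read_bulk_profile",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_vcf",
    "write_tsv",
]


def config_hash(config: object) -> str:
    """Stable short hash of a configuration object (repr-based)."""
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]


def _header(chash: str | None) -> str:
    h = f"# dtctrace v{__version__}"
    if chash:
        h += f" config_hash={chash}"
    return h + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, chash: str | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(chash))
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_binned_counts(counts: BinnedCounts, path: str | Path, chash: str | None = None) -> None:
    """BED-like TSV: chrom, start, end, gc, count."""
    write_tsv(counts.bins[["chrom", "start", "end", "gc", "count"]], path, chash)


def read_binned_counts(path: str | Path, cell_id: str | None = None) -> BinnedCounts:
    """Read a BED-like binned-counts TSV (also accepts 3+2 columns
    without a gc column, in which case gc is set to a constant)."""
    df = _read_tsv(path)
    if "gc" not in df.columns:
        df["gc"] = 0.5
    if "count" not in df.columns:  # positional 3+2-column file
        df.columns = ["chrom", "start", "end", "gc", "count"][: len(df.columns)]
    return BinnedCounts(cell_id=cell_id or Path(path).stem, bins=df)


def write_segments(profile: SegmentProfile, path: str | Path, chash: str | None = None) -> None:
    """SEG-style TSV with one row per segment."""
    seg = profile.segments.copy()
    seg.insert(0, "cell", profile.cell_id)
    seg["ploidy"] = profile.ploidy
    write_tsv(seg, path, chash)


def write_bedgraph(profile: LogRProfile, path: str | Path, chash: str | None = None) -> None:
    """bedGraph of the (corrected) logR track."""
    df = profile.bins[["chrom", "start", "end", "logr"]].copy()
    df["start"] = df["start"] - 1  # bedGraph is 0-based half-open
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(chash))
        fh.write(f'track type=bedGraph name="{profile.cell_id} logR"\n')
        df.to_csv(fh, sep="\t", index=False, header=False)


def write_bulk_profile(bulk_df: pd.DataFrame, path: str | Path, chash: str | None = None) -> None:
    """Battenberg-style TSV: chrom, start, end, total_cn, ccf[, clone]."""
    write_tsv(bulk_df, path, chash)


def read_bulk_profile(path: str | Path, baseline: int = 2) -> BulkProfile:
    """Read a Battenberg-style subclonal segment TSV into a BulkProfile.

    Rows with ccf >= 1 (within 1e-9) are clonal; others subclonal.
    Event direction is judged against ``baseline`` total copy number.
    """
    df = _read_tsv(path)
    clonal, subclonal = [], []
    for r in df.itertuples():
        if int(r.total_cn) == baseline:
            continue
        ev = CnaEvent(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            kind="gain" if r.total_cn > baseline else "loss", cn_state=int(r.total_cn),
        )
        if r.ccf >= 1 - 1e-9:
            clonal.append(ev)
        else:
            subclonal.append((ev, float(r.ccf)))
    return BulkProfile(clonal=clonal, subclonal=subclonal)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path, chash: str | None = None) -> None:
    """Loci x cells TSV of "ref,alt" strings plus a role column."""
    cells = matrix.cells
    out = pd.DataFrame(index=matrix.ref.index)
    out["role"] = matrix.roles
    for c in cells:
        out[c] = matrix.ref[c].astype(str) + "," + matrix.alt[c].astype(str)
    write_tsv(out.reset_index(names="locus"), path, chash)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    df = _read_tsv(path).set_index("locus")
    roles = df.pop("role")
    ref = pd.DataFrame(index=df.index)
    alt = pd.DataFrame(index=df.index)
    for c in df.columns:
        split = df[c].str.split(",", expand=True).astype(int)
        ref[c], alt[c] = split[0], split[1]
    return GenotypeMatrix(ref=ref, alt=alt, roles=roles)


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contigs: dict[str, int] | None = None,
    chash: str | None = None,
) -> None:
    """Minimal uncompressed VCF with per-cell AD (ref,alt depths).

    Loci without genomic coordinates are written on a synthetic contig
    in input order (the matrix is keyed by locus id, not position).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells = matrix.cells
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=dtctrace_v{__version__}\n")
        if chash:
            fh.write(f"##dtctrace_config_hash={chash}\n")
        for name, length in (contigs or {"loci": len(matrix.ref)}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##INFO=<ID=ROLE,Number=1,Type=String,Description="Locus role">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells) + "\n")
        for pos, locus in enumerate(matrix.ref.index, start=1):
            ads = [f"{matrix.ref.at[locus, c]},{matrix.alt.at[locus, c]}" for c in cells]
            fh.write(
                f"loci\t{pos}\t{locus}\tN\tA\t.\tPASS\tROLE={matrix.roles[locus]}\tAD\t"
                + "\t".join(ads)
                + "\n"
            )


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
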