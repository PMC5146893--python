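"""End-to-end orchestration: simulate -> profile -> classify -> genotype
-> rarefy -> tree, as one reproducible run.

All randomness derives from one master seed: the generator seed and the
rarefaction permutation seed are drawn from ``numpy``'s SeedSequence
spawned off the master (masked to 31 bits). Every output file carries a
header with the package version and a hash of the run configuration.
Warnings (QC failures, tree conflicts) are logged, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .classify import (
    BREAKPOINT_TOL,
    MIN_EVENT_SIZE,
    SHARE_FRACTION,
    CellLabel,
    classify_cell,
    match_events,
)
from .cnv import DEFAULT_GAMMA, DEFAULT_MAPD_THRESHOLD, profile_cell
from .genotype import estimate_error_rates, lineage_pvalues
from .phylogeny import Subclone, cooccurrence_refine, pigeonhole_nest, place_cell, render_tree
from .rarefaction import rarefy
from .synthetic import SimConfig, SyntheticCohort, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("dtctrace")


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Stage defaults follow the analysis conventions: PCF penalty
    gamma=25, minimum event size 5 Mb, breakpoint tolerance 5 Mb,
    DTC share fraction 0.8, allelic-fraction filter 0.15, and 100,000
    rarefaction permutations.
    """

    out_dir: str = "dtctrace_run"
    seed: int = 0
    gamma: float = DEFAULT_GAMMA
    mapd_threshold: float = DEFAULT_MAPD_THRESHOLD
    share_fraction: float = SHARE_FRACTION
    min_event_size: int = MIN_EVENT_SIZE
    breakpoint_tol: int = BREAKPOINT_TOL
    n_perm: int = 100_000
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self, sim_seed: int) -> SimConfig:
        return SimConfig(seed=sim_seed, **self.sim)


def _spawn_seeds(master: int, n: int = 2) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def event_label(e) -> str:
    return f"{e.kind}_{e.chrom}:{e.start}-{e.end}"


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run the full pipeline on a synthetic cohort; return a run summary.

    A stage failure aborts the run with the failing stage named;
    outputs of completed stages are retained on disk.
    """
    out = Path(config.out_dir)
    # hash the scientific parameters only, so identical runs in different
    # directories produce identical files
    chash = dio.config_hash({k: v for k, v in sorted(asdict(config).items()) if k != "out_dir"})
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setLevel(logging.INFO)
        logger.addHandler(fh)
    logger.info("run config: %s (hash %s)", asdict(config), chash)

    sim_seed, perm_seed = _spawn_seeds(config.seed)
    stage = "simulate"
    try:
        cohort = simulate_cohort(config.sim_config(sim_seed))
        if write_outputs:
            _write_cohort(cohort, out, chash)

        stage = "profile"
        profiles, qcs = {}, {}
        for cell in cohort.cells:
            seg, qc, logr = profile_cell(
                cell.counts, gamma=config.gamma, mapd_threshold=config.mapd_threshold
            )
            profiles[cell.cell_id], qcs[cell.cell_id] = seg, qc
            if not qc.passed:
                logger.warning("cell %s failed MAPD QC (%.3f)", cell.cell_id, qc.mapd)
            if write_outputs:
                dio.write_segments(seg, out / "segments" / f"{cell.cell_id}.seg", chash)

        stage = "classify"
        labels: dict[str, CellLabel] = {}
        for cell in cohort.cells:
            labels[cell.cell_id] = classify_cell(
                profiles[cell.cell_id],
                qcs[cell.cell_id],
                cohort.bulk,
                min_size=config.min_event_size,
                tol=config.breakpoint_tol,
                share_fraction=config.share_fraction,
            )
        label_df = pd.DataFrame(
            [
                {
                    "cell": cid,
                    "label": lab.label,
                    "n_clonal_matched": lab.n_clonal_matched,
                    "n_clonal_total": lab.n_clonal_total,
                    "n_private": len(lab.private_events),
                    "doublet_suspect": lab.doublet_suspect,
                    "events": ";".join(event_label(e) for e in lab.events),
                }
                for cid, lab in labels.items()
            ]
        )
        if write_outputs:
            dio.write_tsv(label_df, out / "labels.tsv", chash)

        stage = "genotype"
        rates = {c: estimate_error_rates(cohort.genotypes, c) for c in cohort.genotypes.cells}
        somatic = cohort.genotypes.roles == "somatic"
        cov = cohort.genotypes.coverage()
        det = cohort.genotypes.detections()
        lineage_rows = []
        lineage = {}
        for cid in cohort.genotypes.cells:
            n = int((somatic & cov[cid]).sum())
            k = int((somatic & cov[cid] & det[cid]).sum())
            test = lineage_pvalues(n, k, rates[cid])
            lineage[cid] = test
            est = rates[cid]
            lineage_rows.append(
                {
                    "cell": cid, "n": n, "k": k,
                    "p_fp_model": test.p_fp_model, "p_fn_model": test.p_fn_model,
                    "p_fp_hat": est.p_fp, "p_fn_hat": est.p_fn,
                    "locus_dropout": est.locus_dropout,
                }
            )
        lineage_df = pd.DataFrame(lineage_rows)
        if write_outputs:
            dio.write_tsv(lineage_df, out / "lineage.tsv", chash)
            status = pd.DataFrame("no_coverage", index=cohort.genotypes.ref.index,
                                  columns=cohort.genotypes.cells)
            status[cov & det] = "variant"
            status[cov & ~det] = "reference_only"
            dio.write_tsv(status.loc[somatic].reset_index(names="locus"),
                          out / "detection_matrix.tsv", chash)

        stage = "rarefy"
        aberrant_cells = [
            lab.events
            for cid, lab in labels.items()
            if lab.label in ("DTC", "AU")
        ]
        curve = None
        if aberrant_cells:
            curve = rarefy(
                aberrant_cells,
                n_perm=config.n_perm,
                seed=perm_seed,
                min_event_size=config.min_event_size,
                tol=config.breakpoint_tol,
            )
            if write_outputs:
                dio.write_tsv(
                    pd.DataFrame({"k": curve.k, "mean": curve.mean, "sd": curve.sd}),
                    out / "rarefaction.tsv", chash,
                )

        stage = "tree"
        subclones = [
            Subclone(label=event_label(e), ccf=ccf)
            for e, ccf in cohort.bulk.subclonal
        ]
        clonal_labels = tuple(event_label(e) for e in cohort.bulk.clonal)
        dtc_cells = {}
        for cid, lab in labels.items():
            if lab.label != "DTC":
                continue
            carried = set()
            for ce in lab.events:
                for be, _ in cohort.bulk.subclonal:
                    if match_events(ce, be, tol=config.breakpoint_tol):
                        carried.add(event_label(be))
                for be in cohort.bulk.clonal:
                    if match_events(ce, be, tol=config.breakpoint_tol):
                        carried.add(event_label(be))
            dtc_cells[cid] = frozenset(carried)
        order = pigeonhole_nest(subclones)
        tree = cooccurrence_refine(order, subclones, dtc_cells, clonal_events=clonal_labels)
        for c in tree.conflicts:
            logger.warning("tree conflict: %s", c)
        for cid, carried in sorted(dtc_cells.items()):
            if carried & set(clonal_labels):
                place_cell(carried, tree, cell_id=cid)
        newick, node_table = render_tree(tree)
        if write_outputs:
            (out / "tree.nwk").write_text(newick)
            dio.write_tsv(node_table, out / "tree_nodes.tsv", chash)

        stage = "summary"
        summary = _summarize(cohort, labels, lineage_df, curve, config, chash)
        if write_outputs:
            dio.write_json(summary, out / "summary.json")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        if write_outputs:
            logger.removeHandler(fh)

    summary["labels"] = {cid: lab.label for cid, lab in labels.items()}
    summary["_objects"] = {
        "cohort": cohort, "labels": labels, "lineage": lineage,
        "rates": rates, "curve": curve, "tree": tree, "newick": newick,
    }
    return summary


def _write_cohort(cohort: SyntheticCohort, out: Path, chash: str) -> None:
    for cell in cohort.cells:
        dio.write_binned_counts(cell.counts, out / "cells" / f"{cell.cell_id}.tsv", chash)
    dio.write_bulk_profile(cohort.bulk_df, out / "bulk_profile.tsv", chash)
    dio.write_genotype_matrix(cohort.genotypes, out / "genotypes.tsv", chash)
    dio.write_vcf(cohort.genotypes, out / "genotypes.vcf", chash=chash)
    truth = {
        "clones": [
            {"name": c.name, "parent": c.parent, "ccf": c.ccf,
             "events": [asdict(e) for e in c.events]}
            for c in cohort.clones
        ],
        "cells": [
            {"cell_id": c.cell_id, "true_class": c.true_class,
             "true_clone": c.true_clone, "morphology": c.morphology}
            for c in cohort.cells
        ],
    }
    dio.write_json(truth, out / "truth.json")


def _summarize(cohort, labels, lineage_df, curve, config, chash) -> dict:
    truth_classes = {c.cell_id: c.true_class for c in cohort.cells}
    morph = {c.cell_id: c.morphology for c in cohort.cells}
    class_counts = pd.Series([lab.label for lab in labels.values()]).value_counts().to_dict()
    # sequencing class x morphology cross-tab (doublets by truth kept separate)
    crosstab = (
        pd.crosstab(
            pd.Series({cid: lab.label for cid, lab in labels.items()}, name="sequencing"),
            pd.Series(morph, name="morphology"),
        )
        .reindex(columns=["TC", "uncertain", "PHC", "HC"], fill_value=0)
    )
    scored = {
        cid: lab.label for cid, lab in labels.items() if truth_classes[cid] != "doublet"
    }
    n_correct = sum(1 for cid, lab in scored.items() if lab == truth_classes[cid])
    return {
        "config_hash": chash,
        "seed": config.seed,
        "n_cells": len(cohort.cells),
        "class_counts": class_counts,
        "truth_class_counts": pd.Series(list(truth_classes.values())).value_counts().to_dict(),
        "classification_accuracy": n_correct / len(scored) if scored else float("nan"),
        "crosstab": crosstab.to_dict(),
        "median_p_fp_model_true_dtc": float(
            lineage_df.set_index("cell")
            .loc[[cid for cid, t in truth_classes.items() if t == "DTC"], "p_fp_model"]
            .median()
        )
        if any(t == "DTC" for t in truth_classes.values())
        else float("nan"),
        "rarefaction_saturated": bool(curve.saturated) if curve is not None else None,
        "rarefaction_total_unique": curve.total_unique if curve is not None else None,
    }
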