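#!/usr/bin/env python
"""Re-run the pipeline on the published M. florum model and datasets.

This runner expects a directory of files the user has downloaded from the
public deposits (they are not shipped with the package):

    iJL208.json          deposited genome-scale model (BiGG-dialect JSON)
    omics.csv            gene, fpkm, proteins_per_cell  (GEO + PRIDE tables)
    tn_insertions.csv    gene, position_fraction, mutant_id
    tn_growth.csv        mutant_id, doubling_time, sd
    sugars.csv           sugar, exchange_id, observed_growth (0/1)
    layout_genes.tsv / layout_promoters.tsv / layout_tus.tsv
                         genome layout tables (optional, enables reduction)

Usage:
    python scripts/reproduce_published.py <data_dir> [--out report.json]

Every stage that has its inputs present is executed: model census, staged
constraint calibration (lactate min-match, acetate residual), expression
thresholds, pFBA flux-expression accuracy, essentiality revision and
accuracy, carbohydrate screen, and (with layout tables) the iterative
genome reduction. Results print as JSON; stages with missing inputs are
reported as skipped.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("data_dir", type=Path)
    parser.add_argument("--out", type=Path, default=None)
    parser.add_argument("--target-growth", type=float, default=0.44)
    parser.add_argument("--combined-secretion", type=float, default=8.69)
    parser.add_argument("--substrate-uptake", type=float, default=5.26)
    args = parser.parse_args()
    d = args.data_dir

    from minigem.calibration import CalibrationConfig, ModelHandles, calibrate
    from minigem.model import (
        active_genes,
        count_orphans,
        pfba,
        read_model_json,
        single_gene_deletions,
    )
    from minigem.reduction import iterate_reduction, read_layout
    from minigem.validate import (
        TnMutantTable,
        carbohydrate_screen,
        essentiality_confusion,
        expression_calls,
        flux_expression_confusion,
        optimal_thresholds,
        revise_essentiality,
    )

    report: dict = {}

    model_path = d / "iJL208.json"
    if not model_path.exists():
        raise SystemExit(f"{model_path} not found; download the deposited model JSON")
    model = read_model_json(model_path)
    census = count_orphans(model)
    report["census"] = {
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
        "genes": len(model.genes),
        "gene_associated": census.gene_associated,
        "orphans": census.orphan,
        "pseudo_orphans": census.orphan_pseudo,
    }

    # exchange ids follow BiGG conventions in the deposited model
    handles = ModelHandles(
        biomass=next(r.id for r in model.reactions if r.objective_coefficient != 0),
        atpm="ATPM",
        substrate_exchange="EX_sucr_e",
        lactate_exchange="EX_lac__L_e",
        acetate_exchange="EX_ac_e",
        oxygen_exchange="EX_o2_e",
        nox2="NOX2",
    )
    cfg = CalibrationConfig(
        target_growth=args.target_growth,
        substrate_uptake=args.substrate_uptake,
    )
    try:
        _, cal = calibrate(model, cfg, handles, combined_secretion=args.combined_secretion)
        report["calibration"] = {
            "selected": cal.selected,
            "final_growth": cal.final_growth,
            "failed_stage": cal.failed_stage,
        }
    except (KeyError, ValueError) as exc:
        report["calibration"] = {"skipped": f"{exc}"}

    omics_path = d / "omics.csv"
    if omics_path.exists():
        omics = pd.read_csv(omics_path)
        pair = optimal_thresholds(omics)
        report["thresholds"] = {
            "proteins_per_cell": pair.protein_threshold,
            "fpkm": pair.rna_threshold,
            "mcc": pair.mcc,
        }
        calls = expression_calls(omics, pair)
        consistent = {
            g: v
            for g, v in calls.items()
            if v is not None and g in {x.id for x in model.genes}
        }
        state = pfba(model)
        conf = flux_expression_confusion(active_genes(model, state), consistent)
        report["flux_expression"] = {
            "n_consistent_genes": conf.total,
            "accuracy_pct": conf.accuracy,
        }
    else:
        report["thresholds"] = {"skipped": "omics.csv not found"}

    tn_ins, tn_gro = d / "tn_insertions.csv", d / "tn_growth.csv"
    observed = None
    if tn_ins.exists() and tn_gro.exists():
        tn = TnMutantTable(
            insertions=pd.read_csv(tn_ins), growth=pd.read_csv(tn_gro)
        )
        observed = revise_essentiality(tn)
        n_essential = sum(c.essential for c in observed.values())
        report["essentiality_revision"] = {
            "n_genes_called": len(observed),
            "n_essential": n_essential,
        }
        predicted = {
            g: e for g, (_, e) in single_gene_deletions(model).items()
        }
        conf, triage = essentiality_confusion(predicted, observed)
        report["essentiality_accuracy"] = {
            "n_compared": conf.total,
            "accuracy_pct": conf.accuracy,
            "false_positives": len(triage["false_positive"]),
            "false_negatives": len(triage["false_negative"]),
        }
    else:
        report["essentiality_revision"] = {"skipped": "transposon tables not found"}

    sugars_path = d / "sugars.csv"
    if sugars_path.exists():
        sugars = pd.read_csv(sugars_path)
        table = carbohydrate_screen(
            model,
            dict(zip(sugars["sugar"], sugars["exchange_id"])),
            reference="sucrose",
            phenotypes=dict(zip(sugars["sugar"], sugars["observed_growth"].astype(bool))),
        )
        report["carbohydrate_screen"] = {
            "n_sugars": len(table),
            "n_matches": int(table["match"].sum()),
        }
    else:
        report["carbohydrate_screen"] = {"skipped": "sugars.csv not found"}

    layout_paths = [d / f"layout_{n}.tsv" for n in ("genes", "promoters", "tus")]
    if all(p.exists() for p in layout_paths) and observed is not None:
        layout = read_layout(*layout_paths)
        trace = iterate_reduction(layout, model, 0.6, n_iter=100)
        report["reduction"] = {
            "final_genome_bp": trace.genome_sizes[-1] if trace.genome_sizes else None,
            "segments": len(trace.segments),
            "deleted_genes": trace.deleted_genes[-1] if trace.deleted_genes else 0,
            "retained_genes": trace.retained_genes[-1] if trace.retained_genes else None,
        }
    else:
        report["reduction"] = {"skipped": "layout tables or essentiality calls missing"}

    text = json.dumps(report, indent=1, sort_keys=True)
    print(text)
    if args.out:
        args.out.write_text(text)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
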