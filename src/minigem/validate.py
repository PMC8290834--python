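"""Confronting model predictions with omics and transposon data.

Four validation procedures:

* **Expression thresholds.** Transcriptomic (FPKM) and proteomic
  (molecules/cell) abundances are binarized by a threshold pair (i, j)
  drawn from the observed values. Each pair is scored ``S_ij = X_ij *
  M_ij``, where ``M_ij`` is the Matthews correlation between the two
  binary vectors (transcriptomics as reference) and ``X_ij`` the number of
  genes called expressed in *both* datasets; the argmax fixes the
  expressed-gene set used downstream.
* **Flux-expression agreement.** Genes carrying flux in a parsimonious
  flux state (prediction) are compared with expression calls
  (observation) in a confusion matrix.
* **Essentiality revision.** Transposon-insertion data are re-read with a
  decision tree: mutants with unreliable growth replicates (SD > 30% of
  the mean doubling time) are dropped; remaining mutants are non-viable
  when their doubling time exceeds the cohort median + MAD; a gene is
  essential when it was never hit, hit only in its terminal 20%, or hit
  internally only by non-viable mutants.
* **Carbohydrate screen.** Each sugar's exchange is opened alone at a
  fixed uptake bound and predicted growth is normalized to a reference
  sugar, then compared with binary growth phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .biomass import ConfusionCounts, mcc
from .model import fba

__all__ = [
    "ThresholdPair",
    "TnMutantTable",
    "EssentialityCall",
    "optimal_thresholds",
    "flux_expression_confusion",
    "revise_essentiality",
    "essentiality_confusion",
    "carbohydrate_screen",
]

TERMINAL_FRACTION = 0.20
SD_FILTER_FRACTION = 0.30

LIKELY_ESSENTIAL = "likely essential"
PUTATIVE_ESSENTIAL = "putative essential"
LIKELY_NON_ESSENTIAL = "likely non-essential"
PUTATIVE_NON_ESSENTIAL = "putative non-essential"


@dataclass
class ThresholdPair:
    """Optimal expression thresholds and their score."""

    protein_threshold: float
    rna_threshold: float
    score: float
    mcc: float
    n_expressed_both: int


def _binary_calls(values: np.ndarray, threshold: float) -> np.ndarray:
    return values >= threshold


def optimal_thresholds(omics: pd.DataFrame) -> ThresholdPair:
    """Exhaustive threshold-pair search maximizing ``S = X * MCC``.

    ``omics`` needs columns ``gene``, ``fpkm``, ``proteins_per_cell``. The
    candidate grids are the sorted unique observed values of each dataset;
    ties are broken toward lower thresholds (the larger expressed set).
    """
    for col in ("fpkm", "proteins_per_cell"):
        if col not in omics.columns:
            raise ValueError(f"omics table lacks column {col!r}")
    rna = omics["fpkm"].to_numpy(dtype=float)
    prot = omics["proteins_per_cell"].to_numpy(dtype=float)
    if np.unique(rna).size < 2 or np.unique(prot).size < 2:
        raise ValueError("each dataset needs at least two distinct values")

    rna_grid = np.unique(rna)
    prot_grid = np.unique(prot)
    # boolean call matrices: rows = thresholds, columns = genes
    rna_calls = rna[None, :] >= rna_grid[:, None]
    prot_calls = prot[None, :] >= prot_grid[:, None]

    best: ThresholdPair | None = None
    for pi, p_call in zip(prot_grid, prot_calls):
        for ri, r_call in zip(rna_grid, rna_calls):
            tp = int(np.sum(p_call & r_call))
            fp = int(np.sum(p_call & ~r_call))
            fn = int(np.sum(~p_call & r_call))
            tn = int(np.sum(~p_call & ~r_call))
            m = mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            score = tp * m  # X_ij = expressed in both datasets
            if best is None or score > best.score + 1e-12:
                best = ThresholdPair(
                    protein_threshold=float(pi),
                    rna_threshold=float(ri),
                    score=float(score),
                    mcc=float(m),
                    n_expressed_both=tp,
                )
    assert best is not None
    return best


def expression_calls(
    omics: pd.DataFrame, thresholds: ThresholdPair
) -> dict[str, bool | None]:
    """Consensus expressed/silent call per gene; None when discordant."""
    out: dict[str, bool | None] = {}
    for _, row in omics.iterrows():
        rna_on = row["fpkm"] >= thresholds.rna_threshold
        prot_on = row["proteins_per_cell"] >= thresholds.protein_threshold
        out[str(row["gene"])] = bool(rna_on) if rna_on == prot_on else None
    return out


def flux_expression_confusion(
    active_genes: Iterable[str],
    expression: Mapping[str, bool],
) -> ConfusionCounts:
    """Confusion of flux activity (prediction) vs expression (observation).

    Only genes with an expression call participate. TP = expressed and
    active, TN = silent and inactive; accuracy is available on the result.
    """
    active = set(active_genes)
    genes = list(expression)
    if not genes:
        raise ValueError("no genes with expression calls")
    tp = fp = tn = fn = 0
    for gene in genes:
        is_active = gene in active
        expressed = expression[gene]
        if is_active and expressed:
            tp += 1
        elif is_active and not expressed:
            fp += 1
        elif not is_active and not expressed:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class TnMutantTable:
    """Transposon insertions plus per-mutant doubling-time statistics.

    ``insertions``: columns gene, position_fraction (0-1 along the gene),
    mutant_id (may be missing). ``growth``: columns mutant_id,
    doubling_time (h), sd (h).
    """

    insertions: pd.DataFrame
    growth: pd.DataFrame

    def __post_init__(self) -> None:
        pos = self.insertions["position_fraction"]
        if ((pos < 0) | (pos > 1)).any():
            raise ValueError("insertion positions must lie in [0, 1]")


@dataclass
class EssentialityCall:
    gene: str
    label: str

    @property
    def essential(self) -> bool:
        return self.label in (LIKELY_ESSENTIAL, PUTATIVE_ESSENTIAL)


def viability_threshold(doubling_times: np.ndarray) -> float:
    """Median + median absolute deviation of reliable doubling times."""
    med = float(np.median(doubling_times))
    mad = float(np.median(np.abs(doubling_times - med)))
    return med + mad


def revise_essentiality(
    tn: TnMutantTable,
    genes: Iterable[str] | None = None,
    terminal_fraction: float = TERMINAL_FRACTION,
    sd_filter: float = SD_FILTER_FRACTION,
) -> dict[str, EssentialityCall]:
    """Decision-tree re-reading of transposon essentiality data.

    1. keep mutants whose doubling-time SD is within ``sd_filter`` of the
       mean doubling time; 2. mutants above median + MAD of the retained
       doubling times are non-viable; 3. a gene is essential when never
       hit, hit only terminally (all insertions in the last
       ``terminal_fraction`` of its length), or hit internally only by
       non-viable mutants. Insertions without growth data count as viable
       evidence. Four-way labels record whether the call rests on measured
       growth (likely) or its absence (putative).
    """
    growth = tn.growth
    reliable = growth[growth["sd"] <= sd_filter * growth["doubling_time"]]
    nonviable_ids: set = set()
    if len(reliable):
        cutoff = viability_threshold(reliable["doubling_time"].to_numpy(dtype=float))
        nonviable_ids = set(
            reliable.loc[reliable["doubling_time"] > cutoff, "mutant_id"]
        )
    viable_ids = set(reliable["mutant_id"]) - nonviable_ids

    gene_list = list(genes) if genes is not None else sorted(
        set(tn.insertions["gene"])
    )
    by_gene = dict(tuple(tn.insertions.groupby("gene", sort=False)))
    calls: dict[str, EssentialityCall] = {}
    for gene in gene_list:
        hits = by_gene.get(gene)
        if hits is None or not len(hits):
            calls[gene] = EssentialityCall(gene, LIKELY_ESSENTIAL)
            continue
        internal = hits[hits["position_fraction"] < 1.0 - terminal_fraction]
        if not len(internal):
            calls[gene] = EssentialityCall(gene, PUTATIVE_ESSENTIAL)
            continue
        mutants = internal["mutant_id"]
        measured_viable = mutants.isin(viable_ids)
        nonviable = mutants.isin(nonviable_ids)
        if measured_viable.any():
            calls[gene] = EssentialityCall(gene, LIKELY_NON_ESSENTIAL)
        elif nonviable.all():
            # every internal hit produced a growth-impaired mutant
            calls[gene] = EssentialityCall(gene, PUTATIVE_ESSENTIAL)
        else:
            # internal hits without reliable growth data: default branch
            calls[gene] = EssentialityCall(gene, PUTATIVE_NON_ESSENTIAL)
    return calls


def essentiality_confusion(
    predicted: Mapping[str, bool],
    observed: Mapping[str, EssentialityCall] | Mapping[str, bool],
) -> tuple[ConfusionCounts, dict[str, list[str]]]:
    """Confusion of predicted vs observed essentiality.

    Restricted to genes present in both maps; returns the counts plus the
    false-positive / false-negative gene lists for refinement triage.
    """
    shared = sorted(set(predicted) & set(observed))
    if not shared:
        raise ValueError("predicted and observed gene sets are disjoint")
    tp = fp = tn = fn = 0
    fp_genes: list[str] = []
    fn_genes: list[str] = []
    for gene in shared:
        obs = observed[gene]
        obs_ess = obs.essential if isinstance(obs, EssentialityCall) else bool(obs)
        pred = bool(predicted[gene])
        if pred and obs_ess:
            tp += 1
        elif pred and not obs_ess:
            fp += 1
            fp_genes.append(gene)
        elif not pred and not obs_ess:
            tn += 1
        else:
            fn += 1
            fn_genes.append(gene)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), {
        "false_positive": fp_genes,
        "false_negative": fn_genes,
    }


def carbohydrate_screen(
    model,
    sugars: Mapping[str, str],
    reference: str,
    uptake_bound: float = 10.0,
    phenotypes: Mapping[str, bool] | None = None,
    growth_tol: float = 1e-6,
) -> pd.DataFrame:
    """Predict growth on each sugar as the sole opened carbohydrate.

    ``sugars`` maps sugar name to its exchange-reaction id. For each sugar
    all listed exchanges are closed, the tested one is opened at lower
    bound ``-uptake_bound``, and FBA growth is recorded, normalized over
    the ``reference`` sugar. When experimental binary ``phenotypes`` are
    given, a ``match`` column compares predicted growth/no-growth calls.
    """
    if reference not in sugars:
        raise ValueError(f"reference sugar {reference!r} not in the screen")

    def growth_on(name: str) -> float:
        with model:
            for ex_id in sugars.values():
                model.reactions.get_by_id(ex_id).lower_bound = 0.0
            model.reactions.get_by_id(sugars[name]).lower_bound = -uptake_bound
            state = fba(model)
        return state.objective_value if state.ok else 0.0

    ref_growth = growth_on(reference)
    if ref_growth <= growth_tol:
        raise ValueError(f"reference sugar {reference!r} supports no growth")
    rows = []
    for name in sugars:
        g = growth_on(name)
        row = {
            "sugar": name,
            "growth": g,
            "normalized_growth": g / ref_growth,
            "predicted_growth": g > growth_tol,
        }
        if phenotypes is not None and name in phenotypes:
            row["observed_growth"] = bool(phenotypes[name])
            row["match"] = row["predicted_growth"] == row["observed_growth"]
        rows.append(row)
    return pd.DataFrame(rows)
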