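"""Phenotype and gene scoring for pooled CRISPRi/a drug-resistance screens.

The per-sgRNA drug phenotype (rho) is the log2 fold change in guide
frequency between treated and vehicle arms, centered on the median of the
non-targeting controls, divided by the population-doubling difference
between the arms; rho = 1 is full resistance, 0 parental sensitivity, < 0
hypersensitivity.  gamma (vehicle vs T0) and tau (treated vs T0) are the
analogous growth phenotypes.  Genes are scored per transcription start site
by (i) the signed mean of the five strongest rho values by absolute value
and (ii) a Mann-Whitney test of all the gene's rho values against the
non-targeting controls; the TSS with the smallest p-value represents the
gene, and resistance score = mean_top_rho * (-log10 p).  Pseudo-genes built
by randomly grouping non-targeting guides calibrate the score scale, and
the cross-resistance cutoff is the smallest score at which, on average over
the pseudo-gene sets, at most one control gene scores as multi-drug
resistant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .venn import venn_counts


@dataclass
class PhenotypeResult:
    """Per-sgRNA phenotypes for one screen arm.

    ``table`` has columns gene/tss/targeting/rho/passed; ``nontargeting``
    holds the control rho values (median exactly 0 by construction).
    """

    table: pd.DataFrame
    nontargeting: np.ndarray
    arm: str
    doubling_diff: float


def sgrna_phenotypes(
    table: pd.DataFrame,
    treated_col: str,
    reference_col: str,
    doubling_diff: float,
    min_count: int = 25,
    pseudocount: int = 10,
    pseudocount_mode: Literal["all", "zeros"] = "all",
    arm: str = "",
) -> PhenotypeResult:
    """Compute rho-style phenotypes for one treated/reference column pair.

    Counts get a pseudocount (added to all counts for genome-scale screens,
    or only to zeros for the half-library preset), are converted to
    within-sample frequencies, and the log2 fold change treated/reference
    is centered on the non-targeting median and divided by the doubling
    difference.  Guides with fewer than ``min_count`` raw counts in both
    conditions are marked as failed (rho = NaN).  gamma and tau phenotypes
    are the same computation with vehicle-vs-T0 and treated-vs-T0 columns.
    """
    if doubling_diff <= 0:
        raise ValueError("doubling_diff must be positive")
    if "targeting" not in table.columns:
        raise ValueError("table must carry a 'targeting' flag column")
    nt_mask = ~table["targeting"].to_numpy(bool)
    if nt_mask.sum() == 0:
        raise ValueError("no non-targeting sgRNAs: rho is undefined")

    t_raw = table[treated_col].to_numpy(float)
    r_raw = table[reference_col].to_numpy(float)
    passed = (t_raw >= min_count) | (r_raw >= min_count)

    if pseudocount_mode == "all":
        t_adj, r_adj = t_raw + pseudocount, r_raw + pseudocount
    elif pseudocount_mode == "zeros":
        t_adj = np.where(t_raw == 0, pseudocount, t_raw)
        r_adj = np.where(r_raw == 0, pseudocount, r_raw)
    else:
        raise ValueError(f"unknown pseudocount_mode {pseudocount_mode!r}")

    lfc = np.log2((t_adj / t_adj.sum()) / (r_adj / r_adj.sum()))
    nt_median = np.median(lfc[nt_mask & passed])
    rho = (lfc - nt_median) / doubling_diff
    rho[~passed] = np.nan

    out = table[["gene", "tss", "targeting"]].copy()
    out["rho"] = rho
    out["passed"] = passed
    nt_rho = rho[nt_mask & passed]
    return PhenotypeResult(out, nt_rho[np.isfinite(nt_rho)], arm,
                           doubling_diff)


def _mean_top(values: np.ndarray, k: int) -> float:
    """Signed mean of the k values largest in absolute value."""
    if len(values) == 0:
        return float("nan")
    idx = np.argsort(-np.abs(values), kind="stable")[:k]
    return float(values[idx].mean())


def score_genes(
    phenotypes: PhenotypeResult,
    k_top: int = 5,
    min_observed: int = 8,
) -> pd.DataFrame:
    """Aggregate sgRNA phenotypes into per-gene resistance scores.

    Per gene/TSS: the signed mean of the ``k_top`` strongest rho values by
    absolute value, and the two-sided Mann-Whitney p-value of all the
    gene's rho values against the non-targeting controls (normal
    approximation with tie/continuity correction).  Genes with fewer than
    ``min_observed`` passing sgRNA phenotypes are dropped.  For
    multi-TSS genes the TSS with the lowest p-value is kept (ties broken by
    larger |mean_top_rho|, then lexicographically).  Columns:
    mean_top_rho, mw_p, resistance_score (= mean_top_rho * -log10 p),
    hypersensitivity_score (its negation), tss, n_sgrnas.
    """
    controls = phenotypes.nontargeting
    if len(controls) == 0:
        raise ValueError("no passing non-targeting sgRNAs to compare against")
    tab = phenotypes.table
    rows = []
    grouped = tab[tab["targeting"]].groupby(["gene", "tss"], sort=True)
    for (gene, tss), sub in grouped:
        rho = sub["rho"].to_numpy(float)
        rho = rho[np.isfinite(rho)]
        if len(rho) < min_observed:
            continue
        mean_top = _mean_top(rho, k_top)
        mw = stats.mannwhitneyu(rho, controls, alternative="two-sided",
                                method="asymptotic")
        p = max(float(mw.pvalue), np.finfo(float).tiny)
        rows.append((gene, tss, mean_top, p, len(rho)))
    if not rows:
        return pd.DataFrame(columns=["tss", "mean_top_rho", "mw_p",
                                     "resistance_score",
                                     "hypersensitivity_score", "n_sgrnas"])
    df = pd.DataFrame(rows, columns=["gene", "tss", "mean_top_rho", "mw_p",
                                     "n_sgrnas"])
    df["abs_top"] = df["mean_top_rho"].abs()
    df = df.sort_values(["gene", "mw_p", "abs_top", "tss"],
                        ascending=[True, True, False, True])
    df = df.drop_duplicates("gene", keep="first").set_index("gene")
    df["resistance_score"] = df["mean_top_rho"] * (-np.log10(df["mw_p"]))
    df["hypersensitivity_score"] = -df["resistance_score"]
    return df[["tss", "mean_top_rho", "mw_p", "resistance_score",
               "hypersensitivity_score", "n_sgrnas"]]


def build_control_genes(
    table: pd.DataFrame,
    n_genes: int,
    n_sets: int = 10,
    group_size: int = 10,
    seed: int = 0,
) -> list[dict[str, list[str]]]:
    """Assemble pseudo-genes from random groups of non-targeting sgRNAs.

    Each of ``n_sets`` sets contains ``n_genes`` pseudo-genes of
    ``group_size`` guides drawn without replacement within a pseudo-gene
    (guides may recur across pseudo-genes and sets).  Scored exactly like
    real genes, these calibrate the null score distribution per drug.
    """
    nt_ids = list(table.index[~table["targeting"].astype(bool)])
    if len(nt_ids) < group_size:
        raise ValueError("fewer non-targeting sgRNAs than the group size")
    rng = np.random.default_rng(seed)
    nt_arr = np.array(nt_ids)
    sets = []
    for _ in range(n_sets):
        picks = {}
        for g in range(n_genes):
            picks[f"control_{g:05d}"] = list(
                rng.choice(nt_arr, size=group_size, replace=False))
        sets.append(picks)
    return sets


def score_control_genes(
    phenotypes: PhenotypeResult,
    control_sets: Sequence[dict[str, list[str]]],
    k_top: int = 5,
    min_observed: int = 8,
) -> list[pd.DataFrame]:
    """Score each pseudo-gene set with the same rule as real genes."""
    rho = phenotypes.table["rho"]
    out = []
    for cset in control_sets:
        names = []
        vals = []
        for pseudo, ids in cset.items():
            v = rho.reindex(ids).to_numpy(float)
            names.extend([pseudo] * len(v))
            vals.append(v)
        pseudo_tab = pd.DataFrame({
            "gene": names,
            "tss": "pseudo",
            "targeting": True,
            "rho": np.concatenate(vals),
        })
        pseudo_tab["passed"] = np.isfinite(pseudo_tab["rho"])
        res = score_genes(
            PhenotypeResult(pseudo_tab, phenotypes.nontargeting,
                            phenotypes.arm, phenotypes.doubling_diff),
            k_top=k_top, min_observed=min_observed)
        out.append(res)
    return out


def select_cutoff(
    control_scores_by_drug: Mapping[str, Sequence[pd.DataFrame]],
    target_mean_false: float = 1.0,
    step: float = 0.01,
    score_col: str = "resistance_score",
) -> float:
    """Smallest score cutoff leaving <= ``target_mean_false`` multi-drug
    control genes on average over the pseudo-gene sets.

    For each control set, a pseudo-gene counts as falsely multi-drug
    resistant when its score exceeds the cutoff in two or more drugs; the
    cutoff grid is scanned in ``step`` increments from ``step`` upward.
    Raising the cutoff never increases the count, so the smallest
    qualifying cutoff is well defined.
    """
    drugs = list(control_scores_by_drug)
    n_sets = {len(v) for v in control_scores_by_drug.values()}
    if len(n_sets) != 1:
        raise ValueError("every drug needs the same number of control sets")
    (n_sets,) = n_sets
    second_best: list[np.ndarray] = []
    for s in range(n_sets):
        merged = pd.DataFrame(
            {d: control_scores_by_drug[d][s][score_col] for d in drugs})
        arr = merged.to_numpy(float)
        arr = np.where(np.isfinite(arr), arr, -np.inf)
        arr.sort(axis=1)
        second_best.append(arr[:, -2] if arr.shape[1] >= 2 else
                           np.full(len(arr), -np.inf))
    pooled = np.sort(np.concatenate(second_best))
    top = pooled[-1] if len(pooled) else 0.0
    cutoffs = np.arange(step, max(top, step) + 2 * step, step)
    # mean count of pseudo-genes whose 2nd-best score reaches the cutoff
    counts = (len(pooled) - np.searchsorted(pooled, cutoffs,
                                            side="left")) / n_sets
    ok = counts <= target_mean_false
    if not ok.any():
        raise RuntimeError(
            f"no cutoff up to {cutoffs[-1]:.2f} meets the criterion; "
            f"minimum mean false count {counts.min():.2f}")
    return float(np.round(cutoffs[int(np.argmax(ok))], 10))


def call_cross_resistance(
    scores_by_drug: Mapping[str, pd.DataFrame],
    cutoff: float,
    score_col: str = "resistance_score",
    hypersensitivity_col: str = "hypersensitivity_score",
) -> dict:
    """Cross-resistance and cross-hypersensitivity calls at a score cutoff.

    Returns per-drug resistant gene sets with their Venn tallies, the same
    machinery applied to hypersensitivity scores, and collateral pairs:
    genes resistant to one drug and hypersensitive to another, reported as
    (gene, resistant_drug, hypersensitive_drug) with the fraction of
    resistance genes involved.
    """
    res_sets = {d: set(df.index[df[score_col] >= cutoff])
                for d, df in scores_by_drug.items()}
    hyp_sets = {d: set(df.index[df[hypersensitivity_col] >= cutoff])
                for d, df in scores_by_drug.items()}
    collateral = []
    for d_res, genes in res_sets.items():
        for d_hyp, hgenes in hyp_sets.items():
            if d_res == d_hyp:
                continue
            for g in sorted(genes & hgenes):
                collateral.append((g, d_res, d_hyp))
    all_res_genes = set().union(*res_sets.values()) if res_sets else set()
    collateral_genes = {g for g, _, _ in collateral}
    return {
        "cutoff": cutoff,
        "resistance": {"sets": res_sets, **venn_counts(res_sets)},
        "hypersensitivity": {"sets": hyp_sets, **venn_counts(hyp_sets)},
        "collateral_pairs": collateral,
        "collateral_fraction": (len(collateral_genes) / len(all_res_genes)
                                if all_res_genes else 0.0),
    }


def screen_resistance_frequencies(
    scores_by_drug: Mapping[str, pd.DataFrame],
    cutoff: float,
    score_col: str = "resistance_score",
) -> dict:
    """Single-drug counts and pairwise-overlap average for xi estimation.

    Returns per-drug resistant gene counts, the average observed two-drug
    overlap, and the number of scored genes (the common denominator).
    """
    sets = {d: set(df.index[df[score_col] >= cutoff])
            for d, df in scores_by_drug.items()}
    drugs = sorted(sets)
    pair_overlaps = {}
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            pair_overlaps[(a, b)] = len(sets[a] & sets[b])
    n_genes = len(next(iter(scores_by_drug.values())).index)
    return {
        "counts": {d: len(sets[d]) for d in drugs},
        "pair_overlaps": pair_overlaps,
        "mean_pair_overlap": (float(np.mean(list(pair_overlaps.values())))
                              if pair_overlaps else 0.0),
        "n_genes": n_genes,
    }
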