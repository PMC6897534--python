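"""Barcode enrichment statistics for clone-tracing selection experiments.

A clone's resistance to a drug is scored by how reproducibly its barcode is
enriched across replicate cultures: per replicate, enrichment is the
post-treatment barcode frequency divided by the pretreatment frequency
(after flooring rare pretreatment counts at a low quantile so that barcodes
with a handful of reads cannot score as massively enriched); replicates are
merged by the geometric mean with each replicate floored at 1, which
strongly penalizes stochastic, irreproducible enrichment; and scores are
divided by the barcode's vehicle (DMSO) enrichment when that exceeds 1, to
discount drug-independent fitness differences.  False discovery rates for
single- and multi-drug enrichment are estimated from a null built by
scrambling barcode identities within each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .venn import venn_counts

DEFAULT_THRESHOLDS = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


def floor_pretreatment(
    table: pd.DataFrame,
    pretreatment_col: str = "pretreatment",
    quantile: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Raise low pretreatment counts to the column's ``quantile`` value.

    Only the pretreatment column is modified; returns the floored table and
    the floor used.  An all-zero pretreatment column is an error.
    """
    counts = table[pretreatment_col].to_numpy()
    if counts.sum() == 0:
        raise ValueError("pretreatment sample has no counts")
    floor = float(np.quantile(counts, quantile, method="lower"))
    out = table.copy()
    out[pretreatment_col] = np.maximum(counts, floor).astype(table[
        pretreatment_col].dtype)
    return out, floor


def replicate_enrichment(
    table: pd.DataFrame,
    pretreatment_col: str = "pretreatment",
    sample_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-barcode, per-sample frequency ratio against pretreatment.

    Frequencies are counts divided by the column total; enrichment is
    post-treatment frequency over pretreatment frequency.  Apply
    :func:`floor_pretreatment` first so rare pretreatment barcodes do not
    blow up.
    """
    if sample_cols is None:
        sample_cols = [c for c in table.columns if c != pretreatment_col]
    pre = table[pretreatment_col].to_numpy(float)
    if pre.sum() == 0:
        raise ValueError("pretreatment sample has no counts")
    pre_freq = pre / pre.sum()
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in sample_cols:
            post = table[col].to_numpy(float)
            total = post.sum()
            post_freq = post / total if total > 0 else post
            out[col] = np.where(pre_freq > 0, post_freq / pre_freq, np.inf)
    return pd.DataFrame(out, index=table.index)


def _geomean_floored(ratios: np.ndarray) -> np.ndarray:
    """Geometric mean across columns with each value floored at 1."""
    floored = np.maximum(ratios, 1.0)
    return np.exp(np.log(floored).mean(axis=1))


def aggregate_enrichment(
    ratios: pd.DataFrame,
    drug_replicates: Mapping[str, Sequence[str]],
    vehicle: str = "DMSO",
    dmso_mode: Literal["aggregate", "per_replicate"] = "aggregate",
) -> pd.DataFrame:
    """Merge replicate enrichments into one score per barcode per drug.

    Each replicate's ratio is floored at 1 (a barcode absent from one
    flask's inoculum should not be annihilated), then the geometric mean is
    taken.  The resulting drug score is divided by the barcode's vehicle
    geometric-mean enrichment only when that exceeds 1; vehicle depletion
    never inflates a drug score.  ``dmso_mode='per_replicate'`` instead
    divides each replicate ratio by the matching vehicle replicate (when
    > 1) before aggregation.
    """
    missing = {d: [c for c in cols if c not in ratios.columns]
               for d, cols in drug_replicates.items()}
    missing = {d: m for d, m in missing.items() if m}
    if missing:
        warnings.warn(f"missing replicate columns: {missing}; "
                      "aggregating over available ones", stacklevel=2)
    scores = {}
    veh_cols = list(drug_replicates.get(vehicle, []))
    veh_ratio = (ratios[veh_cols].to_numpy(float)
                 if veh_cols else np.empty((len(ratios), 0)))
    veh_score = (_geomean_floored(veh_ratio) if veh_cols
                 else np.ones(len(ratios)))
    for drug, cols in drug_replicates.items():
        cols = [c for c in cols if c in ratios.columns]
        if not cols:
            continue
        vals = ratios[cols].to_numpy(float)
        if drug == vehicle:
            scores[drug] = veh_score
            continue
        if dmso_mode == "per_replicate" and veh_cols:
            k = min(vals.shape[1], veh_ratio.shape[1])
            adj = vals.copy()
            adj[:, :k] = adj[:, :k] / np.maximum(veh_ratio[:, :k], 1.0)
            scores[drug] = _geomean_floored(adj)
        else:
            scores[drug] = (_geomean_floored(vals)
                            / np.maximum(veh_score, 1.0))
    return pd.DataFrame(scores, index=ratios.index)


@dataclass
class FdrCurve:
    """Expected-false vs observed counts over an enrichment threshold grid.

    ``expected`` / ``observed`` / ``fdr_raw`` / ``fdr`` are DataFrames
    indexed by threshold with one column per multiplicity (number of drugs
    in which a barcode exceeds the threshold).  ``fdr`` is regularized to
    be non-increasing in threshold by a right-to-left cumulative maximum;
    the raw curve is kept alongside.
    """

    thresholds: np.ndarray
    expected: pd.DataFrame
    observed: pd.DataFrame
    fdr_raw: pd.DataFrame
    fdr: pd.DataFrame
    n_scrambles: int
    mode: str

    def at(self, threshold: float, multiplicity: int) -> float:
        return float(self.fdr.loc[threshold, multiplicity])


def _counts_by_multiplicity(scores: pd.DataFrame,
                            thresholds: np.ndarray) -> pd.DataFrame:
    """Barcodes scoring >= t in >= m drugs, for each t and m."""
    drugs = list(scores.columns)
    arr = scores.to_numpy(float)
    out = np.zeros((len(thresholds), len(drugs)), dtype=float)
    for i, t in enumerate(thresholds):
        n_above = (arr >= t).sum(axis=1)
        for m in range(1, len(drugs) + 1):
            out[i, m - 1] = np.count_nonzero(n_above >= m)
    return pd.DataFrame(out, index=thresholds,
                        columns=range(1, len(drugs) + 1))


def _poisson_binomial_tail(probs: np.ndarray) -> np.ndarray:
    """P(X >= m) for m = 1..n where X counts successes with given probs."""
    n = len(probs)
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= (1 - p)
    tail = np.cumsum(pmf[::-1])[::-1]
    return tail[1:]


def scrambled_error_model(
    ratios: pd.DataFrame,
    drug_replicates: Mapping[str, Sequence[str]],
    n_scrambles: int = 1000,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    vehicle: str = "DMSO",
    dmso_mode: Literal["aggregate", "per_replicate"] = "aggregate",
    mode: Literal["permute", "independent"] = "permute",
    observed_scores: pd.DataFrame | None = None,
) -> FdrCurve:
    """Estimate enrichment FDR from a scrambled-identity null.

    ``permute`` mode scrambles barcode labels independently within every
    replicate column, re-applies the aggregation rule, and averages the
    counts above each threshold over ``n_scrambles`` rounds — each
    replicate's marginal distribution is preserved exactly.  ``independent``
    mode instead estimates each drug's null score distribution from the
    scrambles and combines drugs analytically (Poisson-binomial), emulating
    an effectively unbounded number of scrambled triplicates.  FDR at a
    threshold and multiplicity is expected false count / max(observed, 1),
    clipped to 1 and monotonized from the right.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    rng = np.random.default_rng(seed)
    thresholds = np.asarray(sorted(thresholds), float)
    drugs = [d for d in drug_replicates if d != vehicle]
    if observed_scores is None:
        observed_scores = aggregate_enrichment(
            ratios, drug_replicates, vehicle=vehicle, dmso_mode=dmso_mode)
    observed = _counts_by_multiplicity(observed_scores[drugs], thresholds)

    n = len(ratios)
    if mode == "permute":
        total = np.zeros((len(thresholds), len(drugs)))
        for _ in range(n_scrambles):
            scrambled = pd.DataFrame(
                {c: rng.permutation(ratios[c].to_numpy())
                 for c in ratios.columns}, index=ratios.index)
            scores = aggregate_enrichment(
                scrambled, drug_replicates, vehicle=vehicle,
                dmso_mode=dmso_mode)
            total += _counts_by_multiplicity(scores[drugs],
                                             thresholds).to_numpy()
        expected = pd.DataFrame(total / n_scrambles, index=thresholds,
                                columns=range(1, len(drugs) + 1))
    else:
        # estimate per-drug null exceedance, then combine analytically:
        # scrambled drug scores are independent across drugs per barcode
        exceed = np.zeros((len(thresholds), len(drugs)))
        for j, d in enumerate(drugs):
            cols = [c for c in drug_replicates[d] if c in ratios.columns]
            null_scores = []
            for _ in range(n_scrambles):
                vals = np.column_stack(
                    [rng.permutation(ratios[c].to_numpy(float))
                     for c in cols])
                s = _geomean_floored(vals)
                if dmso_mode == "aggregate" and vehicle in drug_replicates:
                    vcols = [c for c in drug_replicates[vehicle]
                             if c in ratios.columns]
                    v = _geomean_floored(np.column_stack(
                        [rng.permutation(ratios[c].to_numpy(float))
                         for c in vcols]))
                    s = s / np.maximum(v, 1.0)
                null_scores.append(s)
            pooled = np.concatenate(null_scores)
            exceed[:, j] = [(pooled >= t).mean() for t in thresholds]
        rows = [n * _poisson_binomial_tail(exceed[i]) for i in
                range(len(thresholds))]
        expected = pd.DataFrame(np.vstack(rows), index=thresholds,
                                columns=range(1, len(drugs) + 1))

    fdr_raw = expected / observed.clip(lower=1)
    fdr_raw = fdr_raw.clip(upper=1.0)
    fdr = fdr_raw.iloc[::-1].cummax().iloc[::-1]
    return FdrCurve(thresholds, expected, observed, fdr_raw, fdr,
                    n_scrambles, mode)


def call_resistance(
    scores: pd.DataFrame,
    threshold: float = 10.0,
    drugs: Sequence[str] | None = None,
) -> dict:
    """Call per-drug resistant barcodes and tabulate multi-drug overlaps.

    A barcode is resistant to a drug when its aggregated enrichment score
    is at least ``threshold``.  Returns per-drug sets, exact Venn-region
    counts for every drug subset, and single/double/... multiplicity
    tallies.
    """
    if drugs is None:
        drugs = [c for c in scores.columns if c != "DMSO"]
    sets = {d: set(scores.index[scores[d] >= threshold]) for d in drugs}
    return {"threshold": threshold, "sets": sets, **venn_counts(sets)}
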