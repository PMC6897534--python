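"""Quantitative model of multi-drug resistance under low cross-resistance.

Implements the Law/Frei arithmetic used throughout the pipeline: theoretical
bounds on the frequency of multi-drug resistance (MDR), the cross-resistance
parameter ``xi`` locating an observed MDR frequency between those bounds,
deterministic log-kill bookkeeping, and the design arithmetic for clone
coverage and growth-based selection.

Conventions
-----------
If one cell in ``10**A`` resists drug *a* and one in ``10**B`` resists drug
*b*, then with independent resistance mechanisms about one cell in
``10**(A+B)`` resists both (the theoretical minimum, ``xi = 0``); the
theoretical maximum is the smaller of the two single-drug frequencies
(``xi = 1``).  Any observed MDR frequency is expressed as a weighted sum

    MDR = xi * max_mdr + (1 - xi) * min_mdr

and solved for ``xi``.  The same formula applies to counts (e.g. numbers of
resistant genes in a screen) provided all quantities share one denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class CrossResistanceResult:
    """Estimated cross-resistance for one drug set.

    ``single_freqs`` are per-drug resistance frequencies (or counts on a
    common denominator); ``min_mdr``/``max_mdr`` the theoretical bounds;
    ``xi`` the mixture weight.  ``out_of_range`` is set when the observed
    MDR fell outside the bounds (possible with sampling noise) and ``xi``
    was clamped to [0, 1].
    """

    drug_set: tuple[str, ...]
    single_freqs: tuple[float, ...]
    observed_mdr: float
    min_mdr: float
    max_mdr: float
    xi: float
    out_of_range: bool = False
    undefined: bool = False


@dataclass
class LogKillModel:
    """Deterministic fractional-kill model: survivors = p0 * prod(f_i)."""

    p0: float
    surviving_fractions: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError("initial population p0 must be positive")
        for f in self.surviving_fractions:
            if not (0 < f <= 1):
                raise ValueError(f"surviving fraction {f} not in (0, 1]")


def mdr_bounds(single_freqs: Sequence[float]) -> tuple[float, float]:
    """Theoretical (minimum, maximum) multi-drug resistance frequency.

    Minimum = product of single-drug frequencies (independent mechanisms);
    maximum = smallest single-drug frequency (fully nested resistance).
    """
    freqs = [float(f) for f in single_freqs]
    if not freqs:
        raise ValueError("at least one single-drug frequency is required")
    for f in freqs:
        if f <= 0:  # counts > 1 are allowed; zero/negative are not
            raise ValueError(f"frequency {f} must be positive")
    lo = math.prod(freqs)
    hi = min(freqs)
    return lo, hi


def xi_from_bounds(
    min_mdr: float,
    max_mdr: float,
    observed_mdr: float,
    drug_set: Sequence[str] = (),
    single_freqs: Sequence[float] = (),
) -> CrossResistanceResult:
    """Solve MDR = xi*max + (1-xi)*min for xi, given explicit bounds.

    Equivalently xi = (min - observed) / (min - max).  Used directly when
    the bounds are known as counts (screen analyses) rather than derived
    from frequencies.
    """
    if min_mdr > max_mdr:
        raise ValueError("min_mdr must not exceed max_mdr")
    if min_mdr == max_mdr:
        return CrossResistanceResult(
            tuple(drug_set), tuple(single_freqs), observed_mdr,
            min_mdr, max_mdr, float("nan"), undefined=True,
        )
    xi = (min_mdr - observed_mdr) / (min_mdr - max_mdr)
    out = not (0.0 <= xi <= 1.0)
    return CrossResistanceResult(
        tuple(drug_set), tuple(single_freqs), observed_mdr,
        min_mdr, max_mdr, min(1.0, max(0.0, xi)), out_of_range=out,
    )


def estimate_xi(
    single_freqs: Sequence[float],
    observed_mdr: float,
    drug_set: Sequence[str] = (),
) -> CrossResistanceResult:
    """Estimate the cross-resistance parameter xi for a drug set.

    ``single_freqs`` and ``observed_mdr`` must share a denominator: either
    all frequencies, or all counts over one population.  For more than two
    drugs the minimum is the product over all drugs and the maximum the
    overall smallest frequency (the natural extension of the two-drug
    weighted-sum form).
    """
    lo, hi = mdr_bounds(single_freqs)
    return xi_from_bounds(lo, hi, observed_mdr, drug_set=drug_set,
                          single_freqs=single_freqs)


def xi_table(sets, denominator: int, max_order: int | None = None):
    """Estimate xi for every drug subset of size >= 2 from resistant sets.

    ``sets`` maps drug name -> set of resistant items (barcodes or genes);
    ``denominator`` is the common population size.  Returns a list of
    :class:`CrossResistanceResult` plus arithmetic and geometric summaries
    of the in-range xi values (both are reported because per-set xi spans
    orders of magnitude).
    """
    import itertools

    drugs = sorted(sets)
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    max_order = max_order or len(drugs)
    results: list[CrossResistanceResult] = []
    for size in range(2, min(max_order, len(drugs)) + 1):
        for combo in itertools.combinations(drugs, size):
            freqs = [len(sets[d]) / denominator for d in combo]
            if any(f == 0 for f in freqs):
                continue
            inter = set.intersection(*(sets[d] for d in combo))
            results.append(estimate_xi(freqs, len(inter) / denominator,
                                       drug_set=combo))
    valid = [r.xi for r in results if not r.undefined]
    summary = {
        "mean_xi": float(sum(valid) / len(valid)) if valid else float("nan"),
        "geometric_mean_xi": (
            math.exp(sum(math.log(max(x, 1e-12)) for x in valid)
                     / len(valid)) if valid else float("nan")),
        "n_sets": len(results),
    }
    return results, summary


def survivors(model: LogKillModel) -> dict:
    """Expected survivors of a multi-drug treatment and per-drug log-kills.

    Survivors = p0 * prod(f_i); log-kills (-log10 f_i) add arithmetically.
    """
    surv = model.p0 * math.prod(model.surviving_fractions)
    log_kills = [-math.log10(f) for f in model.surviving_fractions]
    return {
        "survivors": surv,
        "log_kills": log_kills,
        "total_log_kill": sum(log_kills),
    }


def clone_coverage(n_clones: int, n_cells_sampled: int) -> float:
    """Expected fraction of clones represented in a random sample of cells.

    Assumes equal clone abundance and independent assortment:
    1 - (1 - 1/n)**m.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_cells_sampled < 0:
        raise ValueError("n_cells_sampled must be >= 0")
    if n_cells_sampled == 0:
        return 0.0
    return -math.expm1(n_cells_sampled * math.log1p(-1.0 / n_clones))


def growth_selection_enrichment(inhibition: float, divisions: float) -> float:
    """Fold enrichment of a fully resistant clone under growth inhibition.

    A clone that ignores a treatment slowing everyone else's growth by
    ``inhibition`` gains (1/(1-inhibition))**divisions in relative
    abundance over ``divisions`` population doublings.
    """
    if not 0 <= inhibition < 1:
        raise ValueError("inhibition must be in [0, 1)")
    return (1.0 / (1.0 - inhibition)) ** divisions


def unique_barcode_fraction(n_clones: int, library_size: int) -> float:
    """Expected fraction of clones carrying a barcode shared with no other.

    Under uniform random barcode assignment each clone is unique with
    probability (1 - 1/library)**(n_clones - 1).
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_clones == 1:
        return 1.0
    return math.exp((n_clones - 1) * math.log1p(-1.0 / library_size))
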