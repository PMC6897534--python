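"""Synthetic dose-response surfaces, clone-tracing runs and CRISPR screens.

Every downstream statistic in this package is exercised against data with
known ground truth generated here.  The generators mirror the study designs
they stand in for:

* **Checkerboards** — 11 x 11 grids of log-spaced doses spanning a 100-fold
  range per drug, built from Hill-type single-drug kill curves combined
  under a configurable null (Bliss product of survivals, Loewe dose
  equivalence, or margin-preserving antagonism), with multiplicative
  log-normal noise.  Plate spatial effects are not modeled (randomized
  layouts convert them to random error in the real assay).
* **Clone tracing** — a barcoded clonal population with per-drug resistance
  at configurable frequencies and a generative cross-resistance coupling
  ``xi``, pushed through replicate drug bottlenecks (binomial survival),
  deterministic exponential regrowth and multinomial sequencing sampling.
* **CRISPR screens** — a genome-scale library (10 sgRNAs per gene plus
  ~4000 non-targeting controls) in which a gene's true rho effect,
  attenuated by per-sgRNA efficacy, acts as a selection coefficient per
  population doubling, read out by multinomial sequencing of T0, vehicle
  and treated arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import DoseResponseSurface
from .io import SampleSheet


@dataclass
class HillCurve:
    """Single-drug kill curve: kill(c) = max_kill * c^h / (c^h + ic50^h)."""

    ic50: float
    hill_slope: float = 1.0
    max_kill: float = 1.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.hill_slope <= 0:
            raise ValueError("ic50 and hill_slope must be positive")
        if not 0 <= self.max_kill <= 1:
            raise ValueError("max_kill must be in [0, 1]")

    def kill(self, dose):
        dose = np.asarray(dose, float)
        with np.errstate(divide="ignore"):
            ratio = (dose / self.ic50) ** self.hill_slope
        return self.max_kill * ratio / (1.0 + ratio)

    def survival(self, dose):
        return 1.0 - self.kill(dose)


def _lognormal_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def checkerboard_doses(curve: HillCurve, n_doses: int = 11,
                       fold_range: float = 100.0) -> np.ndarray:
    """Zero dose plus ``n_doses`` log-spaced doses spanning ``fold_range``
    centered on the curve's IC50."""
    half = math.sqrt(fold_range)
    pos = np.logspace(math.log10(curve.ic50 / half),
                      math.log10(curve.ic50 * half), n_doses)
    return np.concatenate([[0.0], pos])


def combined_survival(
    curves: Sequence[HillCurve],
    concs: np.ndarray,
    interaction: Literal["bliss", "loewe", "antagonism"] = "bliss",
    antagonism_alpha: float = 0.5,
) -> np.ndarray:
    """Noise-free survival of a drug mixture under a chosen interaction rule.

    ``concs`` has one column per drug.  Under ``bliss`` survival is the
    product of single-drug survivals.  Under ``loewe`` the concentrations
    act as a potency-normalized summed dose on the first curve (exact dose
    equivalence for parallel Hill curves; a drug combined with itself is a
    sham combination).  ``antagonism`` inflates Bliss survival off-margin by
    ``1 + alpha * kill_a * kill_b...`` while leaving single-drug margins
    untouched.
    """
    concs = np.atleast_2d(np.asarray(concs, float))
    if concs.shape[1] != len(curves):
        raise ValueError("one concentration column per drug is required")
    if interaction == "loewe":
        ref = curves[0]
        eq = sum(concs[:, i] * (ref.ic50 / c.ic50)
                 for i, c in enumerate(curves))
        return ref.survival(eq)
    survs = np.column_stack([c.survival(concs[:, i])
                             for i, c in enumerate(curves)])
    bliss = survs.prod(axis=1)
    if interaction == "bliss":
        return bliss
    if interaction == "antagonism":
        kills = 1.0 - survs
        return np.minimum(1.0, bliss * (1.0 + antagonism_alpha
                                        * kills.prod(axis=1)))
    raise ValueError(f"unknown interaction rule {interaction!r}")


def simulate_checkerboard(
    curve_a: HillCurve,
    curve_b: HillCurve,
    interaction: Literal["bliss", "loewe", "antagonism"] = "bliss",
    n_doses: int = 11,
    fold_range: float = 100.0,
    noise_cv: float = 0.0,
    control_doublings: float = 3.0,
    seed: int = 0,
    drug_names: tuple[str, str] = ("drug_a", "drug_b"),
    antagonism_alpha: float = 0.5,
) -> DoseResponseSurface:
    """Simulate a two-drug checkerboard including zero-dose margins.

    Doses are log-spaced over ``fold_range`` centered on each IC50 (11
    points per axis by default); relative viability is the interaction
    rule's survival times multiplicative log-normal noise with coefficient
    of variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    ax_a = checkerboard_doses(curve_a, n_doses, fold_range)
    ax_b = checkerboard_doses(curve_b, n_doses, fold_range)
    aa, bb = np.meshgrid(ax_a, ax_b, indexing="ij")
    concs = np.column_stack([aa.ravel(), bb.ravel()])
    surv = combined_survival([curve_a, curve_b], concs, interaction,
                             antagonism_alpha).reshape(aa.shape)
    surv = surv * _lognormal_noise(rng, surv.shape, noise_cv)
    return DoseResponseSurface(drug_names, (ax_a, ax_b), surv,
                               control_doublings)


def simulate_mixture_response(
    curves: Mapping[str, HillCurve],
    weights: Sequence[float],
    totals: np.ndarray,
    interaction: Literal["bliss", "loewe", "antagonism"] = "loewe",
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose response of a fixed-ratio mixture along a total-dose gradient.

    Returns a DataFrame with a ``dose`` column and ``rep1..repN`` viability
    columns, ready for :func:`combokill.interactions.compute_fic`.
    """
    rng = np.random.default_rng(seed)
    totals = np.asarray(totals, float)
    w = np.asarray(weights, float)
    concs = totals[:, None] * w[None, :]
    surv = combined_survival(list(curves.values()), concs, interaction)
    out = {"dose": totals}
    for r in range(n_replicates):
        out[f"rep{r + 1}"] = surv * _lognormal_noise(rng, surv.shape,
                                                     noise_cv)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# clone tracing
# ---------------------------------------------------------------------------

@dataclass
class CloneUniverse:
    """Ground-truth clonal population for clone-tracing simulations.

    ``resistance_freqs`` gives the marginal frequency of resistant clones
    per drug; ``true_xi`` couples resistant sets pairwise: a clone in the
    larger set belongs to the smaller with probability
    ``xi * f_small / f_large + (1 - xi) * f_small`` (and with probability
    ``(1 - xi) * f_small`` otherwise), so that the expected doubly-resistant
    frequency is exactly ``xi * min + (1 - xi) * product`` — the same
    weighted-sum form the xi estimator solves.  ``resistant_survival`` and
    ``sensitive_survival`` are per-cell survival probabilities of one drug
    pulse; ``fitness`` multiplies a clone's regrowth between pulses.
    """

    n_clones: int = 100_000
    resistance_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"R": 2e-3, "C": 5e-3, "H": 5e-3, "O": 1e-2})
    true_xi: float = 0.0
    resistant_survival: float = 0.5
    sensitive_survival: float = 0.005
    fitness_cv: float = 0.0
    seed: int = 0

    resistant: pd.DataFrame = field(init=False)
    fitness: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.true_xi <= 1:
            raise ValueError("true_xi must be in [0, 1]")
        for d, f in self.resistance_freqs.items():
            if not 0 < f < 1:
                raise ValueError(f"resistance frequency for {d} not in (0,1)")
        rng = np.random.default_rng(self.seed)
        drugs = sorted(self.resistance_freqs,
                       key=lambda d: -self.resistance_freqs[d])
        n = self.n_clones
        flags = {}
        prev = None
        for d in drugs:  # descending frequency: nest smaller sets in larger
            f = self.resistance_freqs[d]
            if prev is None:
                flags[d] = rng.random(n) < f
            else:
                f_prev = self.resistance_freqs[prev]
                p_in = self.true_xi * f / f_prev + (1 - self.true_xi) * f
                p_out = (1 - self.true_xi) * f
                p = np.where(flags[prev], p_in, p_out)
                flags[d] = rng.random(n) < p
            prev = d
        index = [f"bc{i:07d}" for i in range(n)]
        self.resistant = pd.DataFrame(flags, index=index)[
            sorted(self.resistance_freqs)]
        self.fitness = (_lognormal_noise(rng, n, self.fitness_cv)
                        if self.fitness_cv > 0 else np.ones(n))

    def survival_probs(self, drug: str) -> np.ndarray:
        if drug == "DMSO":
            return np.ones(self.n_clones)
        return np.where(self.resistant[drug].to_numpy(),
                        self.resistant_survival, self.sensitive_survival)


@dataclass
class TracingDesign:
    """Treatment plan for a clone-tracing experiment."""

    drugs: tuple[str, ...] = ("C", "H", "O", "R")
    n_replicates: int = 3
    inoculum: int = 1_200_000  # 12-fold coverage of 1e5 clones
    rounds: int = 2
    regrowth_factor: float = 2.0
    depth: int = 1_000_000
    pretreatment_depth: int = 20_000_000
    include_vehicle: bool = True


def simulate_clone_tracing(
    universe: CloneUniverse,
    design: TracingDesign | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet, dict]:
    """Simulate a barcoded selection experiment in replicate.

    Per flask: a multinomial inoculum is drawn from the clone pool, each
    cell survives a drug pulse with its clone's survival probability,
    survivors regrow deterministically (fitness-weighted exponential) to
    ``regrowth_factor`` times the inoculum, and the cycle repeats; final
    abundances are read out by multinomial sequencing at ``depth`` reads.
    The pretreatment sample is sequenced from the common pool.  Returns the
    count table, a sample sheet, and ground truth (resistant sets and any
    extinct flasks).
    """
    design = design or TracingDesign()
    rng = np.random.default_rng(seed)
    n = universe.n_clones
    pool_freq = universe.fitness / universe.fitness.sum()

    columns: dict[str, np.ndarray] = {}
    samples: dict[str, dict] = {}
    extinct: list[str] = []

    columns["pretreatment"] = rng.multinomial(design.pretreatment_depth,
                                              pool_freq)
    samples["pretreatment"] = {"drug": "none", "replicate": 1,
                               "timepoint": "pretreatment"}

    drugs = list(design.drugs)
    if design.include_vehicle and "DMSO" not in drugs:
        drugs.append("DMSO")
    for drug in drugs:
        p_surv = universe.survival_probs(drug)
        for rep in range(1, design.n_replicates + 1):
            abundance = rng.multinomial(design.inoculum, pool_freq).astype(
                float)
            for _ in range(design.rounds):
                cells = rng.binomial(abundance.astype(np.int64), p_surv)
                total = cells.sum()
                if total == 0:
                    abundance = np.zeros(n)
                    break
                grown = cells * universe.fitness
                target = design.regrowth_factor * design.inoculum
                abundance = np.round(grown * (target / grown.sum()))
            sid = f"{drug}_r{rep}"
            if abundance.sum() == 0:
                extinct.append(sid)
                columns[sid] = np.zeros(n, dtype=np.int64)
            else:
                columns[sid] = rng.multinomial(
                    design.depth, abundance / abundance.sum())
            samples[sid] = {"drug": drug, "replicate": rep,
                            "timepoint": "post_treatment"}

    table = pd.DataFrame(columns, index=universe.resistant.index)
    table.index.name = "barcode"
    truth = {
        "resistant": universe.resistant,
        "extinct_flasks": extinct,
        "true_xi": universe.true_xi,
    }
    return table, SampleSheet(samples), truth


# ---------------------------------------------------------------------------
# CRISPR screens
# ---------------------------------------------------------------------------

@dataclass
class ScreenUniverse:
    """Ground truth for a pooled CRISPRi/a-style screen.

    ``true_rho`` is a genes x drugs table of per-gene resistance effects
    (rho units: log2 enrichment per population doubling for a perfect
    guide); non-targeting sgRNAs have zero effect by construction.
    Per-sgRNA ``efficacy`` in [0, 1] attenuates the gene effect.
    """

    true_rho: pd.DataFrame
    sgrnas_per_gene: int = 10
    n_nontargeting: int = 4000
    efficacy_range: tuple[float, float] = (1.0, 1.0)
    abundance_cv: float = 0.3
    doublings: Mapping[str, float] = field(
        default_factory=lambda: {"O": 7.60, "C": 9.34, "H": 7.41, "R": 7.53})
    seed: int = 0

    sgrna_table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        genes = list(self.true_rho.index)
        rows = []
        for g in genes:
            for k in range(self.sgrnas_per_gene):
                rows.append((f"{g}_sg{k}", g, "P1", True))
        for k in range(self.n_nontargeting):
            rows.append((f"non-targeting_{k:05d}", "negative_control",
                         "none", False))
        tab = pd.DataFrame(rows, columns=["sgrna_id", "gene", "tss",
                                          "targeting"]).set_index("sgrna_id")
        lo, hi = self.efficacy_range
        eff = rng.uniform(lo, hi, len(tab))
        eff[~tab["targeting"].to_numpy()] = 0.0
        tab["efficacy"] = eff
        tab["abundance"] = _lognormal_noise(rng, len(tab), self.abundance_cv)
        self.sgrna_table = tab


def simulate_crispr_screen(
    universe: ScreenUniverse,
    arms: Sequence[str] | None = None,
    depth: int = 2_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet, dict]:
    """Simulate sgRNA counts for T0, vehicle and drug-treated arms.

    In a treated arm a guide's abundance is multiplied by
    ``2 ** (efficacy * true_rho * doublings)`` relative to vehicle — i.e.
    the gene effect acts as a selection coefficient per population doubling
    difference — and each arm is sequenced by multinomial sampling at
    ``depth`` reads.  Requires non-targeting controls (phenotype
    normalization is undefined without them).
    """
    tab = universe.sgrna_table
    if (~tab["targeting"]).sum() == 0:
        raise ValueError("screen universe has no non-targeting sgRNAs")
    arms = list(arms) if arms is not None else list(universe.doublings)
    rng = np.random.default_rng(seed)
    base = tab["abundance"].to_numpy()
    counts: dict[str, np.ndarray] = {}
    samples: dict[str, dict] = {}

    counts["T0"] = rng.multinomial(depth, base / base.sum())
    samples["T0"] = {"drug": "none", "replicate": 1, "timepoint": "T0"}
    counts["vehicle"] = rng.multinomial(depth, base / base.sum())
    samples["vehicle"] = {"drug": "DMSO", "replicate": 1,
                          "timepoint": "vehicle_end", "doublings": 0.0}

    eff = tab["efficacy"].to_numpy()
    gene_idx = tab["gene"].to_numpy()
    for drug in arms:
        dd = float(universe.doublings[drug])
        rho = universe.true_rho[drug].reindex(
            pd.Index(gene_idx)).fillna(0.0).to_numpy()
        weight = base * np.exp2(eff * rho * dd)
        counts[drug] = rng.multinomial(depth, weight / weight.sum())
        samples[drug] = {"drug": drug, "replicate": 1,
                         "timepoint": "treated_end", "doublings": dd,
                         "reference": "vehicle"}

    out = tab[["gene", "tss", "targeting"]].copy()
    for sid, c in counts.items():
        out[sid] = c.astype(np.int64)
    truth = {"true_rho": universe.true_rho,
             "efficacy": tab["efficacy"].copy()}
    return out, SampleSheet(samples), truth
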