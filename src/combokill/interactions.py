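"""Pharmacological interaction scoring on dose-response surfaces.

Two null models are implemented.  Bliss independence treats cell killing by
two drugs as statistically independent events: if drugs *a* and *b* alone
kill fractions ``p_a`` and ``p_b``, the expected combined kill is
``p_expected = p_a + (1 - p_a) * p_b`` and deviations are scored on a log
scale as excess over Bliss, ``EOB = log10(1 - p_expected) - log10(1 -
p_observed)`` (positive = synergy).  Loewe additivity treats the drugs as
dilutions of one another (dose equivalence): contours of equal effect
(isoboles) are straight lines under additivity, and fixed-ratio mixtures are
summarized by the fractional inhibitory concentration
``FIC = sum_i c_i / D_i`` where ``c_i`` is drug *i*'s concentration in the
mixture at an effect level and ``D_i`` its single-agent concentration at the
same level (FIC = 1 under additivity).

Viability is normalized to untreated controls (relative cell number); the
growth-rate inhibition metric GR re-expresses it against control doublings
so that GR = 1 means uninhibited growth, GR = 0 growth arrest and GR < 0
net killing.  No lower bound of -1 is imposed on GR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_EPS = 1e-15


@dataclass
class DoseResponseSurface:
    """drugs x concentrations grid of viability relative to untreated.

    ``dose_axes`` each start at 0 (the untreated margin) and then ascend
    strictly; ``relative_viability[i, j]`` is the response at
    ``(dose_axes[0][i], dose_axes[1][j])``.  ``control_doublings`` is the
    number of population doublings of the untreated control over the assay
    window (needed for GR).
    """

    drug_names: tuple[str, str]
    dose_axes: tuple[np.ndarray, np.ndarray]
    relative_viability: np.ndarray
    control_doublings: float = 0.0

    def __post_init__(self) -> None:
        axes = tuple(np.asarray(a, dtype=float) for a in self.dose_axes)
        self.dose_axes = axes
        self.relative_viability = np.asarray(self.relative_viability, float)
        for ax in axes:
            if ax[0] != 0:
                raise ValueError("each dose axis must start at zero dose")
            if np.any(ax[1:] <= 0):
                raise ValueError("non-zero doses must be positive")
            if np.any(np.diff(ax) <= 0):
                raise ValueError("dose axes must be strictly increasing")
        if self.relative_viability.shape != (len(axes[0]), len(axes[1])):
            raise ValueError("viability grid does not match dose axes")


@dataclass
class GRSurface:
    """Growth-rate inhibition values on the same grid as the source surface."""

    drug_names: tuple[str, str]
    dose_axes: tuple[np.ndarray, np.ndarray]
    gr: np.ndarray
    control_doublings: float = 0.0


@dataclass
class InteractionScore:
    """Observed vs Bliss-expected kill and the log-scale excess over Bliss."""

    drug_names: tuple[str, str]
    dose_axes: tuple[np.ndarray, np.ndarray]
    p_expected: np.ndarray
    p_observed: np.ndarray
    eob: np.ndarray


@dataclass
class MixtureDesign:
    """Fixed-ratio multi-drug mixture with potency-scaled weights.

    ``weights`` sum to 1 and are proportional to each drug's equi-effective
    concentration, so every constituent contributes similarly to killing as
    the total dose increases.
    """

    drug_names: tuple[str, ...]
    weights: tuple[float, ...]
    effect_level: float = 0.5
    single_doses: tuple[float, ...] = field(default_factory=tuple)

    def concentrations(self, total: float) -> np.ndarray:
        return total * np.asarray(self.weights)


@dataclass
class FicResult:
    drug_set: tuple[str, ...]
    effect_level: float
    fic: float
    ci95: tuple[float, float] | None = None
    per_replicate: tuple[float, ...] = field(default_factory=tuple)
    emergent_fic: float | None = None


def compute_gr(surface: DoseResponseSurface) -> GRSurface:
    """Convert relative viability to GR values.

    GR = log2(relative_viability * 2**d) / d with d the control doublings;
    GR = 1 for untreated growth, 0 when the final cell count equals the
    initial one (relative viability 2**-d), negative for net killing.  No
    lower clamp is applied.
    """
    d = surface.control_doublings
    if d <= 0:
        raise ValueError("control_doublings must be positive to compute GR")
    rv = np.maximum(surface.relative_viability, _EPS)
    gr = np.log2(rv * 2.0 ** d) / d
    return GRSurface(surface.drug_names, surface.dose_axes, gr, d)


def kill_fractions(surface: DoseResponseSurface) -> np.ndarray:
    """Fraction of cells killed relative to untreated control.

    p = 1 - relative_viability, clipped to [0, 1): viability above 1 counts
    as zero kill, and kill is kept strictly below 1 so log-survival stays
    finite.
    """
    return np.clip(1.0 - surface.relative_viability, 0.0, 1.0 - _EPS)


def bliss_expected(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """Expected kill under Bliss independence from single-drug kills."""
    p_a = np.asarray(p_a, float)[:, None]
    p_b = np.asarray(p_b, float)[None, :]
    return p_a + (1.0 - p_a) * p_b


def excess_over_bliss(surface: DoseResponseSurface) -> InteractionScore:
    """Score deviation from Bliss independence across a checkerboard.

    The single-drug margins (zero-dose row and column) provide ``p_a`` and
    ``p_b``; EOB = log10(1 - p_expected) - log10(1 - p_observed), so
    positive values mean more log-kills than independence predicts
    (synergy) and negative values antagonism.
    """
    p = kill_fractions(surface)
    if surface.dose_axes[0][0] != 0 or surface.dose_axes[1][0] != 0:
        raise ValueError("surface must include zero-dose margins")
    p_a = p[:, 0]
    p_b = p[0, :]
    p_expected = bliss_expected(p_a, p_b)
    eob = np.log10(1.0 - p_expected) - np.log10(1.0 - p)
    return InteractionScore(surface.drug_names, surface.dose_axes,
                            p_expected, p, eob)


def smooth_surface(grid: np.ndarray) -> np.ndarray:
    """Nearest-neighbor median filter for jagged dose-response grids.

    Each cell is replaced by the median of its four axis neighbors with the
    cell's own value counted three times (a center-weighted median; the
    window shrinks at edges).  The center weighting guarantees that any
    surface monotone along both dose axes is a fixed point — the filter
    only alters locally non-monotone (jagged) responses, removing isolated
    spikes — which an unweighted square-window median does not.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 2:
        raise ValueError("expected a 2-D grid")
    out = np.empty_like(grid)
    n, m = grid.shape
    for i in range(n):
        for j in range(m):
            window = [grid[i, j]] * 3
            if i > 0:
                window.append(grid[i - 1, j])
            if i < n - 1:
                window.append(grid[i + 1, j])
            if j > 0:
                window.append(grid[i, j - 1])
            if j < m - 1:
                window.append(grid[i, j + 1])
            out[i, j] = np.median(window)
    return out


def extract_isoboles(
    gr_surface: GRSurface | DoseResponseSurface,
    levels: Sequence[float],
    values: np.ndarray | None = None,
) -> list[dict]:
    """Extract equal-effect contours (isoboles) from a response surface.

    Contours are traced by marching squares with linear interpolation in
    log-dose coordinates over the positive-dose subgrid, then mapped back to
    concentration units.  Each returned dict carries ``level``,
    ``drug_names`` and ``points`` (an (n, 2) array of doses, one column per
    drug).  A level outside the observed range yields an empty list entry
    with a warning.
    """
    from skimage import measure

    if values is None:
        values = gr_surface.gr if isinstance(gr_surface, GRSurface) \
            else gr_surface.relative_viability
    axes = gr_surface.dose_axes
    grid = np.asarray(values, float)[1:, 1:]  # positive doses only
    log_a = np.log10(axes[0][1:])
    log_b = np.log10(axes[1][1:])
    out: list[dict] = []
    for level in levels:
        if not (grid.min() <= level <= grid.max()):
            warnings.warn(
                f"isobole level {level} outside surface range "
                f"[{grid.min():.3g}, {grid.max():.3g}]", stacklevel=2)
            out.append({"level": level, "drug_names": gr_surface.drug_names,
                        "points": np.empty((0, 2))})
            continue
        segments = measure.find_contours(grid, level)
        for seg in segments:
            la = np.interp(seg[:, 0], np.arange(len(log_a)), log_a)
            lb = np.interp(seg[:, 1], np.arange(len(log_b)), log_b)
            out.append({
                "level": level,
                "drug_names": gr_surface.drug_names,
                "points": np.column_stack([10.0 ** la, 10.0 ** lb]),
            })
    return out


def dose_at_effect(
    doses: np.ndarray,
    survival: np.ndarray,
    effect_level: float = 0.5,
    name: str = "drug",
    monotonize: bool = False,
) -> float:
    """Concentration at which a dose-response first crosses an effect level.

    ``effect_level`` is a kill fraction; the crossing of relative viability
    below ``1 - effect_level`` is located by piecewise-linear interpolation
    in log10 dose.  A zero-dose point, if present, is ignored.  With
    ``monotonize`` the curve is first projected onto the nearest
    non-increasing one (isotonic regression), which debiases crossings on
    noisy replicates; a true dose response is unchanged.  Otherwise the
    first crossing is used (with a warning if the response is non-monotone
    and re-crosses).  Never reaching the level is an error naming the drug.
    """
    doses = np.asarray(doses, float)
    survival = np.asarray(survival, float)
    pos = doses > 0
    doses, survival = doses[pos], survival[pos]
    order = np.argsort(doses)
    doses, survival = doses[order], survival[order]
    if monotonize:
        from scipy.optimize import isotonic_regression

        survival = isotonic_regression(survival, increasing=False).x
    target = 1.0 - effect_level
    below = survival <= target
    if not below.any():
        raise ValueError(
            f"{name} never reaches the {effect_level:.0%}-kill level "
            f"within its tested range")
    k = int(np.argmax(below))
    if not below[k:].all():
        warnings.warn(
            f"{name}: non-monotone crossing; using first crossing",
            stacklevel=2)
    if k == 0:
        return float(doses[0])
    x0, x1 = np.log10(doses[k - 1]), np.log10(doses[k])
    y0, y1 = survival[k - 1], survival[k]
    frac = (y0 - target) / (y0 - y1)
    return float(10.0 ** (x0 + frac * (x1 - x0)))


def design_equipotent_mixture(
    single_curves: Mapping[str, tuple[np.ndarray, np.ndarray]],
    effect_level: float = 0.5,
) -> MixtureDesign:
    """Design a fixed-ratio mixture in which drugs contribute equally.

    ``single_curves`` maps drug name -> (doses, relative viability).  Each
    drug's weight is proportional to its equi-effective concentration at
    ``effect_level``, so that in potency-scaled units every constituent is
    equally active.  A drug that never reaches the effect level raises an
    error naming it.
    """
    names = tuple(single_curves)
    eq_doses = np.array([
        dose_at_effect(*single_curves[n], effect_level=effect_level, name=n)
        for n in names
    ])
    weights = eq_doses / eq_doses.sum()
    return MixtureDesign(names, tuple(weights), effect_level,
                         tuple(eq_doses))


def compute_fic(
    mixture_response: pd.DataFrame,
    single_curves: Mapping[str, tuple[np.ndarray, np.ndarray]],
    design: MixtureDesign,
    effect_level: float = 0.5,
    monotonize: bool = True,
) -> FicResult:
    """Fractional inhibitory concentration of a fixed-ratio mixture.

    ``mixture_response`` has a ``dose`` column (total mixture dose) and one
    or more replicate viability columns.  At the mixture's crossing of the
    effect level, FIC = sum_i (w_i * total) / D_i with D_i the single-agent
    dose at the same level.  FIC = 1 indicates Loewe additivity; when
    several replicates are supplied a t-based 95% CI over per-replicate
    FICs is reported.
    """
    names = design.drug_names
    singles = np.array([
        dose_at_effect(*single_curves[n], effect_level=effect_level, name=n,
                       monotonize=monotonize)
        for n in names
    ])
    w = np.asarray(design.weights)
    doses = mixture_response["dose"].to_numpy()
    rep_cols = [c for c in mixture_response.columns if c != "dose"]
    fics = []
    for col in rep_cols:
        total = dose_at_effect(doses, mixture_response[col].to_numpy(),
                               effect_level=effect_level,
                               name="+".join(names),
                               monotonize=monotonize)
        fics.append(float(np.sum(w * total / singles)))
    fic = float(np.mean(fics))
    ci = None
    if len(fics) >= 2:
        from scipy import stats

        sem = np.std(fics, ddof=1) / np.sqrt(len(fics))
        tcrit = stats.t.ppf(0.975, len(fics) - 1)
        ci = (fic - tcrit * sem, fic + tcrit * sem)
    return FicResult(names, effect_level, fic, ci, tuple(fics))


def emergent_fic(
    fic_by_subset: Mapping[tuple[str, ...], float],
    drug_set: Sequence[str],
) -> float:
    """Deviation of an N-drug FIC from its lower-order additive prediction.

    Each (N-1)-drug sub-mixture is treated as a pseudo-drug whose measured
    FIC rescales its potency; composing the N-drug ray dose-additively from
    the N sub-rays makes the predicted N-drug FIC the harmonic mean of the
    (N-1)-order FICs.  Emergent FIC = observed / predicted; 1 means the
    lower-order interactions fully explain the N-drug response, > 1 means
    emergent antagonism.  Requires FICs keyed by sorted drug-name tuples
    for the full set and all its (N-1)-subsets.
    """
    drugs = tuple(sorted(drug_set))
    n = len(drugs)
    if n < 3:
        raise ValueError("emergent interactions require at least 3 drugs")
    key = drugs
    if key not in fic_by_subset:
        raise KeyError(f"missing FIC for drug set {key}")
    subsets = [tuple(sorted(s)) for s in itertools.combinations(drugs, n - 1)]
    missing = [s for s in subsets if s not in fic_by_subset]
    if missing:
        raise KeyError(f"missing FICs for subsets: {missing}")
    predicted = n / sum(1.0 / fic_by_subset[s] for s in subsets)
    return float(fic_by_subset[key] / predicted)
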