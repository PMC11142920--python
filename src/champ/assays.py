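"""Quantitative assay models: FRET quenching stoichiometry in micelles,
thiol-disulfide exchange species quantification, and chemical-shift
perturbation (CSP) interface mapping with helical-periodicity analysis.

FRET model.  A donor-labeled target peptide is titrated with
acceptor-labeled binder at fixed total peptide and detergent.  With
acceptor fraction ``f`` of the partner pool, bound fraction ``b`` and
transfer efficiency ``E``, relative donor intensity is

* dimer (1:1):   ``1 - b E f``             (one partner per donor)
* trimer (2:1):  ``1 - b E (1 - (1-f)^2)`` (two partners per donor)
* monomer:       crowding term only.

Micelle crowding adds nonspecific quenching: with ``lam`` peptides per
micelle (Poisson), a donor shares its micelle with at least one
acceptor with probability ``1 - exp(-lam f)``, contributing a
multiplicative factor ``1 - E_c (1 - exp(-lam f))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from champ.geometry import GeometryError

STOICHIOMETRIES = ("monomer", "dimer", "trimer")


@dataclass
class CrowdingModel:
    """Detergent micelle statistics for nonspecific co-occupancy."""

    total_detergent_mM: float
    cmc_mM: float
    aggregation_number: float
    peptide_uM: float

    def __post_init__(self):
        if self.total_detergent_mM < self.cmc_mM:
            raise ValueError("total detergent below the CMC: no micelles")

    @property
    def micellar_detergent_mM(self) -> float:
        return self.total_detergent_mM - self.cmc_mM

    @property
    def micelle_uM(self) -> float:
        return 1000.0 * self.micellar_detergent_mM / self.aggregation_number

    @property
    def peptides_per_micelle(self) -> float:
        """Poisson rate lambda: mean peptides per micelle."""
        return self.peptide_uM / self.micelle_uM

    @property
    def detergent_per_peptide(self) -> float:
        return 1000.0 * self.micellar_detergent_mM / self.peptide_uM

    @property
    def peptide_mole_fraction(self) -> float:
        """Peptide / micellar detergent mole fraction."""
        return self.peptide_uM / (1000.0 * self.micellar_detergent_mM)

    @property
    def co_occupancy(self) -> float:
        """P(an occupied micelle holds at least one other peptide)."""
        return 1.0 - math.exp(-self.peptides_per_micelle)


def crowding(model: CrowdingModel) -> tuple[float, float, float]:
    """(peptides per micelle, co-occupancy probability, peptide mole
    fraction in micellar detergent)."""
    return (
        model.peptides_per_micelle,
        model.co_occupancy,
        model.peptide_mole_fraction,
    )


@dataclass
class StoichModel:
    """Theoretical oligomer quenching model."""

    stoichiometry: str = "dimer"
    transfer_efficiency: float = 1.0  # E
    bound_fraction: float = 1.0  # b
    lam: float = 0.0  # mean peptides per micelle (crowding)
    crowding_efficiency: float | None = None  # E_c; defaults to E

    def __post_init__(self):
        if self.stoichiometry not in STOICHIOMETRIES:
            raise ValueError(f"unknown stoichiometry {self.stoichiometry!r}")
        for name in ("transfer_efficiency", "bound_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def intensity(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("acceptor fraction must lie in [0, 1]")
        e, b = self.transfer_efficiency, self.bound_fraction
        if self.stoichiometry == "monomer":
            specific = np.ones_like(f)
        elif self.stoichiometry == "dimer":
            specific = 1.0 - b * e * f
        else:  # trimer, two partners per donor
            specific = 1.0 - b * e * (1.0 - (1.0 - f) ** 2)
        ec = self.crowding_efficiency if self.crowding_efficiency is not None else e
        crowd = 1.0 - ec * (1.0 - np.exp(-self.lam * f))
        return specific * crowd


@dataclass
class QuenchTitration:
    """FRET titration: relative donor intensity vs acceptor fraction."""

    acceptor_fraction: np.ndarray
    intensity: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.acceptor_fraction = np.asarray(self.acceptor_fraction, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.acceptor_fraction.shape != self.intensity.shape:
            raise ValueError("acceptor_fraction and intensity shapes differ")
        if np.any((self.acceptor_fraction < 0) | (self.acceptor_fraction > 1)):
            raise ValueError("acceptor fractions must lie in [0, 1]")
        if np.any((self.intensity <= 0) | (self.intensity > 1.2)):
            raise ValueError("relative intensities must lie in (0, 1.2]")
        zero = self.acceptor_fraction == 0
        if zero.any() and np.any(np.abs(self.intensity[zero] - 1.0) > 0.15):
            raise ValueError("intensity at zero acceptor must be ~1 (normalized)")


def fret_theory_curve(model: StoichModel, acceptor_fraction) -> QuenchTitration:
    """Evaluate a theoretical quenching curve on an acceptor-fraction grid."""
    f = np.asarray(acceptor_fraction, dtype=float)
    return QuenchTitration(f, model.intensity(f))


def half_quench_ratio(
    model: StoichModel, max_ratio: float = 2.0, n_grid: int = 2001
) -> float:
    """Acceptor:donor molar ratio at half-maximal donor quenching.

    In the titration design the donor concentration is fixed while
    acceptor replaces unlabeled partner, up to ``max_ratio`` acceptor
    per donor; the acceptor fraction of the partner pool is
    ``ratio / max_ratio``.  The half point is found by interpolation on
    a dense ratio grid.
    """
    ratios = np.linspace(0.0, max_ratio, n_grid)
    q = 1.0 - model.intensity(ratios / max_ratio)
    half = q[-1] / 2.0
    idx = int(np.searchsorted(q, half))
    if idx == 0:
        return 0.0
    r0, r1 = ratios[idx - 1], ratios[idx]
    q0, q1 = q[idx - 1], q[idx]
    return float(r0 + (half - q0) * (r1 - r0) / (q1 - q0))


@dataclass
class StoichFit:
    model: StoichModel
    rss: float
    aicc: float
    residuals: np.ndarray


def fit_stoichiometry(
    data: QuenchTitration,
    candidates: tuple = STOICHIOMETRIES,
    lam: float = 0.0,
    flat_threshold: float = 0.05,
) -> tuple[StoichModel, dict[str, StoichFit]]:
    """Least-squares fit of each candidate stoichiometry; selection by
    small-sample corrected information criterion (AICc).

    Bound fraction and transfer efficiency are both capped at 1.
    Degenerate flat titrations select the monomer model with a warning.
    """
    f = data.acceptor_fraction
    y = data.intensity
    n = len(f)
    if n < 4:
        raise ValueError("need at least 4 titration points")
    fits = {}
    for stoich in candidates:
        if stoich == "monomer":
            k = 1

            def predict(theta, s=stoich):
                return StoichModel(s, theta[0], 0.0, lam).intensity(f)

            x0, bounds = [0.5], ([0.0], [1.0])
        else:
            k = 2

            def predict(theta, s=stoich):
                return StoichModel(s, theta[0], theta[1], lam).intensity(f)

            x0, bounds = [0.5, 0.9], ([0.0, 0.0], [1.0, 1.0])
        res = least_squares(lambda th: predict(th) - y, x0, bounds=bounds,
                            xtol=1e-13, ftol=1e-13, gtol=1e-13)
        rss = float(2.0 * res.cost)
        rss_floor = max(rss, 1e-12)
        aicc = n * math.log(rss_floor / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n - k - 1)
        if stoich == "monomer":
            model = StoichModel(stoich, res.x[0], 0.0, lam)
        else:
            model = StoichModel(stoich, res.x[0], res.x[1], lam)
        fits[stoich] = StoichFit(model, rss, aicc, predict(res.x) - y)
    if np.ptp(y) < flat_threshold and "monomer" in fits:
        warnings.warn("titration is flat; selecting the monomer model")
        return fits["monomer"].model, fits
    best = min(fits, key=lambda s: fits[s].aicc)
    return fits[best].model, fits


# ---------------------------------------------------------------------------
# thiol-disulfide exchange species quantification


@dataclass
class SpeciesQuantification:
    mole_fractions: dict
    heterodimer_over_aa: float
    enrichment: float  # f_AB / (2 sqrt(f_AA f_BB)); 1 under random pairing
    flags: list = field(default_factory=list)


def quantify_species(
    areas: dict[str, float],
    extinction_weights: dict[str, float] | None = None,
) -> SpeciesQuantification:
    """Mole fractions of disulfide-bonded dimer species from chromatogram
    peak areas, plus heterodimer preference statistics.

    UV response is assumed proportional to peptide count per species
    unless per-species extinction weights are supplied.  The enrichment
    statistic compares the heterodimer fraction with the 1:2:1 random-
    association null; an absent homodimer makes it diverge (flagged,
    reported as infinity).
    """
    dimers = ("AA", "AB", "BB")
    for sp, area in areas.items():
        if area < 0:
            raise ValueError(f"negative area for species {sp}")
    if all(areas.get(sp, 0.0) == 0.0 for sp in dimers):
        raise ValueError("all dimer areas are zero")
    weights = extinction_weights or {}
    moles = {sp: areas.get(sp, 0.0) / weights.get(sp, 1.0) for sp in dimers}
    total = sum(moles.values())
    fractions = {sp: moles[sp] / total for sp in dimers}
    flags = []
    f_aa, f_ab, f_bb = fractions["AA"], fractions["AB"], fractions["BB"]
    hetero_over_aa = f_ab / f_aa if f_aa > 0 else math.inf
    if f_aa == 0:
        flags.append("no_AA_homodimer")
    if f_aa > 0 and f_bb > 0:
        enrichment = f_ab / (2.0 * math.sqrt(f_aa * f_bb))
    else:
        enrichment = math.inf
        flags.append("enrichment_divergent")
    return SpeciesQuantification(fractions, hetero_over_aa, enrichment, flags)


# ---------------------------------------------------------------------------
# chemical shift perturbation and interface mapping


@dataclass
class CSPProfile:
    """Per-residue/atom shift perturbations, normalized to the largest."""

    table: pd.DataFrame  # columns: residue, atom, delta_ppm, normalized
    broadened: list  # (residue, atom) flagged, no numeric delta
    unmatched: list  # keys present in only one input table

    def atom_profile(self, atom: str) -> pd.Series:
        sub = self.table[self.table.atom == atom]
        return sub.set_index("residue")["normalized"].sort_index()


def compute_csp(
    free: pd.DataFrame,
    bound: pd.DataFrame,
    nitrogen_weight: float = 0.14,
    broadened: list | None = None,
) -> CSPProfile:
    """Per-atom shift perturbations between free and bound states.

    Inputs carry columns (residue, atom, shift_ppm).  Delta = |bound -
    free| per matched key; amide-nitrogen deltas may be combined with
    protons downstream using ``nitrogen_weight``.  Perturbations are
    normalized 0..1 to the largest value.  Residues broadened beyond
    detection are carried as flags, never as zeros.
    """
    broadened = [tuple(b) for b in (broadened or [])]
    frames = []
    for name, df in (("free", free), ("bound", bound)):
        df = df.copy()
        need = {"residue", "atom", "shift_ppm"}
        if not need <= set(df.columns):
            raise ValueError(f"{name} table must have columns {sorted(need)}")
        if df.duplicated(["residue", "atom"]).any():
            dups = df[df.duplicated(["residue", "atom"])][["residue", "atom"]]
            raise ValueError(f"duplicate keys in {name} table: {dups.values.tolist()}")
        frames.append(df.set_index(["residue", "atom"])["shift_ppm"])
    f, b = frames
    common = f.index.intersection(b.index)
    unmatched = sorted(set(f.index.symmetric_difference(b.index)))
    delta = (b.loc[common] - f.loc[common]).abs()
    mask = [key not in broadened for key in delta.index]
    numeric = delta[mask]
    max_delta = float(numeric.max()) if len(numeric) and numeric.max() > 0 else 0.0
    table = numeric.reset_index()
    table.columns = ["residue", "atom", "delta_ppm"]
    table["normalized"] = (
        table["delta_ppm"] / max_delta if max_delta > 0 else 0.0
    )
    return CSPProfile(table=table, broadened=broadened, unmatched=unmatched)


def combined_amide_csp(profile_h: pd.Series, profile_n: pd.Series,
                       nitrogen_weight: float = 0.14) -> pd.Series:
    """sqrt(dH^2 + (w_N dN)^2) over residues present in both."""
    idx = profile_h.index.intersection(profile_n.index)
    return np.sqrt(profile_h.loc[idx] ** 2 + (nitrogen_weight * profile_n.loc[idx]) ** 2)


@dataclass
class NICProfile:
    """Normalized interhelical closeness per target residue."""

    min_distance: pd.Series  # residue -> min interhelical CA-CA distance, A
    closeness: pd.Series  # residue -> (d_max - d) / (d_max - d_min) over core
    core_residues: list


def nic_profile(model, core_margin: float = 0.0) -> NICProfile:
    """Minimum interhelical CA-CA distance per target residue, min-max
    normalized (closest residue -> 1) over membrane-core residues."""
    target, binder = model.target, model.binder
    if binder is None:
        raise GeometryError("NIC needs a two-helix complex model")
    from scipy.spatial.distance import cdist

    d = cdist(target.ca, binder.ca).min(axis=1)
    residues = np.arange(1, target.n_res + 1)
    zmax = model.frame.half_thickness + core_margin
    core = [int(r) for r in residues if abs(target.ca[r - 1, 2]) <= zmax]
    if len(core) < 2:
        core = [int(r) for r in residues]
    dc = d[[r - 1 for r in core]]
    d_min, d_max = float(dc.min()), float(dc.max())
    closeness = (d_max - d) / (d_max - d_min) if d_max > d_min else np.zeros_like(d)
    return NICProfile(
        min_distance=pd.Series(d, index=residues),
        closeness=pd.Series(np.clip(closeness, 0.0, 1.0), index=residues),
        core_residues=core,
    )


@dataclass
class PeriodicityFit:
    period: float  # residues per cycle
    phase: float  # radians
    amplitude: float
    offset: float
    correlation_with_nic: float | None = None
    correlation_p: float | None = None


def periodicity_fit(
    values: pd.Series,
    period_bounds: tuple = (3.0, 4.5),
    nic: pd.Series | None = None,
) -> PeriodicityFit:
    """Cosine fit ``a cos(2 pi x / T + phi) + c`` with the period bounded
    to the helical range, by grid search over T with linear least
    squares for the harmonics, then local refinement.

    ``values`` is indexed by residue number; entries flagged as
    broadened should simply be absent.  If a NIC closeness profile is
    supplied, the Pearson correlation over shared residues is reported.
    """
    values = values.dropna()
    if len(values) < 10:
        raise ValueError("need at least 10 residues with numeric perturbations")
    x = values.index.to_numpy(dtype=float)
    y = values.to_numpy(dtype=float)

    def harmonics_fit(period):
        w = 2.0 * math.pi / period
        basis = np.column_stack([np.cos(w * x), np.sin(w * x), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ coef
        return coef, float(resid @ resid)

    periods = np.linspace(period_bounds[0], period_bounds[1], 151)
    costs = [harmonics_fit(p)[1] for p in periods]
    p0 = periods[int(np.argmin(costs))]
    # golden-section style local refinement
    lo = max(period_bounds[0], p0 - 0.02)
    hi = min(period_bounds[1], p0 + 0.02)
    fine = np.linspace(lo, hi, 81)
    fcosts = [harmonics_fit(p)[1] for p in fine]
    period = float(fine[int(np.argmin(fcosts))])
    coef, _ = harmonics_fit(period)
    a, b, c = coef
    amplitude = float(math.hypot(a, b))
    phase = float(math.atan2(-b, a))
    corr = corr_p = None
    if nic is not None:
        shared = values.index.intersection(nic.dropna().index)
        if len(shared) >= 3:
            r, p = pearsonr(values.loc[shared], nic.loc[shared])
            corr, corr_p = float(r), float(p)
    return PeriodicityFit(period, phase, amplitude, float(c), corr, corr_p)
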