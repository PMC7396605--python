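"""Synthetic assay data and an isotopologue-resolved forward oracle.

The analysis layer assumes data with the statistical structure of a
sacrificial-vial fractionation assay: nine vials sacrificed across
fractions remaining f = 0.9 ... 0.1, triplicate isotope measurements per
vial, Gaussian analytical noise of 0.5 permil per element, and exact
Rayleigh distillation with per-element bulk enrichment factors.
:func:`simulate_rayleigh_series` generates such series directly from the
closed-form distillation law

    delta_t = (1 + delta_0) * f**(eps/1000) - 1        (deltas as fractions)

:func:`make_study_fixture` seeds the generator with published
enrichment factors for each compound x cultivation-history combination,
standing in for unarchived raw assay data.

Independently of that closed form, :class:`IsotopologueSystem` +
:func:`simulate_isotopologues` integrate first-order consumption of
explicit isotopologue classes with position-specific kinetic isotope
effects.  Because each class decays as an independent exponential the
deterministic trajectory is evaluated in closed form (no integrator
truncation error); a stochastic per-molecule mode exists for small-N
validation.  This simulator is the mechanistic oracle against which the
bulk-epsilon algebra (intramolecular competition, non-reacting-position
dilution) is checked.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import (
    DeltaValue,
    ExperimentSeries,
    InvalidInputError,
    IsotopeMeasurement,
)

__all__ = [
    "DEFAULT_F_GRID",
    "SimulationConfig",
    "IsotopologueSystem",
    "IsotopologueTrajectory",
    "NotDeterminedError",
    "STUDY_EPSILONS",
    "simulate_rayleigh_series",
    "simulate_isotopologues",
    "simulate_isotopologues_stochastic",
    "make_study_fixture",
    "rayleigh_delta",
]

#: Sacrificial-vial design: nine vials at f = 0.9 ... 0.1 in steps of 0.1.
DEFAULT_F_GRID = tuple(round(0.9 - 0.1 * i, 10) for i in range(9))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating truth and design of one synthetic assay series.

    Defaults mirror the assay design the analysis assumes: nine vials
    across f = 0.9 ... 0.1, three replicate measurements per vial, and
    independent Gaussian analytical noise of 0.5 permil per element per
    measurement.  Starting compositions default to typical solvent
    values (delta13C_0 = -30 permil, delta37Cl_0 = 0 permil); slope
    estimates are invariant to this choice.
    """

    epsilon_c: float  # permil
    epsilon_cl: float | None = None  # permil; None = carbon-only assay
    delta0_c: float = -30.0
    delta0_cl: float = 0.0
    f_grid: tuple[float, ...] = DEFAULT_F_GRID
    noise_sd: float = 0.5  # permil, per element per measurement
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f_grid:
            raise InvalidInputError("f_grid must be non-empty")
        for f in self.f_grid:
            if not 0.0 < f <= 1.0:
                raise InvalidInputError(f"f_grid values must lie in (0, 1], got {f}")
        if self.noise_sd < 0.0:
            raise InvalidInputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_replicates < 1:
            raise InvalidInputError(f"n_replicates must be >= 1, got {self.n_replicates}")


def rayleigh_delta(f, epsilon: float, delta0: float = 0.0):
    """Exact Rayleigh composition (permil) of residual substrate at f.

    >>> round(rayleigh_delta(0.5, -27.5), 2)
    19.24
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0):
        raise InvalidInputError("fraction remaining must be > 0")
    out = ((1.0 + delta0 / 1000.0) * f ** (epsilon / 1000.0) - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def simulate_rayleigh_series(
    config: SimulationConfig,
    compound: str = "1,2-DCA",
    cultivation_acceptor: str = "1,2-DCA",
    series_id: str | None = None,
) -> ExperimentSeries:
    """Generate one assay series under exact Rayleigh distillation.

    Each replicate at each f receives independent Gaussian noise of
    ``config.noise_sd`` permil on each element's delta.  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    if series_id is None:
        series_id = f"{compound}@{cultivation_acceptor}#seed{config.seed}"
    measurements: list[IsotopeMeasurement] = []
    for i, f in enumerate(config.f_grid):
        true_c = rayleigh_delta(f, config.epsilon_c, config.delta0_c)
        true_cl = (
            None
            if config.epsilon_cl is None
            else rayleigh_delta(f, config.epsilon_cl, config.delta0_cl)
        )
        for rep in range(1, config.n_replicates + 1):
            dc = true_c + rng.normal(0.0, config.noise_sd) if config.noise_sd else true_c
            measurement = IsotopeMeasurement(
                vial_id=f"vial{i + 1:02d}",
                compound=compound,
                cultivation_acceptor=cultivation_acceptor,
                f=f,
                delta_c=DeltaValue(dc, "C"),
                sd_c=config.noise_sd,
                replicate=rep,
            )
            if true_cl is not None:
                dcl = (
                    true_cl + rng.normal(0.0, config.noise_sd)
                    if config.noise_sd
                    else true_cl
                )
                measurement.delta_cl = DeltaValue(dcl, "Cl")
                measurement.sd_cl = config.noise_sd
            measurements.append(measurement)
    return ExperimentSeries(
        series_id=series_id,
        compound=compound,
        cultivation_acceptor=cultivation_acceptor,
        measurements=measurements,
        delta0_c=config.delta0_c,
        delta0_cl=None if config.epsilon_cl is None else config.delta0_cl,
    )


class NotDeterminedError(LookupError):
    """The requested assay combination was not determined in the study."""


#: Published bulk enrichment factors (eps_C, eps_Cl), permil, per
#: (assay compound, cultivation acceptor).  ``None`` marks combinations
#: reported as not determined.
STUDY_EPSILONS: dict[tuple[str, str], tuple[float, float] | None] = {
    ("PCE", "PCE"): (-5.1, -2.5),
    ("1,2-DCA", "PCE"): None,
    ("cDCE", "PCE"): (-23.3, -1.9),
    ("VC", "PCE"): (-31.7, -1.7),
    ("PCE", "1,2-DCA"): (-9.8, -3.2),
    ("1,2-DCA", "1,2-DCA"): (-27.5, -5.3),
    ("cDCE", "1,2-DCA"): (-21.2, -2.5),
    ("VC", "1,2-DCA"): (-18.7, -1.0),
    ("PCE", "cDCE"): (-8.6, -1.9),
    ("1,2-DCA", "cDCE"): (-18.5, -4.5),
    ("cDCE", "cDCE"): (-24.3, -1.2),
    ("VC", "cDCE"): (-20.0, -0.4),
    ("PCE", "VC"): (-7.7, -5.6),
    ("1,2-DCA", "VC"): None,
    ("cDCE", "VC"): (-14.7, -1.0),
    ("VC", "VC"): (-23.7, -1.6),
}


def make_study_fixture(
    compound: str,
    cultivation_acceptor: str,
    seed: int = 0,
    noise_sd: float = 0.5,
    n_replicates: int = 3,
) -> ExperimentSeries:
    """Seeded synthetic series whose generating truth is a published row.

    Stands in for the study's unarchived raw assay data: the
    (compound, cultivation acceptor) combination selects the published
    (eps_C, eps_Cl) pair as generating truth under the default design.
    Combinations reported as not determined raise
    :class:`NotDeterminedError`.
    """
    key = (compound, cultivation_acceptor)
    if key not in STUDY_EPSILONS:
        raise InvalidInputError(
            f"unknown assay combination {key}; valid: {sorted(STUDY_EPSILONS)}"
        )
    eps = STUDY_EPSILONS[key]
    if eps is None:
        raise NotDeterminedError(
            f"{compound} with {cultivation_acceptor}-grown cells was not "
            "determined (reported n.d.)"
        )
    config = SimulationConfig(
        epsilon_c=eps[0],
        epsilon_cl=eps[1],
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        seed=seed,
    )
    return simulate_rayleigh_series(config, compound, cultivation_acceptor)


# ---------------------------------------------------------------------------
# Isotopologue-resolved forward simulator (mechanistic oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopologueSystem:
    """One element's isotopologue classes in a first-order consumption model.

    Positions are indexed 0 .. n_positions-1; ``reactive_positions``
    names the subset at which the bond breaks.  ``kie_per_position``
    gives the position-specific kinetic isotope effect (light rate /
    heavy rate) applying when that position carries the heavy isotope.

    Rate rules (relative to the all-light rate constant k):

    - ``competing_channels``: each reactive position is an independent
      channel of rate k/z, slowed by its KIE when heavy — intramolecular
      competition between indistinguishable sites.
    - ``single_concerted_channel``: one channel of rate k divided by the
      product of the KIEs of all heavy atoms at reactive positions —
      all reactive bonds break in the single rate-limiting step.

    ``max_heavy`` = 1 is the dilute single-label approximation (at most
    one heavy atom per molecule); set it to ``n_positions`` for full
    multinomial isotopologues (relevant for chlorine, whose heavy
    abundance ~24% is not dilute in polychlorinated species).

    Each system tracks one element; in the dilute limit carbon and
    chlorine isotopologue distributions evolve independently, so a
    dual-element molecule is represented by two systems.
    """

    element: str
    n_positions: int
    reactive_positions: tuple[int, ...]
    kie_per_position: tuple[float, ...]
    channel_rule: str = "competing_channels"
    z: int | None = None  # defaults to len(reactive_positions)
    heavy_abundance: float = 0.011
    max_heavy: int = 1

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise InvalidInputError("n_positions must be >= 1")
        if not self.reactive_positions:
            raise InvalidInputError("at least one reactive position required")
        if any(not 0 <= p < self.n_positions for p in self.reactive_positions):
            raise InvalidInputError("reactive position index out of range")
        if len(self.kie_per_position) != self.n_positions:
            raise InvalidInputError("kie_per_position must cover every position")
        if any(k <= 0.0 for k in self.kie_per_position):
            raise InvalidInputError("all KIE values must be > 0")
        if self.channel_rule not in ("competing_channels", "single_concerted_channel"):
            raise InvalidInputError(f"unknown channel rule {self.channel_rule!r}")
        if not 0.0 < self.heavy_abundance < 0.5:
            raise InvalidInputError("heavy_abundance must lie in (0, 0.5)")
        if not 1 <= self.max_heavy <= self.n_positions:
            raise InvalidInputError("max_heavy must lie in [1, n_positions]")

    @property
    def n_sites(self) -> int:
        return self.z if self.z is not None else len(self.reactive_positions)

    def classes(self) -> list[tuple[int, ...]]:
        """Isotopologue classes as sorted tuples of heavy-position indices."""
        out: list[tuple[int, ...]] = []
        for k in range(self.max_heavy + 1):
            out.extend(itertools.combinations(range(self.n_positions), k))
        return out

    def class_fractions(self, classes: list[tuple[int, ...]]) -> np.ndarray:
        """Initial abundance of each class (independent per-position labels)."""
        a = self.heavy_abundance
        frac = np.array(
            [
                a ** len(c) * (1.0 - a) ** (self.n_positions - len(c))
                for c in classes
            ]
        )
        return frac / frac.sum()  # renormalize over the truncated class set

    def class_rates(self, classes: list[tuple[int, ...]]) -> np.ndarray:
        """First-order rate of each class relative to k = 1 for all-light."""
        rates = np.empty(len(classes))
        for i, heavy in enumerate(classes):
            heavy_set = set(heavy)
            if self.channel_rule == "competing_channels":
                r = 0.0
                for pos in self.reactive_positions:
                    channel = 1.0 / self.n_sites
                    if pos in heavy_set:
                        channel /= self.kie_per_position[pos]
                    r += channel
            else:  # single_concerted_channel
                r = 1.0
                for pos in self.reactive_positions:
                    if pos in heavy_set:
                        r /= self.kie_per_position[pos]
            rates[i] = r
        return rates


@dataclass
class IsotopologueTrajectory:
    """Bulk-composition trajectory of a simulated isotopologue system."""

    f: np.ndarray
    delta_permil: np.ndarray
    counts: np.ndarray  # (n_points, n_classes) surviving fraction per class
    reacted: np.ndarray  # (n_points, n_classes)
    classes: list[tuple[int, ...]]
    system: IsotopologueSystem

    def fitted_epsilon(self) -> float:
        """Bulk enrichment factor (permil): OLS slope of ln(R/R0) vs ln f."""
        r_factor = 1.0 + self.delta_permil / 1000.0
        y = np.log(r_factor)
        x = np.log(self.f)
        slope = np.polyfit(x, y, 1)[0]
        return float(slope * 1000.0)


def _bulk_delta(counts: np.ndarray, classes: list[tuple[int, ...]], n_positions: int):
    """Atom-based bulk ratio heavy/light from class counts; returns (R,)."""
    heavy_per_class = np.array([len(c) for c in classes], dtype=float)
    heavy = counts @ heavy_per_class
    light = counts @ (n_positions - heavy_per_class)
    return heavy / light


def simulate_isotopologues(
    system: IsotopologueSystem,
    f_stop: float,
    n_points: int = 25,
) -> IsotopologueTrajectory:
    """Deterministic trajectory of bulk delta versus fraction remaining.

    Each isotopologue class decays as an independent first-order
    exponential, so the trajectory is evaluated in closed form; the
    times corresponding to the requested f values are located by root
    bracketing.  Counts are normalized to a unit initial total;
    surviving + reacted equals the initial count class-by-class at every
    step.
    """
    if not 0.0 < f_stop < 1.0:
        raise InvalidInputError(f"f_stop must lie in (0, 1), got {f_stop}")
    classes = system.classes()
    n0 = system.class_fractions(classes)
    rates = system.class_rates(classes)

    def total_remaining(t: float) -> float:
        return float(np.sum(n0 * np.exp(-rates * t)))

    # bracket the time at which total remaining hits f_stop
    t_hi = 1.0
    while total_remaining(t_hi) > f_stop:
        t_hi *= 2.0
        if t_hi > 1e9:  # pragma: no cover - degenerate rates
            raise InvalidInputError("consumption never reaches f_stop")
    f_targets = np.linspace(1.0, f_stop, n_points)
    times = np.empty(n_points)
    times[0] = 0.0
    for i, f_t in enumerate(f_targets[1:], start=1):
        times[i] = brentq(lambda t: total_remaining(t) - f_t, 0.0, t_hi, xtol=1e-14)
    counts = n0[None, :] * np.exp(-np.outer(times, rates))
    reacted = n0[None, :] - counts
    ratio = _bulk_delta(counts, classes, system.n_positions)
    delta = (ratio / ratio[0] - 1.0) * 1000.0
    return IsotopologueTrajectory(
        f=counts.sum(axis=1) / n0.sum(),
        delta_permil=delta,
        counts=counts,
        reacted=reacted,
        classes=classes,
        system=system,
    )


def simulate_isotopologues_stochastic(
    system: IsotopologueSystem,
    f_stop: float,
    n_molecules: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Per-molecule stochastic counterpart for small-N validation.

    Assigns each molecule a class by multinomial draw and an exponential
    lifetime at its class rate; survivors at the time when a fraction
    ``f_stop`` remains give the bulk delta.  Returns
    ``(f_actual, delta_permil)``.
    """
    if not 0.0 < f_stop < 1.0:
        raise InvalidInputError(f"f_stop must lie in (0, 1), got {f_stop}")
    if n_molecules < 10:
        raise InvalidInputError("need at least 10 molecules")
    rng = np.random.default_rng(seed)
    classes = system.classes()
    fractions = system.class_fractions(classes)
    rates = system.class_rates(classes)
    assignments = rng.choice(len(classes), size=n_molecules, p=fractions)
    lifetimes = rng.exponential(1.0 / rates[assignments])
    n_survive = int(round(f_stop * n_molecules))
    order = np.argsort(lifetimes)
    survivors = assignments[order[-n_survive:]]
    heavy_per_class = np.array([len(c) for c in classes], dtype=float)
    heavy0 = float(heavy_per_class[assignments].sum())
    light0 = n_molecules * system.n_positions - heavy0
    heavy = float(heavy_per_class[survivors].sum())
    light = n_survive * system.n_positions - heavy
    ratio0 = heavy0 / light0
    ratio = heavy / light
    return n_survive / n_molecules, (ratio / ratio0 - 1.0) * 1000.0
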