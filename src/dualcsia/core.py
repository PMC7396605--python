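"""Domain types and unit conversions for dual-element CSIA.

Compound-specific isotope analysis (CSIA) reports isotope ratios in
delta-notation: the per-mil deviation of a sample's heavy/light isotope
ratio from an international reference standard (V-PDB for carbon-13,
the SMOC-anchored laboratory scale for chlorine-37).  Everything
downstream — Rayleigh regression, dual-element slopes, apparent kinetic
isotope effects — works with ratios of ratios, so delta values are kept
in per-mil externally and converted to fractional ratio multipliers
``R = 1 + delta/1000`` at exactly one boundary: this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Element",
    "COMPOUNDS",
    "REFERENCE_BY_ELEMENT",
    "DeltaValue",
    "IsotopeMeasurement",
    "ExperimentSeries",
    "InvalidCompositionError",
    "InvalidInputError",
    "InsufficientDataError",
    "delta_to_ratio_factor",
    "ratio_factor_to_delta",
    "fraction_remaining",
    "validate_series",
]

#: Elements tracked by the dual-element analysis.
Element = str  # "C" or "Cl"

#: Chlorinated substrates of the dehalogenation assays.
COMPOUNDS = ("PCE", "TCE", "cDCE", "VC", "1,2-DCA")

#: International reference scale per element.  The chlorine scale is an
#: opaque laboratory scale anchored to SMOC; only ratios of ratios enter
#: any downstream computation, so no inter-standard conversion exists.
REFERENCE_BY_ELEMENT = {"C": "V-PDB", "Cl": "SMOC"}


class InvalidCompositionError(ValueError):
    """A delta value at or below -1000 permil implies a non-positive ratio."""


class InvalidInputError(ValueError):
    """Physically impossible input (e.g. non-positive initial concentration)."""


class InsufficientDataError(ValueError):
    """Too few measurements for the requested fit."""


@dataclass(frozen=True)
class DeltaValue:
    """An isotope composition in delta-notation.

    Parameters
    ----------
    value : float
        Per-mil deviation from the reference standard.  Must exceed
        -1000 permil (the isotope ratio must stay positive).
    element : {"C", "Cl"}
    reference : str, optional
        Reference-scale name; defaults to the element's standard scale
        and a mismatching element/reference pair is rejected.
    """

    value: float
    element: Element
    reference: str = ""

    def __post_init__(self) -> None:
        if self.element not in REFERENCE_BY_ELEMENT:
            raise InvalidInputError(
                f"unknown element {self.element!r}; expected one of "
                f"{sorted(REFERENCE_BY_ELEMENT)}"
            )
        expected = REFERENCE_BY_ELEMENT[self.element]
        if not self.reference:
            object.__setattr__(self, "reference", expected)
        elif self.reference != expected:
            raise InvalidInputError(
                f"reference {self.reference!r} does not match element "
                f"{self.element!r} (expected {expected!r})"
            )
        if not self.value > -1000.0:
            raise InvalidCompositionError(
                f"delta = {self.value} permil implies a non-positive isotope ratio"
            )

    @property
    def ratio_factor(self) -> float:
        return delta_to_ratio_factor(self)


def delta_to_ratio_factor(delta: DeltaValue | float) -> float:
    """Convert a delta value (permil) to the ratio multiplier ``R = 1 + delta``.

    ``delta`` is expressed as a fraction internally (permil / 1000); the
    returned multiplier is strictly positive.

    >>> delta_to_ratio_factor(0.0)
    1.0
    >>> delta_to_ratio_factor(-27.5)
    0.9725
    """
    value = delta.value if isinstance(delta, DeltaValue) else float(delta)
    if not value > -1000.0:
        raise InvalidCompositionError(
            f"delta = {value} permil implies a non-positive isotope ratio"
        )
    return 1.0 + value / 1000.0


def ratio_factor_to_delta(factor: float) -> float:
    """Inverse of :func:`delta_to_ratio_factor`; returns permil."""
    if not factor > 0.0:
        raise InvalidCompositionError(f"ratio factor must be positive, got {factor}")
    return (factor - 1.0) * 1000.0


def fraction_remaining(c_t: float, c_0: float) -> float:
    """Fraction of substrate remaining, ``f = C_t / C_0``.

    Concentrations must share units; the ratio is unit-free.  Values
    above 1 (measurement noise around the starting concentration) are
    returned with a warning rather than rejected.
    """
    if not c_0 > 0.0:
        raise InvalidInputError(f"initial concentration must be positive, got {c_0}")
    if c_t < 0.0:
        raise InvalidInputError(f"residual concentration must be >= 0, got {c_t}")
    f = c_t / c_0
    if f > 1.0:
        warnings.warn(
            f"fraction remaining {f:.3g} > 1 (residual above initial); "
            "returned unchanged",
            stacklevel=2,
        )
    return f


@dataclass
class IsotopeMeasurement:
    """One sacrificed vial's observation: fraction remaining plus deltas.

    At least one of ``delta_c`` / ``delta_cl`` must be present;
    ``sd_c`` / ``sd_cl`` are replicate standard deviations in permil.
    """

    vial_id: str
    compound: str
    cultivation_acceptor: str
    f: float
    delta_c: DeltaValue | None = None
    delta_cl: DeltaValue | None = None
    sd_c: float | None = None
    sd_cl: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.f:
            raise InvalidInputError(
                f"vial {self.vial_id!r}: fraction remaining must be > 0, got {self.f}"
            )
        if self.delta_c is None and self.delta_cl is None:
            raise InvalidInputError(
                f"vial {self.vial_id!r}: at least one element's delta is required"
            )
        for sd, name in ((self.sd_c, "sd_c"), (self.sd_cl, "sd_cl")):
            if sd is not None and sd < 0:
                raise InvalidInputError(f"vial {self.vial_id!r}: {name} must be >= 0")

    def delta(self, element: Element) -> DeltaValue | None:
        return self.delta_c if element == "C" else self.delta_cl


@dataclass
class ExperimentSeries:
    """One assay set: ordered vial measurements plus the starting composition.

    Mirrors the sacrificial-vial design: one compound, one cultivation
    history, vials sacrificed across fractions remaining, with the
    initial composition (``delta0_c``, ``delta0_cl``, permil) either
    supplied explicitly or taken from a reference point at f = 1.
    """

    series_id: str
    compound: str
    cultivation_acceptor: str
    measurements: list[IsotopeMeasurement] = field(default_factory=list)
    delta0_c: float | None = None
    delta0_cl: float | None = None

    def delta0(self, element: Element) -> float | None:
        explicit = self.delta0_c if element == "C" else self.delta0_cl
        if explicit is not None:
            return explicit
        ref = [
            m.delta(element).value
            for m in self.measurements
            if m.f == 1.0 and m.delta(element) is not None
        ]
        if ref:
            return sum(ref) / len(ref)
        return None

    def points(self, element: Element) -> list[tuple[float, float]]:
        """(f, delta_permil) pairs for one element, f = 1 reference excluded."""
        return [
            (m.f, m.delta(element).value)
            for m in self.measurements
            if m.delta(element) is not None and m.f < 1.0
        ]

    def paired_points(self) -> list[tuple[float, float]]:
        """(delta37Cl, delta13C) pairs where both elements were measured."""
        return [
            (m.delta_cl.value, m.delta_c.value)
            for m in self.measurements
            if m.delta_c is not None and m.delta_cl is not None
        ]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "series_id": self.series_id,
                    "compound": m.compound,
                    "cultivation_acceptor": m.cultivation_acceptor,
                    "vial_id": m.vial_id,
                    "replicate": m.replicate,
                    "f": m.f,
                    "delta13C_permil": None if m.delta_c is None else m.delta_c.value,
                    "delta37Cl_permil": None if m.delta_cl is None else m.delta_cl.value,
                    "sd13C_permil": m.sd_c,
                    "sd37Cl_permil": m.sd_cl,
                }
            )
        return pd.DataFrame(rows)


def validate_series(series: ExperimentSeries) -> list[str]:
    """Report-only consistency check; returns a list of violation messages.

    Flags: fewer than three vials, fractions outside (0, 1] (f > 1 is a
    warning-grade entry, f <= 0 an error-grade one), elements with no
    data, and a missing starting composition.  Never mutates the series.
    """
    violations: list[str] = []
    n = len(series.measurements)
    if n < 3:
        violations.append(
            f"insufficient points for regression: {n} measurement(s), need >= 3"
        )
    for m in series.measurements:
        if m.f > 1.0:
            violations.append(
                f"vial {m.vial_id!r}: f = {m.f:.3g} > 1 (noise above initial?)"
            )
    has_c = any(m.delta_c is not None for m in series.measurements)
    has_cl = any(m.delta_cl is not None for m in series.measurements)
    if not has_c and not has_cl:
        violations.append("no isotope data for either element")
    for element, has in (("C", has_c), ("Cl", has_cl)):
        if has and series.delta0(element) is None:
            violations.append(
                f"element {element}: no starting composition "
                "(no delta0 and no f = 1 reference point)"
            )
    seen: dict[tuple[str, int], int] = {}
    for m in series.measurements:
        key = (m.vial_id, m.replicate)
        seen[key] = seen.get(key, 0) + 1
    for (vial, rep), count in seen.items():
        if count > 1:
            violations.append(
                f"duplicate vial/replicate pair ({vial!r}, {rep}) appears {count}x"
            )
    return violations
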