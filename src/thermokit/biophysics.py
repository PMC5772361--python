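"""Equilibrium-potential and chord-conductance electrochemistry.

This module carries the closed-form arithmetic used to infer the ionic
selectivity of a non-selective cation channel from ion-substitution
experiments in a voltage-clamped cell.  The framework is the chord
(parallel-battery) conductance model: each permeant ion ``i`` contributes a
fractional conductance ``f_i`` (``sum f_i = 1``) driving current toward its
own Nernst equilibrium potential ``E_i``, so the zero-current (reversal)
potential of the whole channel is the conductance-weighted mean
``E_rev = sum f_i * E_i``.

Within that model, reducing the external concentration of one ion shifts its
equilibrium potential by a predictable amount, and the observed shift in the
channel's reversal potential is that predicted shift scaled by the ion's
fractional conductance.  The inference operations below are exactly this
ratio-of-shifts arithmetic, plus the two-ion bounds obtained by assuming one
of three candidate ions carries no current.

The Goldman-Hodgkin-Katz flux formalism is deliberately not used: the chord
model is linear, which is what makes shift ratios and two-battery bounds
exact, and it is the model under which the substitution arithmetic is
self-consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "CELSIUS_OFFSET",
    "IonSpecies",
    "SolutionComposition",
    "EquilibriumSet",
    "ChordModel",
    "SelectivityEstimate",
    "SubstitutionCondition",
    "SelectivityModel",
    "SelectivityResults",
    "nernst_potential",
    "equilibrium_set",
    "chord_reversal",
    "fraction_from_shift",
    "two_ion_chord_fraction",
    "remainder_bound",
    "fraction_bound_from_small_shift",
    "percent",
    "NA",
    "K",
    "CA",
    "MG",
    "CL",
    "ND96",
    "OOCYTE_INTERNAL",
]

GAS_CONSTANT = 8.314  # J / (mol K)
FARADAY = 96485.0  # C / mol
CELSIUS_OFFSET = 273.15


class DomainError(ValueError):
    """Raised when an operation is evaluated outside its physical domain."""


@dataclass(frozen=True)
class IonSpecies:
    """A permeant ion: a label and a signed valence ``z``."""

    name: str
    valence: int

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise DomainError(f"ion {self.name!r} must have non-zero valence")


NA = IonSpecies("Na", +1)
K = IonSpecies("K", +1)
CA = IonSpecies("Ca", +2)
MG = IonSpecies("Mg", +2)
CL = IonSpecies("Cl", -1)

#: valence lookup for the ions that appear in the standard recording solutions
STANDARD_VALENCES: dict[str, int] = {s.name: s.valence for s in (NA, K, CA, MG, CL)}


@dataclass(frozen=True)
class SolutionComposition:
    """Named ionic concentrations (mM) of a recording medium.

    Ions with zero concentration are omitted rather than listed as 0: the
    equilibrium potential of an absent ion is undefined, and "nominally free"
    solutions are represented by dropping the key.
    """

    name: str
    concentrations_mM: dict[str, float]
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        for ion, c in self.concentrations_mM.items():
            if not c > 0:
                raise DomainError(
                    f"solution {self.name!r}: concentration of {ion!r} must be "
                    f"strictly positive (got {c}); omit absent ions"
                )

    def __getitem__(self, ion: str) -> float:
        return self.concentrations_mM[ion]

    def __contains__(self, ion: str) -> bool:
        return ion in self.concentrations_mM


#: standard oocyte extracellular solution (cations only; 96 NaCl, 2 KCl,
#: 1.8 CaCl2, 1 MgCl2, 5 HEPES, pH-adjusted)
ND96 = SolutionComposition("ND96", {"Na": 96.0, "K": 2.0, "Ca": 1.8, "Mg": 1.0})

#: conventional intracellular reference concentrations for the oocyte
OOCYTE_INTERNAL = SolutionComposition(
    "oocyte-internal", {"Na": 7.0, "K": 100.0, "Ca": 0.1}
)


def thermal_voltage_mV(temperature_C: float) -> float:
    """RT/F in millivolts at the given temperature (``T = t + 273.15`` K)."""
    return GAS_CONSTANT * (temperature_C + CELSIUS_OFFSET) / FARADAY * 1000.0


def nernst_potential(
    ion: IonSpecies, c_out_mM: float, c_in_mM: float, temperature_C: float
) -> float:
    """Equilibrium potential ``(RT / zF) ln(c_out / c_in)`` in mV.

    Parameters
    ----------
    ion
        The permeant species; only its valence enters the formula.
    c_out_mM, c_in_mM
        Extracellular and intracellular concentrations in mM; both must be
        strictly positive.
    temperature_C
        Bath temperature in degrees Celsius.
    """
    if not (c_out_mM > 0 and c_in_mM > 0):
        raise DomainError(
            f"Nernst potential of {ion.name!r} requires strictly positive "
            f"concentrations (got out={c_out_mM}, in={c_in_mM} mM)"
        )
    return thermal_voltage_mV(temperature_C) / ion.valence * math.log(c_out_mM / c_in_mM)


@dataclass(frozen=True)
class EquilibriumSet:
    """Per-ion equilibrium potentials (mV) at a common temperature."""

    potentials_mV: dict[str, float]
    temperature_C: float

    def __getitem__(self, ion: str) -> float:
        return self.potentials_mV[ion]

    def __contains__(self, ion: str) -> bool:
        return ion in self.potentials_mV


def equilibrium_set(
    outside: SolutionComposition,
    inside: SolutionComposition = OOCYTE_INTERNAL,
    temperature_C: float | None = None,
    valences: dict[str, int] | None = None,
) -> EquilibriumSet:
    """Nernst potentials for every ion present in both solutions."""
    if temperature_C is None:
        temperature_C = outside.temperature_C
    valences = dict(STANDARD_VALENCES) | (valences or {})
    pot = {}
    for ion, c_out in outside.concentrations_mM.items():
        if ion in inside and ion in valences:
            pot[ion] = nernst_potential(
                IonSpecies(ion, valences[ion]), c_out, inside[ion], temperature_C
            )
    return EquilibriumSet(pot, temperature_C)


@dataclass(frozen=True)
class ChordModel:
    """Fractional conductances plus the equilibrium potentials they point to."""

    fractions: dict[str, float]
    equilibria: EquilibriumSet

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"chord fractions must sum to 1 (got {total!r})")
        missing = [i for i in self.fractions if i not in self.equilibria]
        if missing:
            raise DomainError(f"no equilibrium potential for ions {missing}")


def chord_reversal(model: ChordModel) -> float:
    """Reversal potential of a chord model: ``sum f_i * E_i`` in mV.

    The result necessarily lies between the smallest and largest single-ion
    equilibrium potential of the model.
    """
    return sum(f * model.equilibria[ion] for ion, f in model.fractions.items())


def _clamp_fraction(x: float, what: str) -> float:
    if 0.0 <= x <= 1.0:
        return x
    clipped = min(1.0, max(0.0, x))
    warnings.warn(
        f"{what} = {x:.4f} lies outside [0, 1]; clamped to {clipped:.2f} "
        "(measurement noise can overshoot the chord-model bounds)",
        stacklevel=3,
    )
    return clipped


def fraction_from_shift(
    erev_a_mV: float,
    erev_b_mV: float,
    e_nernst_a_mV: float,
    e_nernst_b_mV: float,
    clamp: bool = True,
) -> float:
    """Fractional conductance from a substitution experiment.

    Under the chord model, replacing part of one ion's external concentration
    shifts the channel reversal potential by the ion's fraction times the
    shift of its own Nernst potential, so

        f = (erev_b - erev_a) / (E_b - E_a).

    ``a`` and ``b`` label the two solution conditions.  Values outside [0, 1]
    are clamped with a warning when ``clamp`` is true.
    """
    denom = e_nernst_b_mV - e_nernst_a_mV
    if denom == 0:
        raise DomainError("predicted Nernst shift is zero; fraction undefined")
    f = (erev_b_mV - erev_a_mV) / denom
    return _clamp_fraction(f, "shift-ratio fraction") if clamp else f


def two_ion_chord_fraction(erev_mV: float, e_self_mV: float, e_other_mV: float) -> float:
    """Fraction of the "self" ion in a two-ion chord model.

    With only two batteries, ``erev = f*E_self + (1-f)*E_other`` inverts to
    ``f = (E_other - erev) / (E_other - E_self)``.  The reversal potential
    must lie between the two equilibria.
    """
    if e_self_mV == e_other_mV:
        raise DomainError("the two equilibrium potentials coincide")
    lo, hi = sorted((e_self_mV, e_other_mV))
    if not (lo <= erev_mV <= hi):
        raise DomainError(
            f"reversal {erev_mV} mV lies outside the two-ion range [{lo}, {hi}] mV"
        )
    return (e_other_mV - erev_mV) / (e_other_mV - e_self_mV)


def remainder_bound(fractions_assigned: dict[str, float]) -> float:
    """Upper bound ``1 - sum(assigned)`` on the unassigned ion's fraction.

    Printed estimates can overshoot (sum slightly above 1); the bound is then
    floored at 0 with a warning.  A sum far above 1 indicates an input error
    and raises.
    """
    for ion, f in fractions_assigned.items():
        if not (0.0 <= f <= 1.0):
            raise DomainError(f"assigned fraction for {ion!r} must be in [0,1]")
    total = sum(fractions_assigned.values())
    if total > 1.25:
        raise DomainError(f"assigned fractions sum to {total:.3f} > 1")
    rest = 1.0 - total
    if rest < 0:
        warnings.warn(
            f"assigned fractions sum to {total:.3f}; remainder {rest:.3f} "
            "floored at 0",
            stacklevel=2,
        )
        return 0.0
    return rest


def fraction_bound_from_small_shift(delta_erev_max_mV: float, delta_e_ion_mV: float) -> float:
    """Upper bound on a fraction from a small observed reversal shift.

    If substituting an ion moves its Nernst potential by ``delta_e_ion`` but
    the channel reversal moves by at most ``delta_erev_max``, the chord model
    bounds the ion's fraction by the ratio of the magnitudes (capped at 1).
    """
    if delta_e_ion_mV == 0:
        raise DomainError("zero equilibrium-potential shift; bound undefined")
    return min(1.0, abs(delta_erev_max_mV) / abs(delta_e_ion_mV))


def percent(fraction: float) -> int:
    """Integer percent, rounding half away from zero."""
    scaled = fraction * 100.0
    return int(math.floor(scaled + 0.5)) if scaled >= 0 else -int(math.floor(-scaled + 0.5))


# ---------------------------------------------------------------------------
# Selectivity inference as a fitted model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionCondition:
    """One recording condition of an ion-substitution series.

    ``c_out_mM`` is the external concentration of the substituted ion (the
    remainder replaced by an impermeant cation such as NMDG+), ``erev_mV`` the
    measured channel reversal potential, ``sem_mV`` its standard error.
    """

    label: str
    c_out_mM: float
    erev_mV: float
    sem_mV: float | None = None


@dataclass
class SelectivityEstimate:
    """Point fractions, bounds, and the shift computations behind them."""

    point_fractions: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ion, (lo, hi) in self.bounds.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise DomainError(f"bounds for {ion!r} must satisfy 0<=lo<=hi<=1")
            p = self.point_fractions.get(ion)
            if p is not None and not (lo - 1e-12 <= p <= hi + 1e-12):
                raise DomainError(f"point fraction for {ion!r} outside its bounds")
        for ion, p in self.point_fractions.items():
            if not (0.0 <= p <= 1.0):
                raise DomainError(f"point fraction for {ion!r} must be in [0,1]")


class SelectivityModel:
    """Chord-model selectivity inference from an ion-substitution series.

    The model is built from the measured reversal potentials under a series
    of external concentrations of one substituted ion (highest concentration
    = reference condition) plus the fixed concentrations of the other
    candidate ions.  ``fit`` runs the shift-ratio arithmetic:

    * the substituted ion's fraction from each reduced condition is the
      observed reversal shift over the predicted Nernst shift; the point
      estimate is their mean;
    * the second ion's fraction is bracketed by the two-ion chord values
      obtained by assuming each of the other candidates carries no current;
    * the third ion's fraction is bounded above by the remainder.

    Parameters
    ----------
    conditions
        Substitution series for ``substituted_ion``; at least two, including
        the reference (highest ``c_out_mM``).
    substituted_ion, bracketed_ion, remainder_ion
        The ion whose concentration varies, the ion bracketed by two-ion
        models, and the ion bounded by the remainder.
    internal
        Intracellular reference concentrations.
    fixed_external_mM
        External concentrations of the non-substituted candidates in the
        reference solution.
    temperature_C
        Recording temperature.
    """

    def __init__(
        self,
        conditions: list[SubstitutionCondition],
        substituted_ion: IonSpecies = NA,
        bracketed_ion: IonSpecies = K,
        remainder_ion: IonSpecies = CA,
        internal: SolutionComposition = OOCYTE_INTERNAL,
        fixed_external_mM: dict[str, float] | None = None,
        temperature_C: float = 35.0,
    ) -> None:
        if len(conditions) < 2:
            raise DomainError("need a reference plus at least one reduced condition")
        self.conditions = sorted(conditions, key=lambda c: -c.c_out_mM)
        self.substituted_ion = substituted_ion
        self.bracketed_ion = bracketed_ion
        self.remainder_ion = remainder_ion
        self.internal = internal
        self.fixed_external_mM = fixed_external_mM or {
            bracketed_ion.name: ND96[bracketed_ion.name],
            remainder_ion.name: ND96[remainder_ion.name],
        }
        self.temperature_C = temperature_C

    @classmethod
    def from_nd96_series(
        cls, erevs_mV: dict[float, float], temperature_C: float = 35.0
    ) -> "SelectivityModel":
        """Convenience constructor: {external Na+ mM: measured Erev mV}."""
        conds = [
            SubstitutionCondition(f"Na {c:g} mM", c, e) for c, e in erevs_mV.items()
        ]
        return cls(conds, temperature_C=temperature_C)

    def _nernst(self, ion: IonSpecies, c_out: float) -> float:
        return nernst_potential(ion, c_out, self.internal[ion.name], self.temperature_C)

    def fit(self) -> "SelectivityResults":
        sub, brk, rem = self.substituted_ion, self.bracketed_ion, self.remainder_ion
        ref = self.conditions[0]
        provenance: list[str] = []

        e_sub_ref = self._nernst(sub, ref.c_out_mM)
        e_brk = self._nernst(brk, self.fixed_external_mM[brk.name])
        e_rem = self._nernst(rem, self.fixed_external_mM[rem.name])

        per_condition: dict[str, float] = {}
        for cond in self.conditions[1:]:
            e_sub = self._nernst(sub, cond.c_out_mM)
            f = fraction_from_shift(ref.erev_mV, cond.erev_mV, e_sub_ref, e_sub)
            per_condition[cond.label] = f
            provenance.append(
                f"{sub.name} fraction from {ref.label} -> {cond.label}: "
                f"dErev {cond.erev_mV - ref.erev_mV:+.1f} mV / "
                f"dE_{sub.name} {e_sub - e_sub_ref:+.1f} mV = {f:.4f}"
            )
        f_sub = sum(per_condition.values()) / len(per_condition)

        # bracket the second ion with the two extreme two-ion chord models
        f_brk_hi = two_ion_chord_fraction(ref.erev_mV, e_brk, e_sub_ref)
        provenance.append(
            f"{brk.name} upper bound (zero {rem.name} conductance): "
            f"({e_sub_ref:.1f} - {ref.erev_mV:.1f})/({e_sub_ref:.1f} - {e_brk:.1f}) "
            f"= {f_brk_hi:.4f}"
        )
        f_brk_lo = two_ion_chord_fraction(ref.erev_mV, e_brk, e_rem)
        provenance.append(
            f"{brk.name} lower bound (zero {sub.name} conductance): "
            f"({e_rem:.1f} - {ref.erev_mV:.1f})/({e_rem:.1f} - {e_brk:.1f}) "
            f"= {f_brk_lo:.4f}"
        )

        f_rem_hi = remainder_bound({sub.name: f_sub, brk.name: f_brk_lo})
        provenance.append(
            f"{rem.name} upper bound: 1 - {f_sub:.4f} - {f_brk_lo:.4f} = {f_rem_hi:.4f}"
        )

        estimate = SelectivityEstimate(
            point_fractions={sub.name: f_sub},
            bounds={
                sub.name: (min(per_condition.values()), max(per_condition.values()))
                if len(per_condition) > 1
                else (f_sub, f_sub),
                brk.name: (min(f_brk_lo, f_brk_hi), max(f_brk_lo, f_brk_hi)),
                rem.name: (0.0, f_rem_hi),
            },
            provenance=provenance,
        )
        equilibria = EquilibriumSet(
            {sub.name: e_sub_ref, brk.name: e_brk, rem.name: e_rem},
            self.temperature_C,
        )
        return SelectivityResults(self, estimate, per_condition, equilibria)


class SelectivityResults:
    """Fitted fractional conductances with bounds and a summary table."""

    def __init__(
        self,
        model: SelectivityModel,
        estimate: SelectivityEstimate,
        per_condition: dict[str, float],
        equilibria: EquilibriumSet,
    ) -> None:
        self.model = model
        self.estimate = estimate
        self.per_condition_fractions = per_condition
        self.equilibria = equilibria

    @property
    def point_fractions(self) -> dict[str, float]:
        return self.estimate.point_fractions

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return self.estimate.bounds

    def summary(self) -> str:
        lines = [
            "Chord-conductance selectivity estimate",
            f"  temperature: {self.model.temperature_C:.1f} C",
            "  equilibrium potentials (mV): "
            + ", ".join(f"{i}={e:+.1f}" for i, e in self.equilibria.potentials_mV.items()),
            "  fractional conductances:",
        ]
        for ion, (lo, hi) in self.bounds.items():
            point = self.point_fractions.get(ion)
            if point is not None:
                lines.append(
                    f"    {ion:<3} {percent(point):3d}%  (per-condition "
                    f"{percent(lo)}-{percent(hi)}%)"
                )
            elif lo == 0.0:
                lines.append(f"    {ion:<3} <= {percent(hi)}%")
            else:
                lines.append(f"    {ion:<3} {percent(lo)}-{percent(hi)}%")
        lines.append("  provenance:")
        lines.extend(f"    {p}" for p in self.estimate.provenance)
        return "\n".join(lines)
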