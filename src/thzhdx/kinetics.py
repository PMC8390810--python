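"""Two-state (Linderstrøm-Lang) hydrogen-exchange kinetics.

Backbone amide hydrogens of a folded protein exchange with solvent deuterons
through transient structural openings,

    NH(closed)  <==[K_op]==>  NH(open)  --[k_ch]-->  ND (exchanged),

where ``K_op = k_op / k_cl`` is the opening equilibrium constant and ``k_ch``
the intrinsic chemical exchange rate of the exposed amide.  When closing is
much faster than chemistry (the EX2 limit, typical for native proteins) the
observed rate is ``k_ex = K_op * k_ch``; when chemistry outpaces closing (EX1)
it is the opening rate ``k_op``.  This module provides the general steady-state
rate, both limits, pH and temperature scaling of the intrinsic rate, and the
evolution of the protonated fraction over piecewise experimental protocols
(handling, perturbation, room-temperature hold, quenched cold storage).

Units: rates in h^-1, durations in minutes (protocol granularity), energies in
kJ/mol, temperatures in K unless a ``_c`` suffix marks Celsius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Iterable, Mapping

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .experiment import ResidueModel

__all__ = [
    "R_GAS_KJ",
    "ExchangeParams",
    "IntrinsicRateModel",
    "Phase",
    "PhaseSchedule",
    "ReferenceConditions",
    "DEFAULT_REFERENCE",
    "celsius_to_kelvin",
    "exchange_rate_general",
    "ex2_rate",
    "scale_kch_ph",
    "scale_kch_temperature",
    "phase_exchange_rate",
    "protonated_fraction",
]

#: Gas constant in kJ/(mol K).
R_GAS_KJ = 8.314462618e-3


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass(frozen=True)
class ExchangeParams:
    """Microscopic rates of the two-state opening scheme.

    ``K_op`` may be supplied explicitly (e.g. when only the equilibrium is
    known); when both ``k_cl > 0`` and ``K_op`` are given they must agree with
    ``k_op / k_cl`` to 1e-9 relative.
    """

    k_op: float
    k_cl: float
    k_ch: float
    K_op: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_op", "k_cl", "k_ch"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a finite non-negative rate, got {value!r}")
        if self.K_op is None:
            if self.k_cl > 0:
                object.__setattr__(self, "K_op", self.k_op / self.k_cl)
        else:
            if self.K_op <= 0:
                raise ValueError(f"K_op must be positive, got {self.K_op!r}")
            if self.k_cl > 0:
                implied = self.k_op / self.k_cl
                if implied > 0 and abs(self.K_op - implied) > 1e-9 * implied:
                    raise ValueError(
                        f"K_op={self.K_op!r} inconsistent with k_op/k_cl={implied!r}"
                    )


@dataclass(frozen=True)
class IntrinsicRateModel:
    """Intrinsic chemical exchange rate at reference conditions.

    The pH dependence is pure base catalysis (tenfold per pH unit); the
    temperature dependence is Arrhenius with activation energy ``ea_kj_mol``.
    """

    k_ref: float
    ph_ref: float = 6.4
    t_ref_k: float = 298.15
    ea_kj_mol: float = 60.0

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError(f"k_ref must be positive, got {self.k_ref!r}")
        if self.ea_kj_mol < 0:
            raise ValueError(f"ea_kj_mol must be non-negative, got {self.ea_kj_mol!r}")
        if self.t_ref_k <= 0:
            raise ValueError(f"t_ref_k must be positive, got {self.t_ref_k!r}")


@dataclass(frozen=True)
class ReferenceConditions:
    """Conditions at which per-residue ``k_ch_ref`` values are quoted."""

    ph: float = 6.4
    temperature_c: float = 25.0
    ea_kj_mol: float = 60.0


DEFAULT_REFERENCE = ReferenceConditions()


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a constant-condition interval.

    Per-class multipliers perturb opening equilibria (``kop``) or intrinsic
    chemistry (``kch``) for residues of the named hydropathy classes; classes
    absent from a map are unperturbed (factor 1).
    """

    duration_min: float
    temperature_c: float
    ph: float
    kop_multiplier_by_class: Mapping[str, float] = field(default_factory=dict)
    kch_multiplier_by_class: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.duration_min) or self.duration_min < 0:
            raise ValueError(f"duration_min must be finite and >= 0, got {self.duration_min!r}")
        for label, mapping in (
            ("kop", self.kop_multiplier_by_class),
            ("kch", self.kch_multiplier_by_class),
        ):
            for cls, factor in mapping.items():
                if factor <= 0:
                    raise ValueError(f"{label} multiplier for {cls!r} must be > 0, got {factor!r}")
        # freeze the maps so Phase instances are safely hashable/shareable
        object.__setattr__(self, "kop_multiplier_by_class", dict(self.kop_multiplier_by_class))
        object.__setattr__(self, "kch_multiplier_by_class", dict(self.kch_multiplier_by_class))


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous list of protocol phases."""

    phases: tuple[Phase, ...]

    def __init__(self, phases: Iterable[Phase]) -> None:
        object.__setattr__(self, "phases", tuple(phases))
        if not self.phases:
            raise ValueError("schedule must contain at least one phase")
        if self.total_duration_min <= 0:
            raise ValueError("schedule total duration must be positive")

    @property
    def total_duration_min(self) -> float:
        return sum(p.duration_min for p in self.phases)

    def to_dict(self) -> dict[str, Any]:
        return {
            "phases": [
                {
                    "duration_min": p.duration_min,
                    "temperature_c": p.temperature_c,
                    "ph": p.ph,
                    "kop_multiplier_by_class": dict(p.kop_multiplier_by_class),
                    "kch_multiplier_by_class": dict(p.kch_multiplier_by_class),
                }
                for p in self.phases
            ]
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PhaseSchedule":
        return cls(
            Phase(
                duration_min=p["duration_min"],
                temperature_c=p["temperature_c"],
                ph=p["ph"],
                kop_multiplier_by_class=p.get("kop_multiplier_by_class", {}),
                kch_multiplier_by_class=p.get("kch_multiplier_by_class", {}),
            )
            for p in data["phases"]
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhaseSchedule":
        return cls.from_dict(yaml.safe_load(text))


def exchange_rate_general(params: ExchangeParams) -> float:
    """Steady-state observed exchange rate of the two-state scheme (h^-1).

    ``k_op * k_ch / (k_op + k_cl + k_ch)``: reduces to ``K_op * k_ch`` in the
    EX2 limit (k_cl >> k_ch, k_op) and to ``k_op`` in the EX1 limit
    (k_ch >> k_op + k_cl).
    """
    denom = params.k_op + params.k_cl + params.k_ch
    if denom == 0:
        return 0.0
    return params.k_op * params.k_ch / denom


def ex2_rate(K_op: float, k_ch: float) -> float:
    """EX2-limit exchange rate ``K_op * k_ch`` (h^-1)."""
    if K_op <= 0:
        raise ValueError(f"K_op must be positive, got {K_op!r}")
    if k_ch < 0:
        raise ValueError(f"k_ch must be non-negative, got {k_ch!r}")
    return K_op * k_ch


def scale_kch_ph(model: IntrinsicRateModel, ph: float) -> float:
    """Intrinsic rate at ``ph`` under pure base catalysis: tenfold per pH unit."""
    if not math.isfinite(ph):
        raise ValueError(f"ph must be finite, got {ph!r}")
    return model.k_ref * 10.0 ** (ph - model.ph_ref)


def scale_kch_temperature(model: IntrinsicRateModel, t_k: float) -> float:
    """Intrinsic rate at temperature ``t_k`` via Arrhenius scaling."""
    if t_k <= 0:
        raise ValueError(f"temperature must be positive (K), got {t_k!r}")
    return model.k_ref * math.exp(-model.ea_kj_mol / R_GAS_KJ * (1.0 / t_k - 1.0 / model.t_ref_k))


def phase_exchange_rate(
    phase: Phase,
    residue: "ResidueModel",
    reference: ReferenceConditions = DEFAULT_REFERENCE,
) -> float:
    """EX2 exchange rate (h^-1) of ``residue`` under one phase's conditions.

    The residue's ``k_ch_ref`` (quoted at the reference pH and temperature) is
    rescaled to the phase pH (base catalysis) and temperature (Arrhenius), then
    class multipliers on K_op and k_ch are applied.
    """
    model = IntrinsicRateModel(
        k_ref=residue.k_ch_ref if residue.k_ch_ref > 0 else 1.0,
        ph_ref=reference.ph,
        t_ref_k=celsius_to_kelvin(reference.temperature_c),
        ea_kj_mol=reference.ea_kj_mol,
    )
    if residue.k_ch_ref == 0:
        return 0.0
    k_ch = scale_kch_ph(model, phase.ph)
    k_ch *= scale_kch_temperature(model, celsius_to_kelvin(phase.temperature_c)) / model.k_ref
    k_ch *= phase.kch_multiplier_by_class.get(residue.hydropathy_class, 1.0)
    k_op_eff = residue.K_op * phase.kop_multiplier_by_class.get(residue.hydropathy_class, 1.0)
    return ex2_rate(k_op_eff, k_ch)


def protonated_fraction(
    schedule: PhaseSchedule,
    residue: "ResidueModel",
    reference: ReferenceConditions = DEFAULT_REFERENCE,
) -> float:
    """Fraction of the residue's amides still protonated after the schedule.

    First-order irreversible exchange into excess D2O:
    ``prod_i exp(-k_ex,i * dt_i)`` with the per-phase EX2 rate.  Lies in
    (0, 1], is non-increasing as phases are appended and invariant under
    subdividing a phase.
    """
    if residue.K_op <= 0 or residue.k_ch_ref < 0:
        raise ValueError("residue must have K_op > 0 and k_ch_ref >= 0")
    log_p = 0.0
    for phase in schedule.phases:
        k_ex = phase_exchange_rate(phase, residue, reference)
        log_p -= k_ex * phase.duration_min / 60.0
    return math.exp(log_p)
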