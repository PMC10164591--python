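"""Domain types for the deadenylation kinetics model.

The central objects are immutable specifications of a reaction: the RNA
substrate (a non-A "body" carrying a 3'-terminal poly(A) tail), the
multi-subunit deadenylase complex (two catalytic subunits, CCR4 and CAF1,
plus the NOT module that mediates Smaug tethering), the effector proteins
(Smaug, Cup, PABPC) and the rate constants of the mechanism.  Simulation
output is a :class:`TimeCourseEnsemble`: per-molecule tail lengths sampled
on a time grid, with the generating parameters attached as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidInputError",
    "ConfigError",
    "InsufficientDataError",
    "UndefinedModeError",
    "FitFailureError",
    "NonIdentifiableError",
    "SubstrateSpec",
    "EnzymeSpec",
    "EffectorSpec",
    "KineticParams",
    "PopulationState",
    "TimeCourseEnsemble",
    "Curve",
    "fam7_a20",
    "sre_only_a70",
    "tce_a70",
    "mini_complex",
    "core_complex",
    "heterodimer",
    "smaug",
    "cup",
    "pabpc",
]


class InvalidInputError(ValueError):
    """An argument violates a precondition (negative rate, empty grid, ...)."""


class ConfigError(ValueError):
    """A configuration file or mapping fails validation."""


class InsufficientDataError(ValueError):
    """Too few usable data points for an estimator."""


class UndefinedModeError(ValueError):
    """A modal length was requested from an all-zero intensity profile."""


class FitFailureError(RuntimeError):
    """A nonlinear fit did not converge; the message carries diagnostics."""


class NonIdentifiableError(RuntimeError):
    """A free parameter has no influence on the observed data."""

    def __init__(self, parameter: str, message: str | None = None):
        self.parameter = parameter
        super().__init__(message or f"parameter {parameter!r} is not identifiable from the data")


@dataclass(frozen=True)
class SubstrateSpec:
    """An RNA species: a non-A body 5' of an initially homogeneous poly(A) tail.

    ``n_sre`` counts Smaug recognition elements in the body; a point mutation
    in the elements is modelled by ``sre_functional=False`` (Smaug then does
    not bind at all).  ``initial_conc`` is the substrate concentration in nM.
    """

    name: str
    body_length: int
    tail_length0: int
    n_sre: int = 0
    sre_functional: bool = True
    initial_conc: float = 0.0

    def __post_init__(self):
        if self.body_length < 1:
            raise InvalidInputError("body_length must be >= 1")
        if self.tail_length0 < 0:
            raise InvalidInputError("tail_length0 must be >= 0")
        if self.n_sre < 0:
            raise InvalidInputError("n_sre must be >= 0")
        if self.initial_conc < 0:
            raise InvalidInputError("initial_conc must be >= 0")


def fam7_a20(conc: float = 50.0) -> SubstrateSpec:
    """Minimal synthetic substrate: 7-nt body plus 20 3'-terminal A residues."""
    return SubstrateSpec("FAM 7mer-A20", body_length=7, tail_length0=20,
                         n_sre=0, sre_functional=False, initial_conc=conc)


def sre_only_a70(conc: float = 20.0, wild_type: bool = True) -> SubstrateSpec:
    """Short RNA with two Smaug recognition elements and a ~70-nt poly(A) tail.

    The body length is a modelling choice (gels only need it to be fixed);
    the tail length and SRE count follow the experimental substrate.
    """
    name = "SRE(WT)-A70" if wild_type else "SRE(MUT)-A70"
    return SubstrateSpec(name, body_length=80, tail_length0=70,
                         n_sre=2, sre_functional=wild_type, initial_conc=conc)


def tce_a70(conc: float = 50.0, wild_type: bool = True) -> SubstrateSpec:
    """Longer SRE-containing substrate used for burst-phase experiments."""
    name = "TCE(WT)-A70" if wild_type else "TCE(MUT)-A70"
    return SubstrateSpec(name, body_length=150, tail_length0=70,
                         n_sre=2, sre_functional=wild_type, initial_conc=conc)


@dataclass(frozen=True)
class EnzymeSpec:
    """A deadenylase complex variant.

    ``ccr4_active`` / ``caf1_active`` encode active-site point mutants: a
    False flag means the subunit is present but catalytically dead.  If both
    are False the complex removes zero nucleotides in any simulation.
    ``has_not_module`` is True for MINI/FULL complexes and False for the CORE
    complex and the CCR4-CAF1 heterodimer; without the NOT module, Smaug
    tethering is disabled.
    """

    name: str
    conc: float
    ccr4_active: bool = True
    caf1_active: bool = True
    has_not_module: bool = True

    def __post_init__(self):
        if self.conc < 0:
            raise InvalidInputError("enzyme conc must be >= 0")


def mini_complex(conc: float, ccr4_active: bool = True, caf1_active: bool = True) -> EnzymeSpec:
    return EnzymeSpec("CCR4-NOT(MINI)", conc, ccr4_active, caf1_active, has_not_module=True)


def core_complex(conc: float) -> EnzymeSpec:
    return EnzymeSpec("CCR4-NOT(CORE)", conc, has_not_module=False)


def heterodimer(conc: float) -> EnzymeSpec:
    return EnzymeSpec("CCR4-CAF1", conc, has_not_module=False)


@dataclass(frozen=True)
class EffectorSpec:
    """An effector protein at equilibrium with its binding site.

    ``kd`` is the equilibrium binding constant of the effector for its site
    on the substrate (SREs for Smaug, anywhere on the RNA for Cup, a poly(A)
    segment for PABPC).  ``params`` carries kind-specific modifiers that are
    not rate constants (currently unused; the multipliers live in
    :class:`KineticParams`).
    """

    kind: str
    conc: float
    kd: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("smaug", "cup", "pabpc"):
            raise InvalidInputError(f"unknown effector kind {self.kind!r}")
        if self.conc < 0:
            raise InvalidInputError("effector conc must be >= 0")
        if self.kd <= 0:
            raise InvalidInputError("effector kd must be > 0")


def smaug(conc: float, kd: float = 1.0) -> EffectorSpec:
    return EffectorSpec("smaug", conc, kd)


def cup(conc: float, kd: float = 20.0) -> EffectorSpec:
    return EffectorSpec("cup", conc, kd)


def pabpc(conc: float, kd: float = 10.0) -> EffectorSpec:
    return EffectorSpec("pabpc", conc, kd)


@dataclass(frozen=True)
class KineticParams:
    """All rate constants, occupancies and footprints of the mechanism.

    Units: ``k_on`` in /nM/s, ``k_off`` and ``handoff_rate`` in /s, catalytic
    rates in nt removed per second per engaged subunit.  ``theta_dead`` is the
    fraction of engaged time during which a catalytically dead subunit holds
    the 3' end, occluding it from its active partner.  ``tether_off_scale``
    multiplies ``k_off`` when a NOT-module-competent complex is engaged on a
    Smaug-occupied substrate; ``handoff_rate`` is the exponential waiting rate
    between finishing one tail and engaging the next in the processive regime.
    ``cup_on_scale`` multiplies ``k_on`` when Cup occupies the substrate.
    PABPC covers the tail with ``pabpc_footprint`` nt per copy; a covered 3'
    end reduces enzyme association by ``pabpc_end_block``, catalysis through
    covered poly(A) is scaled by ``pabpc_stim``, and each copy beyond the
    first reduces effector-mediated association by ``pabpc_recruit_block``.

    The defaults are the declared model configuration: no rate constants are
    measured directly, so they are chosen to reproduce the observed reaction
    behaviour (see docs/methods.md).
    """

    k_on: float = 0.010
    k_off: float = 200.0
    k_cat_ccr4: float = 25.0
    k_cat_caf1: float = 25.0
    theta_dead: float = 0.6
    tether_off_scale: float = 2.5e-5
    handoff_rate: float = 0.1
    cup_on_scale: float = 10.0
    pabpc_footprint: int = 17
    pabpc_end_block: float = 0.2
    pabpc_stim: float = 1.5
    pabpc_recruit_block: float = 0.5

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_cat_ccr4", "k_cat_caf1", "handoff_rate"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for name in ("tether_off_scale", "cup_on_scale", "pabpc_end_block",
                     "pabpc_stim", "pabpc_recruit_block"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if not 0.0 <= self.theta_dead <= 1.0:
            raise InvalidInputError("theta_dead must be in [0, 1]")
        if self.pabpc_footprint <= 0:
            raise InvalidInputError("pabpc_footprint must be > 0")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass
class PopulationState:
    """Per-molecule state of the substrate population at one time point."""

    time: float
    tail_lengths: np.ndarray
    enzyme_bound: np.ndarray
    pabpc_copies: np.ndarray
    effector_occupied: dict


@dataclass
class TimeCourseEnsemble:
    """A simulated deadenylation time course with its generating ground truth."""

    substrate: SubstrateSpec
    enzyme: EnzymeSpec
    effectors: tuple
    params: KineticParams
    grid: np.ndarray
    states: list
    seed: int
    ground_truth: dict


class Curve(NamedTuple):
    """A summary statistic sampled on a time grid (times in seconds)."""

    times: np.ndarray
    values: np.ndarray
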