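"""Competitive-binding equilibrium and qPCR readout forward model.

A detection probe and one or more competitor ligands bind a single target
site reversibly.  Given total concentrations and dissociation constants the
equilibrium is fully determined by the free-target concentration, which is
the unique root of a monotone mass-balance equation on ``[0, t_tot]``.  The
amount of target-bound probe is then mapped to a qPCR quantification cycle
(Cq): less bound probe means fewer template copies and a later Cq.

All concentrations are in nM.  Inactive competitors are represented by the
sentinel dissociation constant :data:`INFINITE_KD`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

from scipy.optimize import brentq

__all__ = [
    "INFINITE_KD",
    "BindingSystem",
    "EquilibriumState",
    "QpcrCalibration",
    "solve_competitive_equilibrium",
    "multi_bound_probe",
    "bound_probe",
    "two_species_bound",
    "cq_from_bound",
    "delta_cq_forward",
]

#: Sentinel dissociation constant for compounds that do not bind at all.
INFINITE_KD = math.inf

# brentq cannot accept an rtol below ~4*eps; tolerances tighter than that
# are clamped silently.
_MIN_RTOL = 1e-15


def _check_conc(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValueError(f"{name} must be a finite number, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and affinities for one well.

    Parameters
    ----------
    t_tot : float
        Total target concentration, nM.
    p_tot : float
        Total detection-probe concentration, nM.
    i_tot : float
        Total competitor-compound concentration, nM.
    kd_probe : float
        Probe-target dissociation constant, nM.
    kd_compound : float
        Compound-target dissociation constant, nM; ``INFINITE_KD`` marks an
        inactive compound.
    """

    t_tot: float
    p_tot: float
    i_tot: float = 0.0
    kd_probe: float = 1.32
    kd_compound: float = INFINITE_KD

    def __post_init__(self) -> None:
        _check_conc("t_tot", self.t_tot)
        _check_conc("p_tot", self.p_tot)
        _check_conc("i_tot", self.i_tot)
        if not (math.isfinite(self.kd_probe) and self.kd_probe > 0):
            raise ValueError(f"kd_probe must be finite and > 0, got {self.kd_probe!r}")
        if not self.kd_compound > 0:  # also rejects NaN
            raise ValueError(
                f"kd_compound must be > 0 (INFINITE_KD for inactive), got {self.kd_compound!r}"
            )


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound species concentrations at equilibrium (nM)."""

    free_t: float
    free_p: float
    free_i: float
    bound_tp: float
    bound_ti: float


@dataclass(frozen=True)
class QpcrCalibration:
    """Anchor mapping bound-probe quantity to a quantification cycle.

    ``efficiency`` is the per-cycle amplification gain in (0, 1]; 1 means
    perfect doubling, so a twofold drop in template adds exactly one cycle.
    """

    cq_ref: float
    bound_ref: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cq_ref)):
            raise ValueError(f"cq_ref must be finite, got {self.cq_ref!r}")
        if not (math.isfinite(self.bound_ref) and self.bound_ref > 0):
            raise ValueError(f"bound_ref must be > 0, got {self.bound_ref!r}")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError(f"efficiency must be in (0, 1], got {self.efficiency!r}")


def _free_target(
    t_tot: float,
    p_tot: float,
    kd_probe: float,
    competitors: Sequence[Tuple[float, float]],
    tol: float,
) -> float:
    """Root of the target mass balance; monotone increasing in free target."""
    if t_tot == 0.0:
        return 0.0

    def balance(ft: float) -> float:
        total = ft + ft * p_tot / (kd_probe + ft)
        for c_tot, kd in competitors:
            if math.isfinite(kd):
                total += ft * c_tot / (kd + ft)
        return total - t_tot

    # balance(0) = -t_tot < 0 and balance(t_tot) >= 0, so the bracket always
    # holds for valid inputs.
    return brentq(
        balance, 0.0, t_tot, xtol=1e-30, rtol=max(tol, _MIN_RTOL), maxiter=200
    )


def multi_bound_probe(
    t_tot: float,
    p_tot: float,
    kd_probe: float,
    competitors: Sequence[Tuple[float, float]] = (),
    tol: float = 1e-12,
) -> float:
    """Bound-probe concentration with any number of 1:1 competitors.

    ``competitors`` is a sequence of ``(total_concentration, kd)`` pairs;
    entries with an infinite kd contribute nothing.
    """
    _check_conc("t_tot", t_tot)
    _check_conc("p_tot", p_tot)
    if not (math.isfinite(kd_probe) and kd_probe > 0):
        raise ValueError(f"kd_probe must be finite and > 0, got {kd_probe!r}")
    for c_tot, kd in competitors:
        _check_conc("competitor concentration", c_tot)
        if not kd > 0:
            raise ValueError(f"competitor kd must be > 0, got {kd!r}")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ft = _free_target(t_tot, p_tot, kd_probe, competitors, tol)
    return ft * p_tot / (kd_probe + ft)


def solve_competitive_equilibrium(sys: BindingSystem, tol: float = 1e-12) -> EquilibriumState:
    """Solve the three-species (target/probe/compound) equilibrium.

    Returns the unique state satisfying the mass-action relations
    ``bound_tp = free_t*free_p/kd_probe`` and
    ``bound_ti = free_t*free_i/kd_compound`` together with all three mass
    balances, each to relative tolerance ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ft = _free_target(
        sys.t_tot, sys.p_tot, sys.kd_probe, [(sys.i_tot, sys.kd_compound)], tol
    )
    fp = sys.p_tot * sys.kd_probe / (sys.kd_probe + ft)
    bound_tp = ft * sys.p_tot / (sys.kd_probe + ft)
    if math.isfinite(sys.kd_compound):
        fi = sys.i_tot * sys.kd_compound / (sys.kd_compound + ft)
        bound_ti = ft * sys.i_tot / (sys.kd_compound + ft)
    else:
        fi, bound_ti = sys.i_tot, 0.0
    return EquilibriumState(
        free_t=ft, free_p=fp, free_i=fi, bound_tp=bound_tp, bound_ti=bound_ti
    )


def bound_probe(sys: BindingSystem, tol: float = 1e-12) -> float:
    """Equilibrium bound-probe concentration (nM) for one well."""
    return solve_competitive_equilibrium(sys, tol=tol).bound_tp


def two_species_bound(t_tot: float, l_tot: float, kd: float) -> float:
    """Closed-form bound complex for a single 1:1 target-ligand pair.

    Numerically stable form of the quadratic solution; used for probe
    titration fitting where no competitor is present.
    """
    _check_conc("t_tot", t_tot)
    _check_conc("l_tot", l_tot)
    if not (math.isfinite(kd) and kd > 0):
        raise ValueError(f"kd must be finite and > 0, got {kd!r}")
    s = t_tot + l_tot + kd
    disc = s * s - 4.0 * t_tot * l_tot
    return 2.0 * t_tot * l_tot / (s + math.sqrt(disc))


def cq_from_bound(bound: float, cal: QpcrCalibration) -> Optional[float]:
    """Quantification cycle for a bound-probe quantity.

    Returns ``None`` (censored, "no amplification") when ``bound`` is not a
    positive finite number.
    """
    if not (isinstance(bound, (int, float)) and math.isfinite(bound) and bound > 0):
        return None
    return cal.cq_ref - math.log(bound / cal.bound_ref) / math.log1p(cal.efficiency)


def delta_cq_forward(
    sys: BindingSystem, cal: Optional[QpcrCalibration] = None, tol: float = 1e-12
) -> float:
    """Cycle shift of a well relative to the same system without compound.

    The calibration anchor cancels; only ``efficiency`` matters (perfect
    doubling when no calibration is given).  Nonnegative for any finite
    compound kd and zero when ``i_tot`` is zero.
    """
    b_with = bound_probe(sys, tol=tol)
    b_without = bound_probe(replace(sys, i_tot=0.0), tol=tol)
    if b_without <= 0.0 or b_with <= 0.0:
        raise ValueError(
            "delta_cq_forward requires positive bound probe; "
            "t_tot and p_tot must both be > 0"
        )
    efficiency = cal.efficiency if cal is not None else 1.0
    return math.log(b_without / b_with) / math.log1p(efficiency)
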