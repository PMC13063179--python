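"""Dissociation-constant estimation from cycle-shift measurements.

The central relation converts a single well's cycle shift into a compound
dissociation constant:

    kd = (2**-dcq / (1 - 2**-dcq)) * i_tot / (1 + p_tot / kd_probe)

where ``dcq`` is the well's Cq minus the mean Cq of uninhibited wells,
``i_tot`` the total compound concentration and the last factor corrects for
probe occupancy.  The relation assumes target depletion is negligible
(``t_tot`` well below both ``kd_probe`` and the compound kd); callers are
warned outside that regime by :func:`kd_average` via its inputs, and the
validity condition is documented here rather than re-checked per well.

Cycle shifts at or below the detection floor are censored ("no measurable
inhibition") instead of being reported as enormous kd values; shifts at or
above the assay window are flagged saturated while keeping the point
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import QpcrCalibration, two_species_bound

__all__ = [
    "CENSOR_LOW",
    "CENSOR_SATURATED",
    "SingleWellKd",
    "WellMeasurement",
    "KdEstimate",
    "ProbeCalibration",
    "kd_single_well",
    "kd_average",
    "probe_kd_fit",
]

#: Cycle shift at or below the floor: no measurable inhibition.
CENSOR_LOW = "below_detection"
#: Cycle shift at or above the window ceiling: inhibition saturated.
CENSOR_SATURATED = "saturated"


@dataclass(frozen=True)
class SingleWellKd:
    """One well's kd verdict: a point estimate, a censor flag, or both.

    ``kd`` is ``None`` only for low-censored (or unmeasurable) wells;
    saturated wells keep their point estimate alongside the flag.
    """

    kd: Optional[float]
    censor: Optional[str] = None

    @property
    def usable(self) -> bool:
        """True when the estimate should enter an average."""
        return self.kd is not None and self.censor is None


@dataclass(frozen=True)
class WellMeasurement:
    """Raw Cq (or None when the well failed to amplify) at a compound dose."""

    cq: Optional[float]
    i_tot: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.cq is not None and not math.isfinite(self.cq):
            raise ValueError(f"cq must be finite or None, got {self.cq!r}")
        if not (math.isfinite(self.i_tot) and self.i_tot >= 0):
            raise ValueError(f"i_tot must be >= 0, got {self.i_tot!r}")


@dataclass(frozen=True)
class KdEstimate:
    """Per-well kd values with their average over non-censored wells."""

    per_well: Tuple[Tuple[WellMeasurement, SingleWellKd], ...]
    mean_kd: Optional[float]
    sd_kd: Optional[float]
    n_used: int
    n_censored_low: int
    n_censored_high: int

    @property
    def n_total(self) -> int:
        return len(self.per_well)


@dataclass(frozen=True)
class ProbeCalibration:
    """Probe affinity fitted from a titration against constant target."""

    kd_probe: float
    p_tot: float
    fit_residual: float
    ill_conditioned: bool = False

    def __post_init__(self) -> None:
        if not self.kd_probe > 0:
            raise ValueError("kd_probe must be > 0")
        if not self.p_tot > 0:
            raise ValueError("p_tot must be > 0")


def kd_single_well(
    delta_cq: Optional[float],
    i_tot: float,
    p_tot: float = 0.2,
    kd_probe: float = 1.32,
    *,
    low_threshold: float = 0.0,
    high_threshold: float = math.inf,
) -> SingleWellKd:
    """Compound kd from one well's cycle shift.

    Parameters
    ----------
    delta_cq : float or None
        Cycle shift relative to the uninhibited mean.  ``None`` (well did
        not amplify) is treated as beyond-window saturation.
    i_tot : float
        Total compound concentration in the well, nM.
    p_tot, kd_probe : float
        Probe concentration and probe-target kd used in the occupancy
        correction.
    low_threshold : float
        Shifts <= this floor (and any non-positive shift) are censored low.
    high_threshold : float
        Shifts >= this ceiling are flagged saturated but still estimated.
    """
    if not (math.isfinite(i_tot) and i_tot > 0):
        raise ValueError(f"i_tot must be > 0, got {i_tot!r}")
    if not (math.isfinite(p_tot) and p_tot >= 0):
        raise ValueError(f"p_tot must be >= 0, got {p_tot!r}")
    if not (math.isfinite(kd_probe) and kd_probe > 0):
        raise ValueError(f"kd_probe must be > 0, got {kd_probe!r}")

    if delta_cq is None:
        return SingleWellKd(kd=None, censor=CENSOR_SATURATED)
    if math.isnan(delta_cq):
        raise ValueError("delta_cq must not be NaN")
    if delta_cq <= max(low_threshold, 0.0):
        return SingleWellKd(kd=None, censor=CENSOR_LOW)

    # x/(1-x) with x = 2**-dcq, written via expm1 so shifts close to zero
    # stay finite instead of dividing by a rounded-to-zero (1 - x)
    displacement = math.expm1(delta_cq * math.log(2.0))
    kd = i_tot / (displacement * (1.0 + p_tot / kd_probe))
    if not math.isfinite(kd):
        # shift numerically indistinguishable from zero
        return SingleWellKd(kd=None, censor=CENSOR_LOW)
    censor = CENSOR_SATURATED if delta_cq >= high_threshold else None
    return SingleWellKd(kd=kd, censor=censor)


def kd_average(
    wells: Sequence[WellMeasurement],
    neg_mean_cq: float,
    p_tot: float = 0.2,
    kd_probe: float = 1.32,
    *,
    low_threshold: float = 0.0,
    high_threshold: float = math.inf,
    method: str = "arithmetic",
) -> KdEstimate:
    """Average single-well kd estimates across a dilution series.

    Each well's cycle shift is its Cq minus ``neg_mean_cq`` (the uninhibited
    mean of the same plate).  All non-censored wells are pooled with equal
    weight; ``method`` selects an arithmetic (default) or geometric mean.
    The reported SD is always the arithmetic sample SD of the pooled
    estimates.
    """
    if not wells:
        raise ValueError("at least one well is required")
    if method not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown averaging method {method!r}")

    per_well: List[Tuple[WellMeasurement, SingleWellKd]] = []
    for w in wells:
        dcq = None if w.cq is None else w.cq - neg_mean_cq
        est = kd_single_well(
            dcq,
            w.i_tot,
            p_tot,
            kd_probe,
            low_threshold=low_threshold,
            high_threshold=high_threshold,
        )
        per_well.append((w, est))

    used = [est.kd for _, est in per_well if est.usable]
    n_low = sum(1 for _, est in per_well if est.censor == CENSOR_LOW)
    n_high = sum(1 for _, est in per_well if est.censor == CENSOR_SATURATED)

    mean_kd: Optional[float] = None
    sd_kd: Optional[float] = None
    if used:
        if method == "arithmetic":
            mean_kd = float(np.mean(used))
        else:
            mean_kd = float(np.exp(np.mean(np.log(used))))
        if len(used) >= 2:
            sd_kd = float(np.std(used, ddof=1))
    return KdEstimate(
        per_well=tuple(per_well),
        mean_kd=mean_kd,
        sd_kd=sd_kd,
        n_used=len(used),
        n_censored_low=n_low,
        n_censored_high=n_high,
    )


def probe_kd_fit(
    titration: Sequence[Tuple[float, float]],
    t_tot: float,
    cal: QpcrCalibration,
    *,
    working_p_tot: float = 0.2,
) -> ProbeCalibration:
    """Fit the probe-target kd from a probe titration at constant target.

    ``titration`` holds ``(total_probe_nM, cq)`` pairs.  Cq values are
    converted to bound quantities through ``cal`` and the one-site isotherm
    (exact two-species closed form, so probe depletion is handled) is fitted
    by least squares on log-bound residuals, matching the multiplicative
    noise structure of a cycle readout.
    """
    if len(titration) < 4:
        raise ValueError("probe titration needs at least 4 points")
    p = np.asarray([pt[0] for pt in titration], dtype=float)
    cq = np.asarray([pt[1] for pt in titration], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("probe concentrations must be positive and finite")
    if p.max() / p.min() < 10.0:
        raise ValueError(
            "probe titration must span at least a 10-fold concentration range"
        )
    if not (math.isfinite(t_tot) and t_tot > 0):
        raise ValueError(f"t_tot must be > 0, got {t_tot!r}")

    log_bound_obs = np.log(cal.bound_ref) + (cal.cq_ref - cq) * math.log1p(
        cal.efficiency
    )

    def residuals(log_kd: np.ndarray) -> np.ndarray:
        kd = math.exp(float(log_kd[0]))
        model = np.asarray([two_species_bound(t_tot, pi, kd) for pi in p])
        return np.log(model) - log_bound_obs

    x0 = np.array([math.log(float(np.median(p)))])
    result = least_squares(residuals, x0, method="lm")
    if not result.success:
        raise RuntimeError(f"probe kd fit did not converge: {result.message}")

    kd_hat = math.exp(float(result.x[0]))
    resid = result.fun
    ssr = float(resid @ resid)
    # Delta-method variance of log kd; a relative sd above 100% marks the
    # titration as too flat or too saturating to constrain the fit.
    jac = np.atleast_2d(result.jac)
    jtj = float((jac.T @ jac)[0, 0])
    dof = max(len(p) - 1, 1)
    ill = True
    if jtj > 0:
        log_kd_var = (ssr / dof) / jtj
        ill = math.sqrt(log_kd_var) > 1.0
    return ProbeCalibration(
        kd_probe=kd_hat, p_tot=working_p_tot, fit_residual=ssr, ill_conditioned=ill
    )
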