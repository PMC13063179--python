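"""Plate-level screening analysis: QC, cycle shifts, hit calling, filters.

Stages mirror a pooled-screen workflow: compute per-well cycle shifts
against uninhibited controls, derive plate quality metrics, call initial
hits above a threshold, reclassify counter-screen-reactive wells as
interferers, expand surviving pools into an individual retest plan, and
confirm compounds from the retest.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenError",
    "WellRole",
    "HitStatus",
    "WellRecord",
    "QCReport",
    "HitCall",
    "ScreenSummary",
    "well_key",
    "delta_cq_table",
    "qc_metrics",
    "threshold_from_sd",
    "call_hits",
    "counter_screen_filter",
    "deconvolution_plan",
    "confirm_hits",
    "screen_summary",
    "round_sig",
]


class ScreenError(ValueError):
    """Raised when plate data violate the pipeline's preconditions."""


class WellRole(str, Enum):
    NEGATIVE_CONTROL = "negative_control"  # probe only, no competitor
    INHIBITED_CONTROL = "inhibited_control"  # saturating reference ligand
    POSITIVE_CONTROL = "positive_control"  # reference-ligand dilution point
    TEST = "test"
    EMPTY = "empty"


class HitStatus(str, Enum):
    INACTIVE = "inactive"
    INITIAL_HIT = "initial_hit"
    INTERFERER = "interferer"
    CONFIRMED_HIT = "confirmed_hit"
    NOT_CONFIRMED = "not_confirmed"


_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


def valid_well_label(label: str, plate_format: int = 384) -> bool:
    """True when ``label`` names a well of the given plate format."""
    m = _WELL_RE.match(label)
    if not m:
        return False
    row, col = m.group(1), int(m.group(2))
    if plate_format == 384:
        return col >= 1 and col <= 24
    if plate_format == 96:
        return row <= "H" and 1 <= col <= 12
    raise ValueError(f"unsupported plate format {plate_format!r}")


@dataclass(frozen=True)
class WellRecord:
    """One well's identity, content and (optionally) measured Cq."""

    plate_id: str
    well: str
    role: WellRole
    content: Tuple[str, ...] = ()
    i_tot: Optional[float] = None
    pool_id: Optional[str] = None
    cq: Optional[float] = None

    def __post_init__(self) -> None:
        if not (valid_well_label(self.well, 384) or valid_well_label(self.well, 96)):
            raise ValueError(f"invalid well label {self.well!r}")
        role = WellRole(self.role)
        object.__setattr__(self, "role", role)
        if role in (WellRole.NEGATIVE_CONTROL, WellRole.EMPTY):
            if self.content:
                raise ValueError(f"{role.value} well {self.well} must carry no compound")
        elif role in (WellRole.INHIBITED_CONTROL, WellRole.POSITIVE_CONTROL):
            if len(self.content) != 1:
                raise ValueError(
                    f"{role.value} well {self.well} must carry exactly the reference ligand"
                )
            if self.i_tot is None or not self.i_tot > 0:
                raise ValueError(f"{role.value} well {self.well} needs a concentration")
        elif role is WellRole.TEST:
            if not self.content:
                raise ValueError(f"test well {self.well} must carry >= 1 compound")
            if self.i_tot is None or not self.i_tot > 0:
                raise ValueError(f"test well {self.well} needs a concentration")
        if self.cq is not None and not math.isfinite(self.cq):
            raise ValueError(f"cq must be finite or None, got {self.cq!r}")


def well_key(record: WellRecord) -> str:
    """Stable string key ``plate:well`` used across stage tables."""
    return f"{record.plate_id}:{record.well}"


@dataclass(frozen=True)
class QCReport:
    """Control-well statistics for one screen (pooled across plates).

    ``pos_*`` refers to the maximally inhibited control wells; the assay
    window is their mean Cq minus the uninhibited mean.  Values are kept at
    full precision; use :meth:`rounded` for report output.
    """

    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float
    assay_window: float
    z_prime: float
    n_neg: int
    n_pos: int

    def rounded(self, ndigits: int = 2) -> Dict[str, float]:
        return {
            "neg_mean": round(self.neg_mean, ndigits),
            "neg_sd": round(self.neg_sd, ndigits),
            "pos_mean": round(self.pos_mean, ndigits),
            "pos_sd": round(self.pos_sd, ndigits),
            "assay_window": round(self.assay_window, ndigits),
            "z_prime": round(self.z_prime, ndigits),
            "n_neg": self.n_neg,
            "n_pos": self.n_pos,
        }

    def fold_range(self, efficiency: float = 1.0) -> float:
        """Dynamic range of the window as a fold change in bound probe."""
        return (1.0 + efficiency) ** self.assay_window


@dataclass(frozen=True)
class HitCall:
    """A well's or compound's screening verdict."""

    subject: str
    delta_cq: float
    status: HitStatus
    counter_delta_cq: Optional[float] = None
    pool_id: Optional[str] = None
    note: str = ""


def delta_cq_table(wells: Sequence[WellRecord]) -> Dict[str, Optional[float]]:
    """Cycle shift of every non-empty well against its plate's uninhibited mean.

    Censored Cq values propagate as ``None``.  Negative-control shifts
    average to zero on each plate by construction.
    """
    by_plate: Dict[str, List[WellRecord]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)

    out: Dict[str, Optional[float]] = {}
    for plate_id, plate_wells in by_plate.items():
        neg = [
            w.cq
            for w in plate_wells
            if w.role is WellRole.NEGATIVE_CONTROL and w.cq is not None
        ]
        if len(neg) < 2:
            raise ScreenError(
                f"plate {plate_id!r}: need >= 2 negative-control wells with numeric Cq"
            )
        neg_mean = float(np.mean(neg))
        for w in plate_wells:
            if w.role is WellRole.EMPTY:
                continue
            out[well_key(w)] = None if w.cq is None else w.cq - neg_mean
    return out


def qc_metrics(wells: Sequence[WellRecord]) -> QCReport:
    """Control means/SDs, assay window and Z'-factor, pooled across plates.

    Sample SDs (n-1 denominator);
    ``z_prime = 1 - 3*(sd_pos + sd_neg)/|mean_pos - mean_neg|``.
    """
    neg = [
        w.cq for w in wells if w.role is WellRole.NEGATIVE_CONTROL and w.cq is not None
    ]
    pos = [
        w.cq for w in wells if w.role is WellRole.INHIBITED_CONTROL and w.cq is not None
    ]
    if len(neg) < 2 or len(pos) < 2:
        raise ScreenError(
            f"QC needs >= 2 wells of each control; got {len(neg)} negative, "
            f"{len(pos)} inhibited"
        )
    neg_mean, neg_sd = float(np.mean(neg)), float(np.std(neg, ddof=1))
    pos_mean, pos_sd = float(np.mean(pos)), float(np.std(pos, ddof=1))
    window = pos_mean - neg_mean
    if window == 0.0:
        z_prime = 1.0 if (neg_sd == 0.0 and pos_sd == 0.0) else -math.inf
    else:
        z_prime = 1.0 - 3.0 * (pos_sd + neg_sd) / abs(window)
    return QCReport(
        neg_mean=neg_mean,
        neg_sd=neg_sd,
        pos_mean=pos_mean,
        pos_sd=pos_sd,
        assay_window=window,
        z_prime=z_prime,
        n_neg=len(neg),
        n_pos=len(pos),
    )


def threshold_from_sd(neg_sd: float, k: float) -> float:
    """Hit threshold as a multiple of the uninhibited-well SD."""
    if not (math.isfinite(neg_sd) and neg_sd > 0):
        raise ValueError(f"neg_sd must be > 0, got {neg_sd!r}")
    if not (math.isfinite(k) and k > 0):
        raise ValueError(f"k must be > 0, got {k!r}")
    return k * neg_sd


def call_hits(
    dcq: Mapping[str, Optional[float]],
    threshold: float,
    pools: Optional[Mapping[str, Optional[str]]] = None,
) -> List[HitCall]:
    """Classify wells as initial hits (shift >= threshold, inclusive) or inactive.

    A censored shift (no amplification) means the probe signal collapsed
    entirely, so it is called as an initial hit with an infinite shift and
    an explanatory note.  Output is sorted by subject, so permuting the
    input changes nothing.
    """
    if not (math.isfinite(threshold) and threshold > 0):
        raise ValueError(f"threshold must be > 0, got {threshold!r}")
    calls: List[HitCall] = []
    for subject in sorted(dcq):
        value = dcq[subject]
        pool = pools.get(subject) if pools else None
        if value is None:
            calls.append(
                HitCall(
                    subject=subject,
                    delta_cq=math.inf,
                    status=HitStatus.INITIAL_HIT,
                    pool_id=pool,
                    note="censored Cq treated as complete probe loss",
                )
            )
        elif value >= threshold:
            calls.append(
                HitCall(
                    subject=subject,
                    delta_cq=value,
                    status=HitStatus.INITIAL_HIT,
                    pool_id=pool,
                )
            )
        else:
            calls.append(
                HitCall(
                    subject=subject,
                    delta_cq=value,
                    status=HitStatus.INACTIVE,
                    pool_id=pool,
                )
            )
    return calls


def counter_screen_filter(
    hits: Sequence[HitCall],
    counter_dcq: Mapping[str, Optional[float]],
    significance: float,
) -> List[HitCall]:
    """Reclassify initial hits that still shift Cq under ligand saturation.

    ``counter_dcq`` must be computed against the counter screen's own
    saturated baseline.  Initial hits whose counter shift is at or above
    ``significance`` become interferers; the rest keep their status with
    the counter shift recorded.  Hits missing from the counter data are
    retained with a warning note.
    """
    if not (math.isfinite(significance) and significance > 0):
        raise ValueError(f"significance must be > 0, got {significance!r}")
    out: List[HitCall] = []
    for hit in hits:
        if hit.status is not HitStatus.INITIAL_HIT:
            out.append(hit)
            continue
        counter = counter_dcq.get(hit.subject)
        if counter is None and hit.subject not in counter_dcq:
            logger.warning(
                "hit %s missing from counter-screen data; retained unresolved",
                hit.subject,
            )
            out.append(replace(hit, note="unresolved: no counter-screen measurement"))
        elif counter is None:
            # censored counter Cq: total signal loss persists under
            # saturation, which only an interferer can produce
            out.append(
                replace(
                    hit,
                    status=HitStatus.INTERFERER,
                    counter_delta_cq=math.inf,
                    note="censored counter-screen Cq",
                )
            )
        elif counter >= significance:
            logger.info(
                "hit %s reclassified as interferer (counter shift %.2f >= %.2f)",
                hit.subject,
                counter,
                significance,
            )
            out.append(
                replace(hit, status=HitStatus.INTERFERER, counter_delta_cq=counter)
            )
        else:
            out.append(replace(hit, counter_delta_cq=counter))
    return out


def deconvolution_plan(
    hits: Sequence[HitCall],
    pool_map: Mapping[str, Sequence[str]],
    retest_conc: float = 10_000.0,
) -> List[Tuple[str, float]]:
    """Individual retest plan for every compound of every surviving hit pool.

    Each compound appears exactly once even when pools overlap.  Pools are
    expanded in subject order so the plan is deterministic.
    """
    if not (math.isfinite(retest_conc) and retest_conc > 0):
        raise ValueError(f"retest_conc must be > 0, got {retest_conc!r}")
    seen: Dict[str, None] = {}
    for hit in sorted(
        (h for h in hits if h.status is HitStatus.INITIAL_HIT),
        key=lambda h: h.subject,
    ):
        if hit.pool_id is None:
            raise ScreenError(f"hit {hit.subject} has no pool assignment")
        if hit.pool_id not in pool_map:
            raise ScreenError(f"unknown pool {hit.pool_id!r} for hit {hit.subject}")
        for compound in pool_map[hit.pool_id]:
            seen.setdefault(compound, None)
    return [(compound, retest_conc) for compound in seen]


def confirm_hits(
    individual_dcq: Mapping[str, Optional[float]], threshold: float
) -> List[HitCall]:
    """Final verdict per individually retested compound."""
    if not (math.isfinite(threshold) and threshold > 0):
        raise ValueError(f"threshold must be > 0, got {threshold!r}")
    calls: List[HitCall] = []
    for compound in sorted(individual_dcq):
        value = individual_dcq[compound]
        if value is None:
            calls.append(
                HitCall(
                    subject=compound,
                    delta_cq=math.inf,
                    status=HitStatus.CONFIRMED_HIT,
                    note="censored Cq treated as complete probe loss",
                )
            )
        else:
            status = (
                HitStatus.CONFIRMED_HIT
                if value >= threshold
                else HitStatus.NOT_CONFIRMED
            )
            calls.append(HitCall(subject=compound, delta_cq=value, status=status))
    return calls


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


@dataclass(frozen=True)
class ScreenSummary:
    """Status counts and hit rates relative to the library size."""

    library_size: int
    n_wells: int
    n_initial_hits: int
    n_interferers: int
    n_surviving_hits: int
    n_confirmed: Optional[int]
    initial_hit_rate_pct: float
    surviving_hit_rate_pct: float
    confirmed_rate_pct: Optional[float]
    status_counts: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {
            "library_size": self.library_size,
            "n_wells": self.n_wells,
            "n_initial_hits": self.n_initial_hits,
            "n_interferers": self.n_interferers,
            "n_surviving_hits": self.n_surviving_hits,
            "initial_hit_rate_pct": self.initial_hit_rate_pct,
            "surviving_hit_rate_pct": self.surviving_hit_rate_pct,
        }
        if self.n_confirmed is not None:
            d["n_confirmed"] = self.n_confirmed
            d["confirmed_rate_pct"] = self.confirmed_rate_pct
        return d


def screen_summary(
    calls: Sequence[HitCall],
    library_size: int,
    confirmed: Optional[Sequence[HitCall]] = None,
) -> ScreenSummary:
    """Summarise well-level calls (and optional compound confirmations).

    Rates are percentages of ``library_size`` rounded to two significant
    figures.  Wells currently flagged as interferers still count toward the
    initial-hit tally, since they were initial hits before filtering.
    """
    if not (isinstance(library_size, int) and library_size > 0):
        raise ValueError(f"library_size must be a positive integer, got {library_size!r}")
    counts: Dict[str, int] = {status.value: 0 for status in HitStatus}
    for call in calls:
        counts[call.status.value] += 1
    n_surviving = counts[HitStatus.INITIAL_HIT.value]
    n_interferers = counts[HitStatus.INTERFERER.value]
    n_initial = n_surviving + n_interferers
    n_confirmed: Optional[int] = None
    confirmed_rate: Optional[float] = None
    if confirmed is not None:
        n_confirmed = sum(
            1 for c in confirmed if c.status is HitStatus.CONFIRMED_HIT
        )
        confirmed_rate = round_sig(100.0 * n_confirmed / library_size)
    return ScreenSummary(
        library_size=library_size,
        n_wells=len(calls),
        n_initial_hits=n_initial,
        n_interferers=n_interferers,
        n_surviving_hits=n_surviving,
        n_confirmed=n_confirmed,
        initial_hit_rate_pct=round_sig(100.0 * n_initial / library_size),
        surviving_hit_rate_pct=round_sig(100.0 * n_surviving / library_size),
        confirmed_rate_pct=confirmed_rate,
        status_counts=counts,
    )
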