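"""Synthetic screen generation: libraries, plate layouts and noisy Cq reads.

Libraries mix three compound classes: inactive (infinite kd), binders
(finite kd, honest competition through the forward model) and interferers
(an additive Cq shift that persists whether or not the target is already
saturated by a reference ligand — the signature of capture-chemistry or
PCR interference rather than binding).

Every stochastic draw flows from a single seed, so identical designs
reproduce byte-identical screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .equilibrium import (
    INFINITE_KD,
    QpcrCalibration,
    cq_from_bound,
    multi_bound_probe,
)
from .screen import ScreenError, WellRecord, WellRole

__all__ = [
    "REF_LIGAND",
    "CompoundClass",
    "CompoundSpec",
    "ScreenDesign",
    "generate_library",
    "layout_plates",
    "simulate_cq",
    "positive_control_concs",
]

#: Content label used for reference-ligand control wells.
REF_LIGAND = "REF"

CompoundClass = str  # one of "inactive", "binder", "interferer"
_CLASSES = ("inactive", "binder", "interferer")


@dataclass(frozen=True)
class CompoundSpec:
    """Ground-truth identity of one library member."""

    compound_id: str
    compound_class: CompoundClass
    kd: float = INFINITE_KD
    interference_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.compound_class not in _CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.compound_class == "binder":
            if not (math.isfinite(self.kd) and self.kd > 0):
                raise ValueError("binder requires a finite kd > 0")
            if self.interference_shift != 0.0:
                raise ValueError("binder must have zero interference shift")
        elif self.compound_class == "interferer":
            if self.interference_shift == 0.0:
                raise ValueError("interferer requires a nonzero interference shift")
            if math.isfinite(self.kd):
                raise ValueError("interferer kd must be the infinite sentinel")
        else:
            if math.isfinite(self.kd) or self.interference_shift != 0.0:
                raise ValueError("inactive compound must have infinite kd and no shift")


@dataclass(frozen=True)
class ScreenDesign:
    """Layout, chemistry and noise parameters of a simulated screen."""

    pool_size: int = 11
    plate_format: int = 384
    screen_conc: float = 9_000.0  # per-compound concentration in test wells, nM
    retest_conc: float = 10_000.0
    counter_ligand_conc: float = 83.0
    counter_ligand_kd: float = 0.26
    noise_sd: float = 0.15
    seed: int = 0
    # binding-model parameters
    t_tot: float = 0.01
    p_tot: float = 0.2
    kd_probe: float = 1.32
    efficiency: float = 1.0
    cq_ref: float = 9.89
    # control-well layout per plate
    n_neg_per_plate: int = 12
    n_inhib_per_plate: int = 12
    inhib_conc: float = 2_500.0  # reference ligand dose for maximal inhibition
    pos_top_conc: float = 100.0
    pos_dilution: float = 3.0
    n_pos_concs: int = 6
    n_pos_reps: int = 2

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.plate_format not in (96, 384):
            raise ValueError("plate_format must be 96 or 384")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in (
            "screen_conc",
            "retest_conc",
            "counter_ligand_conc",
            "counter_ligand_kd",
            "inhib_conc",
            "pos_top_conc",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def generate_library(
    n: int,
    binder_fraction: float = 0.0,
    interferer_fraction: float = 0.0,
    *,
    binder_kds: Optional[Sequence[float]] = None,
    interferer_shifts: Optional[Sequence[float]] = None,
    kd_range: Tuple[float, float] = (100.0, 50_000.0),
    shift_range: Tuple[float, float] = (1.5, 3.0),
    spacing_pool_size: Optional[int] = None,
    seed: Optional[int] = None,
) -> List[CompoundSpec]:
    """Build a library of ``n`` compounds with planted binders/interferers.

    Class counts come from explicit ``binder_kds``/``interferer_shifts``
    lists when given, otherwise from the fractions (remainder inactive,
    binder kds log-uniform over ``kd_range``, shifts uniform over
    ``shift_range``).  Planted compounds are scattered over random library
    positions; with ``spacing_pool_size`` set, no two planted compounds land
    in the same sequential pool of that size, so pooled-format ground truth
    stays unambiguous.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if binder_fraction < 0 or interferer_fraction < 0:
        raise ValueError("class fractions must be >= 0")
    if binder_fraction + interferer_fraction > 1:
        raise ValueError("class fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    n_binders = len(binder_kds) if binder_kds is not None else round(binder_fraction * n)
    n_interferers = (
        len(interferer_shifts)
        if interferer_shifts is not None
        else round(interferer_fraction * n)
    )
    n_special = n_binders + n_interferers
    if n_special > n:
        raise ValueError("more planted compounds than library members")

    if spacing_pool_size is not None and spacing_pool_size > 1:
        n_pools = math.ceil(n / spacing_pool_size)
        if n_special > n_pools:
            raise ValueError(
                f"{n_special} planted compounds cannot occupy distinct pools "
                f"of size {spacing_pool_size} in a {n}-compound library"
            )
        pool_picks = rng.choice(n_pools, size=n_special, replace=False)
        positions = []
        for p in pool_picks:
            start = int(p) * spacing_pool_size
            width = min(spacing_pool_size, n - start)
            positions.append(start + int(rng.integers(0, width)))
        positions = np.asarray(positions, dtype=int)
    else:
        positions = rng.choice(n, size=n_special, replace=False)

    if binder_kds is not None:
        kds = [float(k) for k in binder_kds]
    else:
        lo, hi = kd_range
        if not (0 < lo < hi):
            raise ValueError("kd_range must satisfy 0 < lo < hi")
        kds = list(np.exp(rng.uniform(math.log(lo), math.log(hi), n_binders)))
    if interferer_shifts is not None:
        shifts = [float(s) for s in interferer_shifts]
    else:
        shifts = list(rng.uniform(shift_range[0], shift_range[1], n_interferers))

    width = max(5, len(str(n)))
    specs: List[CompoundSpec] = [
        CompoundSpec(compound_id=f"C{i + 1:0{width}d}", compound_class="inactive")
        for i in range(n)
    ]
    for pos, kd in zip(positions[:n_binders], kds):
        specs[pos] = CompoundSpec(
            compound_id=specs[pos].compound_id, compound_class="binder", kd=kd
        )
    for pos, shift in zip(positions[n_binders:], shifts):
        specs[pos] = CompoundSpec(
            compound_id=specs[pos].compound_id,
            compound_class="interferer",
            interference_shift=shift,
        )
    return specs


def _plate_labels(plate_format: int) -> List[str]:
    rows = "ABCDEFGHIJKLMNOP" if plate_format == 384 else "ABCDEFGH"
    n_cols = 24 if plate_format == 384 else 12
    return [f"{r}{c}" for r in rows for c in range(1, n_cols + 1)]


def positive_control_concs(design: ScreenDesign) -> List[float]:
    """Reference-ligand dilution series, top concentration downward."""
    return [
        design.pos_top_conc / design.pos_dilution**i for i in range(design.n_pos_concs)
    ]


def layout_plates(
    library: Sequence[CompoundSpec],
    design: ScreenDesign,
    *,
    plate_prefix: str = "plate",
    conc: Optional[float] = None,
    max_plates: Optional[int] = None,
) -> List[WellRecord]:
    """Arrange a library onto plates with control wells, without Cq values.

    Pools are filled sequentially (the last pool may be short).  Each plate
    carries uninhibited controls, maximally inhibited controls and a
    reference-ligand dilution series before test wells.  ``conc`` overrides
    the per-compound test concentration (defaults to ``design.screen_conc``).
    """
    labels = _plate_labels(design.plate_format)
    pos_concs = positive_control_concs(design)
    n_controls = (
        design.n_neg_per_plate
        + design.n_inhib_per_plate
        + design.n_pos_concs * design.n_pos_reps
    )
    capacity = len(labels) - n_controls
    if capacity < 1:
        raise ScreenError("plate format too small for the requested control wells")

    test_conc = design.screen_conc if conc is None else conc
    pools: List[Tuple[Optional[str], Tuple[str, ...]]] = []
    if design.pool_size == 1:
        pools = [(None, (c.compound_id,)) for c in library]
    else:
        for i in range(0, len(library), design.pool_size):
            chunk = tuple(c.compound_id for c in library[i : i + design.pool_size])
            pools.append((f"P{i // design.pool_size + 1:04d}", chunk))

    n_plates = math.ceil(len(pools) / capacity)
    if max_plates is not None and n_plates > max_plates:
        raise ScreenError(
            f"library needs {n_plates} plates but only {max_plates} allowed"
        )

    records: List[WellRecord] = []
    for plate_idx in range(n_plates):
        plate_id = f"{plate_prefix}{plate_idx + 1:02d}"
        cursor = 0

        def take() -> str:
            nonlocal cursor
            label = labels[cursor]
            cursor += 1
            return label

        for _ in range(design.n_neg_per_plate):
            records.append(
                WellRecord(plate_id, take(), WellRole.NEGATIVE_CONTROL)
            )
        for _ in range(design.n_inhib_per_plate):
            records.append(
                WellRecord(
                    plate_id,
                    take(),
                    WellRole.INHIBITED_CONTROL,
                    content=(REF_LIGAND,),
                    i_tot=design.inhib_conc,
                )
            )
        for c in pos_concs:
            for _ in range(design.n_pos_reps):
                records.append(
                    WellRecord(
                        plate_id,
                        take(),
                        WellRole.POSITIVE_CONTROL,
                        content=(REF_LIGAND,),
                        i_tot=c,
                    )
                )
        for pool_id, content in pools[
            plate_idx * capacity : (plate_idx + 1) * capacity
        ]:
            records.append(
                WellRecord(
                    plate_id,
                    take(),
                    WellRole.TEST,
                    content=content,
                    i_tot=test_conc,
                    pool_id=pool_id,
                )
            )
    return records


def default_calibration(design: ScreenDesign) -> QpcrCalibration:
    """Calibration anchored at the uninhibited bound-probe quantity."""
    bound0 = multi_bound_probe(design.t_tot, design.p_tot, design.kd_probe)
    return QpcrCalibration(
        cq_ref=design.cq_ref, bound_ref=bound0, efficiency=design.efficiency
    )


def simulate_cq(
    wells: Sequence[WellRecord],
    library: Sequence[CompoundSpec],
    design: ScreenDesign,
    *,
    cal: Optional[QpcrCalibration] = None,
    counter_screen: bool = False,
    exact_pools: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> List[WellRecord]:
    """Fill in Cq readouts for laid-out wells via the forward model.

    A pooled test well is approximated by its strongest binder (valid when
    at most one active compound sits in a pool); ``exact_pools`` switches to
    the full multi-competitor equilibrium.  Interference shifts add to the
    Cq unconditionally.  In ``counter_screen`` mode the saturating reference
    ligand is added to every well on top of its own content.
    """
    lib: Dict[str, CompoundSpec] = {c.compound_id: c for c in library}
    if cal is None:
        cal = default_calibration(design)
    if rng is None:
        rng = np.random.default_rng(design.seed)

    out: List[WellRecord] = []
    for w in wells:
        if w.role is WellRole.EMPTY:
            out.append(w)
            continue
        competitors: List[Tuple[float, float]] = []
        shift = 0.0
        if w.role in (WellRole.INHIBITED_CONTROL, WellRole.POSITIVE_CONTROL):
            competitors.append((float(w.i_tot), design.counter_ligand_kd))
        elif w.role is WellRole.TEST:
            try:
                specs = [lib[cid] for cid in w.content]
            except KeyError as exc:
                raise ScreenError(
                    f"well {w.plate_id}:{w.well} references unknown compound {exc}"
                ) from None
            shift = sum(s.interference_shift for s in specs)
            finite = [s.kd for s in specs if math.isfinite(s.kd)]
            if finite:
                if exact_pools:
                    competitors.extend((float(w.i_tot), kd) for kd in finite)
                else:
                    competitors.append((float(w.i_tot), min(finite)))
        if counter_screen:
            competitors.append(
                (design.counter_ligand_conc, design.counter_ligand_kd)
            )
        bound = multi_bound_probe(
            design.t_tot, design.p_tot, design.kd_probe, competitors
        )
        cq = cq_from_bound(bound, cal)
        if cq is not None:
            cq += shift
            if design.noise_sd > 0:
                cq += float(rng.normal(0.0, design.noise_sd))
        out.append(replace(w, cq=cq))
    return out
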