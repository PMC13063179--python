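"""End-to-end orchestration of a (synthetic) pooled or individual screen.

Stage order: primary screen -> threshold -> counter screen -> deconvolution
-> confirmation.  Individual-format runs (pool size 1) skip deconvolution;
the surviving hits are the final calls.  All artifacts can be persisted as
delimited text, and a run log records every threshold, seed and filtering
decision.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import io as tables
from .config import PipelineConfig
from .screen import (
    HitCall,
    HitStatus,
    QCReport,
    ScreenSummary,
    WellRecord,
    WellRole,
    call_hits,
    counter_screen_filter,
    confirm_hits,
    deconvolution_plan,
    delta_cq_table,
    qc_metrics,
    screen_summary,
    well_key,
)
from .simulate import (
    CompoundSpec,
    ScreenDesign,
    generate_library,
    layout_plates,
    simulate_cq,
)

logger = logging.getLogger(__name__)

__all__ = ["ScreenOutcome", "run_synthetic_screen", "run_pipeline"]


@dataclass(frozen=True)
class ScreenOutcome:
    """All artifacts of one end-to-end run, plus ground truth for scoring."""

    library: Tuple[CompoundSpec, ...]
    screen_wells: Tuple[WellRecord, ...]
    counter_wells: Tuple[WellRecord, ...]
    deconv_wells: Tuple[WellRecord, ...]
    qc: QCReport
    hit_threshold: float
    counter_significance: float
    hits_initial: Tuple[HitCall, ...]
    hits_filtered: Tuple[HitCall, ...]
    plan: Tuple[Tuple[str, float], ...]
    confirmed: Optional[Tuple[HitCall, ...]]
    summary: ScreenSummary

    # ground truth
    planted_binders: frozenset
    planted_interferers: frozenset
    interferer_wells: frozenset

    @property
    def confirmed_compounds(self) -> Set[str]:
        if self.confirmed is None:
            return set()
        return {
            c.subject
            for c in self.confirmed
            if c.status is HitStatus.CONFIRMED_HIT
        }

    @property
    def interferer_flagged_wells(self) -> Set[str]:
        return {
            h.subject
            for h in self.hits_filtered
            if h.status is HitStatus.INTERFERER
        }


def _test_subset(
    dcq: Dict[str, Optional[float]], wells: Sequence[WellRecord]
) -> Dict[str, Optional[float]]:
    test_keys = {well_key(w) for w in wells if w.role is WellRole.TEST}
    return {k: v for k, v in dcq.items() if k in test_keys}


def _counter_baseline_sd(counter_wells: Sequence[WellRecord]) -> float:
    cqs = [
        w.cq
        for w in counter_wells
        if w.role is WellRole.NEGATIVE_CONTROL and w.cq is not None
    ]
    if len(cqs) < 2:
        raise ValueError("counter screen needs >= 2 baseline wells")
    return float(np.std(cqs, ddof=1))


def run_synthetic_screen(
    library: Sequence[CompoundSpec],
    design: ScreenDesign,
    *,
    hit_threshold: Optional[float] = 0.80,
    threshold_k: Optional[float] = None,
    counter_significance_k: float = 3.0,
    exact_pools: bool = False,
    outdir: Optional[str] = None,
) -> ScreenOutcome:
    """Simulate and analyse one complete screen of ``library``.

    The master seed in ``design`` drives three independent child streams
    (primary screen, counter screen, deconvolution retest), so reruns with
    identical inputs are byte-identical.
    """
    master = np.random.default_rng(design.seed)
    rng_screen, rng_counter, rng_deconv = master.spawn(3)

    wells = layout_plates(library, design)
    screen_wells = simulate_cq(
        wells, library, design, exact_pools=exact_pools, rng=rng_screen
    )
    qc = qc_metrics(screen_wells)
    dcq = delta_cq_table(screen_wells)
    test_dcq = _test_subset(dcq, screen_wells)
    pools = {
        well_key(w): w.pool_id for w in screen_wells if w.role is WellRole.TEST
    }
    if hit_threshold is None:
        if threshold_k is None:
            raise ValueError("either hit_threshold or threshold_k is required")
        from .screen import threshold_from_sd

        hit_threshold = threshold_from_sd(qc.neg_sd, threshold_k)
    logger.info("hit threshold: %.3f cycles", hit_threshold)
    hits = call_hits(test_dcq, hit_threshold, pools=pools)

    counter_wells = simulate_cq(
        wells,
        library,
        design,
        counter_screen=True,
        exact_pools=exact_pools,
        rng=rng_counter,
    )
    counter_dcq = _test_subset(delta_cq_table(counter_wells), counter_wells)
    baseline_sd = _counter_baseline_sd(counter_wells)
    if baseline_sd > 0:
        significance = counter_significance_k * baseline_sd
    else:
        # noise-free runs have a zero baseline SD; fall back to a floor that
        # tolerates the residual displacement a genuine binder still causes
        # on top of ligand saturation
        significance = 0.25
    logger.info("counter-screen significance: %.3f cycles", significance)
    filtered = counter_screen_filter(hits, counter_dcq, significance)

    lib_by_id = {c.compound_id: c for c in library}
    plan: Tuple[Tuple[str, float], ...] = ()
    confirmed: Optional[Tuple[HitCall, ...]] = None
    deconv_wells: Tuple[WellRecord, ...] = ()
    if design.pool_size > 1:
        pool_map = {
            w.pool_id: w.content
            for w in screen_wells
            if w.role is WellRole.TEST and w.pool_id is not None
        }
        plan = tuple(deconvolution_plan(filtered, pool_map, design.retest_conc))
        if plan:
            sub_library = [lib_by_id[cid] for cid, _ in plan]
            deconv_design = replace(design, pool_size=1, screen_conc=design.retest_conc)
            laid = layout_plates(sub_library, deconv_design, plate_prefix="deconv")
            deconv_wells = tuple(
                simulate_cq(laid, library, deconv_design, rng=rng_deconv)
            )
            deconv_dcq_wells = delta_cq_table(deconv_wells)
            compound_dcq = {
                w.content[0]: deconv_dcq_wells[well_key(w)]
                for w in deconv_wells
                if w.role is WellRole.TEST
            }
            confirmed = tuple(confirm_hits(compound_dcq, hit_threshold))
        else:
            confirmed = ()

    summary = screen_summary(filtered, len(library), confirmed=confirmed)

    binders = frozenset(
        c.compound_id for c in library if c.compound_class == "binder"
    )
    interferers = frozenset(
        c.compound_id for c in library if c.compound_class == "interferer"
    )
    interferer_wells = frozenset(
        well_key(w)
        for w in screen_wells
        if w.role is WellRole.TEST and any(cid in interferers for cid in w.content)
    )

    outcome = ScreenOutcome(
        library=tuple(library),
        screen_wells=tuple(screen_wells),
        counter_wells=tuple(counter_wells),
        deconv_wells=deconv_wells,
        qc=qc,
        hit_threshold=hit_threshold,
        counter_significance=significance,
        hits_initial=tuple(hits),
        hits_filtered=tuple(filtered),
        plan=plan,
        confirmed=confirmed,
        summary=summary,
        planted_binders=binders,
        planted_interferers=interferers,
        interferer_wells=interferer_wells,
    )
    if outdir is not None:
        persist_outcome(outcome, outdir, efficiency=design.efficiency)
    return outcome


def persist_outcome(outcome: ScreenOutcome, outdir: str, efficiency: float = 1.0) -> None:
    """Write every stage artifact of a run as delimited text."""
    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)
    tables.write_ground_truth(outcome.library, join("ground_truth.csv"))
    tables.write_plate_map(outcome.screen_wells, join("plate_map.csv"))
    tables.write_cq_results(outcome.screen_wells, join("cq_results.csv"))
    tables.write_cq_results(outcome.counter_wells, join("counter_cq_results.csv"))
    tables.write_qc_report(outcome.qc, join("qc_report.csv"), efficiency)
    tables.write_hits(outcome.hits_filtered, join("hits.csv"))
    tables.write_deconvolution_plan(outcome.plan, join("deconvolution_plan.csv"))
    if outcome.deconv_wells:
        tables.write_plate_map(outcome.deconv_wells, join("deconv_plate_map.csv"))
        tables.write_cq_results(outcome.deconv_wells, join("deconv_cq_results.csv"))
    if outcome.confirmed is not None:
        tables.write_hits(outcome.confirmed, join("confirmed_hits.csv"))
    tables.write_summary(outcome.summary, join("summary.csv"))
    with open(join("run_log.txt"), "w", encoding="utf-8") as fh:
        fh.write(f"hit_threshold_cycles={outcome.hit_threshold!r}\n")
        fh.write(f"counter_significance_cycles={outcome.counter_significance!r}\n")
        fh.write(f"n_initial_hits={outcome.summary.n_initial_hits}\n")
        fh.write(f"n_interferers={outcome.summary.n_interferers}\n")
        fh.write(f"n_surviving_hits={outcome.summary.n_surviving_hits}\n")
        for h in outcome.hits_filtered:
            if h.status is HitStatus.INTERFERER:
                fh.write(
                    f"excluded {h.subject}: counter shift "
                    f"{h.counter_delta_cq!r} >= {outcome.counter_significance!r}\n"
                )


def run_pipeline(config: PipelineConfig) -> ScreenOutcome:
    """Run the full synthetic pipeline described by a config."""
    lib_cfg = config.library
    library = generate_library(
        lib_cfg.n_compounds,
        lib_cfg.binder_fraction,
        lib_cfg.interferer_fraction,
        binder_kds=lib_cfg.binder_kds,
        interferer_shifts=lib_cfg.interferer_shifts,
        kd_range=tuple(lib_cfg.kd_range),
        shift_range=tuple(lib_cfg.shift_range),
        spacing_pool_size=config.design.pool_size if lib_cfg.distinct_pools else None,
        seed=config.design.seed,
    )
    return run_synthetic_screen(
        library,
        config.design,
        hit_threshold=config.analysis.hit_threshold,
        threshold_k=config.analysis.threshold_k,
        counter_significance_k=config.analysis.counter_significance_k,
        outdir=config.outdir,
    )
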