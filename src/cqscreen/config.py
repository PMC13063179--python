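"""Pipeline configuration: documented defaults, YAML loading, validation.

Defaults follow the printed assay constants: 200 pM probe, probe kd
1.32 nM, pooled hit threshold 0.80 cycles, 10 uM individual retest and an
83 nM reference-ligand counter screen.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional

import yaml

from .simulate import ScreenDesign

__all__ = ["LibraryParams", "AnalysisParams", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class LibraryParams:
    """Synthetic-library composition for simulated runs."""

    n_compounds: int = 5_280
    binder_fraction: float = 0.0
    interferer_fraction: float = 0.0
    binder_kds: Optional[List[float]] = None
    interferer_shifts: Optional[List[float]] = None
    kd_range: List[float] = field(default_factory=lambda: [100.0, 50_000.0])
    shift_range: List[float] = field(default_factory=lambda: [1.5, 3.0])
    distinct_pools: bool = True

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.binder_fraction + self.interferer_fraction > 1:
            raise ValueError("class fractions must sum to <= 1")


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholding and filtering policy.

    ``hit_threshold`` is an absolute cycle cutoff; when ``None`` the cutoff
    is ``threshold_k`` times the uninhibited-well SD.  The counter-screen
    significance is always ``counter_significance_k`` times the counter
    plate's own baseline SD.
    """

    hit_threshold: Optional[float] = 0.80
    threshold_k: Optional[float] = None
    counter_significance_k: float = 3.0
    kd_low_censor_k: float = 3.0
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.hit_threshold is None and self.threshold_k is None:
            raise ValueError("either hit_threshold or threshold_k must be set")
        if self.hit_threshold is not None and not self.hit_threshold > 0:
            raise ValueError("hit_threshold must be > 0")
        if self.threshold_k is not None and not self.threshold_k > 0:
            raise ValueError("threshold_k must be > 0")
        if not self.counter_significance_k > 0:
            raise ValueError("counter_significance_k must be > 0")

    def resolve_threshold(self, neg_sd: float) -> float:
        from .screen import threshold_from_sd

        if self.hit_threshold is not None:
            return self.hit_threshold
        return threshold_from_sd(neg_sd, self.threshold_k)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one end-to-end (synthetic) run."""

    design: ScreenDesign = field(default_factory=ScreenDesign)
    library: LibraryParams = field(default_factory=LibraryParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    outdir: str = "cqscreen_run"

    @property
    def seed(self) -> int:
        return self.design.seed


def _build(cls, data: Mapping[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {where} option(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path: str, overrides: Optional[Mapping[str, Any]] = None) -> PipelineConfig:
    """Load a YAML config file; ``overrides`` replace top-level scalars.

    Structure::

        design:   {pool_size: 11, screen_conc: 9000, noise_sd: 0.15, seed: 1, ...}
        library:  {n_compounds: 5280, binder_kds: [...], ...}
        analysis: {hit_threshold: 0.80, counter_significance_k: 3.0, ...}
        outdir:   results/run1
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    known = {"design", "library", "analysis", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown section(s): {sorted(unknown)}")
    if overrides:
        for key, value in overrides.items():
            section, _, name = key.partition(".")
            if name:
                raw.setdefault(section, {})[name] = value
            else:
                raw[key] = value
    design = _build(ScreenDesign, raw.get("design", {}), "design")
    library = _build(LibraryParams, raw.get("library", {}), "library")
    analysis = _build(AnalysisParams, raw.get("analysis", {}), "analysis")
    return PipelineConfig(
        design=design,
        library=library,
        analysis=analysis,
        outdir=str(raw.get("outdir", "cqscreen_run")),
    )
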