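"""Stepwise conditional association strategies.

A strategy is a declarative sequence of conditioning choices: each step is
either an explicit variant id (the analyst's judgment call, e.g. starting
from B*08 because the top SNP tags it) or the rule ``top_remaining`` (pick
the most significant variant of the previous step's scan). Conditioning at
step k always uses exactly the variants chosen at steps 1..k-1; the run
stops when no variant remains below the family-wise threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import AssociationResult, DosageMatrix, VariantDescriptor
from .association import AssociationError, ScanSettings, bonferroni_threshold, scan

TOP_REMAINING = "top_remaining"


@dataclass
class ConditionalStrategy:
    name: str
    steps: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "ConditionalStrategy":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(name=raw["name"], steps=list(raw["steps"]))


@dataclass
class StrategyStep:
    conditioning_set: tuple[str, ...]
    results: list[AssociationResult]
    chosen: str | None          # None on the terminal (stop-rule) scan
    exhausted: bool             # nothing below the family threshold


@dataclass
class StrategyRun:
    strategy: str
    threshold: float
    steps: list[StrategyStep] = field(default_factory=list)

    @property
    def conditioning_set(self) -> tuple[str, ...]:
        return tuple(s.chosen for s in self.steps if s.chosen is not None)

    @property
    def terminated_cleanly(self) -> bool:
        return bool(self.steps) and self.steps[-1].exhausted


def _significant(results: list[AssociationResult], threshold: float):
    return [r for r in results if r.converged and r.p_value <= threshold]


def _top(results: list[AssociationResult], threshold: float) -> str | None:
    """Most significant variant; ties break on smaller p, larger |beta|, id.

    p and |beta| are compared at 10 significant digits so that exact mirror
    variants (dosage reflections) tie deterministically on the id.
    """
    sig = _significant(results, threshold)
    if not sig:
        return None
    return min(
        sig,
        key=lambda r: (float(f"{r.p_value:.10g}"),
                       -float(f"{abs(r.beta):.10g}"),
                       r.variant_id),
    ).variant_id


def run_strategy(
    matrix: DosageMatrix,
    status: np.ndarray,
    strategy: ConditionalStrategy,
    settings: ScanSettings | None = None,
    threshold: float | None = None,
) -> StrategyRun:
    """Execute a conditional strategy, retaining every step's full scan.

    Explicit steps are followed verbatim; ``top_remaining`` steps stop the
    run cleanly when nothing is left below the threshold (that is the stop
    state, not an error). A terminal scan conditioning on everything chosen
    is always appended so the stop rule is verified on the final set.
    """
    settings = settings or ScanSettings()
    if threshold is None:
        threshold = bonferroni_threshold(len(matrix.variants), settings.alpha_family)
    run = StrategyRun(strategy.name, threshold)
    chosen: list[str] = []
    stopped = False
    for step_spec in strategy.steps:
        results = scan(matrix, status, conditioning=chosen, settings=settings)
        exhausted = not _significant(results, threshold)
        if step_spec == TOP_REMAINING:
            pick = _top(results, threshold)
            if pick is None:
                run.steps.append(StrategyStep(tuple(chosen), results, None, True))
                stopped = True
                break
        else:
            pick = step_spec
            if pick in chosen:
                raise AssociationError(f"variant {pick!r} already in conditioning set")
            if pick not in matrix:
                raise AssociationError(f"strategy step variant {pick!r} not in manifest")
        run.steps.append(StrategyStep(tuple(chosen), results, pick, exhausted))
        chosen.append(pick)
    if not stopped:
        results = scan(matrix, status, conditioning=chosen, settings=settings)
        run.steps.append(StrategyStep(
            tuple(chosen), results, None, not _significant(results, threshold)
        ))
    return run


def condition_on_single(
    matrix: DosageMatrix,
    status: np.ndarray,
    variant_id: str,
    settings: ScanSettings | None = None,
) -> list[AssociationResult]:
    """Scan conditioning on one variant (independence check of all others)."""
    return scan(matrix, status, conditioning=[variant_id], settings=settings)


@dataclass
class ResidualSummary:
    conditioning_set: tuple[str, ...]
    n_below: int
    top_variant: str | None
    top_p: float
    by_category: dict[str, int]
    exhausted: bool


def residual_report(
    run: StrategyRun,
    descriptors: dict[str, VariantDescriptor] | None = None,
    threshold: float | None = None,
) -> list[ResidualSummary]:
    """Per-step residual-signal summary of a strategy run."""
    descriptors = descriptors or {}
    threshold = threshold if threshold is not None else run.threshold
    out = []
    for step in run.steps:
        sig = _significant(step.results, threshold)
        by_cat: dict[str, int] = {}
        for r in sig:
            d = descriptors.get(r.variant_id)
            cat = d.category if d else "unknown"
            by_cat[cat] = by_cat.get(cat, 0) + 1
        top = min(sig, key=lambda r: (r.p_value, r.variant_id)) if sig else None
        conv = [r for r in step.results if r.converged]
        out.append(ResidualSummary(
            conditioning_set=step.conditioning_set,
            n_below=len(sig),
            top_variant=top.variant_id if top else None,
            top_p=top.p_value if top else (min(r.p_value for r in conv) if conv else float("nan")),
            by_category=by_cat,
            exhausted=not sig,
        ))
    return out
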