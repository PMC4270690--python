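"""Linkage-disequilibrium r^2 between dosage variables and haplotype-extension
profiles: the span of SNPs exceeding r^2 categories (>0.8, >0.5, >0.2) around
an anchor variant, computed in controls by default (best-guess genotypic
correlation, which equals haplotype r^2 under random mating)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DosageMatrix, VariantDescriptor


class LDError(ValueError):
    pass


R2_CATEGORIES = (0.8, 0.5, 0.2)  # nested: >0.8 within >0.5 within >0.2


def genotypic_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite (dosage-correlation) r^2 on the shared complete-case set.

    A constant vector leaves r^2 undefined: that is an error, never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise LDError("fewer than two shared complete cases")
    if x.std() == 0 or y.std() == 0:
        raise LDError("r^2 undefined for a constant dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LDProfile:
    anchor: str
    snp_ids: list[str] = field(default_factory=list)
    positions: list[int] = field(default_factory=list)
    r2: list[float] = field(default_factory=list)
    category: list[str] = field(default_factory=list)  # ">0.8" / ">0.5" / ">0.2" / "below"
    spans: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.snp_ids,
            "position_bp": self.positions,
            "r2": self.r2,
            "category": self.category,
        })


def _categorize(r2: float) -> str:
    for cut in R2_CATEGORIES:
        if r2 > cut:
            return f">{cut}"
    return "below"


def extension_profile(
    anchor: str,
    matrix: DosageMatrix,
    descriptors: list[VariantDescriptor],
    status: np.ndarray | None = None,
    controls_only: bool = True,
) -> LDProfile:
    """r^2 of the anchor against every positioned SNP, with category spans.

    The span of category ``>c`` is the (min, max) base-pair range of SNPs
    whose r^2 with the anchor exceeds c; categories are nested by
    construction. Computed in controls when ``controls_only`` (the default)
    and a status vector is given.
    """
    if anchor not in matrix:
        raise LDError(f"anchor {anchor!r} not in manifest")
    rows = np.ones(len(matrix.subjects), dtype=bool)
    if controls_only:
        if status is None:
            raise LDError("controls_only profile needs a status vector")
        rows = np.asarray(status) == 0
    a = matrix.column(anchor)[rows]
    if np.nanstd(a) == 0:
        raise LDError(f"anchor {anchor!r} constant in the profiled subjects")
    profile = LDProfile(anchor)
    for d in descriptors:
        if d.category != "snp" or d.position_bp <= 0 or d.variant_id == anchor:
            continue
        col = matrix.column(d.variant_id)[rows]
        try:
            r2 = genotypic_r2(a, col)
        except LDError:
            continue  # monomorphic SNP in the profiled subset
        profile.snp_ids.append(d.variant_id)
        profile.positions.append(d.position_bp)
        profile.r2.append(r2)
        profile.category.append(_categorize(r2))
    for cut in R2_CATEGORIES:
        pos = [p for p, r in zip(profile.positions, profile.r2) if r > cut]
        profile.spans[f">{cut}"] = (min(pos), max(pos)) if pos else None
    return profile
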