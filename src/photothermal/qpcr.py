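"""qPCR relative expression (delta-Ct) and per-timepoint genotype comparisons.

Technical replicates are collapsed to one Ct per biological replicate
(mean of detected wells; a bio rep with no detected well is undetected).
Relative expression is computed per biological replicate against a
reference gene measured on the same (genotype, photoperiod, ZT, bio rep):

    rel_expr = 2 ** -(Ct_target - Ct_reference)

i.e. the delta-Ct method — no calibrator sample, no primer-efficiency
correction.  Group comparisons are two-sided t-tests on log2 relative
expression (equivalently -delta-Ct), the scale on which qPCR noise is
closest to homoscedastic.  Cells with fewer than two detected biological
replicates in either group are flagged untestable, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import CtRecord, ValidationError

__all__ = [
    "BioRepCt",
    "ExpressionValue",
    "collapse_tech_reps",
    "relative_expression",
    "compare_expression",
    "DEFAULT_REFERENCE_GENE",
]

DEFAULT_REFERENCE_GENE = "HvTubA"


@dataclass(frozen=True)
class BioRepCt:
    """One biological replicate's Ct after collapsing technical replicates."""

    gene: str
    genotype: str
    photoperiod_h: float
    zt: float
    bio_rep: int
    ct: Optional[float]
    undetected: bool
    n_tech_detected: int
    n_tech_total: int

    @property
    def partial_detection(self) -> bool:
        return 0 < self.n_tech_detected < self.n_tech_total


@dataclass(frozen=True)
class ExpressionValue:
    """Relative expression of one biological replicate vs the reference gene."""

    gene: str
    genotype: str
    photoperiod_h: float
    zt: float
    bio_rep: int
    rel_expr: float  # 2^(-delta Ct), >= 0
    delta_ct: float


def collapse_tech_reps(records: Sequence[CtRecord]) -> List[BioRepCt]:
    """Mean Ct across detected technical replicates, per biological replicate."""
    groups: Dict[tuple, List[CtRecord]] = {}
    for r in records:
        key = (r.gene, r.genotype, r.photoperiod_h, r.zt, r.bio_rep)
        groups.setdefault(key, []).append(r)
    out: List[BioRepCt] = []
    for key in sorted(groups):
        gene, geno, p, zt, bio = key
        wells = groups[key]
        detected = [w.ct for w in wells if not w.undetected]
        out.append(BioRepCt(
            gene=gene, genotype=geno, photoperiod_h=p, zt=zt, bio_rep=bio,
            ct=float(np.mean(detected)) if detected else None,
            undetected=not detected,
            n_tech_detected=len(detected),
            n_tech_total=len(wells),
        ))
    return out


def relative_expression(
    records: Sequence[CtRecord],
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> Tuple[List[ExpressionValue], List[str]]:
    """Delta-Ct relative expression per biological replicate.

    Returns the expression values together with a log of the cells omitted
    because the target or the matching reference well was undetected or
    missing.
    """
    collapsed = collapse_tech_reps(records)
    reference = {
        (b.genotype, b.photoperiod_h, b.zt, b.bio_rep): b
        for b in collapsed if b.gene == reference_gene
    }
    if not reference:
        raise ValidationError(
            f"reference gene {reference_gene!r} absent from the Ct table"
        )
    values: List[ExpressionValue] = []
    omitted: List[str] = []
    for b in collapsed:
        if b.gene == reference_gene:
            continue
        label = (f"{b.gene}/{b.genotype}/P{b.photoperiod_h:g}/ZT{b.zt:g}/"
                 f"bio{b.bio_rep}")
        if b.undetected:
            omitted.append(f"{label}: target undetected")
            continue
        ref = reference.get((b.genotype, b.photoperiod_h, b.zt, b.bio_rep))
        if ref is None:
            omitted.append(f"{label}: no matching reference well")
            continue
        if ref.undetected:
            omitted.append(f"{label}: reference undetected")
            continue
        delta = b.ct - ref.ct
        values.append(ExpressionValue(
            gene=b.gene, genotype=b.genotype, photoperiod_h=b.photoperiod_h,
            zt=b.zt, bio_rep=b.bio_rep,
            rel_expr=float(2.0 ** (-delta)), delta_ct=float(delta),
        ))
    return values, omitted


def compare_expression(
    values: Sequence[ExpressionValue],
    genotype_pairs: Sequence[Tuple[str, str]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided t-tests on log2 relative expression per gene x photoperiod
    x ZT x genotype pair.

    Rows with fewer than two detected biological replicates in either group
    carry ``untestable = True`` and a reason.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    df = pd.DataFrame([
        {
            "gene": v.gene, "genotype": v.genotype,
            "photoperiod_h": v.photoperiod_h, "zt": v.zt,
            "log2_rel_expr": float(np.log2(v.rel_expr)),
        }
        for v in values
    ])
    rows = []
    if df.empty:
        cells = []
    else:
        cells = sorted(
            df.groupby(["gene", "photoperiod_h", "zt"]).groups.keys()
        )
    for gene, p, zt in cells:
        cell = df[(df["gene"] == gene) & (df["photoperiod_h"] == p)
                  & (df["zt"] == zt)]
        for ga, gb in genotype_pairs:
            a = cell.loc[cell["genotype"] == ga, "log2_rel_expr"].to_numpy()
            b = cell.loc[cell["genotype"] == gb, "log2_rel_expr"].to_numpy()
            row = {
                "gene": gene, "photoperiod_h": p, "zt": zt,
                "genotype_a": ga, "genotype_b": gb,
                "n_a": len(a), "n_b": len(b),
                "mean_log2_a": float(np.mean(a)) if len(a) else np.nan,
                "mean_log2_b": float(np.mean(b)) if len(b) else np.nan,
            }
            if len(a) < 2 or len(b) < 2:
                row.update(t_statistic=np.nan, p_value=np.nan,
                           significant=False, untestable=True,
                           reason=f"needs >= 2 detected bio reps per group "
                                  f"(n_a={len(a)}, n_b={len(b)})")
            else:
                t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
                if np.isnan(t_stat):  # identical degenerate samples
                    t_stat, p_val = 0.0, 1.0
                row.update(t_statistic=float(t_stat), p_value=float(p_val),
                           significant=bool(p_val < alpha),
                           untestable=False, reason="")
            rows.append(row)
    return pd.DataFrame(rows, columns=[
        "gene", "photoperiod_h", "zt", "genotype_a", "genotype_b",
        "n_a", "n_b", "mean_log2_a", "mean_log2_b",
        "t_statistic", "p_value", "significant", "untestable", "reason",
    ])
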