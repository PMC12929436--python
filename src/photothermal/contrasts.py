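"""Pairwise photoperiod treatment contrasts on thermal time to heading.

For each genotype and each requested photoperiod pair (by default 16 h vs
20 h — the sensitivity window — and 20 h vs 22 h — the speed-breeding
standard against the putative threshold), a two-sided two-sample Student's
t-test (pooled variance; Welch available as a switch) compares plant-level
thermal times.  Experiment repetitions are pooled within genotype x
photoperiod by default.  No multiplicity adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import PlantRecord, ValidationError

__all__ = ["ContrastResult", "photoperiod_contrasts", "contrasts_frame"]

DEFAULT_PAIRS: Tuple[Tuple[float, float], ...] = ((16.0, 20.0), (20.0, 22.0))


@dataclass(frozen=True)
class ContrastResult:
    genotype: str
    pair: Tuple[float, float]
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    significant: bool
    skipped: bool = False
    reason: str = ""


def photoperiod_contrasts(
    records: Sequence[PlantRecord],
    pairs: Sequence[Tuple[float, float]] = DEFAULT_PAIRS,
    alpha: float = 0.05,
    equal_var: bool = True,
    repetition: Optional[int] = None,
) -> List[ContrastResult]:
    """Two-sided t-tests per genotype x photoperiod pair.

    Contrasts with fewer than two observations in either arm are returned
    as skipped entries with a reason, never silently dropped.  Set
    ``repetition`` to restrict to a single experiment repetition instead of
    pooling.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    subset = [r for r in records
              if repetition is None or r.repetition == repetition]
    genos = sorted({r.genotype for r in subset})
    results: List[ContrastResult] = []
    for geno in genos:
        for (p_a, p_b) in pairs:
            a = np.array([r.thermal_time_cd for r in subset
                          if r.genotype == geno and r.photoperiod_h == p_a])
            b = np.array([r.thermal_time_cd for r in subset
                          if r.genotype == geno and r.photoperiod_h == p_b])
            if len(a) < 2 or len(b) < 2:
                results.append(ContrastResult(
                    geno, (p_a, p_b),
                    float(np.mean(a)) if len(a) else float("nan"),
                    float(np.mean(b)) if len(b) else float("nan"),
                    len(a), len(b), float("nan"), float("nan"),
                    significant=False, skipped=True,
                    reason=f"needs >= 2 observations per arm "
                           f"(n={len(a)} at {p_a} h, n={len(b)} at {p_b} h)",
                ))
                continue
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
            # identical degenerate samples: define t = 0, p = 1
            if np.isnan(t_stat):
                t_stat, p_val = 0.0, 1.0
            results.append(ContrastResult(
                geno, (p_a, p_b), float(np.mean(a)), float(np.mean(b)),
                len(a), len(b), float(t_stat), float(p_val),
                significant=bool(p_val < alpha),
            ))
    return results


def contrasts_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Tabular view of contrast results for CSV export."""
    return pd.DataFrame(
        [
            {
                "genotype": r.genotype,
                "photoperiod_a": r.pair[0],
                "photoperiod_b": r.pair[1],
                "mean_a_cd": r.mean_a,
                "mean_b_cd": r.mean_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "skipped": r.skipped,
                "reason": r.reason,
            }
            for r in results
        ]
    )
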