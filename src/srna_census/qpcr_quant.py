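"""Relative qPCR quantification by the efficiency-corrected (Pfaffl) ratio.

Per replicate, expression of a target miRNA relative to a reference gene
(e.g. eF1alpha) across a treated/control contrast:

``ratio = E_target ** (Ct_target_control - Ct_target_treated)
        / E_ref    ** (Ct_ref_control    - Ct_ref_treated)``

With both efficiencies at the ideal 2.0 this reduces to ``2 ** -ddCt``.
Replicate ratios are log2-transformed (fold changes are multiplicative, so
logs are the normally-distributed scale) and a two-sided one-sample t-test of
the mean log-ratio against 0 gives the per-miRNA significance call (default
alpha 0.05) with an up/down direction label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["QPCRMeasurement", "FoldChangeResult", "pfaffl_ratio", "fold_change_stats"]

_EFF_LO, _EFF_HI = 1.0, 2.1  # amplification efficiency bounds (+0.1 tolerance)


@dataclass(frozen=True)
class QPCRMeasurement:
    mirna_id: str
    replicate: int
    ct_target_treated: float
    ct_target_control: float
    ct_ref_treated: float
    ct_ref_control: float
    e_target: float = 2.0
    e_ref: float = 2.0

    def __post_init__(self):
        for name in ("ct_target_treated", "ct_target_control",
                     "ct_ref_treated", "ct_ref_control"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("e_target", "e_ref"):
            v = getattr(self, name)
            if not (_EFF_LO <= v <= _EFF_HI):
                raise ValueError(
                    f"{name}={v} outside amplification-efficiency bounds "
                    f"[{_EFF_LO}, {_EFF_HI}]"
                )


def pfaffl_ratio(m: QPCRMeasurement) -> float:
    """Efficiency-corrected expression ratio (treated vs control) for one
    replicate; 1.0 means no change."""
    dct_target = m.ct_target_control - m.ct_target_treated
    dct_ref = m.ct_ref_control - m.ct_ref_treated
    return (m.e_target ** dct_target) / (m.e_ref ** dct_ref)


@dataclass(frozen=True)
class FoldChangeResult:
    mirna_id: str
    n: int
    mean_log2_fc: float
    sem_log2_fc: float
    t_statistic: float
    p_value: float
    significant: bool
    direction: str            # 'up' | 'down' | 'none'


def fold_change_stats(
    ratios: Sequence[float],
    mirna_id: str = "",
    alpha: float = 0.05,
) -> FoldChangeResult:
    """Mean log2 fold change +/- SEM and a one-sample t-test against no change.

    Requires at least 2 replicates and strictly positive ratios.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 replicates")
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    logs = np.log2(ratios)
    n = logs.size
    mean = float(logs.mean())
    sem = float(logs.std(ddof=1) / math.sqrt(n))
    t, p = stats.ttest_1samp(logs, 0.0)
    significant = bool(p <= alpha)
    if not significant or mean == 0.0:
        direction = "none"
    else:
        direction = "up" if mean > 0 else "down"
    return FoldChangeResult(
        mirna_id=mirna_id, n=n, mean_log2_fc=mean, sem_log2_fc=sem,
        t_statistic=float(t), p_value=float(p),
        significant=significant, direction=direction,
    )
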