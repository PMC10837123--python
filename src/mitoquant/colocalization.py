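"""Intercellular mitochondrial-mixing quantification.

For each cell a global threshold of the summed green and red channels
defines the mitochondrial mask; the Pearson correlation coefficient (PCC)
of the two channels over the mask pixels measures mixing (≈0–1 for mixed
populations, strongly negative/low for unmixed ones). Group comparisons
use an unpaired two-tailed t test on per-cell PCC values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "ColocalizationResult",
    "MixingComparison",
    "sum_threshold_mask",
    "pearson_in_mask",
    "compare_mixing",
]


@dataclass(frozen=True)
class ColocalizationResult:
    cell_id: str
    pcc: float
    n_mask_pixels: int
    threshold_used: float


@dataclass(frozen=True)
class MixingComparison:
    """Unpaired two-tailed t test between mixed and unmixed PCC groups."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    p_value: float


def sum_threshold_mask(ch_green: np.ndarray, ch_red: np.ndarray,
                       method: str | float = "otsu"
                       ) -> tuple[np.ndarray, float]:
    """Mitochondrial mask from a global threshold on the channel sum.

    Returns (mask, threshold). ``method`` is ``"otsu"`` (default reading
    of "global threshold") or a fixed numeric threshold.

    Raises
    ------
    ValueError
        If the sum image is constant (no threshold exists) or the mask
        comes out empty.
    """
    g = np.asarray(ch_green, dtype=np.float64)
    r = np.asarray(ch_red, dtype=np.float64)
    if g.shape != r.shape:
        raise ValueError("channels must have the same shape")
    total = g + r
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if total.max() == total.min():
            raise ValueError("constant sum image: no global threshold")
        t = float(threshold_otsu(total))
    else:
        t = float(method)
    mask = total > t
    if not mask.any():
        raise ValueError("sum-threshold mask is empty")
    return mask, t


def pearson_in_mask(ch_green: np.ndarray, ch_red: np.ndarray,
                    mask: np.ndarray, cell_id: str = "cell",
                    threshold_used: float = float("nan")
                    ) -> ColocalizationResult:
    """Sample Pearson correlation of the two channels over mask pixels.

    Undefined inputs (fewer than two mask pixels, or zero variance in
    either channel within the mask) raise rather than reporting 0, since
    a spurious zero would read as "no mixing".
    """
    mask = np.asarray(mask, dtype=bool)
    g = np.asarray(ch_green, dtype=np.float64)[mask]
    r = np.asarray(ch_red, dtype=np.float64)[mask]
    if g.size < 2:
        raise ValueError("need at least 2 mask pixels for a correlation")
    if g.std() == 0 or r.std() == 0:
        raise ValueError("zero variance within mask: PCC undefined")
    pcc = float(np.corrcoef(g, r)[0, 1])
    return ColocalizationResult(cell_id=cell_id, pcc=pcc,
                                n_mask_pixels=int(mask.sum()),
                                threshold_used=threshold_used)


def compare_mixing(results_a: Sequence[ColocalizationResult | float],
                   results_b: Sequence[ColocalizationResult | float]
                   ) -> MixingComparison:
    """Unpaired two-tailed t test on per-cell PCC values of two groups."""
    def _vals(seq):
        return np.array([x.pcc if isinstance(x, ColocalizationResult) else
                         float(x) for x in seq])

    a, b = _vals(results_a), _vals(results_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two PCC values")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return MixingComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t_stat=float(t_stat), p_value=float(p))
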