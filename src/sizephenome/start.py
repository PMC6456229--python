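"""Critical cell size at Start and quantitative size-epistasis calls.

The critical size is read off an elutriation release time course as the
population median size at which a threshold fraction of cells (default
25%) has formed a bud.  The budding index is first made monotone by
pool-adjacent-violators (isotonic) smoothing — bud counts are binomial
samples, so raw indices can dip — and the threshold crossing is then
linearly interpolated on the size axis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import isotonic_regression

from .datatypes import CriticalSizeResult, ElutriationTimecourse, EpistasisCall

__all__ = [
    "budding_index",
    "critical_size",
    "epistasis_call",
    "LowCellCountWarning",
]


class LowCellCountWarning(UserWarning):
    """Fewer cells scored than the recommended minimum."""


def budding_index(n_budded: int, n_total: int, min_cells: int = 200) -> float:
    """Fraction of budded cells in a sample.

    Warns (``LowCellCountWarning``) when fewer than ``min_cells`` cells
    were scored, the conventional minimum for a stable index.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_budded < 0 or n_budded > n_total:
        raise ValueError("need 0 <= n_budded <= n_total")
    if n_total < min_cells:
        warnings.warn(
            f"budding index from only {n_total} cells (< {min_cells})",
            LowCellCountWarning,
            stacklevel=2,
        )
    return n_budded / n_total


def critical_size(
    tc: ElutriationTimecourse, threshold: float = 0.25
) -> CriticalSizeResult:
    """Median cell size at the first crossing of the budding threshold.

    Parameters
    ----------
    tc : ElutriationTimecourse
    threshold : float
        Budding fraction defining Start passage (default 0.25).

    Raises
    ------
    ValueError
        If the first fraction is already above the threshold, or if the
        threshold is never reached.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LowCellCountWarning)
        bi_raw = np.array(
            [budding_index(b, t) for b, t in zip(tc.n_budded, tc.n_total)]
        )
    bi = isotonic_regression(bi_raw, weights=tc.n_total.astype(float)).x
    sizes = tc.median_fL
    if bi[0] > threshold:
        raise ValueError(
            f"population already budded: first fraction at {bi[0]:.3f} > {threshold}"
        )
    crossing = np.nonzero(bi >= threshold)[0]
    if crossing.size == 0:
        raise ValueError(
            f"threshold not reached: budding index peaks at {bi.max():.3f} < {threshold}"
        )
    i = int(crossing[0])
    if i == 0:  # first fraction sits exactly on the threshold
        return CriticalSizeResult(float(sizes[0]), threshold, (0, 0))
    s0, s1 = sizes[i - 1], sizes[i]
    b0, b1 = bi[i - 1], bi[i]
    cs = s0 + (threshold - b0) / (b1 - b0) * (s1 - s0)
    return CriticalSizeResult(float(cs), threshold, (i - 1, i))


def _rel_diff_pct(x: float, y: float) -> float:
    return 100.0 * abs(x - y) / y


def epistasis_call(
    wt: float,
    single_a: float,
    single_b: float,
    double: float,
    tolerance_pct: float = 5.0,
    pair: tuple[str, str] = ("A", "B"),
) -> EpistasisCall:
    """Classify the size relation of a double mutant to its singles.

    With d(x, y) = 100 |x - y| / y:

    * ``epistatic_to_A`` — the double matches single A within
      ``tolerance_pct`` but not single B (and symmetrically for B);
      when it matches both, the closer single wins and an exact tie is
      ``intermediate``;
    * ``additive`` — the double deviates from the wild type further than
      either single, on the same side, and matches neither single;
    * ``intermediate`` — anything else (e.g. partial epistasis).

    An epistatic call is conventionally read as pathway order (the
    matched gene acts downstream/upstream masking the other), an
    additive call as parallel pathways.
    """
    for name, v in (("wt", wt), ("single_a", single_a), ("single_b", single_b), ("double", double)):
        if v <= 0:
            raise ValueError(f"{name} median must be positive, got {v}")
    if tolerance_pct <= 0:
        raise ValueError("tolerance_pct must be positive")

    d_a = _rel_diff_pct(double, single_a)
    d_b = _rel_diff_pct(double, single_b)
    within_a = d_a <= tolerance_pct
    within_b = d_b <= tolerance_pct

    if within_a and within_b:
        if d_a < d_b:
            relation = "epistatic_to_A"
        elif d_b < d_a:
            relation = "epistatic_to_B"
        else:
            relation = "intermediate"
    elif within_a:
        relation = "epistatic_to_A"
    elif within_b:
        relation = "epistatic_to_B"
    else:
        dev_d, dev_a, dev_b = double - wt, single_a - wt, single_b - wt
        same_side = dev_d * dev_a > 0 and dev_d * dev_b > 0
        if same_side and abs(dev_d) >= abs(dev_a) and abs(dev_d) >= abs(dev_b):
            relation = "additive"
        else:
            relation = "intermediate"
    return EpistasisCall(pair=tuple(pair), relation=relation, tolerance_pct=tolerance_pct)
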