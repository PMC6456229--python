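"""Size-phenome statistics and Whi/Lge classification.

This module turns binned Coulter-counter volume distributions into
summary statistics (mean, interpolated median, peak mode), aggregates
replicates into per-strain medians, computes percent size change against
the parental wild type, classifies mutants as Whi (small) or Lge (large)
at an inclusive percent cutoff, calibrates that cutoff from a benchmark
set of known size mutants, and organises distribution profiles by
hierarchical clustering.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datatypes import (
    BenchmarkSet,
    SizeCall,
    SizeDistribution,
    SizeSummary,
    StrainSummary,
)

__all__ = [
    "normalize",
    "summarize",
    "aggregate_replicates",
    "percent_size_change",
    "reported_reduction_pct",
    "classify_strain",
    "calibrate_cutoff",
    "cluster_profiles",
    "screen_report",
]


def normalize(dist: SizeDistribution) -> np.ndarray:
    """Return the per-bin cell frequencies (counts / total count).

    Raises
    ------
    ValueError
        If the distribution contains no cells.
    """
    total = dist.counts.sum()
    if total <= 0:
        raise ValueError(
            f"cannot normalize all-zero distribution for strain {dist.strain_id!r}"
        )
    return dist.counts / total


def _interpolated_median(volumes: np.ndarray, counts: np.ndarray) -> float:
    """Grouped-data median: invert the mid-count cumulative positions.

    Each populated bin centre v_i is placed at cumulative fraction
    (F_{i-1} + F_i) / 2 (the position of the bin's middle cell), and the
    piecewise-linear curve through those points is inverted at 0.5.  For
    integer counts the result is additionally kept within half a bin
    width of the exact per-cell median (the interpolation refines the
    estimate *within* the median bin; empty neighbouring bins must not
    drag it outside).
    """
    mask = counts > 0
    v = volumes[mask]
    c = counts[mask]
    if v.size == 1:
        return float(v[0])
    total = c.sum()
    frac = np.cumsum(c) / total
    mid = frac - c / (2.0 * total)
    # mid is strictly increasing over populated bins
    est = float(np.interp(0.5, mid, v))
    if not np.allclose(counts, np.round(counts)):
        return est  # weighted data: no per-cell expansion exists
    # exact median of the expanded per-cell list, from cumulative counts
    cum = np.cumsum(c)
    n = int(round(total))
    b1 = int(np.searchsorted(cum, (n + 1) // 2))
    b2 = int(np.searchsorted(cum, n // 2 + 1))
    exact = 0.5 * (v[b1] + v[b2])

    def _bin_width(j_populated: int) -> float:
        j = int(np.nonzero(mask)[0][j_populated])  # index into the full layout
        left = volumes[j] - volumes[j - 1] if j > 0 else volumes[j + 1] - volumes[j]
        right = (
            volumes[j + 1] - volumes[j]
            if j < volumes.size - 1
            else volumes[j] - volumes[j - 1]
        )
        return 0.5 * (left + right)

    half_width = 0.5 * max(_bin_width(b1), _bin_width(b2))
    return float(np.clip(est, exact - half_width, exact + half_width))


def summarize(dist: SizeDistribution) -> SizeSummary:
    """Mean, interpolated median and peak-mode volume of a distribution.

    The mean is the count-weighted mean of bin centres; the median is
    the volume at cumulative fraction 0.5 with linear interpolation
    across bin centres; the mode is the centre of the maximum-count bin
    (smallest volume on ties).
    """
    total = dist.counts.sum()
    if total <= 0:
        raise ValueError(
            f"cannot summarize all-zero distribution for strain {dist.strain_id!r}"
        )
    mean = float(np.dot(dist.counts, dist.volumes_fL) / total)
    median = _interpolated_median(dist.volumes_fL, dist.counts)
    mode = float(dist.volumes_fL[int(np.argmax(dist.counts))])
    return SizeSummary(mean_fL=mean, median_fL=median, mode_fL=mode, total_count=float(total))


def aggregate_replicates(dists: Sequence[SizeDistribution]) -> StrainSummary:
    """Average per-replicate medians into a strain summary.

    The spread is the sample standard deviation (n-1 denominator) of the
    replicate medians, 0 for a single replicate.
    """
    if not dists:
        raise ValueError("need at least one replicate")
    strain_ids = {d.strain_id for d in dists}
    if len(strain_ids) != 1:
        raise ValueError(f"mixed strain ids in replicate set: {sorted(strain_ids)}")
    medians = np.array([summarize(d).median_fL for d in dists])
    sd = float(np.std(medians, ddof=1)) if medians.size > 1 else 0.0
    return StrainSummary(
        strain_id=dists[0].strain_id,
        median_fL=float(medians.mean()),
        median_sd_fL=sd,
        n_replicates=int(medians.size),
    )


def percent_size_change(mutant_median_fL: float, wt_median_fL: float) -> float:
    """Signed percent size change, 100 * (mutant - wt) / wt."""
    if wt_median_fL <= 0:
        raise ValueError("wild-type median must be positive")
    return 100.0 * (mutant_median_fL - wt_median_fL) / wt_median_fL


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reported_reduction_pct(mutant_median_fL: float, wt_median_fL: float) -> int:
    """Integer percent size *reduction* vs wild type, rounded half-up.

    This is the reporting convention of screen summary tables: a strain
    20% smaller than its parent is reported as a reduction of 20; a
    larger strain yields a negative reduction.
    """
    return _round_half_up(-percent_size_change(mutant_median_fL, wt_median_fL))


def classify_strain(
    mutant: StrainSummary, wt: StrainSummary, cutoff_pct: float = 20.0
) -> SizeCall:
    """Call a mutant Whi/Lge/normal against its parental wild type.

    The cutoff is inclusive: a strain whose median is exactly
    ``cutoff_pct`` percent below (above) the wild type is called Whi
    (Lge).
    """
    if cutoff_pct <= 0:
        raise ValueError("cutoff_pct must be positive")
    change = percent_size_change(mutant.median_fL, wt.median_fL)
    if change <= -cutoff_pct:
        call = "Whi"
    elif change >= cutoff_pct:
        call = "Lge"
    else:
        call = "normal"
    return SizeCall(
        strain_id=mutant.strain_id,
        wt_id=wt.strain_id,
        percent_change=change,
        call=call,
        cutoff_pct=cutoff_pct,
    )


def calibrate_cutoff(
    summaries: Mapping[str, StrainSummary],
    wt_map: Mapping[str, str],
    benchmark: BenchmarkSet,
) -> int:
    """Largest integer cutoff consistent with a benchmark set.

    Returns the largest integer ``c`` such that every benchmark small
    strain shows a size reduction >= c percent and every benchmark large
    strain an increase >= c percent versus its parental wild type,
    i.e. the floor of the smallest absolute benchmark change.
    """
    magnitudes = []
    for strain, expect_sign in [(s, -1) for s in benchmark.whi_strains] + [
        (s, +1) for s in benchmark.lge_strains
    ]:
        if strain not in summaries:
            raise ValueError(f"benchmark strain {strain!r} missing from panel")
        if strain not in wt_map:
            raise ValueError(f"benchmark strain {strain!r} has no wild-type reference")
        wt_id = wt_map[strain]
        if wt_id not in summaries:
            raise ValueError(f"wild type {wt_id!r} for benchmark strain {strain!r} missing")
        change = percent_size_change(
            summaries[strain].median_fL, summaries[wt_id].median_fL
        )
        if change == 0 or (change > 0) != (expect_sign > 0):
            raise ValueError(
                f"benchmark strain {strain!r} changed by {change:+.1f}%, "
                f"inconsistent with its benchmark class"
            )
        magnitudes.append(abs(change))
    return int(math.floor(min(magnitudes)))


def cluster_profiles(
    profiles: Mapping[str, np.ndarray],
) -> tuple[list[str], np.ndarray]:
    """Hierarchically cluster normalized size profiles.

    Agglomerative clustering with Euclidean distance and average
    linkage on the frequency vectors.  Strains are ordered
    lexicographically before linkage so the leaf order is deterministic
    and ties break by strain label.

    Returns
    -------
    leaf_order : list of strain labels in dendrogram leaf order
    merge_tree : scipy linkage matrix (rows index the sorted labels)
    """
    labels = sorted(profiles)
    if len(labels) < 2:
        raise ValueError("clustering needs at least 2 strains")
    vectors = [np.asarray(profiles[lab], dtype=float) for lab in labels]
    lengths = {v.size for v in vectors}
    if len(lengths) != 1:
        raise ValueError("all profiles must share the same bin layout")
    X = np.vstack(vectors)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return [labels[i] for i in order], Z


def screen_report(
    summaries: Mapping[str, StrainSummary],
    wt_map: Mapping[str, str],
    cutoff_pct: float = 20.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every mutant in a panel and tally Whi/Lge/normal counts.

    ``wt_map`` maps each mutant strain to its parental wild-type label
    and thereby *defines* the mutant set; strains appearing only as
    wild-type references are not called.  Returns the per-strain report
    table and the summary counts.
    """
    rows = []
    counts = {"Whi": 0, "Lge": 0, "normal": 0}
    for strain in sorted(wt_map):
        if strain not in summaries:
            raise ValueError(f"strain {strain!r} in the wt map is missing from the panel")
        wt_id = wt_map[strain]
        if wt_id not in summaries:
            raise ValueError(f"wild type {wt_id!r} for strain {strain!r} missing from panel")
        call = classify_strain(summaries[strain], summaries[wt_id], cutoff_pct)
        counts[call.call] += 1
        rows.append(
            {
                "strain": strain,
                "wt": wt_id,
                "median_fL": summaries[strain].median_fL,
                "median_sd_fL": summaries[strain].median_sd_fL,
                "percent_change": call.percent_change,
                "call": call.call,
            }
        )
    columns = ["strain", "wt", "median_fL", "median_sd_fL", "percent_change", "call"]
    return pd.DataFrame(rows, columns=columns), counts
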