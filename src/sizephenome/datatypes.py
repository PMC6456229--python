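"""Core data containers shared across the pipeline.

Conventions
-----------
Volumes are femtoliters (fL) throughout, times are minutes, optical
densities are dimensionless plate-reader readings, and ChIP ratios are
log2(IP/control).  Containers validate their structural invariants at
construction; statistical preconditions (e.g. a non-empty distribution)
are checked by the operations that need them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SizeDistribution",
    "SizeSummary",
    "StrainSummary",
    "SizeCall",
    "BenchmarkSet",
    "PanelTruth",
    "GrowthCurve",
    "GrowthSummary",
    "ElutriationParams",
    "ElutriationTimecourse",
    "CriticalSizeResult",
    "EpistasisCall",
    "ProbeSet",
    "EnrichedRegions",
    "GeneSetOverlap",
]

CALL_LABELS = ("Whi", "Lge", "normal")
EPISTASIS_RELATIONS = ("epistatic_to_A", "epistatic_to_B", "additive", "intermediate")


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class SizeDistribution:
    """A binned cell-volume histogram for one strain x replicate.

    ``volumes_fL`` holds bin-centre volumes (strictly increasing, default
    layout 256 equal-width bins) and ``counts`` the cell count per bin.
    """

    strain_id: str
    replicate_id: str
    volumes_fL: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        vols = _as_1d_float(self.volumes_fL, "volumes_fL")
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size != vols.size:
            raise ValueError("counts must be 1-D and match volumes_fL in length")
        if vols.size < 1:
            raise ValueError("distribution needs at least one bin")
        if vols.size > 1 and not np.all(np.diff(vols) > 0):
            raise ValueError("bin volumes must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("bin counts must be non-negative")
        object.__setattr__(self, "volumes_fL", vols)
        object.__setattr__(self, "counts", counts)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return int(self.volumes_fL.size)


@dataclass(frozen=True)
class SizeSummary:
    """Mean / median / mode volume of one binned distribution."""

    mean_fL: float
    median_fL: float
    mode_fL: float
    total_count: float


@dataclass(frozen=True)
class StrainSummary:
    """Replicate-averaged median size for one strain (Table-style ``m ± sd``)."""

    strain_id: str
    median_fL: float
    median_sd_fL: float
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.median_sd_fL < 0:
            raise ValueError("median_sd_fL must be >= 0")


@dataclass(frozen=True)
class SizeCall:
    """Whi/Lge/normal call of a mutant against its parental wild type."""

    strain_id: str
    wt_id: str
    percent_change: float
    call: str
    cutoff_pct: float

    def __post_init__(self):
        if self.call not in CALL_LABELS:
            raise ValueError(f"call must be one of {CALL_LABELS}")


@dataclass(frozen=True)
class BenchmarkSet:
    """Conserved small/large mutants used to calibrate the size cutoff."""

    whi_strains: tuple[str, ...]
    lge_strains: tuple[str, ...]

    def __post_init__(self):
        whi = tuple(self.whi_strains)
        lge = tuple(self.lge_strains)
        if not whi and not lge:
            raise ValueError("benchmark set must name at least one strain")
        if set(whi) & set(lge):
            raise ValueError("whi and lge benchmark sets must be disjoint")
        object.__setattr__(self, "whi_strains", whi)
        object.__setattr__(self, "lge_strains", lge)


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth attached to a simulated screen strain."""

    strain_id: str
    true_median_fL: float
    true_class: str
    parent_wt: str

    def __post_init__(self):
        if self.true_class not in CALL_LABELS:
            raise ValueError(f"true_class must be one of {CALL_LABELS}")


@dataclass(frozen=True)
class GrowthCurve:
    """An OD time series for one strain under one condition."""

    strain_id: str
    condition: str
    times_min: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        t = _as_1d_float(self.times_min, "times_min")
        od = _as_1d_float(self.od, "od")
        if t.size != od.size:
            raise ValueError("times_min and od must match in length")
        if t.size < 2:
            raise ValueError("growth curve needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD readings must be non-negative")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class GrowthSummary:
    doubling_time_min: float
    t_half_min: float
    relative_growth_rate: float | None = None


@dataclass(frozen=True)
class ElutriationParams:
    """Parameters of a simulated elutriation release experiment.

    ``critical_mean_fL`` is the *population* critical size: the size at
    which a fraction ``readout_fraction`` (default 25%) of cells have
    budded, matching the operational definition used on real time
    courses.  Per-cell budding thresholds are normal with spread
    ``critical_sd_fL`` and are centred so that the population readout
    equals ``critical_mean_fL``.
    """

    initial_median_fL: float
    growth_rate_per_min: float
    critical_mean_fL: float
    critical_sd_fL: float
    n_cells: int
    sample_interval_min: float
    n_fractions: int
    seed: int
    initial_cv: float = 0.03
    readout_fraction: float = 0.25

    def __post_init__(self):
        if self.initial_median_fL <= 0 or self.critical_mean_fL <= 0:
            raise ValueError("volumes must be positive")
        if self.growth_rate_per_min <= 0:
            raise ValueError("growth_rate_per_min must be positive")
        if self.critical_sd_fL < 0:
            raise ValueError("critical_sd_fL must be >= 0")
        if self.n_cells < 200:
            raise ValueError("n_cells must be >= 200")
        if self.sample_interval_min <= 0 or self.n_fractions < 2:
            raise ValueError("need a positive sample interval and >= 2 fractions")
        if not 0 < self.readout_fraction < 1:
            raise ValueError("readout_fraction must lie in (0, 1)")
        if self.initial_cv < 0:
            raise ValueError("initial_cv must be >= 0")
        if self.critical_mean_fL <= self.initial_median_fL:
            raise ValueError(
                "critical_mean_fL must exceed initial_median_fL "
                "(population would start budded)"
            )


@dataclass(frozen=True)
class ElutriationTimecourse:
    """Ordered fractions (time, median size, budded/total counts)."""

    strain_id: str
    times_min: np.ndarray
    median_fL: np.ndarray
    n_budded: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        t = _as_1d_float(self.times_min, "times_min")
        m = _as_1d_float(self.median_fL, "median_fL")
        nb = np.asarray(self.n_budded, dtype=int)
        nt = np.asarray(self.n_total, dtype=int)
        if not (t.size == m.size == nb.size == nt.size):
            raise ValueError("fraction arrays must match in length")
        if t.size < 2:
            raise ValueError("time course needs at least 2 fractions")
        if not np.all(np.diff(t) > 0):
            raise ValueError("fraction times must be strictly increasing")
        if np.any(nt <= 0):
            raise ValueError("every fraction needs n_total > 0")
        if np.any(nb < 0) or np.any(nb > nt):
            raise ValueError("need 0 <= n_budded <= n_total in every fraction")
        if np.any(m <= 0):
            raise ValueError("median sizes must be positive")
        for name, val in (("times_min", t), ("median_fL", m), ("n_budded", nb), ("n_total", nt)):
            object.__setattr__(self, name, val)

    @property
    def n_fractions(self) -> int:
        return int(self.times_min.size)


@dataclass(frozen=True)
class CriticalSizeResult:
    """Critical size at Start read off a budding-index-vs-size curve."""

    critical_size_fL: float
    threshold_fraction: float
    bracketing_fractions: tuple[int, int]


@dataclass(frozen=True)
class EpistasisCall:
    pair: tuple[str, str]
    relation: str
    tolerance_pct: float

    def __post_init__(self):
        if self.relation not in EPISTASIS_RELATIONS:
            raise ValueError(f"relation must be one of {EPISTASIS_RELATIONS}")


@dataclass(frozen=True)
class ProbeSet:
    """Per-probe replicate log2 IP/control ratios with region annotation."""

    probe_ids: tuple[str, ...]
    region_types: tuple[str, ...]
    log2_ratios: np.ndarray  # shape (n_probes, n_replicates)

    def __post_init__(self):
        ids = tuple(self.probe_ids)
        regions = tuple(self.region_types)
        ratios = np.asarray(self.log2_ratios, dtype=float)
        if ratios.ndim != 2:
            raise ValueError("log2_ratios must be 2-D (probes x replicates)")
        if ratios.shape[1] < 1:
            raise ValueError("need at least one replicate")
        if len(ids) != ratios.shape[0] or len(regions) != ratios.shape[0]:
            raise ValueError("probe_ids, region_types and log2_ratios rows must align")
        if len(set(ids)) != len(ids):
            raise ValueError("probe ids must be unique")
        object.__setattr__(self, "probe_ids", ids)
        object.__setattr__(self, "region_types", regions)
        object.__setattr__(self, "log2_ratios", ratios)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_replicates(self) -> int:
        return int(self.log2_ratios.shape[1])


@dataclass(frozen=True)
class EnrichedRegions:
    """Probes above the mean + k.SD log-ratio cutoff."""

    cutoff_log2: float
    enriched_ids: tuple[str, ...]
    counts_by_region: dict[str, int]
    fold_change_at_cutoff: float


@dataclass(frozen=True)
class GeneSetOverlap:
    """Hypergeometric overlap between two gene sets in a finite universe."""

    k: int
    K: int
    n: int
    N: int
    p_value: float

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("need 0 <= k <= min(K, n)")
        if not (self.K <= self.N and self.n <= self.N):
            raise ValueError("set sizes cannot exceed the universe")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
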