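"""Synthetic instrument data with known ground truth.

Every input the analysis modules consume can be generated here with a
mandatory seed, so the whole pipeline is testable without Coulter
counter, plate reader or microarray data:

* steady-state cell-volume distributions (log-normal on the volume
  scale: right-skewed, positive support, parameterized by median and
  coefficient of variation, binned like the instrument into 256
  equal-width bins);
* screen panels of mutants with prescribed percent size effects around
  a wild type, with truth records for recovery tests;
* lag/exponential/saturation OD growth curves with additive read noise;
* elutriation release time courses in which each cell grows
  exponentially and buds on crossing a personal stochastic size
  threshold;
* ChIP probe sets with a spiked enriched subset;
* gene universes with an exact prescribed overlap between two sets.

All generators are deterministic given their seed and never touch
global random state.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
from scipy.stats import norm

from .datatypes import (
    ElutriationParams,
    ElutriationTimecourse,
    GrowthCurve,
    PanelTruth,
    ProbeSet,
    SizeDistribution,
)

__all__ = [
    "gen_size_distribution",
    "gen_screen_panel",
    "gen_growth_curve",
    "gen_elutriation_timecourse",
    "gen_chip_probes",
    "gen_gene_universe",
]


def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal: sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_volumes(
    median_fL: float, cv: float, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal volumes with the requested median and CV."""
    if cv == 0:
        return np.full(n_cells, median_fL, dtype=float)
    sigma = _lognormal_sigma(cv)
    return median_fL * np.exp(sigma * rng.standard_normal(n_cells))


def gen_size_distribution(
    median_fL: float,
    cv: float,
    n_cells: int,
    n_bins: int = 256,
    vol_min_fL: float = 10.0,
    vol_max_fL: float = 200.0,
    seed: int = 0,
    strain_id: str = "sim",
    replicate_id: str = "r1",
    return_draws: bool = False,
):
    """Draw ``n_cells`` volumes and histogram them like the instrument.

    Volumes are log-normal with the requested median and coefficient of
    variation; draws outside [vol_min_fL, vol_max_fL] are clipped into
    the end bins.  The binned total always equals ``n_cells``.

    With ``return_draws=True`` the raw (pre-binned, pre-clipped) draws
    are returned alongside the distribution, for oracle checks.
    """
    if median_fL <= 0:
        raise ValueError("median_fL must be positive")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not vol_min_fL < median_fL < vol_max_fL:
        raise ValueError("median_fL must lie inside (vol_min_fL, vol_max_fL)")

    rng = np.random.default_rng(seed)
    draws = _draw_volumes(median_fL, cv, n_cells, rng)
    edges = np.linspace(vol_min_fL, vol_max_fL, n_bins + 1)
    counts, _ = np.histogram(np.clip(draws, vol_min_fL, vol_max_fL), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dist = SizeDistribution(
        strain_id=strain_id,
        replicate_id=replicate_id,
        volumes_fL=centers,
        counts=counts,
    )
    return (dist, draws) if return_draws else dist


def gen_screen_panel(
    wt_median_fL: float,
    effects_pct: Mapping[str, float],
    n_replicates: int = 3,
    n_cells: int = 5000,
    cv: float = 0.35,
    seed: int = 0,
    cutoff_pct: float = 20.0,
    wt_label: str = "WT",
    n_bins: int = 256,
    vol_min_fL: float = 10.0,
    vol_max_fL: float = 200.0,
) -> tuple[list[SizeDistribution], list[PanelTruth]]:
    """One wild type plus one strain per effect, each with replicates.

    ``effects_pct`` maps strain label to its signed percent size effect
    relative to the wild type (e.g. -20 for a strain 20% smaller).
    Truth records carry the intended class under ``cutoff_pct``
    (boundary inclusive).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if wt_label in effects_pct:
        raise ValueError(f"duplicate strain label {wt_label!r}")
    if len(set(effects_pct)) != len(effects_pct):
        raise ValueError("duplicate strain labels in effects_pct")
    for strain, eff in effects_pct.items():
        if eff <= -100:
            raise ValueError(f"effect for {strain!r} must exceed -100%")

    seeds = np.random.SeedSequence(seed).spawn(len(effects_pct) + 1)
    dists: list[SizeDistribution] = []
    truths: list[PanelTruth] = []

    def _replicates(strain: str, median: float, ss: np.random.SeedSequence):
        for rep, child in enumerate(ss.spawn(n_replicates), start=1):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            dists.append(
                gen_size_distribution(
                    median, cv, n_cells, n_bins, vol_min_fL, vol_max_fL,
                    seed=rep_seed, strain_id=strain, replicate_id=f"r{rep}",
                )
            )

    _replicates(wt_label, wt_median_fL, seeds[0])
    truths.append(PanelTruth(wt_label, wt_median_fL, "normal", wt_label))
    for (strain, eff), ss in zip(sorted(effects_pct.items()), seeds[1:]):
        median = wt_median_fL * (1.0 + eff / 100.0)
        if eff <= -cutoff_pct:
            cls = "Whi"
        elif eff >= cutoff_pct:
            cls = "Lge"
        else:
            cls = "normal"
        _replicates(strain, median, ss)
        truths.append(PanelTruth(strain, median, cls, wt_label))
    return dists, truths


def gen_growth_curve(
    od0: float,
    od_max: float,
    doubling_time_min: float,
    lag_min: float = 0.0,
    noise_sd: float = 0.0,
    interval_min: float = 10.0,
    duration_min: float = 1440.0,
    seed: int = 0,
    strain_id: str = "sim",
    condition: str = "untreated",
) -> GrowthCurve:
    """Lag + logistic OD curve sampled at a fixed interval.

    The culture sits at ``od0`` for ``lag_min`` minutes, then follows a
    logistic with exponential rate ln(2)/doubling_time_min saturating at
    ``od_max``.  Independent Gaussian read noise (sd ``noise_sd``) is
    added and truncated at zero.
    """
    if not 0 < od0 < od_max:
        raise ValueError("need 0 < od0 < od_max")
    if doubling_time_min <= 0:
        raise ValueError("doubling_time_min must be positive")
    if lag_min < 0 or noise_sd < 0:
        raise ValueError("lag_min and noise_sd must be >= 0")
    if duration_min < 2 * interval_min:
        raise ValueError("duration must cover at least two sampling intervals")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    rate = np.log(2) / doubling_time_min
    tp = np.maximum(t - lag_min, 0.0)
    od = od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-rate * tp))
    if noise_sd > 0:
        od = np.clip(od + rng.normal(0.0, noise_sd, t.size), 0.0, None)
    return GrowthCurve(strain_id=strain_id, condition=condition, times_min=t, od=od)


def gen_elutriation_timecourse(
    params: ElutriationParams, strain_id: str = "sim"
) -> ElutriationTimecourse:
    """Simulate a synchronous G1 release and score budding per fraction.

    Each cell starts unbudded at a volume near ``initial_median_fL``
    (log-normal, CV ``initial_cv`` — elutriated fractions are nearly
    uniform in size) and grows exponentially,
    v_i(t) = v_i(0) exp(rate t).  A cell is scored budded once its
    volume exceeds a personal threshold drawn from a normal with spread
    ``critical_sd_fL``, centred so that the *population* budding
    fraction reaches ``readout_fraction`` exactly when the population
    median equals ``critical_mean_fL`` (see ElutriationParams).  The
    budded fraction is therefore non-decreasing and the per-fraction
    median size strictly increasing.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    v0 = _draw_volumes(p.initial_median_fL, p.initial_cv, p.n_cells, rng)
    # centre personal thresholds so the readout-quantile equals critical_mean
    mu_threshold = p.critical_mean_fL - norm.ppf(p.readout_fraction) * p.critical_sd_fL
    thresholds = rng.normal(mu_threshold, p.critical_sd_fL, p.n_cells)

    times = np.arange(p.n_fractions) * p.sample_interval_min
    medians = np.empty(p.n_fractions)
    budded = np.empty(p.n_fractions, dtype=int)
    for i, t in enumerate(times):
        v = v0 * np.exp(p.growth_rate_per_min * t)
        medians[i] = np.median(v)
        budded[i] = int(np.sum(v > thresholds))
    return ElutriationTimecourse(
        strain_id=strain_id,
        times_min=times,
        median_fL=medians,
        n_budded=budded,
        n_total=np.full(p.n_fractions, p.n_cells, dtype=int),
    )


def gen_chip_probes(
    n_probes: int,
    n_enriched: int,
    baseline_sd: float = 0.3,
    effect_log2: float = 2.0,
    n_replicates: int = 2,
    frac_intergenic: float = 8300 / 14400,
    seed: int = 0,
) -> tuple[ProbeSet, set[str]]:
    """Background-normal probe ratios with a spiked enriched subset.

    Replicate log2 ratios are Normal(0, baseline_sd); the ``n_enriched``
    randomly chosen truth probes are shifted up by ``effect_log2``.
    Region types (intergenic vs ORF) are assigned at the requested
    proportion.  Returns the probe set and the truth set of enriched
    probe ids.
    """
    if n_enriched < 0 or n_enriched >= n_probes:
        raise ValueError("need 0 <= n_enriched < n_probes")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be >= 0")
    if not 0 <= frac_intergenic <= 1:
        raise ValueError("frac_intergenic must lie in [0, 1]")
    if n_replicates < 1 or baseline_sd < 0:
        raise ValueError("need n_replicates >= 1 and baseline_sd >= 0")

    rng = np.random.default_rng(seed)
    width = len(str(n_probes))
    ids = tuple(f"probe_{i:0{width}d}" for i in range(n_probes))
    n_inter = int(round(frac_intergenic * n_probes))
    region = np.array(["intergenic"] * n_inter + ["ORF"] * (n_probes - n_inter))
    rng.shuffle(region)
    ratios = rng.normal(0.0, baseline_sd, size=(n_probes, n_replicates))
    truth_idx = rng.choice(n_probes, size=n_enriched, replace=False)
    ratios[truth_idx, :] += effect_log2
    ps = ProbeSet(probe_ids=ids, region_types=tuple(region), log2_ratios=ratios)
    return ps, {ids[i] for i in truth_idx}


def gen_gene_universe(
    n_universe: int, n_set_a: int, n_set_b: int, overlap_k: int, seed: int = 0
) -> tuple[list[str], list[str], list[str]]:
    """Gene universe with two sets sharing exactly ``overlap_k`` genes."""
    if n_set_a > n_universe or n_set_b > n_universe:
        raise ValueError("set sizes cannot exceed the universe")
    if overlap_k > min(n_set_a, n_set_b):
        raise ValueError("overlap_k cannot exceed the smaller set")
    if n_set_a + n_set_b - overlap_k > n_universe:
        raise ValueError("universe too small for the requested overlap")

    rng = np.random.default_rng(seed)
    width = len(str(n_universe))
    universe = [f"gene_{i:0{width}d}" for i in range(n_universe)]
    a_idx = rng.choice(n_universe, size=n_set_a, replace=False)
    set_a = [universe[i] for i in a_idx]
    shared = rng.choice(n_set_a, size=overlap_k, replace=False)
    outside = np.setdiff1d(np.arange(n_universe), a_idx)
    b_only = rng.choice(outside, size=n_set_b - overlap_k, replace=False)
    set_b = sorted(
        [set_a[i] for i in shared] + [universe[i] for i in b_only]
    )
    return universe, sorted(set_a), set_b
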