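"""ChIP log-ratio thresholding and hypergeometric gene-set statistics.

ChIP-chip enrichment follows the mean + k.SD convention: replicate log2
IP/control ratios are averaged per probe and probes strictly above
mean + k_sd standard deviations of the averaged ratios are called
enriched.  Gene-set overlaps use the upper-tail hypergeometric test
(P(X >= k)); term enrichment adds Benjamini-Hochberg adjustment across
terms while always retaining the raw p-values.
"""

from __future__ import annotations

import warnings
from collections.abc import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import EnrichedRegions, GeneSetOverlap, ProbeSet

__all__ = [
    "average_replicates",
    "chip_enrichment_threshold",
    "hypergeom_pvalue",
    "overlap_test",
    "term_enrichment",
]


def average_replicates(ps: ProbeSet) -> np.ndarray:
    """Arithmetic mean of replicate log2 ratios per probe, order preserved."""
    bad = np.nonzero(~np.isfinite(ps.log2_ratios).all(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"missing replicate value for probe {ps.probe_ids[int(bad[0])]!r}"
        )
    return ps.log2_ratios.mean(axis=1)


def chip_enrichment_threshold(
    mean_log2: np.ndarray,
    probe_ids: Sequence[str] | None = None,
    region_types: Sequence[str] | None = None,
    k_sd: float = 2.0,
) -> EnrichedRegions:
    """Call probes enriched above mean + k_sd standard deviations.

    The cutoff is mean + ``k_sd`` times the sample (n-1) standard
    deviation of the per-probe mean log2 ratios; enrichment is strict
    inequality.  ``fold_change_at_cutoff`` (2**cutoff) reports the
    realized linear fold change at the cutoff.  A zero-variance input
    yields an empty enriched set with a warning.
    """
    values = np.asarray(mean_log2, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector of at least 2 per-probe values")
    if probe_ids is None:
        probe_ids = [f"probe_{i}" for i in range(values.size)]
    if len(probe_ids) != values.size:
        raise ValueError("probe_ids must match mean_log2 in length")
    if region_types is not None and len(region_types) != values.size:
        raise ValueError("region_types must match mean_log2 in length")

    sd = float(np.std(values, ddof=1))
    cutoff = float(values.mean() + k_sd * sd)
    if sd == 0 and k_sd > 0:
        warnings.warn("zero variance across probes; enriched set is empty")
    enriched_mask = values > cutoff
    enriched_ids = tuple(str(probe_ids[i]) for i in np.nonzero(enriched_mask)[0])
    counts: dict[str, int] = {}
    if region_types is not None:
        for i in np.nonzero(enriched_mask)[0]:
            counts[region_types[i]] = counts.get(region_types[i], 0) + 1
    return EnrichedRegions(
        cutoff_log2=cutoff,
        enriched_ids=enriched_ids,
        counts_by_region=counts,
        fold_change_at_cutoff=float(2.0**cutoff),
    )


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail inclusive hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` items are drawn without replacement
    from a universe of ``N`` containing ``K`` marked items.  Computed
    from the survival function in log-stable form by scipy.
    """
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(K, n):
        raise ValueError("overlap k cannot exceed min(K, n)")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.finfo(float).tiny), 1.0)


def overlap_test(
    set_a: Collection[str], set_b: Collection[str], universe: Collection[str]
) -> GeneSetOverlap:
    """Hypergeometric overlap of two gene sets within a universe."""
    uni = set(universe)
    a = set(set_a)
    b = set(set_b)
    for name, s in (("set A", a), ("set B", b)):
        outside = s - uni
        if outside:
            raise ValueError(f"gene {sorted(outside)[0]!r} of {name} not in universe")
    k = len(a & b)
    return GeneSetOverlap(
        k=k, K=len(a), n=len(b), N=len(uni),
        p_value=hypergeom_pvalue(k, len(a), len(b), len(uni)),
    )


def term_enrichment(
    gene_sets: Mapping[str, Collection[str]],
    query: Collection[str],
    universe: Collection[str],
    fdr_method: str = "BH",
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a query gene list.

    One upper-tail hypergeometric test per term against the query,
    followed by multiple-testing adjustment across terms
    (``fdr_method``: "BH" for Benjamini-Hochberg, "bonferroni").  Raw
    p-values are always retained.  Rows sorted by raw p, ties broken by
    term label.
    """
    uni = set(universe)
    q = set(query)
    if not q:
        raise ValueError("empty query gene list")
    outside = q - uni
    if outside:
        raise ValueError(f"query gene {sorted(outside)[0]!r} not in universe")
    methods = {"BH": "fdr_bh", "bonferroni": "bonferroni"}
    if fdr_method not in methods:
        raise ValueError(f"fdr_method must be one of {sorted(methods)}")

    rows = []
    for term in sorted(gene_sets):
        genes = set(gene_sets[term])
        bad = genes - uni
        if bad:
            raise ValueError(f"gene {sorted(bad)[0]!r} of term {term!r} not in universe")
        k = len(genes & q)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": len(genes),
                "n_query": len(q),
                "N_universe": len(uni),
                "p_value": hypergeom_pvalue(k, len(genes), len(q), len(uni)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "k", "K", "n_query", "N_universe", "p_value"]
    )
    if len(df):
        df["adj_p_value"] = multipletests(df["p_value"], method=methods[fdr_method])[1]
        df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["adj_p_value"] = []
    return df
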