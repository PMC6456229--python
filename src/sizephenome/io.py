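"""Delimited-text readers and writers for every pipeline table.

All tables are UTF-8 delimited text with a mandatory header; comma or
tab is auto-detected from the header line.  Formats:

* distributions   strain,replicate,bin_volume_fL,count
* wt map          strain,wt
* growth curves   strain,condition,time_min,od
* time courses    strain,time_min,median_fL,n_budded,n_total
* probe table     probe_id,region_type,rep1_log2,rep2_log2,...
* epistasis table gene_a,gene_b,wt_median_fL,a_median_fL,b_median_fL,double_median_fL
* gene lists      one id per line
* gene sets       GMT (term <tab> description <tab> genes...)
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ElutriationTimecourse, GrowthCurve, ProbeSet, SizeDistribution

__all__ = [
    "read_distribution_table",
    "write_distribution_table",
    "read_wt_map",
    "write_wt_map",
    "read_growth_table",
    "write_growth_table",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_probe_table",
    "write_probe_table",
    "read_epistasis_table",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
]


class ParseError(ValueError):
    """A table failed to parse; the message names the file and problem."""


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header line is 1
        raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
    return vals


def read_distribution_table(path) -> list[SizeDistribution]:
    """Read a long-form binned distribution table, one record per
    strain x replicate, with bin order validated."""
    df = _read_table(path, ["strain", "replicate", "bin_volume_fL", "count"])
    df = df.assign(
        bin_volume_fL=_numeric(df, "bin_volume_fL", path),
        count=_numeric(df, "count", path),
    )
    if (df["count"] < 0).any():
        line = int((df["count"] < 0).idxmax()) + 2
        raise ParseError(f"{path}: negative count at line {line}")
    out = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        vols = grp["bin_volume_fL"].to_numpy()
        if vols.size > 1 and not np.all(np.diff(vols) > 0):
            raise ParseError(
                f"{path}: non-monotone bin volumes for strain {strain!r} "
                f"replicate {rep!r}"
            )
        out.append(
            SizeDistribution(
                strain_id=str(strain),
                replicate_id=str(rep),
                volumes_fL=vols,
                counts=grp["count"].to_numpy(),
            )
        )
    return out


def write_distribution_table(dists: Iterable[SizeDistribution], path, sep: str = ",") -> None:
    frames = [
        pd.DataFrame(
            {
                "strain": d.strain_id,
                "replicate": d.replicate_id,
                "bin_volume_fL": d.volumes_fL,
                "count": d.counts.astype(int)
                if np.allclose(d.counts, np.round(d.counts))
                else d.counts,
            }
        )
        for d in dists
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_wt_map(path) -> dict[str, str]:
    df = _read_table(path, ["strain", "wt"])
    if df["strain"].duplicated().any():
        dup = df.loc[df["strain"].duplicated(), "strain"].iloc[0]
        raise ParseError(f"{path}: duplicate strain {dup!r} in wt map")
    return dict(zip(df["strain"].astype(str), df["wt"].astype(str)))


def write_wt_map(wt_map: Mapping[str, str], path, sep: str = ",") -> None:
    pd.DataFrame(
        {"strain": list(wt_map), "wt": [wt_map[s] for s in wt_map]}
    ).to_csv(path, sep=sep, index=False)


def read_growth_table(path) -> list[GrowthCurve]:
    df = _read_table(path, ["strain", "condition", "time_min", "od"])
    df = df.assign(
        time_min=_numeric(df, "time_min", path), od=_numeric(df, "od", path)
    )
    out = []
    for (strain, cond), grp in df.groupby(["strain", "condition"], sort=True):
        out.append(
            GrowthCurve(
                strain_id=str(strain),
                condition=str(cond),
                times_min=grp["time_min"].to_numpy(),
                od=grp["od"].to_numpy(),
            )
        )
    return out


def write_growth_table(curves: Iterable[GrowthCurve], path, sep: str = ",") -> None:
    frames = [
        pd.DataFrame(
            {
                "strain": c.strain_id,
                "condition": c.condition,
                "time_min": c.times_min,
                "od": c.od,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_timecourse_table(path) -> list[ElutriationTimecourse]:
    df = _read_table(path, ["strain", "time_min", "median_fL", "n_budded", "n_total"])
    for col in ("time_min", "median_fL", "n_budded", "n_total"):
        df[col] = _numeric(df, col, path)
    out = []
    for strain, grp in df.groupby("strain", sort=True):
        out.append(
            ElutriationTimecourse(
                strain_id=str(strain),
                times_min=grp["time_min"].to_numpy(),
                median_fL=grp["median_fL"].to_numpy(),
                n_budded=grp["n_budded"].to_numpy(dtype=int),
                n_total=grp["n_total"].to_numpy(dtype=int),
            )
        )
    return out


def write_timecourse_table(tcs: Iterable[ElutriationTimecourse], path, sep: str = ",") -> None:
    frames = [
        pd.DataFrame(
            {
                "strain": tc.strain_id,
                "time_min": tc.times_min,
                "median_fL": tc.median_fL,
                "n_budded": tc.n_budded,
                "n_total": tc.n_total,
            }
        )
        for tc in tcs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_probe_table(path) -> ProbeSet:
    df = _read_table(path, ["probe_id", "region_type"])
    rep_cols = [c for c in df.columns if c not in ("probe_id", "region_type")]
    if not rep_cols:
        raise ParseError(f"{path}: no replicate log-ratio columns")
    for col in rep_cols:
        df[col] = _numeric(df, col, path)
    return ProbeSet(
        probe_ids=tuple(df["probe_id"].astype(str)),
        region_types=tuple(df["region_type"].astype(str)),
        log2_ratios=df[rep_cols].to_numpy(),
    )


def write_probe_table(ps: ProbeSet, path, sep: str = ",") -> None:
    data = {"probe_id": ps.probe_ids, "region_type": ps.region_types}
    for j in range(ps.n_replicates):
        data[f"rep{j + 1}_log2"] = ps.log2_ratios[:, j]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_epistasis_table(path) -> pd.DataFrame:
    cols = [
        "gene_a",
        "gene_b",
        "wt_median_fL",
        "a_median_fL",
        "b_median_fL",
        "double_median_fL",
    ]
    df = _read_table(path, cols)
    for col in cols[2:]:
        df[col] = _numeric(df, col, path)
    return df[cols]


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            term = parts[0]
            if term in sets:
                raise ParseError(f"{path}: duplicate term {term!r} at line {lineno}")
            sets[term] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in gene_sets:
            genes = "\t".join(gene_sets[term])
            fh.write(f"{term}\t{description}\t{genes}\n")
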