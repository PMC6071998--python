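"""Candidate windows around significant SNPs and gene/QTL overlap.

A significant SNP seeds a window of ``half_width`` bp (default 250 kb) on
each side, clipped at position 1 (and at the chromosome length when known).
Overlapping windows from the same method and population on one chromosome
are merged, keeping the peak SNP with the largest |score|.  Overlap with
gene/QTL intervals is any-overlap (>= 1 bp), 1-based inclusive on both ends.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .io import IntervalSet

_WINDOW_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "source_method",
    "population",
    "peak_snp",
    "peak_pos_bp",
    "peak_score",
    "merged_from",
]


def make_windows(
    sig_snps: pd.DataFrame,
    half_width: int = 250_000,
    merge: bool = True,
    chrom_lengths: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Build (and optionally merge) candidate windows around significant SNPs.

    ``sig_snps`` needs columns chrom, pos_bp, snp_id, score, method,
    population.  Returns one row per (merged) window with the peak SNP
    (largest |score|) retained.
    """
    if sig_snps.empty:
        return pd.DataFrame(columns=_WINDOW_COLUMNS)
    req = {"chrom", "pos_bp", "snp_id", "score", "method", "population"}
    missing = req - set(sig_snps.columns)
    if missing:
        raise ValueError(f"sig_snps missing columns {sorted(missing)}")
    df = sig_snps.copy()
    df["start_bp"] = (df["pos_bp"] - half_width).clip(lower=1)
    df["end_bp"] = df["pos_bp"] + half_width
    if chrom_lengths is not None:
        df["end_bp"] = [
            min(e, chrom_lengths.get(int(c), e)) for e, c in zip(df["end_bp"], df["chrom"])
        ]
    rows = []
    for (method, pop, chrom), grp in df.groupby(["method", "population", "chrom"], sort=True):
        grp = grp.sort_values(["start_bp", "pos_bp"], kind="mergesort")
        if not merge:
            for _, r in grp.iterrows():
                rows.append(
                    (chrom, r["start_bp"], r["end_bp"], method, pop, r["snp_id"], r["pos_bp"], r["score"], 1)
                )
            continue
        cur = None
        for _, r in grp.iterrows():
            if cur is None or r["start_bp"] > cur["end_bp"]:
                if cur is not None:
                    rows.append(tuple(cur[k] for k in _WINDOW_COLUMNS))
                cur = {
                    "chrom": chrom,
                    "start_bp": r["start_bp"],
                    "end_bp": r["end_bp"],
                    "source_method": method,
                    "population": pop,
                    "peak_snp": r["snp_id"],
                    "peak_pos_bp": r["pos_bp"],
                    "peak_score": r["score"],
                    "merged_from": 1,
                }
            else:
                cur["end_bp"] = max(cur["end_bp"], r["end_bp"])
                cur["merged_from"] += 1
                if abs(r["score"]) > abs(cur["peak_score"]):
                    cur["peak_snp"], cur["peak_pos_bp"], cur["peak_score"] = (
                        r["snp_id"],
                        r["pos_bp"],
                        r["score"],
                    )
        if cur is not None:
            rows.append(tuple(cur[k] for k in _WINDOW_COLUMNS))
    out = pd.DataFrame(rows, columns=_WINDOW_COLUMNS)
    for col in ("chrom", "start_bp", "end_bp", "peak_pos_bp", "merged_from"):
        out[col] = out[col].astype(np.int64)
    return out


def overlap_intervals(windows: pd.DataFrame, intervals: IntervalSet) -> pd.DataFrame:
    """Gene/QTL records overlapping any candidate window (>= 1 bp, inclusive).

    Returns one row per interval with the supporting windows, methods and
    populations; intervals with no overlap are absent.  Intervals on
    chromosomes not represented among the windows are skipped with a warning.
    """
    if windows.empty or len(intervals) == 0:
        return pd.DataFrame(
            columns=["name", "category", "chrom", "start_bp", "end_bp", "n_windows", "methods", "populations"]
        )
    known_chroms = set(windows["chrom"].astype(int))
    iv = intervals.table
    off_map = ~iv["chrom"].astype(int).isin(known_chroms)
    if off_map.any():
        warnings.warn(f"{int(off_map.sum())} intervals on chromosomes without any candidate window")
    rows = []
    for _, g in iv.iterrows():
        w = windows[
            (windows["chrom"] == g["chrom"])
            & (windows["start_bp"] <= g["end_bp"])
            & (g["start_bp"] <= windows["end_bp"])
        ]
        if w.empty:
            continue
        rows.append(
            (
                g["name"],
                g["category"],
                int(g["chrom"]),
                int(g["start_bp"]),
                int(g["end_bp"]),
                len(w),
                ",".join(sorted(set(w["source_method"]))),
                ",".join(sorted(set(w["population"]))),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["name", "category", "chrom", "start_bp", "end_bp", "n_windows", "methods", "populations"],
    )


def consensus_genes(
    hits_by_method: Mapping[str, pd.DataFrame], min_methods: int = 1
) -> pd.DataFrame:
    """Union of gene hits annotated with the set of supporting methods.

    ``hits_by_method`` maps a method name (e.g. "fst", "ihs", "xpehh") to its
    :func:`overlap_intervals` output.  ``min_methods=2`` keeps only genes
    supported by more than one approach.
    """
    support: dict[str, dict] = {}
    for method, hits in hits_by_method.items():
        if hits is None or hits.empty:
            continue
        for _, r in hits.iterrows():
            entry = support.setdefault(
                r["name"],
                {
                    "name": r["name"],
                    "category": r["category"],
                    "chrom": int(r["chrom"]),
                    "start_bp": int(r["start_bp"]),
                    "end_bp": int(r["end_bp"]),
                    "methods": set(),
                    "populations": set(),
                },
            )
            entry["methods"].add(method)
            entry["populations"].update(str(r.get("populations", "")).split(","))
    rows = [
        (
            e["name"],
            e["category"],
            e["chrom"],
            e["start_bp"],
            e["end_bp"],
            len(e["methods"]),
            ",".join(sorted(e["methods"])),
            ",".join(sorted(x for x in e["populations"] if x)),
        )
        for e in support.values()
        if len(e["methods"]) >= min_methods
    ]
    out = pd.DataFrame(
        rows,
        columns=["name", "category", "chrom", "start_bp", "end_bp", "n_methods", "methods", "populations"],
    )
    return out.sort_values(["chrom", "start_bp", "name"], kind="mergesort").reset_index(drop=True)
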