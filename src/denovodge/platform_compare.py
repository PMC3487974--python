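"""Microarray vs RNA-Seq fold-change concordance.

Each microarray target (probe) is matched to the contig of its best
homology hit; fold changes are then correlated over all matches and
over the subset significant on both platforms, with a least-squares
line fit on the doubly significant set.  Contigs detected in only one
RNA-Seq condition carry a sentinel fold change (+/- 0.5 in place of an
infinite ratio) and are excluded from correlations by default, since a
finite array ratio against an artificial sentinel is not informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotate_group import AnnotConfig, best_hits, filter_hits

__all__ = ["ConcordanceReport", "match_targets", "concordance", "dynamic_range"]


@dataclass(frozen=True)
class ConcordanceReport:
    """Pearson correlations over all matches (r_all) and over the
    doubly significant subset (r_significant), with the least-squares
    line (array fold change regressed on RNA-Seq fold change) fit on
    that subset."""

    r_all: float
    r_significant: float
    n_all: int
    n_significant: int
    n_excluded_sentinel: int
    slope: float
    intercept: float


def match_targets(
    array: pd.DataFrame,
    probe_hits: pd.DataFrame,
    de: pd.DataFrame,
    config: AnnotConfig = AnnotConfig(),
) -> pd.DataFrame:
    """Best-hit match of array probes to contigs, joined with the DE
    table.

    ``array`` needs columns probe_id, log2fc, significant;
    ``probe_hits`` is a tabular hit file with probes as queries and
    contigs as subjects.  Probes with no hit surviving the e-value
    filter, or whose matched contig is absent from the DE table, are
    omitted.  One row per probe.
    """
    if array["probe_id"].duplicated().any():
        dupes = array.loc[array["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicated probe ids: {dupes[:5]}")
    best = best_hits(filter_hits(probe_hits, config))
    rows = []
    for _, probe in array.iterrows():
        pid = probe["probe_id"]
        if pid not in best.index:
            continue
        contig = best.loc[pid, "sseqid"]
        if contig not in de.index:
            continue
        d = de.loc[contig]
        rows.append(
            {
                "probe_id": pid,
                "contig_id": contig,
                "array_log2fc": float(probe["log2fc"]),
                "rnaseq_log2fc": float(d["log2fc"]),
                "array_significant": bool(probe["significant"]),
                "rnaseq_significant": bool(d["significant"]),
                "rnaseq_sentinel": bool(d["one_condition_flag"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "contig_id",
            "array_log2fc",
            "rnaseq_log2fc",
            "array_significant",
            "rnaseq_significant",
            "rnaseq_sentinel",
        ],
    )


def concordance(matches: pd.DataFrame, exclude_sentinels: bool = True) -> ConcordanceReport:
    """Cross-platform fold-change concordance report."""
    retained = matches[~matches["rnaseq_sentinel"]] if exclude_sentinels else matches
    n_excluded = len(matches) - len(retained)
    if len(retained) < 3:
        raise ValueError("need at least 3 matches for a correlation")
    r_all = float(
        stats.pearsonr(retained["rnaseq_log2fc"], retained["array_log2fc"]).statistic
    )
    sig = retained[retained["array_significant"] & retained["rnaseq_significant"]]
    if len(sig) < 3:
        raise ValueError("need at least 3 doubly significant matches")
    fit = stats.linregress(sig["rnaseq_log2fc"], sig["array_log2fc"])
    return ConcordanceReport(
        r_all=r_all,
        r_significant=float(fit.rvalue),
        n_all=int(len(retained)),
        n_significant=int(len(sig)),
        n_excluded_sentinel=int(n_excluded),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def dynamic_range(matches: pd.DataFrame) -> Dict[str, Tuple[float, float]]:
    """Per-platform fold-change extrema over non-sentinel rows."""
    rows = matches[~matches["rnaseq_sentinel"]]
    if rows.empty:
        raise ValueError("no non-sentinel matches")
    return {
        "rnaseq": (float(rows["rnaseq_log2fc"].min()), float(rows["rnaseq_log2fc"].max())),
        "array": (float(rows["array_log2fc"].min()), float(rows["array_log2fc"].max())),
    }
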