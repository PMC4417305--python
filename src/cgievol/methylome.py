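"""Per-CGI methylation and hydroxymethylation levels from bisulfite call counts.

Input is a per-cytosine table of methylated / unmethylated call counts
(one row per covered CpG cytosine per strand), as produced by standard
bisulfite-alignment callers after trivial column mapping.  Three estimator
variants of the CGI-level methylation percentage are provided:

``pooled_strand_averaged``
    Pool calls per strand, level = 100*S/(S+C) on each strand, then take
    the unweighted mean of the two strand levels (whole-genome bisulfite
    style).  A strand with zero calls is ignored, not treated as 0%.
``pooled``
    One pooled ratio over all calls, both strands together (RRBS style).
``site_mean``
    Unweighted mean of per-site ratios over sites covered by at least
    ``min_reads_per_site`` total calls.

A CGI with fewer than ``min_total_calls`` (default 5) calls overall is
excluded.  Levels <= 20% are labelled LM (low methylation), >= 80% HM
(high methylation), inclusive at both boundaries; everything in between
is ``intermediate``.  Hydroxymethylation (5hmC) uses the same pooled
ratio with hydroxymethylated / non-hydroxymethylated calls in the two
count roles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

from .regions import GenomicInterval

MIN_TOTAL_CALLS = 5
LM_MAX = 20.0
HM_MIN = 80.0

ESTIMATORS = ("pooled_strand_averaged", "pooled", "site_mean")

SITE_COLUMNS = ["chrom", "pos", "strand", "meth_calls", "unmeth_calls"]


@dataclass(frozen=True)
class MethylationLevel:
    """A CGI-level methylation percentage, or an exclusion marker."""

    value: float  # percentage in [0, 100]; NaN when excluded
    n_calls: int
    estimator: str

    @property
    def excluded(self) -> bool:
        return math.isnan(self.value)


def read_site_calls(source: str | IO[str]) -> pd.DataFrame:
    """Load a per-site call-count TSV (chrom, pos, strand, meth, unmeth)."""
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site-call table missing columns: {sorted(missing)}")
    if (df[["meth_calls", "unmeth_calls"]] < 0).any().any():
        raise ValueError("negative call counts")
    return df


def sites_in_cgi(sites: pd.DataFrame, cgi: GenomicInterval) -> pd.DataFrame:
    """Sites whose cytosine position falls within [cgi.start, cgi.end)."""
    m = (
        (sites["chrom"] == cgi.chrom)
        & (sites["pos"] >= cgi.start)
        & (sites["pos"] < cgi.end)
    )
    return sites.loc[m]


def minimum_call_filter(sites: pd.DataFrame, min_total_calls: int = MIN_TOTAL_CALLS) -> bool:
    """True when the CGI passes the minimum-total-call filter.

    The total is methylated + unmethylated calls over all sites and both
    strands; fewer than ``min_total_calls`` excludes the CGI.
    """
    total = int(sites["meth_calls"].sum() + sites["unmeth_calls"].sum())
    return total >= min_total_calls


def _excluded(estimator: str, n_calls: int = 0) -> MethylationLevel:
    return MethylationLevel(float("nan"), n_calls, estimator)


def cgi_level_pooled_strand_averaged(
    sites: pd.DataFrame, min_total_calls: int = 1
) -> MethylationLevel:
    """Strand-averaged pooled level: mean of the two per-strand pooled ratios."""
    n_calls = int(sites["meth_calls"].sum() + sites["unmeth_calls"].sum())
    if n_calls < min_total_calls:
        return _excluded("pooled_strand_averaged", n_calls)
    strand_levels = []
    for _, grp in sites.groupby("strand"):
        s = grp["meth_calls"].sum()
        c = grp["unmeth_calls"].sum()
        if s + c > 0:
            strand_levels.append(100.0 * s / (s + c))
    if not strand_levels:
        return _excluded("pooled_strand_averaged", n_calls)
    return MethylationLevel(
        float(np.mean(strand_levels)), n_calls, "pooled_strand_averaged"
    )


def cgi_level_pooled(
    sites: pd.DataFrame, min_total_calls: int = 1
) -> MethylationLevel:
    """Single pooled ratio 100*S/(S+C) over all calls, both strands together."""
    s = int(sites["meth_calls"].sum())
    c = int(sites["unmeth_calls"].sum())
    if s + c < min_total_calls or s + c == 0:
        return _excluded("pooled", s + c)
    return MethylationLevel(100.0 * s / (s + c), s + c, "pooled")


def cgi_level_site_mean(
    sites: pd.DataFrame,
    min_reads_per_site: int = 0,
    min_total_calls: int = 1,
) -> MethylationLevel:
    """Unweighted mean of per-site methylation ratios.

    Sites with total coverage below ``min_reads_per_site`` are dropped
    before averaging (use 4 for RRBS-style informative-site filtering,
    0 to average all covered sites).
    """
    n_calls = int(sites["meth_calls"].sum() + sites["unmeth_calls"].sum())
    if n_calls < min_total_calls:
        return _excluded("site_mean", n_calls)
    cov = sites["meth_calls"] + sites["unmeth_calls"]
    keep = sites.loc[(cov >= max(min_reads_per_site, 1))]
    if keep.empty:
        return _excluded("site_mean", n_calls)
    ratios = keep["meth_calls"] / (keep["meth_calls"] + keep["unmeth_calls"])
    return MethylationLevel(100.0 * float(ratios.mean()), n_calls, "site_mean")


def cgi_hydroxymethylation_level(
    sites: pd.DataFrame, min_total_calls: int = 1
) -> MethylationLevel:
    """Pooled 5hmC level, 100*HC/(HC+NHC).

    The input table carries hydroxymethylated calls in ``meth_calls`` and
    non-hydroxymethylated calls in ``unmeth_calls``.
    """
    lvl = cgi_level_pooled(sites, min_total_calls)
    return MethylationLevel(lvl.value, lvl.n_calls, "pooled_5hmc")


def methylation_label(
    level: MethylationLevel | float,
    lm_max: float = LM_MAX,
    hm_min: float = HM_MIN,
) -> str:
    """Map a level to {LM, HM, intermediate, excluded}; bounds inclusive."""
    value = level.value if isinstance(level, MethylationLevel) else float(level)
    if math.isnan(value):
        return "excluded"
    if value <= lm_max:
        return "LM"
    if value >= hm_min:
        return "HM"
    return "intermediate"


_ESTIMATOR_FNS = {
    "pooled_strand_averaged": cgi_level_pooled_strand_averaged,
    "pooled": cgi_level_pooled,
}


def cgi_methylation_table(
    sites: pd.DataFrame,
    cgis: list[tuple[str, GenomicInterval]],
    sample: str,
    estimator: str = "pooled_strand_averaged",
    min_reads_per_site: int = 0,
    min_total_calls: int = MIN_TOTAL_CALLS,
    lm_max: float = LM_MAX,
    hm_min: float = HM_MIN,
) -> pd.DataFrame:
    """Per-CGI levels and labels for one sample under one estimator.

    Returns a DataFrame with columns cgi_id, sample, estimator, level,
    n_calls, label.  Excluded CGIs appear with level NaN and label
    'excluded'.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    records = []
    for cgi_id, cgi in cgis:
        sub = sites_in_cgi(sites, cgi)
        if estimator == "site_mean":
            lvl = cgi_level_site_mean(sub, min_reads_per_site, min_total_calls)
        else:
            lvl = _ESTIMATOR_FNS[estimator](sub, min_total_calls)
        records.append(
            {
                "cgi_id": cgi_id,
                "sample": sample,
                "estimator": estimator,
                "level": lvl.value,
                "n_calls": lvl.n_calls,
                "label": methylation_label(lvl, lm_max, hm_min),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["cgi_id", "sample", "estimator", "level", "n_calls", "label"]
    )


def cgis_with_hydroxymethylation(
    hmc_sites: pd.DataFrame, cgis: list[tuple[str, GenomicInterval]]
) -> set[str]:
    """Ids of CGIs containing at least one hydroxymethylated call.

    Supports the sensitivity analysis that removes such CGIs, since
    bisulfite chemistry cannot distinguish 5hmC from 5mC yet 5hmC
    deaminates far less readily.
    """
    flagged = set()
    for cgi_id, cgi in cgis:
        sub = sites_in_cgi(hmc_sites, cgi)
        if int(sub["meth_calls"].sum()) >= 1:
            flagged.add(cgi_id)
    return flagged
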