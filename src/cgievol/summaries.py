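"""Cohort tables: label counts by genomic position, cross-sample label
cross-tabs, and grouped mean +/- SEM substitution-rate summaries.

The unit of analysis is the per-CGI profile: one row per CGI carrying
its positional category and coding status, per-sample methylation level
and HM/LM label, the six substitution rates, and (optionally) the leaf
of the fitted rate stump.  All tables here are plain DataFrames so they
can be written as TSV or inspected interactively.

Undefined rates (no ancestral opportunity, or coverage-filtered CGIs)
are excluded from that rate's n/mean/SEM rather than imputed; SEM uses
the n-1 sample standard deviation and is undefined for n < 2.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .subrates import RATE_NAMES

CATEGORY_ORDER = ("five_prime", "three_prime", "intragenic", "intergenic")


def build_profiles(
    classification: pd.DataFrame,
    methylation: pd.DataFrame,
    rates: pd.DataFrame | None = None,
    stump_leaves: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-stage tables into one wide per-CGI profile table.

    ``classification`` is the output of :func:`cgievol.regions.classify_all`;
    ``methylation`` is long-form (cgi_id, sample, level, label) and is
    pivoted to ``level_<sample>`` / ``label_<sample>`` columns; ``rates``
    is the output of :func:`cgievol.subrates.cgi_rate_table`;
    ``stump_leaves`` has columns cgi_id, leaf.
    """
    prof = classification.copy()
    wide = methylation.pivot_table(
        index="cgi_id", columns="sample", values="level", aggfunc="first"
    ).rename(columns=lambda s: f"level_{s}")
    labels = methylation.pivot_table(
        index="cgi_id", columns="sample", values="label", aggfunc="first"
    ).rename(columns=lambda s: f"label_{s}")
    prof = prof.merge(wide, on="cgi_id", how="left")
    prof = prof.merge(labels, on="cgi_id", how="left")
    if rates is not None:
        keep = ["cgi_id", "coverage", "passed_coverage", *RATE_NAMES]
        prof = prof.merge(rates[keep], on="cgi_id", how="left")
    if stump_leaves is not None:
        prof = prof.merge(stump_leaves[["cgi_id", "leaf"]], on="cgi_id", how="left")
    return prof


def _position_cells(profiles: pd.DataFrame) -> list[tuple[str, str]]:
    # the full 7-cell shell is always emitted, empty cells included
    del profiles
    cells = []
    for cat in CATEGORY_ORDER:
        codings = ("coding", "noncoding") if cat != "intergenic" else ("noncoding",)
        cells.extend((cat, coding) for coding in codings)
    return cells


def position_label_counts(profiles: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Counts of LM and HM CGIs per (category x coding) cell, with totals.

    Intermediate and excluded CGIs are omitted from the counts, as in a
    positional HM/LM census table.
    """
    lab = profiles[f"label_{sample}"]
    rows = []
    for cat, coding in _position_cells(profiles):
        m = (profiles["category"] == cat) & (profiles["coding"] == coding)
        rows.append(
            {
                "category": cat,
                "coding": coding,
                "LM": int((m & (lab == "LM")).sum()),
                "HM": int((m & (lab == "HM")).sum()),
            }
        )
    out = pd.DataFrame(rows)
    total = {"category": "total", "coding": "", "LM": int(out["LM"].sum()),
             "HM": int(out["HM"].sum())}
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def crosstab(
    profiles: pd.DataFrame, sample_a: str, sample_b: str
) -> pd.DataFrame:
    """Per (category x coding x sample_a label) stratum, counts of
    sample_b LM and HM.

    CGIs whose sample_b label is intermediate or excluded fall in neither
    column, so LM+HM need not equal the stratum size.
    """
    lab_a = profiles[f"label_{sample_a}"]
    lab_b = profiles[f"label_{sample_b}"]
    rows = []
    for cat, coding in _position_cells(profiles):
        cell = (profiles["category"] == cat) & (profiles["coding"] == coding)
        for a_label in ("HM", "LM"):
            m = cell & (lab_a == a_label)
            rows.append(
                {
                    "category": cat,
                    "coding": coding,
                    f"{sample_a}_label": a_label,
                    "n": int(m.sum()),
                    f"{sample_b}_LM": int((m & (lab_b == "LM")).sum()),
                    f"{sample_b}_HM": int((m & (lab_b == "HM")).sum()),
                }
            )
    return pd.DataFrame(rows)


def group_rate_summary(
    profiles: pd.DataFrame,
    grouping: Sequence[str],
    rate_names: Iterable[str] = RATE_NAMES,
) -> pd.DataFrame:
    """n / mean / SEM of each substitution rate within each group.

    ``grouping`` names profile columns (e.g. ["category", "coding",
    "label_sperm"]).  For each rate, n counts only CGIs where that rate
    is defined; SEM = sd(n-1)/sqrt(n), NaN for n < 2.
    """
    rows = []
    for key, grp in profiles.groupby(list(grouping), dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        base = dict(zip(grouping, key))
        for rate in rate_names:
            vals = grp[rate].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    **base,
                    "rate_type": rate,
                    "n": n,
                    "mean": float(np.mean(vals)) if n else float("nan"),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(n))
                    if n >= 2 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def threshold_partition_report(
    profiles: pd.DataFrame,
    threshold: float,
    sperm_sample: str,
    h1_sample: str,
    rate: str = "cpg_to_tpg_cpa",
) -> pd.DataFrame:
    """Per (category x coding x H1 label) stratum: how many CGIs fall
    below the rate threshold, and how many of those are also sperm-LM.

    Fractions are of the stratum size (CGIs with a defined rate) and are
    reported to full precision; round for presentation.
    """
    lab_h1 = profiles[f"label_{h1_sample}"]
    lab_sp = profiles[f"label_{sperm_sample}"]
    r = profiles[rate]
    rows = []
    for cat, coding in _position_cells(profiles):
        cell = (profiles["category"] == cat) & (profiles["coding"] == coding)
        for h1_label in ("HM", "LM"):
            m = cell & (lab_h1 == h1_label) & r.notna()
            n = int(m.sum())
            below = m & (r < threshold)
            below_lm = below & (lab_sp == "LM")
            rows.append(
                {
                    "category": cat,
                    "coding": coding,
                    f"{h1_sample}_label": h1_label,
                    "n": n,
                    "n_below_threshold": int(below.sum()),
                    "frac_below_threshold": int(below.sum()) / n if n else float("nan"),
                    "n_below_and_sperm_LM": int(below_lm.sum()),
                    "frac_below_and_sperm_LM": int(below_lm.sum()) / n
                    if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)
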