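"""Single-split CART stump on the CpG->TpG/CpA rate with HM/LM class labels.

Finds the rate threshold t minimising the size-weighted Gini impurity of
the two children {rate >= t} (left) and {rate < t} (right), the split a
CART package produces at depth 1.  Candidate thresholds are midpoints of
consecutive distinct sorted rate values; ties in impurity are broken
toward the smallest threshold.  The left/right orientation (>= / <)
matches the convention of reporting the high-rate leaf first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABELS = ("HM", "LM")


def gini(n_a: int, n_b: int) -> float:
    """Binary Gini impurity 1 - p_a^2 - p_b^2; 0 for an empty node."""
    n = n_a + n_b
    if n == 0:
        return 0.0
    pa, pb = n_a / n, n_b / n
    return 1.0 - pa * pa - pb * pb


@dataclass
class StumpFit:
    """A fitted one-split stump over (rate, label) data.

    ``left`` collects points with rate >= threshold, ``right`` those with
    rate < threshold; each is an (n_HM, n_LM) pair.  ``degenerate`` marks
    fits on single-class or constant-rate data, where no threshold is
    defined.
    """

    threshold: float | None
    root: tuple[int, int]
    left: tuple[int, int]
    right: tuple[int, int]
    weighted_gini: float
    degenerate: bool = False

    @property
    def root_gini(self) -> float:
        return gini(*self.root)

    def leaf_majority(self, leaf: str) -> tuple[str, float]:
        """Majority label of a leaf and its fraction of the leaf."""
        n_hm, n_lm = self.left if leaf == "left" else self.right
        n = n_hm + n_lm
        if n == 0:
            return ("none", float("nan"))
        if n_hm >= n_lm:
            return ("HM", n_hm / n)
        return ("LM", n_lm / n)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "root": {"HM": self.root[0], "LM": self.root[1], "gini": self.root_gini},
            "left_ge_threshold": {"HM": self.left[0], "LM": self.left[1],
                                  "gini": gini(*self.left)},
            "right_lt_threshold": {"HM": self.right[0], "LM": self.right[1],
                                   "gini": gini(*self.right)},
            "weighted_gini": self.weighted_gini,
            "degenerate": self.degenerate,
        }


def fit_stump(
    rates: np.ndarray, labels: np.ndarray, min_leaf_size: int = 1
) -> StumpFit:
    """Exhaustive best single Gini split of rates into HM/LM leaves.

    Parameters
    ----------
    rates : array of float
        Per-CGI CpG->TpG/CpA substitution rates (must be finite).
    labels : array of str
        "HM" or "LM" per CGI.
    min_leaf_size : int
        Candidate splits leaving fewer points in either child are not
        considered (CART ``minbucket`` analogue; default 1).
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    if rates.shape != labels.shape:
        raise ValueError("rates and labels differ in length")
    if not np.isfinite(rates).all():
        raise ValueError("rates must be finite; drop undefined rates upstream")
    bad = set(np.unique(labels)) - set(LABELS)
    if bad:
        raise ValueError(f"labels must be HM/LM, got extras {sorted(bad)}")

    n_hm_root = int((labels == "HM").sum())
    n_lm_root = int((labels == "LM").sum())
    root = (n_hm_root, n_lm_root)
    n = n_hm_root + n_lm_root
    if n_hm_root == 0 or n_lm_root == 0 or len(np.unique(rates)) < 2:
        return StumpFit(None, root, root, (0, 0), gini(*root), degenerate=True)

    order = np.argsort(rates, kind="stable")
    r = rates[order]
    is_hm = (labels[order] == "HM").astype(np.int64)
    # prefix sums: below[i] = counts among the i smallest rates (right child)
    cum_hm = np.cumsum(is_hm)
    cum_n = np.arange(1, n + 1)
    # candidate split after position i (0-based): right = first i+1 points
    distinct = r[:-1] < r[1:]
    cand = np.flatnonzero(distinct)
    n_right = cum_n[cand]
    hm_right = cum_hm[cand]
    lm_right = n_right - hm_right
    n_left = n - n_right
    hm_left = n_hm_root - hm_right
    lm_left = n_lm_root - lm_right

    ok = (n_left >= min_leaf_size) & (n_right >= min_leaf_size)
    if not ok.any():
        return StumpFit(None, root, root, (0, 0), gini(*root), degenerate=True)
    cand, n_right, n_left = cand[ok], n_right[ok], n_left[ok]
    hm_right, lm_right = hm_right[ok], lm_right[ok]
    hm_left, lm_left = hm_left[ok], lm_left[ok]

    g_left = 1.0 - (hm_left / n_left) ** 2 - (lm_left / n_left) ** 2
    g_right = 1.0 - (hm_right / n_right) ** 2 - (lm_right / n_right) ** 2
    weighted = (n_left * g_left + n_right * g_right) / n

    best = int(np.argmin(weighted))  # argmin takes the first = smallest threshold
    i = cand[best]
    threshold = 0.5 * (r[i] + r[i + 1])
    return StumpFit(
        threshold=float(threshold),
        root=root,
        left=(int(hm_left[best]), int(lm_left[best])),
        right=(int(hm_right[best]), int(lm_right[best])),
        weighted_gini=float(weighted[best]),
    )


def fit_stump_frame(data: pd.DataFrame, min_leaf_size: int = 1) -> StumpFit:
    """fit_stump on a DataFrame with columns ``rate`` and ``label``."""
    return fit_stump(
        data["rate"].to_numpy(), data["label"].to_numpy(), min_leaf_size
    )


def leaf_composition(fit: StumpFit) -> pd.DataFrame:
    """Per-leaf majority label and fraction, as printed in a stump report."""
    if fit.degenerate:
        raise ValueError("degenerate fit has no leaves")
    rows = []
    for leaf, side in (("left", ">= threshold"), ("right", "< threshold")):
        label, frac = fit.leaf_majority(leaf)
        n_hm, n_lm = fit.left if leaf == "left" else fit.right
        rows.append({"leaf": leaf, "condition": side, "n_HM": n_hm, "n_LM": n_lm,
                     "majority_label": label, "majority_fraction": frac})
    return pd.DataFrame(rows)


def assign_leaves(
    rates: np.ndarray, threshold: float
) -> np.ndarray:
    """Leaf membership per CGI: 'ge_threshold' or 'lt_threshold'."""
    rates = np.asarray(rates, dtype=float)
    out = np.where(rates >= threshold, "ge_threshold", "lt_threshold")
    return np.where(np.isfinite(rates), out, "excluded")
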