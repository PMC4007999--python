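"""Dosage classification, segregation distortion and marker QC.

In a pseudo-testcross a dominant marker present on ``k`` of the ``m``
homologues of the informative parent (and absent from the other parent)
is transmitted to a progeny unless the gamete misses every copy, which
under random chromosomal segregation happens with probability
``C(m-k, m/2) / C(m, m/2)``.  Single-dose (SD) markers therefore
segregate 1:1 present:absent at any ploidy, double-dose (DD) markers
55:15 at m = 8, and triple-dose (TD) 65:5.  Classification is by chi2
goodness of fit (1 df) against these expectations: markers compatible
with 1:1 are SD; markers with significant but moderate distortion are
kept as skewed SD provided the 1:1 fit still beats the DD fit; markers
fitting the DD or TD ratio are excluded from single-dose mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log2

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MarkerMatrix

__all__ = [
    "DosageCall",
    "expected_present_fraction",
    "classify_dosage",
    "skew_statistic",
    "score_matrix",
    "find_duplicates",
    "collapse_duplicates",
    "quality_filter",
]


def expected_present_fraction(dose: int, ploidy: int) -> float:
    """P(progeny shows a dose-``dose`` dominant marker) under random
    chromosomal segregation at even ``ploidy``."""
    if ploidy % 2 or ploidy < 4:
        raise ValueError(f"ploidy must be even and >= 4, got {ploidy}")
    if not 1 <= dose <= ploidy:
        raise ValueError(f"dose must be in 1..{ploidy}, got {dose}")
    gam = ploidy // 2
    absent = comb(ploidy - dose, gam) / comb(ploidy, gam) if ploidy - dose >= gam else 0.0
    return 1.0 - absent


def _chi2_1df(n_present: int, n_absent: int, p_expected: float) -> float:
    n = n_present + n_absent
    e1, e0 = n * p_expected, n * (1.0 - p_expected)
    return (n_present - e1) ** 2 / e1 + (n_absent - e0) ** 2 / e0


@dataclass
class DosageCall:
    marker: str
    n_present: int
    n_absent: int
    n_missing: int
    chi2_1to1: float
    chi2_dd: float
    chi2_td: float
    p_1to1: float
    skew_log2: float
    skew_significant: bool
    dosage_class: str  # SD | SD_skewed | DD | TD | biparental_3to1 | unclassified


def classify_dosage(
    n_present: int,
    n_absent: int,
    ploidy: int = 8,
    alpha: float = 0.05,
    marker: str = "",
    n_missing: int = 0,
    in_second_parent: bool = False,
) -> DosageCall:
    """Assign a dosage class from segregation counts.

    Decision rule: SD when the 1:1 chi2 is non-significant at ``alpha``;
    SD_skewed when 1:1 is rejected but its chi2 is still strictly below
    the chi2 against the ploidy-specific DD ratio (moderate distortion
    kept, likely DD excluded); otherwise DD or TD when the respective
    chi2 is the minimum and non-significant; otherwise unclassified.
    Markers flagged ``in_second_parent`` are instead tested against the
    3:1 bi-parental ratio and never enter single-dose mapping.
    """
    if ploidy % 2:
        raise ValueError(f"ploidy must be even, got {ploidy}")
    if n_present == 0 and n_absent == 0:
        raise ValueError(f"marker {marker!r}: no scored progeny")

    chi2_11 = _chi2_1df(n_present, n_absent, 0.5)
    chi2_dd = _chi2_1df(n_present, n_absent, expected_present_fraction(2, ploidy))
    chi2_td = _chi2_1df(n_present, n_absent, expected_present_fraction(3, ploidy))
    p_11 = float(stats.chi2.sf(chi2_11, df=1))
    crit = float(stats.chi2.ppf(1.0 - alpha, df=1))

    skew, skew_sig = skew_statistic(n_present, n_absent, alpha)

    if in_second_parent:
        chi2_31 = _chi2_1df(n_present, n_absent, 0.75)
        cls = "biparental_3to1" if chi2_31 <= crit else "unclassified"
    elif chi2_11 <= crit:
        cls = "SD"
    elif chi2_11 < chi2_dd:
        cls = "SD_skewed"
    else:
        best, chi2_best = ("DD", chi2_dd) if chi2_dd <= chi2_td else ("TD", chi2_td)
        cls = best if chi2_best <= crit else "unclassified"

    return DosageCall(
        marker=marker,
        n_present=int(n_present),
        n_absent=int(n_absent),
        n_missing=int(n_missing),
        chi2_1to1=chi2_11,
        chi2_dd=chi2_dd,
        chi2_td=chi2_td,
        p_1to1=p_11,
        skew_log2=skew,
        skew_significant=skew_sig,
        dosage_class=cls,
    )


def skew_statistic(
    n_present: int, n_absent: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """Segregation skew as log2(present/absent) with a chi2 flag.

    A zero count gives infinite skew (signed) and is flagged
    significant.  Swapping the counts negates the statistic.
    """
    if n_present == 0 and n_absent == 0:
        raise ValueError("no scored progeny")
    if n_present == 0:
        return float("-inf"), True
    if n_absent == 0:
        return float("inf"), True
    skew = log2(n_present / n_absent)
    crit = float(stats.chi2.ppf(1.0 - alpha, df=1))
    return skew, _chi2_1df(n_present, n_absent, 0.5) > crit


def score_matrix(
    matrix: MarkerMatrix, ploidy: int = 8, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-marker dosage report for a whole matrix (complete-case counts)."""
    counts = matrix.counts()
    bipar = None
    if matrix.metadata is not None and "in_second_parent" in matrix.metadata:
        bipar = matrix.metadata["in_second_parent"].astype(bool)
    rows = []
    for m, row in counts.iterrows():
        call = classify_dosage(
            int(row.n_present),
            int(row.n_absent),
            ploidy=ploidy,
            alpha=alpha,
            marker=m,
            n_missing=int(row.n_missing),
            in_second_parent=bool(bipar[m]) if bipar is not None else False,
        )
        rows.append(vars(call))
    return pd.DataFrame(rows).set_index("marker")


def find_duplicates(matrix: MarkerMatrix, min_overlap: int = 50) -> list[list[str]]:
    """Cluster markers that are identical wherever both are scored.

    Two markers join a cluster when they agree on every progeny scored
    for both and share at least ``min_overlap`` scored progeny (guarding
    against spurious merges among panel-restricted markers).  Clusters
    are connected components of that relation; only clusters of size
    >= 2 are returned, sorted for determinism.
    """
    X = matrix.calls.to_numpy(dtype=float)
    valid = ~np.isnan(X)
    P = np.where(valid, X, 0.0)  # present indicator
    A = np.where(valid, 1.0 - X, 0.0)  # absent indicator
    mismatch = P @ A.T + A @ P.T
    overlap = valid.astype(float) @ valid.astype(float).T
    adj = (mismatch == 0) & (overlap >= min_overlap)
    np.fill_diagonal(adj, False)

    ids = matrix.marker_ids
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(*np.nonzero(adj)):
        if i < j:
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[str]] = {}
    for i, m in enumerate(ids):
        groups.setdefault(find(i), []).append(m)
    clusters = [sorted(g) for g in groups.values() if len(g) > 1]
    return sorted(clusters)


def collapse_duplicates(
    matrix: MarkerMatrix, min_overlap: int = 50
) -> tuple[MarkerMatrix, dict[str, str]]:
    """Keep one representative per duplicate cluster.

    The representative is the member with the highest call rate, ties
    broken by name.  Returns the reduced matrix and a map from each
    removed marker to its representative.
    """
    clusters = find_duplicates(matrix, min_overlap=min_overlap)
    call_rate = matrix.call_rate()
    removed: dict[str, str] = {}
    for cluster in clusters:
        rep = sorted(cluster, key=lambda m: (-call_rate[m], m))[0]
        for m in cluster:
            if m != rep:
                removed[m] = rep
    keep = [m for m in matrix.marker_ids if m not in removed]
    return matrix.subset(keep), removed


def quality_filter(
    matrix: MarkerMatrix, q_min: float = 80.0, call_rate_min: float = 0.8
) -> tuple[MarkerMatrix, dict[str, int]]:
    """Drop markers failing quality (strict Q > q_min) or call rate
    (inclusive >= call_rate_min); returns the filtered matrix and
    removal counts per criterion.

    When the metadata carries ``n_assayed`` (markers assayed only on a
    reduced progeny panel), the call rate is scored calls / assayed
    progeny, so panel-restricted markers are not penalised for the
    progeny never attempted.
    """
    if matrix.n_markers == 0:
        return matrix, {"quality": 0, "call_rate": 0}
    if matrix.metadata is None or "quality" not in matrix.metadata:
        raise ValueError("quality metadata required for quality_filter")
    quality = matrix.metadata["quality"]
    bad_q = quality.isna()
    if bad_q.any():
        raise ValueError(
            f"marker {quality.index[bad_q][0]!r} has no quality score"
        )
    if "n_assayed" in matrix.metadata:
        denom = matrix.metadata["n_assayed"].astype(float).clip(lower=1)
        call_rate = matrix.n_scored() / denom
    else:
        call_rate = matrix.call_rate()
    fail_q = ~(quality > q_min)
    fail_cr = call_rate < call_rate_min
    keep = matrix.calls.index[~(fail_q | fail_cr)]
    log = {"quality": int(fail_q.sum()), "call_rate": int(fail_cr.sum())}
    return matrix.subset(keep), log
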