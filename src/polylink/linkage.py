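"""Two-point linkage estimation, grouping, ordering and map building.

All mapped markers are coupling-phase single-dose markers of one parent
(pseudo-testcross), so each informative progeny is a direct observation
of one meiosis: the recombination fraction between two markers is the
discordance rate R/n, and the two-point LOD is the likelihood ratio of
linkage at rf = R/n against free recombination,

    LOD = R log10(rf) + (n - R) log10(1 - rf) + n log10(2),

with the rf = 0 limit equal to n log10(2).  Map distances use the
Haldane function d = -50 ln(1 - 2 rf), which assumes no crossover
interference.  Markers are grouped by single-linkage transitive closure
over pairs with LOD >= lod_min and rf <= rf_max, ordered within each
group by SARF-minimising seriation (greedy insertion + 2-opt), and the
map is built in two stages: a framework from fully scored markers, then
single insertion of panel-restricted markers against the fixed
framework order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import MarkerMatrix

__all__ = [
    "TwoPointEstimate",
    "LinkageGroup",
    "GeneticMap",
    "two_point",
    "two_point_tables",
    "haldane_cm",
    "group_markers",
    "order_group",
    "two_stage_build",
]

LOG10_2 = math.log10(2.0)

# adjacent rf just below 0.5 would blow up the Haldane distance; cap it
_RF_CAP = 0.49


@dataclass
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    rf: float
    lod: float
    n_informative: int
    informative: bool = True


@dataclass
class LinkageGroup:
    """An ordered run of coupling-phase markers on one homologue.

    Positions are cumulative Haldane cM starting at 0 for the first
    marker; orientation is canonical (lexicographically smaller terminal
    marker first).
    """

    name: str
    markers: list[str]
    positions: np.ndarray
    hg: Optional[int] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) < 2:
            raise ValueError(f"LG {self.name}: needs >= 2 markers")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError(f"LG {self.name}: positions must be non-decreasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1])

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def position_of(self, marker: str) -> float:
        return float(self.positions[self.markers.index(marker)])


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    unplaced: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_length(self) -> float:
        return float(sum(g.length for g in self.groups))

    def lg_of(self) -> dict[str, str]:
        return {m: g.name for g in self.groups for m in g.markers}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lg": g.name, "marker": m, "position_cm": p, "hg": g.hg}
            for g in self.groups
            for m, p in zip(g.markers, g.positions)
        ]
        return pd.DataFrame(rows, columns=["lg", "marker", "position_cm", "hg"])


def two_point(
    calls_a: Sequence[float],
    calls_b: Sequence[float],
    marker_a: str = "A",
    marker_b: str = "B",
    min_informative: int = 30,
) -> TwoPointEstimate:
    """Two-point rf/LOD between two coupling-phase SD markers.

    Only progeny scored for both markers are used.  Pairs with fewer
    than ``min_informative`` shared observations are flagged
    uninformative (rf/lod reported but excluded from grouping).
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n == 0:
        return TwoPointEstimate(marker_a, marker_b, 0.5, 0.0, 0, informative=False)
    r = int((a[ok] != b[ok]).sum())
    rf, lod = _rf_lod(r, n)
    return TwoPointEstimate(marker_a, marker_b, rf, lod, n, informative=n >= min_informative)


def _rf_lod(r: int, n: int) -> tuple[float, float]:
    rf = min(r / n, 0.5)
    if rf == 0.0:
        return 0.0, n * LOG10_2
    if rf == 0.5:
        return 0.5, 0.0
    lod = r * math.log10(rf) + (n - r) * math.log10(1.0 - rf) + n * LOG10_2
    return rf, lod


def two_point_tables(
    calls: pd.DataFrame, min_informative: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs rf, LOD and informative-count matrices (vectorised).

    Returns square arrays aligned with ``calls.index``; the diagonal is
    rf 0 / LOD n log10(2).  Pairs with no shared observations get
    rf = 0.5, LOD = 0, n = 0.
    """
    X = calls.to_numpy(dtype=float)
    V = (~np.isnan(X)).astype(float)
    P = np.where(np.isnan(X), 0.0, X)
    A = V - P
    n = V @ V.T
    discord = P @ A.T + A @ P.T
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, np.minimum(discord / np.maximum(n, 1), 0.5), 0.5)
        lod = np.where(
            (rf > 0) & (rf < 0.5),
            discord * np.log10(np.where(rf > 0, rf, 1.0))
            + (n - discord) * np.log10(np.where(rf < 1, 1.0 - rf, 1.0))
            + n * LOG10_2,
            0.0,
        )
    lod = np.where((rf == 0.0) & (n > 0), n * LOG10_2, lod)
    return rf, lod, n.astype(int)


def haldane_cm(rf: float) -> float:
    """Haldane map distance d = -50 ln(1 - 2 rf), in cM."""
    if rf < 0 or rf >= 0.5:
        raise ValueError(f"rf must be in [0, 0.5), got {rf}")
    return -50.0 * math.log1p(-2.0 * rf)


def group_markers(
    rf: np.ndarray,
    lod: np.ndarray,
    n_inf: np.ndarray,
    marker_ids: Sequence[str],
    lod_min: float = 10.0,
    rf_max: float = 0.35,
    min_informative: int = 30,
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage marker groups (inclusive thresholds).

    An edge joins two markers when LOD >= lod_min, rf <= rf_max and the
    pair has at least ``min_informative`` shared observations; groups
    are the connected components with >= 2 markers, singletons are
    returned as unlinked.
    """
    ids = list(marker_ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.nonzero(
        np.triu((lod >= lod_min) & (rf <= rf_max) & (n_inf >= min_informative), k=1)
    )
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(iu, ju))
    groups, unlinked = [], []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            groups.append(sorted(comp))
        else:
            unlinked.extend(comp)
    groups.sort(key=lambda c: c[0])
    return groups, sorted(unlinked)


def _sarf(order: list[int], rf: np.ndarray) -> float:
    return float(sum(rf[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _greedy_order(rf: np.ndarray, ids: list[str]) -> list[int]:
    """Greedy insertion seriation; deterministic lexicographic ties."""
    k = len(ids)
    if k == 2:
        return [0, 1]
    # seed with the globally closest pair (ties by marker names)
    best = None
    for i in range(k):
        for j in range(i + 1, k):
            key = (rf[i, j], min(ids[i], ids[j]), max(ids[i], ids[j]))
            if best is None or key < best[0]:
                best = (key, [i, j])
    order = best[1]
    remaining = sorted(set(range(k)) - set(order), key=lambda i: ids[i])
    while remaining:
        choice = None
        for m in remaining:
            for slot in range(len(order) + 1):
                if slot == 0:
                    inc = rf[m, order[0]]
                elif slot == len(order):
                    inc = rf[order[-1], m]
                else:
                    a, b = order[slot - 1], order[slot]
                    inc = rf[a, m] + rf[m, b] - rf[a, b]
                key = (inc, ids[m], slot)
                if choice is None or key < choice[0]:
                    choice = (key, m, slot)
        _, m, slot = choice
        order.insert(slot, m)
        remaining.remove(m)
    return order


def _two_opt_pass(order: list[int], rf: np.ndarray) -> bool:
    """One best-improvement segment reversal; True if SARF decreased."""
    k = len(order)
    best_delta, best_move = 1e-12, None
    for i in range(k - 1):
        for j in range(i + 1, k):
            left = rf[order[i - 1], order[i]] if i > 0 else 0.0
            right = rf[order[j], order[j + 1]] if j < k - 1 else 0.0
            new_left = rf[order[i - 1], order[j]] if i > 0 else 0.0
            new_right = rf[order[i], order[j + 1]] if j < k - 1 else 0.0
            delta = (left + right) - (new_left + new_right)
            if delta > best_delta:
                best_delta, best_move = delta, (i, j)
    if best_move is None:
        return False
    i, j = best_move
    order[i : j + 1] = reversed(order[i : j + 1])
    return True


def _or_opt_pass(order: list[int], rf: np.ndarray) -> bool:
    """One best-improvement relocation of a 1-3 marker segment
    (optionally reversed); True if SARF decreased."""
    k = len(order)
    base = _sarf(order, rf)
    best_delta, best_state = 1e-12, None
    for seg_len in (1, 2, 3):
        for i in range(k - seg_len + 1):
            seg = order[i : i + seg_len]
            rest = order[:i] + order[i + seg_len :]
            for variant in (seg, seg[::-1]) if seg_len > 1 else (seg,):
                for slot in range(len(rest) + 1):
                    cand = rest[:slot] + variant + rest[slot:]
                    delta = base - _sarf(cand, rf)
                    if delta > best_delta:
                        best_delta, best_state = delta, cand
    if best_state is None:
        return False
    order[:] = best_state
    return True


def _refine(order: list[int], rf: np.ndarray) -> list[int]:
    """Alternate 2-opt reversals and or-opt relocations to a local
    SARF minimum under both neighbourhoods."""
    order = list(order)
    while True:
        if _two_opt_pass(order, rf):
            continue
        if _or_opt_pass(order, rf):
            continue
        return order


def order_group(
    rf: pd.DataFrame, lod: Optional[pd.DataFrame] = None, name: str = "LG1"
) -> LinkageGroup:
    """Order one marker group by minimising the sum of adjacent
    recombination fractions (SARF).

    Greedy insertion seriation refined by 2-opt, deterministic
    tie-breaking; positions are cumulative Haldane cM over adjacent rfs
    and the orientation is canonicalised so the lexicographically
    smaller terminal marker comes first.
    """
    ids = rf.index.tolist()
    if len(ids) < 2:
        raise ValueError("order_group needs >= 2 markers")
    if rf.isna().to_numpy().any():
        raise ValueError(f"LG {name}: rf matrix has missing entries")
    m = rf.to_numpy(dtype=float)
    order = _refine(_greedy_order(m, ids), m)
    if ids[order[-1]] < ids[order[0]]:
        order = order[::-1]
    markers = [ids[i] for i in order]
    adj = [min(m[order[i], order[i + 1]], _RF_CAP) for i in range(len(order) - 1)]
    positions = np.concatenate([[0.0], np.cumsum([haldane_cm(r) for r in adj])])
    return LinkageGroup(name=name, markers=markers, positions=positions)


def _insertion_cost(
    framework: list[int], new: int, rf: np.ndarray
) -> tuple[float, int]:
    """Best (SARF increase, slot) for inserting ``new`` into the fixed
    framework order."""
    best = (math.inf, 0)
    k = len(framework)
    for slot in range(k + 1):
        if slot == 0:
            inc = rf[new, framework[0]]
        elif slot == k:
            inc = rf[framework[-1], new]
        else:
            a, b = framework[slot - 1], framework[slot]
            inc = rf[a, new] + rf[new, b] - rf[a, b]
        if inc < best[0]:
            best = (inc, slot)
    return best


def two_stage_build(
    matrix: MarkerMatrix,
    lod_min: float = 10.0,
    rf_max: float = 0.35,
    framework_min_scored: int = 188,
    min_informative: int = 30,
) -> GeneticMap:
    """Framework-then-insertion map construction.

    Markers scored on at least ``framework_min_scored`` progeny form the
    framework: they are grouped (LOD >= lod_min, rf <= rf_max) and each
    group ordered by SARF seriation.  The remaining (panel-restricted)
    markers are then inserted one at a time into the linkage group
    holding their best framework linkage, at the slot minimising the
    SARF increase, without reordering the framework.  Markers with no
    framework linkage at the thresholds stay unplaced.
    """
    scored = matrix.n_scored()
    fw_ids = scored.index[scored >= framework_min_scored].tolist()
    extra_ids = scored.index[scored < framework_min_scored].tolist()

    rf_all, lod_all, n_all = two_point_tables(matrix.calls, min_informative)
    idx = {m: i for i, m in enumerate(matrix.marker_ids)}

    fw_pos = [idx[m] for m in fw_ids]
    groups, unlinked = group_markers(
        rf_all[np.ix_(fw_pos, fw_pos)],
        lod_all[np.ix_(fw_pos, fw_pos)],
        n_all[np.ix_(fw_pos, fw_pos)],
        fw_ids,
        lod_min=lod_min,
        rf_max=rf_max,
        min_informative=min_informative,
    )

    lgs: list[LinkageGroup] = []
    ordered_idx: list[list[int]] = []
    for gi, members in enumerate(groups, start=1):
        sub = [idx[m] for m in members]
        rf_df = pd.DataFrame(rf_all[np.ix_(sub, sub)], index=members, columns=members)
        lg = order_group(rf_df, name=f"LG{gi}")
        lgs.append(lg)
        ordered_idx.append([idx[m] for m in lg.markers])

    unplaced = list(unlinked)
    for m in extra_ids:
        mi = idx[m]
        best = None  # (neg best lod, lg index)
        for li, members in enumerate(ordered_idx):
            ok = (
                (lod_all[mi, members] >= lod_min)
                & (rf_all[mi, members] <= rf_max)
                & (n_all[mi, members] >= min_informative)
            )
            if ok.any():
                top = float(lod_all[mi, members][ok].max())
                if best is None or top > best[0]:
                    best = (top, li)
        if best is None:
            unplaced.append(m)
            continue
        li = best[1]
        _, slot = _insertion_cost(ordered_idx[li], mi, rf_all)
        ordered_idx[li].insert(slot, mi)

    rebuilt: list[LinkageGroup] = []
    ids = matrix.marker_ids
    for li, members in enumerate(ordered_idx):
        names = [ids[i] for i in members]
        if names[-1] < names[0]:
            members = members[::-1]
            names = names[::-1]
        adj = [
            min(rf_all[members[i], members[i + 1]], _RF_CAP)
            for i in range(len(members) - 1)
        ]
        positions = np.concatenate([[0.0], np.cumsum([haldane_cm(r) for r in adj])])
        rebuilt.append(LinkageGroup(name=lgs[li].name, markers=names, positions=positions))

    return GeneticMap(groups=rebuilt, unplaced=sorted(unplaced))
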