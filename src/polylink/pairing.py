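"""Repulsion-phase linkage and the difference-ratio statistic.

Repulsion between single-dose markers on different homologues is only
detectable when those homologues pair preferentially at meiosis, so
repulsion linkage between two LGs is a signature of (partial) disomy.
Detection follows the matrix-inversion trick: the segregation matrix is
phase-inverted (present <-> absent) and two-point analysis is run
between original and inverted markers — the repulsion LOD of (a, b)
equals the coupling LOD of a with the complement of b.  A LG pair is
accepted as being in repulsion only when several marker pairs support
it and the supporting markers span a substantial part of both LGs,
since artefactual repulsion tends to involve single marker pairs.

The difference ratio compares interval structure between homologous
LGs: for the shared marker intervals (defined through common locus
families) between the most densely mapped LG of a HG and another LG,

    ratio = sum_k |LGmax_k - LGi_k| / (LGmax + LGi),

where the denominator is the summed shared-interval length on both LGs.
Identical interval structure gives 0; structurally diverged homologues
approach 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .linkage import GeneticMap, LinkageGroup, two_point_tables
from .matrix import MarkerMatrix

__all__ = [
    "RepulsionLink",
    "DifferenceRatioRecord",
    "invert_matrix",
    "detect_repulsion",
    "difference_ratio",
    "hg_difference_ratios",
    "pairing_summary",
]


@dataclass
class RepulsionLink:
    lg_a: str
    lg_b: str
    best_lod: float
    support: list[tuple[str, str]]  # (marker on lg_a, marker on lg_b)
    span_frac_a: float
    span_frac_b: float
    accepted: bool


@dataclass
class DifferenceRatioRecord:
    hg: str
    reference_lg: str
    compared_lg: str
    k: int  # shared marker intervals used
    ref_intervals: list[float]
    cmp_intervals: list[float]
    sum_abs_diff: float
    sum_total: float
    ratio: float
    skipped_intervals: int = 0


def invert_matrix(matrix: MarkerMatrix, suffix: str = "_r") -> MarkerMatrix:
    """Phase-inverted copy of the segregation matrix (see
    :meth:`MarkerMatrix.invert`)."""
    return matrix.invert(suffix=suffix)


def _span_fraction(positions: Sequence[float], lg: LinkageGroup) -> float:
    if lg.length == 0.0:
        return 1.0
    return (max(positions) - min(positions)) / lg.length


def detect_repulsion(
    matrix: MarkerMatrix,
    gmap: GeneticMap,
    lod_min: float = 5.0,
    min_support: int = 3,
    min_span_frac: float = 0.3,
    min_informative: int = 30,
) -> list[RepulsionLink]:
    """Repulsion links between linkage groups.

    Two-point analysis is run between every mapped marker and the
    phase-inverted copy of every marker on a different LG; marker pairs
    reaching LOD >= ``lod_min`` are aggregated per LG pair.  A link is
    accepted when at least ``min_support`` marker pairs agree and the
    involved markers span at least ``min_span_frac`` of each LG's
    length.  All candidate links (accepted or not) are returned, sorted
    by LG pair.
    """
    lg_of = gmap.lg_of()
    mapped = [m for m in matrix.marker_ids if m in lg_of]
    calls = matrix.calls.loc[mapped]
    X = calls.to_numpy(dtype=float)
    V = (~np.isnan(X)).astype(float)
    P = np.where(np.isnan(X), 0.0, X)
    A = V - P
    n = V @ V.T
    # discordance with the INVERTED partner = concordance with the original
    concord = P @ P.T + A @ A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, np.minimum(concord / np.maximum(n, 1), 0.5), 0.5)
        lod = np.where(
            (rf > 0) & (rf < 0.5),
            concord * np.log10(np.where(rf > 0, rf, 1.0))
            + (n - concord) * np.log10(np.where(rf < 1, 1.0 - rf, 1.0))
            + n * np.log10(2.0),
            0.0,
        )
    lod = np.where((rf == 0.0) & (n > 0), n * np.log10(2.0), lod)

    by_lg: dict[str, LinkageGroup] = {g.name: g for g in gmap.groups}
    pair_support: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    iu, ju = np.nonzero(np.triu((lod >= lod_min) & (n >= min_informative), k=1))
    for i, j in zip(iu, ju):
        a, b = mapped[int(i)], mapped[int(j)]
        la, lb = lg_of[a], lg_of[b]
        if la == lb:
            continue
        if lb < la:
            la, lb, a, b = lb, la, b, a
        pair_support.setdefault((la, lb), []).append((a, b, float(lod[i, j])))

    links = []
    for (la, lb), hits in sorted(pair_support.items()):
        ga, gb = by_lg[la], by_lg[lb]
        pos_a = [ga.position_of(a) for a, _, _ in hits]
        pos_b = [gb.position_of(b) for _, b, _ in hits]
        span_a = _span_fraction(pos_a, ga)
        span_b = _span_fraction(pos_b, gb)
        best = max(l for _, _, l in hits)
        accepted = (
            len(hits) >= min_support
            and span_a >= min_span_frac
            and span_b >= min_span_frac
        )
        links.append(
            RepulsionLink(
                lg_a=la,
                lg_b=lb,
                best_lod=best,
                support=[(a, b) for a, b, _ in hits],
                span_frac_a=span_a,
                span_frac_b=span_b,
                accepted=accepted,
            )
        )
    return links


def _shared_families(
    lg: LinkageGroup, families: Mapping[str, str]
) -> dict[str, float]:
    """family -> position for families with exactly one allele on the LG."""
    hits: dict[str, list[float]] = {}
    for m, p in zip(lg.markers, lg.positions):
        fam = families.get(m)
        if fam:
            hits.setdefault(fam, []).append(float(p))
    return {f: ps[0] for f, ps in hits.items() if len(ps) == 1}


def difference_ratio(
    reference: LinkageGroup,
    compared: LinkageGroup,
    families: Mapping[str, str],
    hg: str = "",
) -> Optional[DifferenceRatioRecord]:
    """Difference ratio between two homologous LGs.

    Shared markers are locus families with exactly one mapped allele on
    each LG (homologous LGs never share a single-dose marker itself);
    intervals run between consecutive shared markers in the reference
    order.  The compared LG is flipped if its shared markers run
    backwards overall; intervals whose order conflicts on the compared
    LG after that are skipped and counted.  Returns None when fewer
    than two shared markers remain.
    """
    ref_fams = _shared_families(reference, families)
    cmp_fams = _shared_families(compared, families)
    shared = sorted(set(ref_fams) & set(cmp_fams), key=lambda f: ref_fams[f])
    if len(shared) < 2:
        return None

    ref_pos = np.array([ref_fams[f] for f in shared])
    cmp_pos = np.array([cmp_fams[f] for f in shared])
    # overall orientation of the compared LG relative to the reference
    if np.sum(np.sign(np.diff(cmp_pos))) < 0:
        cmp_pos = -cmp_pos

    ref_iv, cmp_iv, skipped = [], [], 0
    for k in range(len(shared) - 1):
        d_ref = ref_pos[k + 1] - ref_pos[k]
        d_cmp = cmp_pos[k + 1] - cmp_pos[k]
        if d_cmp < 0:  # order conflict on the compared LG
            skipped += 1
            continue
        ref_iv.append(float(d_ref))
        cmp_iv.append(float(d_cmp))
    if not ref_iv:
        return None

    sum_abs = float(sum(abs(a - b) for a, b in zip(ref_iv, cmp_iv)))
    sum_total = float(sum(ref_iv) + sum(cmp_iv))
    ratio = 0.0 if sum_total == 0.0 else sum_abs / sum_total
    return DifferenceRatioRecord(
        hg=hg,
        reference_lg=reference.name,
        compared_lg=compared.name,
        k=len(ref_iv),
        ref_intervals=ref_iv,
        cmp_intervals=cmp_iv,
        sum_abs_diff=sum_abs,
        sum_total=sum_total,
        ratio=ratio,
        skipped_intervals=skipped,
    )


def hg_difference_ratios(
    hg_members: Mapping[str, Sequence[str]],
    gmap: GeneticMap,
    families: Mapping[str, str],
) -> list[DifferenceRatioRecord]:
    """Difference ratios of every LG in each HG against the HG's most
    densely mapped LG (most markers; ties by name)."""
    by_name = {g.name: g for g in gmap.groups}
    records = []
    for hg, members in sorted(hg_members.items(), key=lambda kv: str(kv[0])):
        lgs = [by_name[m] for m in members]
        ref = sorted(lgs, key=lambda g: (-g.n_markers, g.name))[0]
        for lg in lgs:
            if lg.name == ref.name:
                continue
            rec = difference_ratio(ref, lg, families, hg=str(hg))
            if rec is not None:
                records.append(rec)
    return records


def pairing_summary(
    links: Sequence[RepulsionLink],
    ratios: Sequence[DifferenceRatioRecord],
    hg_of_lg: Mapping[str, int | str],
    hg_members: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-HG pairing table and the cross-HG association.

    For each HG: number of member LGs, number and percentage involved
    in accepted repulsion links (both LGs within the HG), and the mean
    difference ratio.  Across HGs with both statistics, the coefficient
    of determination R^2 of a least-squares line of repulsion
    percentage on mean ratio is returned (None with fewer than 3 HGs).
    """
    in_rep: dict[str, set[str]] = {str(h): set() for h in hg_members}
    for link in links:
        if not link.accepted:
            continue
        ha, hb = hg_of_lg.get(link.lg_a), hg_of_lg.get(link.lg_b)
        if ha is not None and ha == hb:
            in_rep[str(ha)].update((link.lg_a, link.lg_b))

    mean_ratio: dict[str, float] = {}
    for hg in hg_members:
        vals = [r.ratio for r in ratios if r.hg == str(hg)]
        if vals:
            mean_ratio[str(hg)] = float(np.mean(vals))

    rows = []
    for hg, members in sorted(hg_members.items(), key=lambda kv: str(kv[0])):
        n_lg = len(members)
        n_rep = len(in_rep[str(hg)])
        rows.append(
            {
                "hg": str(hg),
                "n_lg": n_lg,
                "n_lg_repulsion": n_rep,
                "pct_repulsion": round(100.0 * n_rep / n_lg, 1) if n_lg else 0.0,
                "mean_difference_ratio": round(mean_ratio.get(str(hg), np.nan), 2),
            }
        )
    table = pd.DataFrame(rows).set_index("hg")

    complete = table.dropna(subset=["mean_difference_ratio"])
    r2 = None
    if len(complete) >= 3:
        x = complete["mean_difference_ratio"].to_numpy(dtype=float)
        y = complete["pct_repulsion"].to_numpy(dtype=float)
        coeffs, *_ = np.linalg.lstsq(np.column_stack([x, np.ones_like(x)]), y, rcond=None)
        fitted = coeffs[0] * x + coeffs[1]
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return table, r2
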