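"""Homology-group assembly from multi-allelic anchor loci.

In an autopolyploid each basic chromosome is represented by many
linkage groups (one per homologue, or part of one).  Single-dose
markers are private to one homologue, so LGs are tied into homology
groups (HGs) through multi-allelic locus families: an SSR/SNP/RFLP
source locus whose distinct alleles map to different LGs anchors those
LGs to the same basic chromosome.  Two LGs are joined when they share
at least ``min_shared`` distinct anchor families, and HGs are the
connected components of the resulting LG graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .linkage import GeneticMap, LinkageGroup

__all__ = [
    "AnchorFamilies",
    "HomologyGroup",
    "anchor_families",
    "assemble_hgs",
    "hg_summary",
    "multilocus_rate",
    "cluster_fraction",
]


@dataclass
class AnchorFamilies:
    """Locus families split into informative anchors and the rest.

    ``anchors`` maps family id -> set of LGs carrying a mapped allele
    (>= 2 distinct LGs); ``uninformative`` lists families with fewer.
    """

    anchors: dict[str, set[str]]
    uninformative: list[str]

    @property
    def n_families(self) -> int:
        return len(self.anchors) + len(self.uninformative)


@dataclass
class HomologyGroup:
    id: int
    members: list[str]  # LG names
    #: anchor families supporting the group: family -> member LGs hit
    evidence: dict[str, set[str]] = field(default_factory=dict)
    #: LGs whose removal disconnects the group (flagged for review)
    articulation_lgs: list[str] = field(default_factory=list)


def anchor_families(
    metadata: pd.DataFrame, lg_of: Mapping[str, str]
) -> AnchorFamilies:
    """Collect multi-allelic locus families over mapped markers.

    ``metadata`` must carry a ``locus_family`` column (empty string or
    NaN = not part of a family); ``lg_of`` maps mapped marker -> LG.
    Families whose mapped alleles hit >= 2 distinct LGs are anchors;
    families with a single mapped allele or a single LG are
    uninformative.
    """
    if "locus_family" not in metadata:
        raise ValueError("metadata lacks a locus_family column")
    fams: dict[str, set[str]] = {}
    for marker, fam in metadata["locus_family"].items():
        if fam is None or (isinstance(fam, float) and np.isnan(fam)) or fam == "":
            continue
        lg = lg_of.get(marker)
        if lg is None:
            continue
        fams.setdefault(str(fam), set()).add(lg)
    anchors = {f: lgs for f, lgs in fams.items() if len(lgs) >= 2}
    uninformative = sorted(f for f, lgs in fams.items() if len(lgs) < 2)
    return AnchorFamilies(anchors=anchors, uninformative=uninformative)


def assemble_hgs(
    lg_names: Sequence[str],
    anchors: AnchorFamilies | Mapping[str, set[str]],
    min_shared: int = 2,
) -> tuple[list[HomologyGroup], list[str]]:
    """Assemble LGs into homology groups.

    An edge joins two LGs when they share >= ``min_shared`` distinct
    anchor families; HGs are connected components with >= 2 LGs,
    numbered 1..k by decreasing size (ties by first LG name).
    Components held together by a single articulation LG are flagged on
    the HomologyGroup for user review.  Returns (HGs, unassigned LGs).
    """
    fam_lgs = anchors.anchors if isinstance(anchors, AnchorFamilies) else dict(anchors)
    known = set(lg_names)
    for fam, lgs in fam_lgs.items():
        unknown = lgs - known
        if unknown:
            raise ValueError(f"anchor family {fam!r} references unknown LG {sorted(unknown)[0]!r}")

    shared: dict[tuple[str, str], set[str]] = {}
    for fam, lgs in fam_lgs.items():
        members = sorted(lgs)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                shared.setdefault((members[i], members[j]), set()).add(fam)

    g = nx.Graph()
    g.add_nodes_from(lg_names)
    for (a, b), fams in shared.items():
        if len(fams) >= min_shared:
            g.add_edge(a, b)

    comps = [sorted(c) for c in nx.connected_components(g)]
    assigned = [c for c in comps if len(c) >= 2]
    unassigned = sorted(c[0] for c in comps if len(c) == 1)
    assigned.sort(key=lambda c: (-len(c), c[0]))

    hgs = []
    for i, members in enumerate(assigned, start=1):
        mset = set(members)
        evidence = {
            f: lgs & mset for f, lgs in fam_lgs.items() if len(lgs & mset) >= 2
        }
        arts = sorted(nx.articulation_points(g.subgraph(members)))
        hgs.append(
            HomologyGroup(
                id=i, members=members, evidence=evidence, articulation_lgs=arts
            )
        )
    return hgs, unassigned


def hg_summary(
    hgs: Sequence[HomologyGroup],
    gmap: GeneticMap,
    unassigned: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-HG totals: LG count, marker count, summed length, density.

    Density is length / marker count, rounded to 1 decimal at report
    time only.  A final ``Total`` row aggregates every listed LG.
    """
    by_name = {g.name: g for g in gmap.groups}
    rows = []

    def _row(label: str, members: Sequence[str]) -> dict:
        lgs = [by_name[m] for m in members]
        if not lgs:
            raise ValueError(f"HG {label}: no member LGs")
        n_markers = sum(g.n_markers for g in lgs)
        length = sum(g.length for g in lgs)
        return {
            "hg": label,
            "n_lg": len(lgs),
            "n_markers": n_markers,
            "length_cm": round(length, 1),
            "density_cm": round(length / n_markers, 1),
        }

    for hg in hgs:
        rows.append(_row(str(hg.id), hg.members))
    if unassigned:
        rows.append(_row("Unassigned", list(unassigned)))
    all_members = [m for hg in hgs for m in hg.members] + list(unassigned)
    rows.append(_row("Total", all_members))
    return pd.DataFrame(rows).set_index("hg")


def multilocus_rate(
    anchors: AnchorFamilies,
    hg_of_lg: Mapping[str, int | str],
) -> tuple[int, int, float]:
    """Families whose alleles hit more than one homology group.

    Counts every family (anchors plus uninformative ones) as the
    denominator and returns (n_multi_hg, n_families, fraction).
    Unassigned LGs do not contribute a HG.
    """
    n_multi = 0
    for fam, lgs in anchors.anchors.items():
        hgs = {hg_of_lg[lg] for lg in lgs if lg in hg_of_lg}
        if len(hgs) >= 2:
            n_multi += 1
    total = anchors.n_families
    return n_multi, total, (n_multi / total if total else 0.0)


def cluster_fraction(
    gmap: GeneticMap,
    window: float = 10.0,
    min_markers: int = 5,
    system_of: Optional[Mapping[str, str]] = None,
    system: Optional[str] = None,
) -> float:
    """Fraction of markers falling in dense clusters.

    Within each LG, markers (optionally restricted to one marker
    system) are greedily partitioned into maximal consecutive runs whose
    span is <= ``window`` cM; runs with >= ``min_markers`` markers are
    clusters.  Returns clustered markers / considered markers.
    """
    clustered = 0
    total = 0
    for lg in gmap.groups:
        if system is not None:
            if system_of is None:
                raise ValueError("system filter requires system_of mapping")
            sel = [
                (m, p)
                for m, p in zip(lg.markers, lg.positions)
                if system_of.get(m) == system
            ]
        else:
            sel = list(zip(lg.markers, lg.positions))
        if not sel:
            continue
        total += len(sel)
        pos = [p for _, p in sel]
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[start] > window:
                if i - start >= min_markers:
                    clustered += i - start
                start = i
    return clustered / total if total else 0.0
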