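"""Forward simulator of an autopolyploid pseudo-testcross.

The simulator emulates the mapping design used for highly polyploid,
vegetatively propagated crops such as sugarcane: a heterozygous
aneu-polyploid parent (the informative parent) is crossed to a second
parent that contributes no segregating alleles for the mapped markers,
and dominant presence/absence markers are scored in the F1 progeny.

The informative parent's genome is organised into homology groups (HGs),
each a set of homologous chromosomes ("homologues").  Dominant markers
sit on one (single dose, SD), two (double dose, DD) or three (triple
dose, TD) homologues of one HG.  Meiosis is polysomic: within each HG
the homologues are partitioned into bivalents — uniformly at random
under full polysomy, or preferentially within designated partner sets —
crossovers are placed on each bivalent with a Poisson count (no
interference, consistent with the Haldane map function), and one
recombinant chromatid per bivalent is transmitted to the gamete.

Under uniformly random bivalent pairing the set of transmitted
homologues is uniform over all m/2-subsets of the m homologues, so a
gamete lacks every copy of a dose-k marker with probability
C(m-k, m/2)/C(m, m/2) — e.g. 15/70 for DD and 5/70 for TD at m = 8 —
which is the classical random-chromosomal-segregation expectation.

Every simulated marker is recorded in a truth table (true dosage, HG,
homologue(s), position), so downstream dosage classification, linkage
grouping, homology-group assembly and pairing detection can be scored
against known truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import MarkerMatrix

__all__ = [
    "SimulationConfig",
    "ParentGenome",
    "Gamete",
    "SimulatedCross",
    "simulate_parent",
    "simulate_meiosis",
    "generate_population",
]

#: homologue counts per HG mirroring the LG counts observed per HG in a
#: ~110-chromosome aneu-polyploid cultivar (8 basic chromosomes).
DEFAULT_HOMOLOGUES_PER_HG = (17, 23, 20, 18, 13, 18, 16, 22)

_ENZYME_TAGS = ("PTB", "PTH", "PTP")


class ConfigError(ValueError):
    """Raised when a SimulationConfig field is invalid; names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the simulated cross.

    Attributes
    ----------
    n_homology_groups:
        Number of basic chromosomes (homology groups) of the informative
        parent.
    homologues_per_hg:
        Homologue count for each HG.  ``None`` uses
        :data:`DEFAULT_HOMOLOGUES_PER_HG` (13–23, aneuploid).  A single
        int is broadcast to every HG.
    markers_per_homologue:
        Dominant markers placed on each homologue, evenly spaced along
        the chromosome.
    chromosome_length:
        Genetic length of every homologue in centiMorgans.
    n_progeny:
        Number of F1 individuals scored.
    dosage_mix:
        Proportions of SD/DD/TD among the grid markers; must sum to 1.
    pairing_preference:
        Probability, per meiosis and HG, that bivalents form within the
        designated partner sets rather than uniformly at random.
        0 = fully polysomic, 1 = strict preferential (disomic when the
        partner sets are pairs).
    partner_sets:
        Per-HG grouping of homologue indices into preferential-pairing
        subsets; ``None`` with ``pairing_preference > 0`` defaults to
        consecutive pairs.
    missing_rate:
        Per-call probability of a missing score.
    subset_scored_fraction:
        Fraction of DArT markers scored only on a reduced progeny panel
        (the first ``subset_panel_size`` individuals); all other progeny
        are missing for those markers.
    subset_panel_size:
        Size of the reduced panel.
    anchor_families_per_hg:
        Multi-allelic locus families (SSR/SNP-like) placed per HG; each
        family puts one SD allele at a homologous position on each of
        several distinct homologues, anchoring the homologues into a HG.
    anchor_allele_range:
        Inclusive (lo, hi) range of alleles per anchor family.
    cross_hg_anchor_rate:
        Probability that an anchor family also drops one allele into a
        second, random HG (multi-locus families, as commonly seen for
        SSRs in polyploids).
    distorted_homologue_fraction:
        Fraction of homologues carrying a hidden viability locus causing
        segregation distortion of linked markers.
    distortion_strength:
        Transmission bias at the viability locus: the carrier homologue
        is transmitted there with probability 0.5 + strength.
    partner_set_divergence:
        Standard deviation (cM) of a per-partner-set shift applied to
        anchor-family positions, emulating structural divergence between
        homologue subsets inherited from different ancestral genomes
        (0 = all homologues share identical anchor positions).
    seed:
        Master seed; every operation draws from an independent child
        stream so stages are individually reproducible.
    """

    n_homology_groups: int = 8
    homologues_per_hg: Optional[Sequence[int] | int] = None
    markers_per_homologue: int = 10
    chromosome_length: float = 100.0
    n_progeny: int = 227
    dosage_mix: tuple[float, float, float] = (0.78, 0.16, 0.06)
    pairing_preference: float = 0.0
    partner_sets: Optional[Sequence[Sequence[Sequence[int]]]] = None
    missing_rate: float = 0.03
    subset_scored_fraction: float = 0.33
    subset_panel_size: int = 94
    anchor_families_per_hg: int = 10
    anchor_allele_range: tuple[int, int] = (2, 5)
    cross_hg_anchor_rate: float = 0.2
    distorted_homologue_fraction: float = 0.25
    distortion_strength: float = 0.15
    partner_set_divergence: float = 0.0
    seed: int = 0

    def resolved_homologues(self) -> list[int]:
        h = self.homologues_per_hg
        if h is None:
            base = DEFAULT_HOMOLOGUES_PER_HG
            return [base[i % len(base)] for i in range(self.n_homology_groups)]
        if isinstance(h, (int, np.integer)):
            return [int(h)] * self.n_homology_groups
        h = [int(x) for x in h]
        if len(h) != self.n_homology_groups:
            raise ConfigError(
                "homologues_per_hg: expected "
                f"{self.n_homology_groups} entries, got {len(h)}"
            )
        return h

    def validate(self) -> None:
        if self.n_homology_groups < 1:
            raise ConfigError("n_homology_groups: must be >= 1")
        for hg, n in enumerate(self.resolved_homologues()):
            if n < 2:
                raise ConfigError(f"homologues_per_hg: HG{hg + 1} has {n} (< 2)")
        if self.markers_per_homologue < 0:
            raise ConfigError("markers_per_homologue: must be >= 0")
        if self.chromosome_length <= 0:
            raise ConfigError("chromosome_length: must be > 0")
        if self.n_progeny < 1:
            raise ConfigError("n_progeny: must be >= 1")
        if len(self.dosage_mix) != 3 or any(p < 0 for p in self.dosage_mix):
            raise ConfigError("dosage_mix: three non-negative proportions required")
        if not math.isclose(sum(self.dosage_mix), 1.0, abs_tol=1e-9):
            raise ConfigError("dosage_mix: proportions must sum to 1")
        for name in (
            "pairing_preference",
            "missing_rate",
            "subset_scored_fraction",
            "cross_hg_anchor_rate",
            "distorted_homologue_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        if not 0.0 <= self.distortion_strength < 0.5:
            raise ConfigError("distortion_strength: must be in [0, 0.5)")
        if self.partner_set_divergence < 0:
            raise ConfigError("partner_set_divergence: must be >= 0")
        if self.partner_sets is not None:
            homs = self.resolved_homologues()
            if len(self.partner_sets) != self.n_homology_groups:
                raise ConfigError("partner_sets: one grouping per HG required")
            for hg, sets in enumerate(self.partner_sets):
                flat = [h for s in sets for h in s]
                if sorted(flat) != list(range(homs[hg])):
                    raise ConfigError(
                        f"partner_sets: HG{hg + 1} sets must partition "
                        f"homologues 0..{homs[hg] - 1}"
                    )

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for a named operation."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class _Allele:
    """One marker copy on one homologue (a marker has 1–3 alleles)."""

    marker: str
    hg: int  # 0-based
    homologue: int
    position: float


@dataclass
class _MarkerDef:
    marker: str
    hg: int
    homologues: tuple[int, ...]
    position: float
    dosage: int
    system: str
    enzyme: str
    family: str  # "" when not part of a multi-allelic locus family


@dataclass
class ParentGenome:
    """The informative parent: homologue structure plus marker placements."""

    config: SimulationConfig
    n_homologues: list[int]
    markers: list[_MarkerDef]
    #: per HG, list of (homologue, locus position) viability loci
    distorted: list[list[tuple[int, float]]]
    #: per HG, partner sets actually used for preferential pairing
    partner_sets: list[list[list[int]]]

    def __post_init__(self) -> None:
        self.marker_ids = [m.marker for m in self.markers]
        self._col = {m: i for i, m in enumerate(self.marker_ids)}
        # flattened allele arrays per HG for the vectorised meiosis core
        self._alleles: list[dict[str, np.ndarray]] = []
        for hg in range(len(self.n_homologues)):
            homs, pos, cols = [], [], []
            for m in self.markers:
                if m.hg != hg:
                    continue
                for h in m.homologues:
                    homs.append(h)
                    pos.append(m.position)
                    cols.append(self._col[m.marker])
            self._alleles.append(
                {
                    "hom": np.asarray(homs, dtype=np.int64),
                    "pos": np.asarray(pos, dtype=float),
                    "col": np.asarray(cols, dtype=np.int64),
                }
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def truth_table(self) -> pd.DataFrame:
        """Ground truth per marker: dosage, HG, homologues, position."""
        rows = [
            {
                "marker": m.marker,
                "dosage": m.dosage,
                "hg": m.hg + 1,
                "homologues": ";".join(str(h) for h in m.homologues),
                "position_cm": m.position,
                "system": m.system,
                "locus_family": m.family,
            }
            for m in self.markers
        ]
        return pd.DataFrame(rows).set_index("marker")


@dataclass
class Gamete:
    """One simulated gamete: marker presence plus the bivalent pairing used."""

    presence: np.ndarray  # bool, aligned with parent.marker_ids
    pairing: list[list[tuple[int, int]]]  # per HG, homologue index pairs


@dataclass
class SimulatedCross:
    """A simulated mapping population with its ground truth."""

    matrix: MarkerMatrix
    truth: pd.DataFrame
    parent: ParentGenome
    config: SimulationConfig


def simulate_parent(config: SimulationConfig) -> ParentGenome:
    """Build the informative parent's genome.

    Grid markers are evenly spaced along each homologue and assigned a
    dosage class from ``config.dosage_mix``: SD markers sit on exactly
    one homologue, DD on two and TD on three homologues of the same HG,
    all at the same position.  Anchor families add SD alleles (shared
    locus family id) at one homologous position on several distinct
    homologues, occasionally spilling one allele into a second HG.
    """
    config.validate()
    rng = config.rng("parent")
    homs = config.resolved_homologues()
    L = config.chromosome_length

    if config.partner_sets is not None:
        psets = [[list(s) for s in sets] for sets in config.partner_sets]
    else:
        psets = [
            [[a, a + 1] for a in range(0, n - 1, 2)] + ([[n - 1]] if n % 2 else [])
            for n in homs
        ]
    set_of = [
        {h: si for si, s in enumerate(sets) for h in s} for sets in psets
    ]

    markers: list[_MarkerDef] = []
    dart_counter = 0
    aflp_counter = 0

    n_grid = config.markers_per_homologue
    if n_grid == 1:
        grid = np.array([L / 2.0])
    else:
        grid = np.linspace(0.0, L, n_grid) if n_grid else np.array([])

    for hg in range(config.n_homology_groups):
        for h in range(homs[hg]):
            for gi, x in enumerate(grid):
                u = rng.random()
                if u < config.dosage_mix[0]:
                    dosage = 1
                elif u < config.dosage_mix[0] + config.dosage_mix[1]:
                    dosage = 2
                else:
                    dosage = 3
                dosage = min(dosage, homs[hg])
                extra: list[int] = []
                if dosage > 1:
                    others = [o for o in range(homs[hg]) if o != h]
                    extra = sorted(
                        rng.choice(others, size=dosage - 1, replace=False).tolist()
                    )
                # two thirds DArT (enzyme-tagged), one third AFLP
                if (gi + h) % 3 < 2:
                    dart_counter += 1
                    enzyme = _ENZYME_TAGS[dart_counter % 3]
                    name = f"c{dart_counter:05d}{enzyme}"
                    system = "DArT"
                else:
                    aflp_counter += 1
                    name = f"aflp{aflp_counter:04d}"
                    system, enzyme = "AFLP", "none"
                markers.append(
                    _MarkerDef(
                        marker=name,
                        hg=hg,
                        homologues=tuple(sorted([h] + extra)),
                        position=float(x),
                        dosage=dosage,
                        system=system,
                        enzyme=enzyme,
                        family="",
                    )
                )

    # multi-allelic anchor families
    fam_counter = 0
    lo, hi = config.anchor_allele_range
    anchor_coverage = [np.zeros(n, dtype=int) for n in homs]
    for hg in range(config.n_homology_groups):
        for _ in range(config.anchor_families_per_hg):
            fam_counter += 1
            fam = f"SSR{fam_counter:03d}"
            system = "SSR" if fam_counter % 4 else "SNP"
            n_alleles = int(rng.integers(lo, min(hi, homs[hg]) + 1))
            # spread families over homologues: least-anchored first, so
            # every homologue accumulates anchor evidence
            cov = anchor_coverage[hg]
            order = rng.permutation(homs[hg])
            order = order[np.argsort(cov[order], kind="stable")]
            carriers = sorted(int(h) for h in order[:n_alleles])
            cov[carriers] += 1
            x = float(rng.uniform(0.0, L))
            # structural divergence between partner sets: each set sees
            # the family at a set-specific shifted position
            set_shift: dict[int, float] = {}
            if config.partner_set_divergence > 0:
                for si in range(len(psets[hg])):
                    set_shift[si] = float(
                        rng.normal(0.0, config.partner_set_divergence)
                    )
            allele_no = 0
            for h in carriers:
                allele_no += 1
                shift = set_shift.get(set_of[hg].get(h, -1), 0.0)
                markers.append(
                    _MarkerDef(
                        marker=f"{fam.lower()}_{allele_no}",
                        hg=hg,
                        homologues=(h,),
                        position=float(np.clip(x + shift, 0.0, L)),
                        dosage=1,
                        system=system,
                        enzyme="none",
                        family=fam,
                    )
                )
            if (
                config.n_homology_groups > 1
                and rng.random() < config.cross_hg_anchor_rate
            ):
                other = int(rng.choice([g for g in range(config.n_homology_groups) if g != hg]))
                allele_no += 1
                markers.append(
                    _MarkerDef(
                        marker=f"{fam.lower()}_{allele_no}",
                        hg=other,
                        homologues=(int(rng.integers(homs[other])),),
                        position=float(rng.uniform(0.0, L)),
                        dosage=1,
                        system=system,
                        enzyme="none",
                        family=fam,
                    )
                )

    distorted: list[list[tuple[int, float]]] = []
    for hg in range(config.n_homology_groups):
        loci = []
        for h in range(homs[hg]):
            if rng.random() < config.distorted_homologue_fraction:
                loci.append((h, float(rng.uniform(0.0, L))))
        distorted.append(loci)

    return ParentGenome(
        config=config,
        n_homologues=homs,
        markers=markers,
        distorted=distorted,
        partner_sets=psets,
    )


def _pair_within_sets(sets: list[list[int]], n_prog: int, rng) -> np.ndarray:
    """Permutations that keep partner-set members adjacent (P x H)."""
    blocks = []
    for s in sets:
        arr = np.tile(np.asarray(s, dtype=np.int64), (n_prog, 1))
        blocks.append(rng.permuted(arr, axis=1))
    return np.concatenate(blocks, axis=1)


def _simulate_hg_gametes(
    parent: ParentGenome, hg: int, n_prog: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised meioses for one HG.

    Returns (transmitted, perm): ``transmitted`` is a boolean
    (n_prog x n_alleles) matrix over this HG's flattened allele list and
    ``perm`` the (n_prog x H) homologue permutation whose consecutive
    pairs are the bivalents (a trailing unpaired homologue, if H is odd,
    is dropped from that meiosis).
    """
    cfg = parent.config
    H = parent.n_homologues[hg]
    L = cfg.chromosome_length

    perm_rand = rng.permuted(np.tile(np.arange(H, dtype=np.int64), (n_prog, 1)), axis=1)
    if cfg.pairing_preference > 0.0:
        perm_pref = _pair_within_sets(parent.partner_sets[hg], n_prog, rng)
        pref = rng.random(n_prog) < cfg.pairing_preference
        perm = np.where(pref[:, None], perm_pref, perm_rand)
    else:
        perm = perm_rand

    n_pairs = H // 2
    paired = 2 * n_pairs
    slot = np.argsort(perm, axis=1)  # slot[p, h] = position of homologue h

    # crossover breakpoints per bivalent, padded with +inf
    counts = rng.poisson(L / 100.0, size=(n_prog, n_pairs))
    max_c = int(counts.max()) if counts.size else 0
    if max_c:
        breaks = rng.uniform(0.0, L, size=(n_prog, n_pairs, max_c))
        invalid = np.arange(max_c)[None, None, :] >= counts[:, :, None]
        breaks[invalid] = np.inf
    else:
        breaks = np.empty((n_prog, n_pairs, 0))

    start = rng.integers(0, 2, size=(n_prog, n_pairs))

    # segregation distortion: bias the transmitted strand at each
    # viability locus toward the carrier homologue
    delta = cfg.distortion_strength
    if delta > 0.0:
        for h_d, x_d in parent.distorted[hg]:
            s = slot[:, h_d]
            in_biv = s < paired
            k = np.where(in_biv, s // 2, 0)
            side = s % 2
            nb = (breaks[np.arange(n_prog), k, :] < x_d).sum(axis=1)
            want = (side - nb) % 2  # start making h_d transmitted at x_d
            take = rng.random(n_prog) < 0.5 + delta
            biased = np.where(take, want, 1 - want)
            start[np.arange(n_prog), k] = np.where(
                in_biv, biased, start[np.arange(n_prog), k]
            )

    al = parent._alleles[hg]
    n_alleles = al["hom"].size
    transmitted = np.zeros((n_prog, n_alleles), dtype=bool)
    rows = np.arange(n_prog)
    for a in range(n_alleles):
        h, x = al["hom"][a], al["pos"][a]
        s = slot[:, h]
        in_biv = s < paired
        k = np.where(in_biv, s // 2, 0)
        side = s % 2
        nb = (breaks[rows, k, :] < x).sum(axis=1)
        transmitted[:, a] = in_biv & (((start[rows, k] + nb) % 2) == side)
    return transmitted, perm


def _population_presence(
    parent: ParentGenome, n_prog: int, rng: np.random.Generator
) -> np.ndarray:
    presence = np.zeros((n_prog, parent.n_markers), dtype=bool)
    for hg in range(len(parent.n_homologues)):
        transmitted, _ = _simulate_hg_gametes(parent, hg, n_prog, rng)
        cols = parent._alleles[hg]["col"]
        for a in range(cols.size):
            presence[:, cols[a]] |= transmitted[:, a]
    return presence


def simulate_meiosis(
    parent: ParentGenome, config: SimulationConfig | None = None, seed: int | None = None
) -> Gamete:
    """Simulate one gamete of the informative parent.

    Within each HG, homologues are partitioned into bivalents (random or
    preferential per the config), crossovers placed with Poisson count
    ``length/100`` and uniform positions, and one chromatid per bivalent
    transmitted.  With an odd homologue count, one unpaired homologue is
    dropped at random from that meiosis.
    """
    config = config or parent.config
    rng = np.random.default_rng(seed) if seed is not None else config.rng("meiosis")
    presence = np.zeros(parent.n_markers, dtype=bool)
    pairing: list[list[tuple[int, int]]] = []
    for hg in range(len(parent.n_homologues)):
        transmitted, perm = _simulate_hg_gametes(parent, hg, 1, rng)
        cols = parent._alleles[hg]["col"]
        for a in range(cols.size):
            if transmitted[0, a]:
                presence[cols[a]] = True
        n_pairs = parent.n_homologues[hg] // 2
        pairing.append(
            [(int(perm[0, 2 * k]), int(perm[0, 2 * k + 1])) for k in range(n_pairs)]
        )
    return Gamete(presence=presence, pairing=pairing)


def generate_population(config: SimulationConfig) -> SimulatedCross:
    """Simulate the full mapping population.

    One gamete per progeny is drawn from the informative parent; the
    second parent contributes no segregating alleles, so a progeny shows
    a dominant marker iff its gamete carries at least one copy.  A
    configured fraction of DArT markers is scored only on the reduced
    progeny panel (the first ``subset_panel_size`` individuals), and
    random missingness is added on top.
    """
    config.validate()
    parent = simulate_parent(config)
    rng = config.rng("population")
    n = config.n_progeny

    presence = _population_presence(parent, n, rng)
    calls = presence.astype(float).T  # markers x progeny

    meta = parent.truth_table().copy()
    enzymes = {m.marker: m.enzyme for m in parent.markers}

    # panel restriction: a fraction of DArT markers scored on 94 progeny
    dart_idx = [i for i, m in enumerate(parent.markers) if m.system == "DArT"]
    panel_restricted = np.zeros(parent.n_markers, dtype=bool)
    if dart_idx and config.subset_scored_fraction > 0 and config.subset_panel_size < n:
        k = int(round(config.subset_scored_fraction * len(dart_idx)))
        chosen = rng.choice(dart_idx, size=k, replace=False)
        panel_restricted[chosen] = True
        calls[np.ix_(chosen, np.arange(config.subset_panel_size, n))] = np.nan

    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = np.nan

    progeny = [f"P{i + 1:03d}" for i in range(n)]
    calls_df = pd.DataFrame(
        calls, index=pd.Index(parent.marker_ids, name="marker"), columns=progeny
    )

    quality = rng.uniform(81.0, 100.0, size=parent.n_markers).round(1)
    n_assayed = np.where(panel_restricted, config.subset_panel_size, n)
    metadata = pd.DataFrame(
        {
            "system": meta["system"].to_numpy(),
            "enzyme": [enzymes[m] for m in parent.marker_ids],
            "locus_family": meta["locus_family"].to_numpy(),
            "quality": quality,
            "panel_restricted": panel_restricted,
            "n_assayed": n_assayed,
        },
        index=pd.Index(parent.marker_ids, name="marker"),
    )
    matrix = MarkerMatrix(calls=calls_df, metadata=metadata)

    truth = parent.truth_table()
    truth["panel_restricted"] = panel_restricted
    return SimulatedCross(matrix=matrix, truth=truth, parent=parent, config=config)
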