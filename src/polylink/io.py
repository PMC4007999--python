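"""File formats: genotype CSV, metadata/map/report TSVs, JoinMap .loc,
and the pipeline configuration."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .linkage import GeneticMap, LinkageGroup
from .matrix import MarkerMatrix

__all__ = [
    "PipelineConfig",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "write_loc",
    "read_loc",
]


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    Every threshold that drives a stage is a field here with the
    published value as its default; nothing is hard-coded downstream.
    """

    genotypes: Optional[str] = None
    metadata: Optional[str] = None
    outdir: str = "polylink_out"
    ploidy: int = 8
    alpha: float = 0.05
    q_min: float = 80.0
    call_rate_min: float = 0.8
    duplicate_min_overlap: int = 50
    lod_min: float = 10.0
    rf_max: float = 0.35
    framework_min_scored: int = 188
    min_informative: int = 30
    min_shared_anchors: int = 2
    repulsion_lod_min: float = 5.0
    repulsion_min_support: int = 3
    repulsion_min_span_frac: float = 0.3
    cluster_window_cm: float = 10.0
    cluster_min_markers: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.ploidy % 2 or self.ploidy < 4:
            raise ValueError(f"ploidy must be even and >= 4, got {self.ploidy}")
        if not 0.0 < self.rf_max <= 0.5:
            raise ValueError(f"rf_max must be in (0, 0.5], got {self.rf_max}")
        if self.lod_min < 0 or self.repulsion_lod_min < 0:
            raise ValueError("LOD thresholds must be >= 0")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")
        if not 0.0 <= self.repulsion_min_span_frac <= 1.0:
            raise ValueError("repulsion_min_span_frac must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def write_genotypes(
    matrix: MarkerMatrix, calls_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write calls as CSV (1/0/NA) and metadata as TSV."""
    out = matrix.calls.copy()
    out.index.name = "marker"
    # integers where scored, NA where missing
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.replace("", "NA").to_csv(calls_path)
    if metadata_path is not None:
        if matrix.metadata is None:
            raise ValueError("matrix has no metadata to write")
        meta = matrix.metadata.copy()
        meta.index.name = "marker"
        meta.to_csv(metadata_path, sep="\t")


def read_genotypes(
    calls_path: str | Path, metadata_path: str | Path | None = None
) -> MarkerMatrix:
    calls = pd.read_csv(calls_path, index_col=0, na_values=["NA"], dtype=str)
    if calls.empty:
        raise ValueError(f"genotype file {calls_path} contains no markers")

    def _parse(v, marker, progeny):
        if pd.isna(v):
            return np.nan
        if v in ("0", "1"):
            return float(v)
        raise ValueError(
            f"genotype file {calls_path}: marker {marker!r}, progeny "
            f"{progeny!r}: bad call {v!r}"
        )

    parsed = pd.DataFrame(
        {c: [_parse(v, m, c) for m, v in calls[c].items()] for c in calls.columns},
        index=calls.index,
    )
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0, keep_default_na=False)
        if "quality" in meta:
            meta["quality"] = pd.to_numeric(meta["quality"], errors="coerce")
    return MarkerMatrix(calls=parsed, metadata=meta)


def write_map(gmap: GeneticMap, path: str | Path, system_of=None) -> None:
    df = gmap.to_frame()
    df["position_cm"] = df["position_cm"].astype(float).round(3)
    if system_of is not None:
        df["system"] = [system_of.get(m, "") for m in df["marker"]]
    df.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"lg": str})
    groups = []
    for lg, sub in df.groupby("lg", sort=True):
        pos = sub["position_cm"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            row = sub.index[np.argmin(np.diff(pos) >= 0) + 1]
            raise ValueError(f"map file {path}: non-monotone positions in LG {lg} (line {row + 2})")
        hg = None
        if "hg" in sub and sub["hg"].notna().any():
            hg = sub["hg"].iloc[0]
        groups.append(
            LinkageGroup(name=str(lg), markers=sub["marker"].tolist(), positions=pos, hg=hg)
        )
    return GeneticMap(groups=groups)


def write_loc(
    matrix: MarkerMatrix, path: str | Path, name: str = "polylink"
) -> None:
    """Write a JoinMap-style .loc file for a CP (cross-pollinator)
    population: dominant one-parent markers coded <lmxll>, calls
    ``lm`` (present) / ``ll`` (absent) / ``--`` (missing)."""
    lines = [
        f"name = {name}",
        "popt = CP",
        f"nloc = {matrix.n_markers}",
        f"nind = {matrix.n_progeny}",
        "",
    ]
    code = {1.0: "lm", 0.0: "ll"}
    for m in matrix.marker_ids:
        calls = matrix.calls.loc[m]
        tokens = [code.get(v, "--") if pd.notna(v) else "--" for v in calls]
        lines.append(f"{m} <lmxll>\t" + " ".join(tokens))
    Path(path).write_text("\n".join(lines) + "\n")


def read_loc(path: str | Path) -> MarkerMatrix:
    """Read the .loc dialect written by :func:`write_loc`."""
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    for ln, line in enumerate(text, start=1):
        line = line.strip()
        if not line:
            continue
        if "=" in line and not line.split()[0].startswith("<") and len(rows) == 0 and "<" not in line:
            k, _, v = line.partition("=")
            header[k.strip()] = v.strip()
            continue
        try:
            name, rest = line.split("<lmxll>")
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln}: malformed row") from exc
        decode = {"lm": 1.0, "ll": 0.0, "--": np.nan}
        try:
            rows[name.strip()] = [decode[t] for t in rest.split()]
        except KeyError as exc:
            raise ValueError(f"{path}: line {ln}: bad call {exc.args[0]!r}") from exc
    if header.get("popt") != "CP":
        raise ValueError(f"{path}: expected popt = CP")
    n_ind = int(header.get("nind", 0))
    progeny = [f"P{i + 1:03d}" for i in range(n_ind)]
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=progeny)
    return MarkerMatrix(calls=calls)
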