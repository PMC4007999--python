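"""The markers x progeny presence/absence matrix and its metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["MarkerMatrix", "MARKER_SYSTEMS"]

MARKER_SYSTEMS = ("DArT", "AFLP", "SSR", "SNP", "RFLP", "RAPD")


@dataclass
class MarkerMatrix:
    """Dominant marker calls for a mapping population.

    ``calls`` is a markers x progeny DataFrame with values 1.0 (present),
    0.0 (absent) and NaN (missing).  ``metadata`` is indexed by marker id
    and may carry: system, enzyme, locus_family, quality, plus anything
    a stage wants to pass along.  Call rate and scored counts are always
    derived from ``calls``, never trusted from input.
    """

    calls: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        vals = self.calls.to_numpy(dtype=float, copy=False)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"call for marker {self.calls.index[r]!r}, progeny "
                f"{self.calls.columns[c]!r} is {vals[r, c]!r}; expected 1/0/NA"
            )
        if self.metadata is not None:
            missing = self.calls.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(
                    f"metadata missing for markers: {missing[:5].tolist()}"
                )
            self.metadata = self.metadata.loc[self.calls.index]

    @property
    def marker_ids(self) -> list[str]:
        return self.calls.index.tolist()

    @property
    def progeny_ids(self) -> list[str]:
        return self.calls.columns.tolist()

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_progeny(self) -> int:
        return self.calls.shape[1]

    def n_scored(self) -> pd.Series:
        """Non-missing calls per marker."""
        return self.calls.notna().sum(axis=1)

    def call_rate(self) -> pd.Series:
        return self.n_scored() / self.n_progeny

    def counts(self) -> pd.DataFrame:
        """Per-marker n_present / n_absent / n_missing."""
        present = (self.calls == 1.0).sum(axis=1)
        absent = (self.calls == 0.0).sum(axis=1)
        missing = self.calls.isna().sum(axis=1)
        return pd.DataFrame(
            {"n_present": present, "n_absent": absent, "n_missing": missing}
        )

    def subset(self, markers) -> "MarkerMatrix":
        calls = self.calls.loc[markers]
        meta = self.metadata.loc[markers] if self.metadata is not None else None
        return MarkerMatrix(calls=calls, metadata=meta)

    def invert(self, suffix: str = "_r") -> "MarkerMatrix":
        """Phase-inverted copy: present <-> absent, missing preserved.

        Marker ids gain ``suffix`` to mark the reversed phase.  Applying
        the inversion twice restores the original calls.
        """
        calls = 1.0 - self.calls
        calls.index = [f"{m}{suffix}" for m in self.calls.index]
        meta = None
        if self.metadata is not None:
            meta = self.metadata.copy()
            meta.index = calls.index
        return MarkerMatrix(calls=calls, metadata=meta)
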