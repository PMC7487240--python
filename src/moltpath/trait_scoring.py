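"""Region-wise molt/dichromatism score matrices and ordinal life-history codes.

Each species is scored per feather region on a three-level scale: 1 = the
region is completely replaced (molt channel) or completely dichromatic
(dichromatism channel), 0.5 = partial replacement/dichromatism or
intraspecific variation, 0 = absent.  Two derived variables drive most of the
downstream analyses: *extent* (the row sum of region scores, half scores
counting 0.5) and *presence* (1 if any region scores above zero).  The region
list is data, not code: the default canonical order runs head to alula along
the stereotyped succession in which regions join the molt, but any ordered
list may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_REGIONS",
    "RegionScoreMatrix",
    "OrdinalCodes",
    "extent",
    "presence",
    "presence_by_region",
    "succession_index",
    "consistency_diagnostic",
]

CANONICAL_REGIONS = [
    "head", "breast", "belly", "back", "tertials",
    "median_coverts", "greater_coverts", "rump", "tail", "remiges", "alula",
]

_VALID_SCORES = {0.0, 0.5, 1.0}

_ORDINAL_RANGES = {
    "habitat": (0, 6),     # 0 = tall deciduous forest ... 6 = open habitat
    "stratum": (0, 4),     # 0 = ground or near ground ... 4 = canopy/edge/open
    "nest_type": (0, 2),   # 0 = cavity; 1 = dome/closed; 2 = open cup
}


@dataclass
class RegionScoreMatrix:
    """Species x feather-region scores for one channel (molt or dichromatism)."""

    scores: pd.DataFrame    # index = species, columns = regions, values in {0, .5, 1}
    channel: str            # "molt" or "dichromatism"

    def __post_init__(self):
        if self.channel not in ("molt", "dichromatism"):
            raise ValueError(f"unknown channel {self.channel!r}")
        vals = set(np.unique(self.scores.to_numpy(dtype=float)))
        bad = vals - _VALID_SCORES
        if bad:
            raise ValueError(f"scores must be in {{0, 0.5, 1}}; found {sorted(bad)}")

    @property
    def species(self) -> list:
        return list(self.scores.index)

    @property
    def regions(self) -> list:
        return list(self.scores.columns)

    # -- I/O ----------------------------------------------------------------
    _PREFIX = {"molt": "pa", "dichromatism": "sd"}

    def to_frame(self) -> pd.DataFrame:
        """Wide table with ``<prefix>_<region>`` columns plus derived
        ``*_extent`` and ``*_presence``."""
        pre = self._PREFIX[self.channel]
        out = self.scores.add_prefix(f"{pre}_")
        out[f"{pre}_extent"] = extent(self)
        out[f"{pre}_presence"] = presence(self)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channel: str,
                   regions: list | None = None) -> "RegionScoreMatrix":
        pre = cls._PREFIX[channel]
        cols = [c for c in df.columns
                if c.startswith(f"{pre}_") and c not in (f"{pre}_extent", f"{pre}_presence")]
        scores = df[cols].rename(columns=lambda c: c[len(pre) + 1:])
        if regions is not None:
            scores = scores[regions]
        return cls(scores.astype(float), channel)


def extent(matrix: RegionScoreMatrix, round_halves: bool = False) -> pd.Series:
    """Per-species molt/dichromatism extent: row sum of region scores.

    ``round_halves=True`` rounds each 0.5 up to 1 before summing (an
    alternative integer-counting convention); the default keeps half scores
    as halves.
    """
    s = matrix.scores
    if round_halves:
        s = np.ceil(s)
    return s.sum(axis=1)


def presence(matrix: RegionScoreMatrix) -> pd.Series:
    """1 iff any region scores above zero (partial scores count as present)."""
    return (matrix.scores > 0).any(axis=1).astype(int)


def presence_by_region(matrix: RegionScoreMatrix) -> pd.DataFrame:
    return (matrix.scores > 0).astype(int)


def succession_index(matrix: RegionScoreMatrix, order: list | None = None) -> dict:
    """Does each species' replaced-region set form a prefix of the canonical
    succession order?

    Returns per-species booleans and the per-region inclusion frequency across
    species (the family-level gradient: on succession-obeying data the
    frequencies are monotone non-increasing along the order).
    """
    order = list(order) if order is not None else CANONICAL_REGIONS
    missing = [r for r in matrix.regions if r not in order]
    if missing:
        raise ValueError(f"regions not in supplied order: {missing}")
    order = [r for r in order if r in matrix.regions]
    inc = presence_by_region(matrix)[order]
    arr = inc.to_numpy()
    # a prefix pattern never has a 1 after the first 0
    first_zero = np.where(arr == 0, np.arange(arr.shape[1]), arr.shape[1]).min(axis=1)
    last_one = np.where(arr == 1, np.arange(arr.shape[1]), -1).max(axis=1)
    is_prefix = pd.Series(last_one < first_zero, index=matrix.species)
    freq = inc.mean(axis=0)
    return {"is_prefix": is_prefix, "region_frequency": freq}


def consistency_diagnostic(molt: RegionScoreMatrix, dichromatism: RegionScoreMatrix) -> pd.DataFrame:
    """Cells where a region is dichromatic but not molted.

    Dichromatism within a region logically requires that region to be renewed
    by the molt, but observed data may disagree (intraspecific variation,
    scoring from different sources); violations are reported, never enforced.
    """
    m = molt.scores.align(dichromatism.scores, join="inner")[0]
    d = dichromatism.scores.loc[m.index, m.columns]
    viol = (d > 0) & (molt.scores.loc[m.index, m.columns] == 0)
    rows = [(sp, rg) for sp in viol.index for rg in viol.columns if viol.at[sp, rg]]
    return pd.DataFrame(rows, columns=["species", "region"])


@dataclass
class OrdinalCodes:
    """Integer habitat / foraging-stratum / nest-type codes per species.

    Habitat (0-6) and stratum (0-4) are scored separately for the breeding
    and wintering periods; the codes order environments roughly by solar
    exposure (0 = most shaded).
    """

    table: pd.DataFrame  # columns like habitat_breeding, stratum_winter, nest_type

    def __post_init__(self):
        for col in self.table.columns:
            base = next((k for k in _ORDINAL_RANGES if col.startswith(k)), None)
            if base is None:
                raise ValueError(f"unrecognized ordinal column {col!r}")
            lo, hi = _ORDINAL_RANGES[base]
            vals = self.table[col]
            if not np.all(vals == vals.astype(int)):
                raise ValueError(f"{col}: ordinal codes must be integers")
            if vals.min() < lo or vals.max() > hi:
                raise ValueError(f"{col}: codes must lie in [{lo}, {hi}]")
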