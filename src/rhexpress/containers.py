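"""Core in-memory containers.

The pipeline operates on three kinds of objects:

``ExpressionMatrix``
    A probes x samples table of normalized log2 expression values together
    with a per-sample metadata sheet (condition, pair, subject, timepoint,
    arm) and a platform tag.  All downstream stages consume this container;
    nothing in the package touches raw array files.

``PlatformAnnotation``
    The probe -> gene map with platform membership, used to collapse
    probe-level results to unique genes and to restrict gene sets to the
    probe universe of a smaller array platform.

``GeneSetCollection``
    Named gene sets with GMT semantics (name, description, member ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError

#: canonical sample-sheet columns, in file order
SAMPLE_COLUMNS = ("condition", "pair_id", "subject_id", "timepoint", "arm")


def _require_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one float column per sample.
    samples
        DataFrame indexed by sample id with columns ``condition``,
        ``pair_id``, ``subject_id``, ``timepoint``, ``arm`` (missing
        metadata is stored as the empty string).
    platform
        Label of the array platform the probe universe belongs to.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str = "APlus2"

    def __post_init__(self) -> None:
        _require_unique(self.values.index, "probe")
        _require_unique(self.values.columns, "sample")
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")
        sheet = self.samples.copy()
        for col in SAMPLE_COLUMNS:
            if col not in sheet.columns:
                sheet[col] = ""
        sheet = sheet[list(SAMPLE_COLUMNS)].fillna("").astype(str)
        missing = [s for s in self.values.columns if s not in sheet.index]
        if missing:
            raise DataError(f"samples missing from sample sheet: {missing[:5]}")
        # keep the sheet in matrix column order
        self.samples = sheet.loc[self.values.columns]

    # -- basic geometry -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionMatrix":
        probes = pd.Index(probes)
        return ExpressionMatrix(self.values.loc[probes], self.samples, self.platform)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples], self.samples.loc[samples], self.platform
        )

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose metadata matches every ``column=value`` pair."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in conditions.items():
            if col not in self.samples.columns:
                raise InvalidParameterError(f"unknown sample-sheet column {col!r}")
            mask &= self.samples[col] == val
        return self.samples.index[mask].tolist()


@dataclass
class PlatformAnnotation:
    """Probe -> (gene, symbol, platform membership) map.

    ``table`` is indexed by probe id with columns ``gene_id``, ``symbol``
    and ``platforms`` (a frozenset of platform labels).  Every probe maps
    to exactly one gene; a gene may own many probes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.table.index, "probe")
        for col in ("gene_id", "symbol", "platforms"):
            if col not in self.table.columns:
                raise DataError(f"annotation lacks required column {col!r}")
        self.table = self.table.copy()
        self.table["platforms"] = self.table["platforms"].map(
            lambda p: frozenset(p.split(",")) if isinstance(p, str) else frozenset(p)
        )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def platform_universe(self) -> frozenset:
        out: set = set()
        for p in self.table["platforms"]:
            out |= p
        return frozenset(out)

    def gene_of(self, probe: str) -> str:
        return self.table.at[probe, "gene_id"]

    def genes_of(self, probes: Iterable[str]) -> set[str]:
        probes = list(probes)
        missing = [p for p in probes if p not in self.table.index]
        if missing:
            raise DataError(f"probes absent from annotation: {sorted(missing)[:10]}")
        return set(self.table.loc[probes, "gene_id"])

    def probes_on(self, platform: str) -> pd.Index:
        if platform not in self.platform_universe:
            raise InvalidParameterError(
                f"unknown platform {platform!r}; known: {sorted(self.platform_universe)}"
            )
        mask = self.table["platforms"].map(lambda p: platform in p)
        return self.table.index[mask]


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]  # deduplicated, first-seen order

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m, None)
        self.members = tuple(seen)
        if not self.members:
            raise DataError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls({k: GeneSet(k, "", tuple(v)) for k, v in d.items()})

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise DataError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def as_float_array(x, name: str) -> np.ndarray:
    """Coerce to a 1-D float array, rejecting NaN."""
    arr = np.asarray(x, dtype=float).ravel()
    if np.isnan(arr).any():
        raise DataError(f"{name} contains NaN")
    return arr
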