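"""Probe-to-gene collapsing, platform restriction, and Venn partitions.

An array platform measures probe-sets; several probe-sets can interrogate
one gene, so DEG counts exist at two granularities (e.g. "641 probe-sets
representing 490 unique genes").  This module collapses directional
probe-level DEG calls to unique gene sets, restricts a DEG set to the
probe universe of a smaller platform (needed when comparing against
cohorts profiled on the smaller array), and partitions 2-3 labelled gene
sets into disjoint Venn regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import PlatformAnnotation
from .exceptions import DataError, InvalidParameterError

__all__ = ["DegSet", "collapse_to_genes", "restrict_to_platform", "venn_partition"]


@dataclass
class DegSet:
    """Directional DEG membership at probe and unique-gene level.

    ``conflicts`` lists genes that are up via one probe and down via
    another; such genes stay in both directional gene sets.
    """

    label: str
    platform: str
    probes_up: frozenset = frozenset()
    probes_down: frozenset = frozenset()
    genes_up: frozenset = frozenset()
    genes_down: frozenset = frozenset()
    conflicts: frozenset = frozenset()

    def __post_init__(self) -> None:
        both = self.probes_up & self.probes_down
        if both:
            raise DataError(f"probes in both directions: {sorted(both)[:5]}")

    @property
    def probes(self) -> frozenset:
        return self.probes_up | self.probes_down

    @property
    def genes(self) -> frozenset:
        return self.genes_up | self.genes_down

    def counts(self) -> dict:
        return {
            "label": self.label,
            "n_probes_up": len(self.probes_up),
            "n_probes_down": len(self.probes_down),
            "n_probes": len(self.probes),
            "n_genes_up": len(self.genes_up),
            "n_genes_down": len(self.genes_down),
            "n_genes": len(self.genes),
            "n_conflicts": len(self.conflicts),
        }


def collapse_to_genes(
    degs: pd.DataFrame,
    annotation: PlatformAnnotation,
    label: str = "",
    platform: str = "",
) -> DegSet:
    """Collapse a DEG table (indexed by probe, with ``is_deg`` and
    ``direction`` columns) to probe and unique-gene sets per direction.

    A gene is up-regulated iff at least one of its probes is an up-DEG
    (likewise down); genes hit in both directions are kept in both sets
    and reported in ``conflicts``.
    """
    flagged = (
        degs.loc[degs["is_deg"].astype(bool)] if "is_deg" in degs.columns else degs
    )
    probes_up = frozenset(flagged.index[flagged["direction"] == "up"])
    probes_down = frozenset(flagged.index[flagged["direction"] == "down"])
    missing = (probes_up | probes_down) - set(annotation.probe_ids)
    if missing:
        raise DataError(
            f"DEG probes absent from annotation: {sorted(missing)[:10]}"
        )
    genes_up = frozenset(annotation.genes_of(probes_up)) if probes_up else frozenset()
    genes_down = (
        frozenset(annotation.genes_of(probes_down)) if probes_down else frozenset()
    )
    return DegSet(
        label=label,
        platform=platform,
        probes_up=probes_up,
        probes_down=probes_down,
        genes_up=genes_up,
        genes_down=genes_down,
        conflicts=genes_up & genes_down,
    )


def restrict_to_platform(
    s: DegSet, platform: str, annotation: PlatformAnnotation
) -> tuple[DegSet, int]:
    """Drop probes absent from ``platform``'s universe and recompute the
    gene sets from the survivors.  Returns (restricted set, number of
    probes excluded)."""
    on_platform = set(annotation.probes_on(platform))
    probes_up = frozenset(s.probes_up & on_platform)
    probes_down = frozenset(s.probes_down & on_platform)
    n_excluded = len(s.probes) - len(probes_up) - len(probes_down)
    genes_up = frozenset(annotation.genes_of(probes_up)) if probes_up else frozenset()
    genes_down = (
        frozenset(annotation.genes_of(probes_down)) if probes_down else frozenset()
    )
    restricted = DegSet(
        label=s.label,
        platform=platform,
        probes_up=probes_up,
        probes_down=probes_down,
        genes_up=genes_up,
        genes_down=genes_down,
        conflicts=genes_up & genes_down,
    )
    return restricted, n_excluded


def venn_partition(sets: list[tuple[str, set]]) -> dict[tuple[str, ...], int]:
    """Disjoint region counts for 2 or 3 labelled sets.

    Keys are tuples of the labels a region belongs to (sorted in input
    label order); every non-empty membership signature appears, regions
    are disjoint, and counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise InvalidParameterError("venn_partition needs 2 or 3 sets")
    labels = [lbl for lbl, _ in sets]
    if len(set(labels)) != len(labels):
        raise InvalidParameterError("set labels must be unique")
    members = {lbl: set(s) for lbl, s in sets}
    universe = set().union(*members.values())
    regions: dict[tuple[str, ...], int] = {}
    k = len(labels)
    for signature in range(1, 2**k):
        in_labels = [labels[i] for i in range(k) if signature >> i & 1]
        out_labels = [labels[i] for i in range(k) if not signature >> i & 1]
        region = set(universe)
        for lbl in in_labels:
            region &= members[lbl]
        for lbl in out_labels:
            region -= members[lbl]
        regions[tuple(in_labels)] = len(region)
    assert sum(regions.values()) == len(universe)
    return regions
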