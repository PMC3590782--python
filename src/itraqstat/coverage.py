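"""Proteome-coverage set comparisons and immunodepletion arithmetic.

Pure set/arithmetic operations: overlap of an identified-protein list
with a reference database (e.g. a published nonredundant plasma protein
list), the seven-region Venn decomposition of three workflow-replicate
identification lists, and percent depletion of high-abundance proteins
from before/after abundance tables.

Comparisons are literal accession-string matches; no identifier mapping
(UniProt/IPI/gene symbol) is attempted, so the caller must ensure both
lists share a namespace.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .tables_io import ProteinList

logger = logging.getLogger(__name__)


@dataclass
class CoverageResult:
    """Overlap between an identified set and a reference list."""

    n_identified: int
    n_reference: int
    n_shared: int
    n_novel: int
    shared: set[str] = field(default_factory=set)
    novel: set[str] = field(default_factory=set)


def compare_to_reference(
    identified: ProteinList, reference: ProteinList
) -> CoverageResult:
    """Exact set intersection/difference counts against a reference list."""
    shared = identified.accessions & reference.accessions
    novel = identified.accessions - reference.accessions
    logger.info(
        "coverage: %d identified vs %d reference -> %d shared, %d novel "
        "(literal accession match, no ID mapping)",
        len(identified),
        len(reference),
        len(shared),
        len(novel),
    )
    return CoverageResult(
        n_identified=len(identified),
        n_reference=len(reference),
        n_shared=len(shared),
        n_novel=len(novel),
        shared=shared,
        novel=novel,
    )


@dataclass
class VennCounts:
    """Region counts of a 3-set Venn diagram.

    ``regions`` maps a membership pattern - a tuple of 0/1 flags in the
    order of ``labels`` - to the number of elements with exactly that
    pattern; e.g. ``(1, 1, 1)`` is the center, ``(1, 0, 0)`` the part
    unique to the first set.  Region counts sum to the union size.
    """

    labels: tuple
    regions: dict[tuple, int]
    n_union: int

    @property
    def center(self) -> int:
        return self.regions[(1,) * len(self.labels)]


def replicate_venn(sets_by_label: dict) -> VennCounts:
    """Exclusive region counts for the Venn diagram of (up to 3) sets.

    ``sets_by_label`` maps a replicate label to its identified-protein
    set; labels are kept in sorted order.
    """
    labels = tuple(sorted(sets_by_label))
    if not 2 <= len(labels) <= 3:
        raise ValueError("replicate_venn expects 2 or 3 sets")
    sets = [set(sets_by_label[lbl]) for lbl in labels]
    union = set().union(*sets)
    regions = {}
    for pattern in itertools.product((0, 1), repeat=len(labels)):
        if not any(pattern):
            continue
        members = union.copy()
        for flag, s in zip(pattern, sets):
            members &= s if flag else (union - s)
        regions[pattern] = len(members)
    assert sum(regions.values()) == len(union)
    return VennCounts(labels=labels, regions=regions, n_union=len(union))


def depletion_efficiency(
    before: dict, after: dict
) -> tuple[dict[str, float], float]:
    """Percent depletion per protein and the mean over evaluated proteins.

    ``%depletion = 100 * (1 - after/before)``; proteins absent from
    ``after`` are treated as fully depleted (after = 0).  Units cancel,
    so any non-negative abundance proxy (peak area, spectral counts)
    works.
    """
    if not before:
        raise ValueError("no proteins to evaluate")
    per_protein = {}
    for pid, b in before.items():
        if b <= 0:
            raise ValueError(f"before-abundance of {pid!r} must be > 0")
        a = after.get(pid, 0.0)
        if a < 0:
            raise ValueError(f"after-abundance of {pid!r} must be >= 0")
        per_protein[pid] = 100.0 * (1.0 - a / b)
    mean = sum(per_protein.values()) / len(per_protein)
    logger.info(
        "depletion: mean %.1f%% over %d proteins", mean, len(per_protein)
    )
    return per_protein, mean
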