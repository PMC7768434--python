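"""Maximal-biclique ("concept") enumeration for the bipartite interview network.

A biclique is a pair (code set, interviewee set), both non-empty, such that
every cross pair is a link; it is maximal when no node from either partition
can be added without breaking completeness.  Maximal bicliques of a bipartite
graph coincide with the formal concepts of its incidence relation (those with
two non-empty sides), so enumeration here walks the concept lattice with the
NextClosure algorithm over the smaller partition, using bitmask closures.
This is exhaustive and exact; output size is worst-case exponential, so a
configurable cap guards runaway instances.

Canonical output order: descending number of codes, then descending number of
interviewees, then lexicographic on the sorted code ids — deterministic for
golden-file comparisons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Collection, Iterator, Sequence

from .coding_data import IncidenceMatrix
from .errors import CapacityError, ValidationError

__all__ = [
    "Biclique",
    "BicliqueSummary",
    "enumerate_maximal_bicliques",
    "summarize_bicliques",
    "bicliques_containing",
]

DEFAULT_MAX_BICLIQUES = 10**6


@dataclass(frozen=True)
class Biclique:
    code_set: frozenset[str]
    interviewee_set: frozenset[str]

    @property
    def size(self) -> tuple[int, int]:
        return (len(self.code_set), len(self.interviewee_set))

    def sort_key(self) -> tuple:
        return (
            -len(self.code_set),
            -len(self.interviewee_set),
            tuple(sorted(self.code_set)),
        )


@dataclass(frozen=True)
class BicliqueSummary:
    """Frequency of each (num_codes, num_interviewees) size pair."""

    frequency: dict[tuple[int, int], int]

    @property
    def total(self) -> int:
        return sum(self.frequency.values())


def _bit_indices(mask: int) -> Iterator[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _concepts(obj_masks: list[int], n_attr: int, cap: int) -> Iterator[tuple[int, int]]:
    """Yield (object_mask, attribute_mask) for every formal concept.

    Objects are the rows of the relation handed in; each object's mask marks
    the attributes it is related to.  NextClosure walks closed attribute sets
    in lectic order.
    """
    full = (1 << n_attr) - 1
    lower = [(1 << i) - 1 for i in range(n_attr + 1)]

    def close(attr_set: int) -> tuple[int, int]:
        objs = 0
        common = full
        for o, m in enumerate(obj_masks):
            if m & attr_set == attr_set:
                objs |= 1 << o
                common &= m
        if objs == 0:
            common = full
        return objs, common

    count = 0
    objs, attrs = close(0)
    while True:
        count += 1
        if count > cap:
            raise CapacityError(
                f"maximal biclique count exceeded the cap of {cap}; "
                "raise max_bicliques to proceed"
            )
        yield objs, attrs
        if attrs == full:
            return
        A = attrs
        found = False
        for i in range(n_attr - 1, -1, -1):
            bit = 1 << i
            if A & bit:
                A &= ~bit
            else:
                cand_objs, cand_attrs = close((A & lower[i]) | bit)
                if cand_attrs & lower[i] == A & lower[i]:
                    objs, attrs = cand_objs, cand_attrs
                    found = True
                    break
        if not found:  # pragma: no cover - full set is always reachable
            return


def enumerate_maximal_bicliques(
    incidence: IncidenceMatrix,
    min_codes: int = 1,
    min_interviewees: int = 1,
    max_bicliques: int = DEFAULT_MAX_BICLIQUES,
) -> list[Biclique]:
    """Enumerate every maximal biclique meeting the size thresholds.

    An incidence with no links yields an empty list.  Raises
    :class:`CapacityError` if more than ``max_bicliques`` concepts arise.
    """
    if min_codes < 1 or min_interviewees < 1:
        raise ValidationError("minimum biclique side sizes must be >= 1")
    M, N = incidence.M, incidence.N
    codes = incidence.code_index
    ivs = incidence.interviewee_index
    # run NextClosure over the smaller partition as the attribute side
    if N <= M:
        obj_masks = [
            sum(1 << j for j in range(N) if incidence.B[i, j]) for i in range(M)
        ]
        out: list[Biclique] = []
        for obj_mask, attr_mask in _concepts(obj_masks, N, max_bicliques):
            if obj_mask and attr_mask:
                bc = Biclique(
                    code_set=frozenset(codes[i] for i in _bit_indices(obj_mask)),
                    interviewee_set=frozenset(ivs[j] for j in _bit_indices(attr_mask)),
                )
                if len(bc.code_set) >= min_codes and len(bc.interviewee_set) >= min_interviewees:
                    out.append(bc)
    else:
        obj_masks = [
            sum(1 << i for i in range(M) if incidence.B[i, j]) for j in range(N)
        ]
        out = []
        for obj_mask, attr_mask in _concepts(obj_masks, M, max_bicliques):
            if obj_mask and attr_mask:
                bc = Biclique(
                    code_set=frozenset(codes[i] for i in _bit_indices(attr_mask)),
                    interviewee_set=frozenset(ivs[j] for j in _bit_indices(obj_mask)),
                )
                if len(bc.code_set) >= min_codes and len(bc.interviewee_set) >= min_interviewees:
                    out.append(bc)
    out.sort(key=Biclique.sort_key)
    return out


def summarize_bicliques(bicliques: Sequence[Biclique]) -> BicliqueSummary:
    """Frequency table keyed by (|code_set|, |interviewee_set|)."""
    freq = Counter(bc.size for bc in bicliques)
    return BicliqueSummary(frequency=dict(sorted(freq.items())))


def bicliques_containing(
    bicliques: Sequence[Biclique],
    node_id: str,
    valid_ids: Collection[str] | None = None,
) -> list[Biclique]:
    """Sublist of bicliques containing ``node_id`` in either partition.

    If ``valid_ids`` is supplied, an id outside it is rejected; a valid id
    appearing in no biclique simply yields an empty list.
    """
    if valid_ids is not None and node_id not in valid_ids:
        raise ValidationError(f"unknown node id {node_id!r}")
    return [
        bc for bc in bicliques if node_id in bc.code_set or node_id in bc.interviewee_set
    ]
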