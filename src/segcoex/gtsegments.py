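"""Enumeration, scoring and selection of GTSegments.

A *GTSegment* is a contiguous arc of the (circular) gene order containing
at least 2 and at most 50 elements whose two extremities are connected by a
path lying entirely inside the arc's induced co-expression subgraph. Its
*reachable set* R(S) is the connected component of that induced subgraph
containing both extremities, and its *density*

    d(S) = |R(S)| / |S|

measures the fraction of the arc's members behaving co-ordinately; arcs
with d >= 0.6 are treated as good transcription-unit candidates. Among
candidates, segment B *dominates* A when R(A) is a proper-or-equal subset
of R(B) and d(A) < d(B) (strict); the reported *dominant* segments are
those dominated by none. Overlapping dominant segments are retained as
distinct objects; :func:`unique_regions` collapses them by transitive
member overlap when a per-locus view is wanted.
"""

from __future__ import annotations

from collections import Counter, defaultdict, deque
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datatypes import GenomeLayout, ReferenceOperons
from .errors import DataError

DEFAULT_MIN_LEN = 2
DEFAULT_MAX_LEN = 50
DEFAULT_DENSITY_MIN = 0.6


@dataclass(frozen=True)
class GTSegment:
    """A contiguous arc with its reachable set and density.

    ``start`` indexes the arc's first member in the element order the
    segment was enumerated over (genes-only order by default).
    """

    start: int
    member_ids: tuple[str, ...]
    reachable: frozenset[str]
    density: float

    def __post_init__(self) -> None:
        k = len(self.member_ids)
        if k < 2:
            raise DataError("a GTSegment has at least 2 members")
        if not self.reachable:
            raise DataError("a GTSegment has a non-empty reachable set")
        for ext in (self.member_ids[0], self.member_ids[-1]):
            if ext not in self.reachable:
                raise DataError(f"extremity {ext!r} not in reachable set")
        if abs(self.density - len(self.reachable) / k) > 1e-12:
            raise DataError("density must equal |R(S)| / |S|")

    @property
    def length(self) -> int:
        return len(self.member_ids)

    @property
    def extremities(self) -> tuple[str, str]:
        return self.member_ids[0], self.member_ids[-1]


def reachable_set(members: tuple[str, ...], network: nx.Graph) -> frozenset[str]:
    """R(S) for an arc: the induced-subgraph component holding both extremities.

    Returns the empty set when the extremities are not mutually connected
    inside the arc (the arc is then not a valid segment). Since validity
    requires an extremity-to-extremity path, the component containing one
    extremity contains both; this equivalence with the per-extremity
    reachability definition is exercised by the test suite.
    """
    if len(members) < 2:
        raise DataError("an arc has at least 2 members")
    member_set = set(members)
    first, last = members[0], members[-1]
    adj = network.adj
    comp = {first}
    queue = deque([first])
    while queue:
        u = queue.popleft()
        if u not in adj:
            continue
        for v in adj[u]:
            if v in member_set and v not in comp:
                comp.add(v)
                queue.append(v)
    if last not in comp:
        return frozenset()
    return frozenset(comp)


def density(segment: GTSegment) -> float:
    """d(S) = |R(S)| / |S|."""
    return len(segment.reachable) / segment.length


def enumerate_segments(
    layout: GenomeLayout,
    network: nx.Graph,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    genes_only: bool = True,
) -> list[GTSegment]:
    """All valid GTSegments of the layout, sorted by (start index, length).

    On circular layouts arcs wrap past the origin and the arc length is
    additionally capped at #elements - 1 (the degenerate whole-genome arc
    is excluded); on linear layouts arcs do not wrap.
    """
    order = layout.ordered_ids(genes_only=genes_only)
    n = len(order)
    if n == 0:
        return []
    if layout.circular:
        hi = min(max_len, n - 1)
    else:
        hi = min(max_len, n)
    lo = max(min_len, 2)
    segments: list[GTSegment] = []
    doubled = order + order  # simple wrap indexing
    for start in range(n):
        for k in range(lo, hi + 1):
            if not layout.circular and start + k > n:
                break
            members = tuple(doubled[start:start + k])
            reach = reachable_set(members, network)
            if reach:
                segments.append(GTSegment(
                    start=start,
                    member_ids=members,
                    reachable=reach,
                    density=len(reach) / k,
                ))
    segments.sort(key=lambda s: (s.start, s.length))
    return segments


def dominates(b: GTSegment, a: GTSegment) -> bool:
    """True when B dominates A: R(A) subset of R(B) and d(A) < d(B) (strict)."""
    return a.density < b.density and a.reachable <= b.reachable


def dominant_segments(
    segments: list[GTSegment],
    density_min: float = DEFAULT_DENSITY_MIN,
    apply_density_filter: bool = True,
    dominance_first: bool = False,
) -> list[GTSegment]:
    """Select segments not dominated by any other segment.

    By default the density filter defines the candidate set *before*
    dominance is evaluated (candidates and reported segments both satisfy
    d >= density_min). With ``dominance_first`` dominance is evaluated
    among all enumerated segments and the density filter applied to the
    survivors, for sensitivity analysis.
    """
    if apply_density_filter and not dominance_first:
        candidates = [s for s in segments if s.density >= density_min]
    else:
        candidates = list(segments)

    # R(A) subset of R(B) requires sharing members: index candidates by
    # reachable-set membership and only test those sharing an element.
    by_member: dict[str, list[GTSegment]] = defaultdict(list)
    for s in candidates:
        for m in s.reachable:
            by_member[m].append(s)

    dominant = []
    for a in candidates:
        probe = min(a.reachable)
        if not any(dominates(b, a) for b in by_member[probe] if b is not a):
            dominant.append(a)

    if apply_density_filter and dominance_first:
        dominant = [s for s in dominant if s.density >= density_min]
    dominant.sort(key=lambda s: (s.start, s.length))
    return dominant


def classify_strandedness(segment: GTSegment, layout: GenomeLayout) -> str:
    """``same_direction`` when all gene members share a strand, else ``mixed``.

    Intergenic members are excluded from the vote.
    """
    strands = {
        layout.by_id(m).strand
        for m in segment.member_ids
        if layout.by_id(m).kind == "gene"
    }
    if not strands:
        raise DataError("segment has no gene members to classify")
    return "same_direction" if len(strands) == 1 else "mixed"


MATCH_CATEGORIES = ("exact", "contained_in_operon", "contains_operon", "overlap", "none")


def compare_to_reference(
    segments: list[GTSegment],
    reference: ReferenceOperons,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Classify each segment against a reference operon annotation.

    Categories (by member id sets, best match wins, one row per segment):
    ``exact`` (equal to an operon), ``contained_in_operon`` (proper subset),
    ``contains_operon`` (proper superset), ``overlap`` (intersects one or
    more operons), ``none``.
    """
    operon_sets = [frozenset(o) for o in reference.operons]
    if layout is not None:
        known = set(layout.ids)
        for seg in segments:
            unknown = [m for m in seg.member_ids if m not in known]
            if unknown:
                raise DataError(f"segment member(s) not in layout: {unknown}")
        for oset in operon_sets:
            unknown = sorted(oset - known)
            if unknown:
                raise DataError(f"operon member(s) not in layout: {unknown}")
    rows = []
    for seg in segments:
        mset = frozenset(seg.member_ids)
        category = "none"
        for oset in operon_sets:
            if mset == oset:
                category = "exact"
                break
            if mset < oset:
                category = "contained_in_operon"
            elif mset > oset and category not in ("contained_in_operon",):
                category = "contains_operon"
            elif mset & oset and category == "none":
                category = "overlap"
        rows.append({
            "members": ",".join(seg.member_ids),
            "length": seg.length,
            "density": seg.density,
            "category": category,
        })
    table = pd.DataFrame(rows, columns=["members", "length", "density", "category"])
    return table


def match_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts per match category (all categories present, zero-filled)."""
    counts = Counter(table["category"]) if len(table) else Counter()
    return {c: int(counts.get(c, 0)) for c in MATCH_CATEGORIES}


def unique_regions(segments: list[GTSegment]) -> list[frozenset[str]]:
    """Collapse segments into unique regions by transitive member overlap."""
    parent = list(range(len(segments)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_member: dict[str, int] = {}
    for i, s in enumerate(segments):
        for m in s.member_ids:
            if m in by_member:
                ri, rj = find(i), find(by_member[m])
                if ri != rj:
                    parent[ri] = rj
            else:
                by_member[m] = i
    groups: dict[int, set[str]] = defaultdict(set)
    for i, s in enumerate(segments):
        groups[find(i)].update(s.member_ids)
    return [frozenset(g) for g in groups.values()]
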