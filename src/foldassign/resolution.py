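"""Domain layout resolution and chopping.

Candidate domain hits on a protein usually conflict: HMM matches from
different families overlap, and discontinuous domains interleave. The
resolver picks the score-maximal subset of hits in which no two selected
hits share more than a small tolerance of residues — the "best possible
combination of domains for optimal coverage" semantics of hit-resolution
tools. The optimum is exact (branch-and-bound over the pairwise conflict
graph, which also handles discontinuous hits correctly via their residue
sets rather than bounding intervals).

Chopping extracts a resolved region from the model that contains it. For
long proteins predicted as overlapping sliding-window fragments, the
region must sit entirely inside one fragment; among several candidates the
fragment whose centre is nearest the region centre is used, because window
edges carry degraded prediction confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_io import DomainHit, FragmentSet, StructureModel

__all__ = [
    "DomainRegion",
    "ResolvedLayout",
    "UnchoppableError",
    "resolve_hits",
    "choose_fragment",
    "chop",
    "MIN_DOMAIN_SIZE",
]

#: Minimum length of a domain-sized region, the classical classification cut.
MIN_DOMAIN_SIZE = 40


class UnchoppableError(ValueError):
    """No single fragment contains the whole region."""


@dataclass
class DomainRegion:
    """A candidate or confirmed domain region on one protein."""

    protein_id: str
    segments: list[tuple[int, int]]
    source: str = "NewFam"
    candidate_superfamily: str = ""
    confidence: float | None = None

    def __post_init__(self) -> None:
        for (a, b) in self.segments:
            if a > b:
                raise ValueError(f"segment start {a} > stop {b}")
        for (_, b1), (a2, _) in zip(self.segments, self.segments[1:]):
            if a2 <= b1:
                raise ValueError("segments overlap or are unsorted")

    @classmethod
    def from_hit(cls, hit: DomainHit) -> "DomainRegion":
        sf = hit.family_id if hit.source in ("CATH-PDB", "CATH-HMM") else ""
        return cls(hit.protein_id, list(hit.segments), hit.source, sf)

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def stop(self) -> int:
        return self.segments[-1][1]

    @property
    def is_domain_sized(self) -> bool:
        return self.n_residues >= MIN_DOMAIN_SIZE

    @property
    def domain_id(self) -> str:
        segs = "_".join(f"{a}-{b}" for a, b in self.segments)
        return f"{self.protein_id}_{segs}"

    def residue_indices(self) -> list[int]:
        return [i for a, b in self.segments for i in range(a, b + 1)]


@dataclass
class ResolvedLayout:
    """Outcome of hit resolution for one protein."""

    protein_id: str
    selected: list[DomainHit]
    rejected: list[tuple[DomainHit, str]] = field(default_factory=list)
    coverage: float = 0.0


def _hit_sort_key(hit: DomainHit):
    # deterministic preference: higher score, then longer, then lower start
    return (-hit.score, -hit.n_residues, hit.start, hit.family_id)


def resolve_hits(hits: list[DomainHit], overlap_tolerance: int = 10,
                 protein_length: int | None = None) -> ResolvedLayout:
    """Score-maximal set of hits with pairwise overlap <= ``overlap_tolerance``.

    Exact optimum by branch-and-bound over hits in canonical order (score
    desc, length desc, start asc); a new subset replaces the incumbent only
    on strictly larger total score, so ties resolve to the canonical-first
    subset and the result is deterministic. Discontinuous hits conflict via
    their actual residue sets, so nested domains are never wrongly blocked
    by a bounding interval.
    """
    if not hits:
        return ResolvedLayout("", [], [], 0.0)
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    if any(h.score < 0 for h in hits):
        raise ValueError("hit scores must be non-negative")
    order = sorted(hits, key=_hit_sort_key)
    n = len(order)
    residue_sets = [h.residue_set() for h in order]
    conflict = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if len(residue_sets[i] & residue_sets[j]) > overlap_tolerance:
                conflict[i][j] = conflict[j][i] = True
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + order[i].score

    best_subset: list[int] = []
    best_score = -1.0

    def search(i: int, chosen: list[int], score: float) -> None:
        nonlocal best_subset, best_score
        if score + suffix[i] <= best_score:
            return
        if i == n:
            if score > best_score:
                best_score = score
                best_subset = chosen[:]
            return
        if all(not conflict[i][j] for j in chosen):
            chosen.append(i)
            search(i + 1, chosen, score + order[i].score)
            chosen.pop()
        search(i + 1, chosen, score)

    search(0, [], 0.0)
    selected_idx = set(best_subset)
    selected = [order[i] for i in sorted(best_subset)]
    rejected = []
    for i in range(n):
        if i in selected_idx:
            continue
        clash = next((j for j in sorted(best_subset) if conflict[i][j]), None)
        reason = ("conflicts with selected hit "
                  f"{order[clash].family_id or 'NewFam'}@{order[clash].start}-"
                  f"{order[clash].stop}" if clash is not None
                  else "excluded by score-maximal selection")
        rejected.append((order[i], reason))
    covered = set().union(*(order[i].residue_set() for i in best_subset)) \
        if best_subset else set()
    if protein_length is None:
        protein_length = max((h.stop for h in hits), default=0)
    coverage = len(covered) / protein_length if protein_length else 0.0
    return ResolvedLayout(order[0].protein_id, selected, rejected, coverage)


def choose_fragment(region: DomainRegion, fragset: FragmentSet) -> int:
    """Index of the fragment that fully contains the region.

    Among several containing fragments the one whose centre is closest to
    the region centre wins (ties: lower index). Raises
    :class:`UnchoppableError` when no fragment contains the whole region.
    """
    candidates = [
        (idx, first, last) for idx, first, last in fragset.fragments
        if first <= region.start and region.stop <= last
    ]
    if not candidates:
        raise UnchoppableError(
            f"{region.domain_id}: region {region.start}-{region.stop} fits no "
            f"fragment of {fragset.protein_id} "
            f"(scheme {fragset.fragment_length}/{fragset.step})")
    centre = (region.start + region.stop) / 2.0
    best = min(candidates,
               key=lambda f: (abs((f[1] + f[2]) / 2.0 - centre), f[0]))
    return best[0]


def chop(model: StructureModel, region: DomainRegion) -> StructureModel:
    """Sub-model restricted to the region's segments.

    Residue numbering and pLDDT are carried over unchanged; a missing
    residue raises ``KeyError`` listing the absent indices.
    """
    return model.subset(region.residue_indices())
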