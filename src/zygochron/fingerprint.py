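"""Stage 2: resolve commingled, disarticulated vertebrae into individuals.

Isolated vertebrae become nodes of a per-lot compatibility graph.  Two
vertebrae are compatible — i.e., could derive from one individual — when
their combined line counts differ by at most an age margin (default one
year, the intra-column variation observed in extant snakes), their
centrum lengths sit within a k·sigma size envelope (sigma expressed as a
coefficient of variation of the pair mean), and optionally their spacing
patterns are sufficiently similar.

A candidate assignment of vertebrae to individuals is a partition of the
nodes into cliques (every within-individual pair must be compatible) that
is *coarsest*: no two individuals could be merged into one.  The spread of
block counts over all such admissible partitions yields the minimum and
maximum number of individuals, and per-record candidate labels reproduce
the "2, 3"-style ambiguity entries of the published fossil table.
"""

from __future__ import annotations

import itertools
import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from sympy.utilities.iterables import multiset_partitions

from .records import (
    CompatibilityParams,
    SizeCapError,
    VertebraRecord,
    combined_count,
)
from .profiling import SpacingPattern, spacing_similarity

logger = logging.getLogger(__name__)

Partition = tuple[frozenset[str], ...]

DEFAULT_MAX_EXACT = 16


def compatible(u: VertebraRecord, v: VertebraRecord,
               params: CompatibilityParams = CompatibilityParams()) -> bool:
    """Could these two vertebrae come from the same individual?

    True iff (a) combined counts differ by at most ``age_margin``; (b) the
    centrum lengths, when both present, differ by at most
    ``k_sigma * (cv_percent/100) * mean(lengths)`` (a missing length
    passes or fails per ``missing_length_policy``); and (c), only when a
    ``spacing_threshold`` is configured and both records carry patterns,
    the RMS spacing dissimilarity does not exceed it.
    """
    cu, cv_ = combined_count(u), combined_count(v)
    if not (cu.scorable and cv_.scorable):
        raise ValueError("both records need a scorable combined count")
    if abs(cu.value - cv_.value) > params.age_margin:
        return False

    lu, lv = u.centrum_length_mm, v.centrum_length_mm
    if lu is None or lv is None:
        if params.missing_length_policy == "fail" and u.record_id != v.record_id:
            return False
    else:
        envelope = params.k_sigma * (params.cv_percent / 100.0) * (lu + lv) / 2.0
        if abs(lu - lv) > envelope:
            return False

    if params.spacing_threshold is not None:
        pu, pv = _pattern(u), _pattern(v)
        if pu is not None and pv is not None:
            if abs(len(pu) - len(pv)) > 1:
                return False
            if spacing_similarity(pu, pv) > params.spacing_threshold:
                return False
    return True


def _pattern(v: VertebraRecord) -> Optional[SpacingPattern]:
    for z in (v.left, v.right):
        if z.scorable and z.line_positions is not None:
            return SpacingPattern(z.line_positions)
    return None


def build_graph(records: Sequence[VertebraRecord],
                params: CompatibilityParams = CompatibilityParams(),
                per_lot: bool = True) -> nx.Graph:
    """Materialize the pairwise compatibility rule as an undirected graph.

    Nodes are record ids (sorted), annotated with count, centrum length
    and lot.  Edges join exactly the compatible pairs — within a lot by
    default, across lots when ``per_lot`` is False.  Records without a
    scorable combined count are excluded with a warning.
    """
    scorable: dict[str, VertebraRecord] = {}
    for v in sorted(records, key=lambda r: r.record_id):
        cc = combined_count(v)
        if not cc.scorable:
            logger.warning("excluding unscorable record %s (no intact zygantrum)",
                           v.record_id)
            continue
        scorable[v.record_id] = v
    g = nx.Graph()
    for rid, v in scorable.items():
        g.add_node(rid, count=combined_count(v).value,
                   centrum_length_mm=v.centrum_length_mm, lot_id=v.lot_id)
    for (ru, u), (rv, v) in itertools.combinations(scorable.items(), 2):
        if per_lot and u.lot_id != v.lot_id:
            continue
        ok = compatible(u, v, params)
        logger.debug("edge decision %s--%s: %s", ru, rv, ok)
        if ok:
            g.add_edge(ru, rv)
    return g


# ---------------------------------------------------------------------------
# Coarsest clique-partition enumeration

def _mergeable(a: frozenset, b: frozenset, adj: dict) -> bool:
    """Union of two cliques is again a clique iff all cross pairs are edges."""
    return all(y in adj[x] for x in a for y in b)


def _cliques_containing(v, candidates: frozenset, adj: dict) -> Iterable[frozenset]:
    """All cliques within ``candidates`` that contain ``v``."""
    rest = sorted(candidates & adj[v])

    def grow(clique: tuple, pool: list):
        yield frozenset(clique)
        for i, u in enumerate(pool):
            if all(u in adj[w] for w in clique):
                yield from grow(clique + (u,), pool[i + 1:])

    yield from grow((v,), rest)


def _coarsest_partitions(nodes: Iterable[str], adj: dict) -> list[Partition]:
    """Enumerate all partitions into cliques with no mergeable block pair.

    Blocks are built one at a time, each containing the smallest node not
    yet assigned; a block mergeable with an already-closed block prunes
    the branch immediately, so every surviving leaf is admissible and each
    admissible partition is generated exactly once.
    """
    out: list[Partition] = []

    def extend(remaining: frozenset, closed: tuple):
        if not remaining:
            out.append(closed)
            return
        v = min(remaining)
        for clique in _cliques_containing(v, remaining, adj):
            if any(_mergeable(clique, b, adj) for b in closed):
                continue
            extend(remaining - clique, closed + (clique,))

    extend(frozenset(nodes), ())
    return [_canonical(p) for p in out]


def _canonical(p: Iterable[frozenset]) -> Partition:
    return tuple(sorted(p, key=lambda b: sorted(b)))


def enumerate_admissible_partitions(g: nx.Graph,
                                    max_exact: int = DEFAULT_MAX_EXACT
                                    ) -> list[Partition]:
    """All coarsest clique partitions of ``g``, in deterministic order.

    Computed independently per connected component and combined by
    Cartesian product (no clique spans components).  Refuses graphs with
    more than ``max_exact`` nodes (SizeCapError): at commingled-assemblage
    scales the enumeration is instant, but it is exponential in general.
    """
    if g.number_of_nodes() > max_exact:
        raise SizeCapError(
            f"{g.number_of_nodes()} nodes exceeds the exact-enumeration cap "
            f"({max_exact}); raise max_exact or verify with "
            f"brute_force_partitions on a subset")
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    per_component = [
        _coarsest_partitions(comp, adj)
        for comp in sorted(nx.connected_components(g), key=min)
    ]
    combined = [
        _canonical(itertools.chain.from_iterable(choice))
        for choice in itertools.product(*per_component)
    ] if per_component else []
    return sorted(combined, key=lambda p: [sorted(b) for b in p])


def brute_force_partitions(g: nx.Graph, max_nodes: int = 12) -> list[Partition]:
    """Oracle: filter every set partition of the nodes by the invariants.

    Independent of the incremental enumerator — it walks all set
    partitions (via sympy) and keeps those whose blocks are cliques with
    no mergeable pair.  Exponential; capped at ``max_nodes``.
    """
    nodes = sorted(g.nodes)
    if len(nodes) > max_nodes:
        raise SizeCapError(f"{len(nodes)} nodes exceeds brute-force cap {max_nodes}")
    if not nodes:
        return []
    adj = {n: set(g.neighbors(n)) for n in g.nodes}

    def is_clique(block: Sequence[str]) -> bool:
        return all(b in adj[a] for a, b in itertools.combinations(block, 2))

    admissible = []
    for part in multiset_partitions(nodes):
        blocks = [frozenset(b) for b in part]
        if not all(is_clique(tuple(b)) for b in blocks):
            continue
        if any(_mergeable(a, b, adj)
               for a, b in itertools.combinations(blocks, 2)):
            continue
        admissible.append(_canonical(blocks))
    return sorted(admissible, key=lambda p: [sorted(b) for b in p])


# ---------------------------------------------------------------------------
# MNI estimation

@dataclass(frozen=True)
class LotResult:
    """Admissible partitions and individual-count bounds for one lot."""

    lot_id: str
    min_individuals: int
    max_individuals: int
    partitions: tuple[Partition, ...]
    ambiguity: dict[str, tuple[int, ...]]
    excluded: tuple[str, ...] = ()
    # record_id -> (combined count, centrum length or None), for reporting
    nodes: dict[str, tuple[int, Optional[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lot_id": self.lot_id,
            "min_individuals": self.min_individuals,
            "max_individuals": self.max_individuals,
            "partitions": [[sorted(b) for b in p] for p in self.partitions],
            "ambiguity": {r: list(l) for r, l in sorted(self.ambiguity.items())},
            "excluded": list(self.excluded),
            "nodes": {r: list(m) for r, m in sorted(self.nodes.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LotResult":
        return cls(
            lot_id=d["lot_id"],
            min_individuals=d["min_individuals"],
            max_individuals=d["max_individuals"],
            partitions=tuple(_canonical(frozenset(b) for b in p)
                             for p in d["partitions"]),
            ambiguity={r: tuple(l) for r, l in d["ambiguity"].items()},
            excluded=tuple(d.get("excluded", ())),
            nodes={r: (m[0], m[1]) for r, m in d.get("nodes", {}).items()},
        )


@dataclass(frozen=True)
class MNIResult:
    """Per-lot individual-count ranges and their assemblage totals."""

    lots: tuple[LotResult, ...]
    params: CompatibilityParams

    @property
    def total_min(self) -> int:
        return sum(l.min_individuals for l in self.lots)

    @property
    def total_max(self) -> int:
        return sum(l.max_individuals for l in self.lots)

    def lot(self, lot_id: str) -> LotResult:
        for l in self.lots:
            if l.lot_id == lot_id:
                return l
        raise KeyError(lot_id)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "lots": [l.to_dict() for l in self.lots],
            "totals": {"min": self.total_min, "max": self.total_max},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MNIResult":
        return cls(lots=tuple(LotResult.from_dict(l) for l in d["lots"]),
                   params=CompatibilityParams.from_dict(d["params"]))


def _node_key(g: nx.Graph, rid: str) -> tuple:
    data = g.nodes[rid]
    cl = data.get("centrum_length_mm")
    return (data["count"], cl if cl is not None else float("inf"), rid)


def _block_key(g: nx.Graph, block: frozenset) -> tuple:
    return min(_node_key(g, r) for r in block)


def _reference_labels(g: nx.Graph, partitions: Sequence[Partition]
                      ) -> dict[str, int]:
    """Label records 1..M via the canonical finest admissible partition.

    The finest partitions (maximal block count) are the most cautious
    reading of the evidence; ties between them are broken by the
    deterministic block-key order.  Blocks are numbered ascending by
    minimal member (count, length, id), so label 1 is the youngest
    candidate individual.
    """
    finest = max(len(p) for p in partitions)
    candidates = [p for p in partitions if len(p) == finest]
    canonical = min(candidates,
                    key=lambda p: sorted((_block_key(g, b), tuple(sorted(b)))
                                         for b in p))
    ordered = sorted(canonical, key=lambda b: _block_key(g, b))
    return {rid: i + 1 for i, block in enumerate(ordered) for rid in block}


def _ambiguity(g: nx.Graph, partitions: Sequence[Partition]
               ) -> dict[str, tuple[int, ...]]:
    """Candidate individual labels per record, across admissible partitions.

    Within each partition a record inherits the minimal reference label in
    its block; the union over partitions yields the candidate set (e.g.
    "2, 3" for a vertebra attachable to either of two individuals).
    """
    ref = _reference_labels(g, partitions)
    cand: dict[str, set[int]] = {rid: set() for rid in g.nodes}
    for p in partitions:
        for block in p:
            label = min(ref[r] for r in block)
            for r in block:
                cand[r].add(label)
    return {r: tuple(sorted(s)) for r, s in cand.items()}


def mni_range(records: Sequence[VertebraRecord],
              params: CompatibilityParams = CompatibilityParams(),
              per_lot: bool = True,
              max_exact: int = DEFAULT_MAX_EXACT) -> MNIResult:
    """Minimum/maximum number of individuals in a commingled assemblage.

    Per lot (or pooled), enumerates the admissible partitions of the
    compatibility graph; the block-count span gives the per-lot range and
    totals are the sums of per-lot minima and maxima.
    """
    groups: dict[str, list[VertebraRecord]] = {}
    for v in records:
        key = v.lot_id if per_lot else "<pooled>"
        groups.setdefault(key, []).append(v)

    lots = []
    for lot_id in sorted(groups):
        group = groups[lot_id]
        excluded = tuple(sorted(v.record_id for v in group
                                if not combined_count(v).scorable))
        g = build_graph(group, params, per_lot=per_lot)
        nodes = {r: (g.nodes[r]["count"], g.nodes[r]["centrum_length_mm"])
                 for r in g.nodes}
        if g.number_of_nodes() == 0:
            lots.append(LotResult(lot_id, 0, 0, (), {}, excluded))
            continue
        parts = enumerate_admissible_partitions(g, max_exact=max_exact)
        sizes = [len(p) for p in parts]
        lots.append(LotResult(
            lot_id=lot_id,
            min_individuals=min(sizes),
            max_individuals=max(sizes),
            partitions=tuple(parts),
            ambiguity=_ambiguity(g, parts),
            excluded=excluded,
            nodes=nodes,
        ))
    return MNIResult(lots=tuple(lots), params=params)


def mni_bracket(records: Sequence[VertebraRecord],
                cv_percents: Sequence[float] = CompatibilityParams.DEFAULT_CV_BRACKET,
                params: CompatibilityParams = CompatibilityParams(),
                per_lot: bool = True,
                max_exact: int = DEFAULT_MAX_EXACT) -> dict[float, MNIResult]:
    """Evaluate the size envelope at each bracketing CV%% and report all.

    The published procedure runs the envelope at the coefficients of
    variation of the two closest extant relatives (12.7 and 19.5) as lower
    and upper boundaries.
    """
    return {cv: mni_range(records, params.with_cv(cv), per_lot, max_exact)
            for cv in cv_percents}


@dataclass(frozen=True)
class AgeStructure:
    min_age: int
    median_age: float
    max_age: int
    tallies: dict[int, int] = field(default_factory=dict)


def age_structure(records: Sequence[VertebraRecord]) -> AgeStructure:
    """Age distribution of the scorable vertebrae (counts as years).

    The median uses the midpoint-of-two-middle-values rule for even n.
    """
    counts = sorted(combined_count(v).value for v in records
                    if combined_count(v).scorable)
    if not counts:
        raise ValueError("no scorable records")
    return AgeStructure(
        min_age=counts[0],
        median_age=float(statistics.median(counts)),
        max_age=counts[-1],
        tallies=dict(sorted(Counter(counts).items())),
    )
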