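"""Molecular networking: modified-cosine similarity, graph construction
with the standard edge filters, spectral families, and library search.

The modified cosine extends the plain spectral cosine by also matching
fragment pairs offset by the precursor mass difference, so structural
analogs (e.g. lipopeptide homologs differing by CH2 in the acyl chain)
score highly even though their fragment ladders are shifted.  Square-
root intensity weighting and greedy one-to-one peak assignment follow
the GNPS convention; an exhaustive optimal-assignment matcher is kept
in the test suite as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .features import Feature
from .spectra import FragmentSpectrum

__all__ = [
    "NetworkEdge",
    "modified_cosine",
    "build_network",
    "spectral_families",
    "library_search",
    "LibraryHit",
]


@dataclass(frozen=True)
class NetworkEdge:
    """An undirected cosine-scored edge between two feature nodes."""

    node_a: int
    node_b: int
    cosine: float
    matched_peaks: int
    mass_shift: float

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError("edges are canonical with node_a < node_b")
        if not 0.0 <= self.cosine <= 1.0:
            raise ValueError("cosine must lie in [0, 1]")


def _candidate_pairs(
    a: FragmentSpectrum, b: FragmentSpectrum, tol: float
) -> list[tuple[float, int, int]]:
    """(score-product, i, j) for all allowed peak pairs.

    A pair is allowed if the m/z values agree within ``tol`` directly or
    after shifting by the precursor mass difference.
    """
    shift = b.precursor_mz - a.precursor_mz
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    out = []
    for i, ma in enumerate(a.mz):
        for j, mb in enumerate(b.mz):
            if abs(ma - mb) <= tol or abs(mb - ma - shift) <= tol:
                out.append((float(wa[i] * wb[j]), i, j))
    return out


def modified_cosine(
    a: FragmentSpectrum, b: FragmentSpectrum, fragment_tol: float = 0.9
) -> tuple[float, int]:
    """Modified cosine score and matched-peak count between two spectra.

    Peaks pair if their m/z agree within ``fragment_tol`` either
    directly or after shifting by the precursor difference; candidate
    pairs are ranked by the product of square-root intensities and
    assigned greedily one-to-one.  The score is the sum of matched
    products normalized by the norms of the square-root intensity
    vectors, clipped to [0, 1].  Empty spectra score 0.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    pairs = _candidate_pairs(a, b, fragment_tol)
    if not pairs:
        return 0.0, 0
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    matched = 0
    for score, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += score
        matched += 1
    norm = float(
        np.linalg.norm(np.sqrt(a.intensity)) * np.linalg.norm(np.sqrt(b.intensity))
    )
    score = min(1.0, total / norm) if norm > 0 else 0.0
    return score, matched


def build_network(
    spectra: list[FragmentSpectrum],
    features: list[Feature] | None = None,
    cosine_threshold: float = 0.7,
    min_matched: int = 4,
    fragment_tol: float = 0.9,
    precursor_tol: float = 0.02,
    top_k: int | None = None,
) -> nx.Graph:
    """Score all spectrum pairs and keep edges passing both filters.

    An edge survives iff its cosine exceeds ``cosine_threshold`` AND its
    matched-peak count is at least ``min_matched`` (default 4, i.e.
    "more than three").  ``precursor_tol`` is recorded as a graph
    attribute (it governs how identical precursors would be merged
    upstream; no merging happens here).  Optional ``top_k`` pruning
    keeps an edge only if each endpoint ranks the other within its K
    best neighbours (off by default).  Node attributes carry m/z, RT
    and abundance when ``features`` are supplied.  The edge set is
    invariant under permutation of the input spectra.
    """
    g = nx.Graph(
        cosine_threshold=cosine_threshold,
        min_matched=min_matched,
        fragment_tol=fragment_tol,
        precursor_tol=precursor_tol,
    )
    feat_by_id = {f.id: f for f in (features or [])}
    specs = sorted(
        (s for s in spectra if s.feature_id is not None),
        key=lambda s: s.feature_id,
    )
    for s in specs:
        f = feat_by_id.get(s.feature_id)
        g.add_node(
            s.feature_id,
            mz=float(f.mz if f else s.precursor_mz),
            rt=float(f.rt_apex) if f else (s.rt if s.rt is not None else 0.0),
            abundance=float(f.area) if f else 0.0,
            height=float(f.height) if f else 0.0,
            sample=f.sample if f else "sample",
            bioactive=False,
            annotation="",
        )
    edges = []
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            a, b = specs[i], specs[j]
            cos, matched = modified_cosine(a, b, fragment_tol)
            if cos > cosine_threshold and matched >= min_matched:
                u, v = sorted((a.feature_id, b.feature_id))
                edges.append(
                    NetworkEdge(
                        u, v, cos, matched,
                        mass_shift=float(b.precursor_mz - a.precursor_mz),
                    )
                )
    if top_k is not None:
        ranks: dict[int, list[tuple[float, int]]] = {}
        for e in edges:
            ranks.setdefault(e.node_a, []).append((-e.cosine, e.node_b))
            ranks.setdefault(e.node_b, []).append((-e.cosine, e.node_a))
        allowed = {
            node: {nb for _, nb in sorted(rs)[:top_k]}
            for node, rs in ranks.items()
        }
        edges = [
            e for e in edges
            if e.node_b in allowed[e.node_a] and e.node_a in allowed[e.node_b]
        ]
    for e in edges:
        g.add_edge(
            e.node_a, e.node_b,
            cosine=round(e.cosine, 6),
            matched_peaks=e.matched_peaks,
            mass_shift=round(e.mass_shift, 5),
        )
    return g


def spectral_families(g: nx.Graph) -> tuple[list[list[int]], int]:
    """Connected components with >= 2 nodes, plus the singleton count.

    Families are returned largest first, ties broken by the smallest
    node id; nodes inside a family are sorted ascending.
    """
    comps = [sorted(c) for c in nx.connected_components(g)]
    families = sorted(
        (c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c[0])
    )
    singletons = sum(1 for c in comps if len(c) == 1)
    return families, singletons


@dataclass
class LibraryHit:
    """Best library annotation for one query spectrum."""

    feature_id: int
    name: str
    score: float
    matched_peaks: int


def library_search(
    spectra: list[FragmentSpectrum],
    library: list[FragmentSpectrum],
    score_min: float = 0.7,
    matched_min: int = 3,
    fragment_tol: float = 0.9,
) -> dict[int, LibraryHit]:
    """Annotate queries against a spectral library.

    Each query keeps its best-scoring library entry that clears both
    the score floor (> ``score_min``) and the matched-peak floor
    (>= ``matched_min``); queries with no qualifying hit are absent
    from the result.
    """
    if not library:
        raise ValueError("library must be non-empty")
    hits: dict[int, LibraryHit] = {}
    for q in spectra:
        if q.feature_id is None:
            continue
        best: LibraryHit | None = None
        for entry in library:
            cos, matched = modified_cosine(q, entry, fragment_tol)
            if cos > score_min and matched >= matched_min:
                if best is None or cos > best.score:
                    best = LibraryHit(
                        q.feature_id, entry.name or "library entry",
                        cos, matched,
                    )
        if best is not None:
            hits[q.feature_id] = best
    return hits
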