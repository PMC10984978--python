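"""Correlation of bioactivity peaks with MS features, in-source
relation annotation, and bioactive-node marking in the network.

Once the bioactivity trace sits on the MS time axis (see
:mod:`nanorapids.alignment`), every feature whose apex elutes inside a
called negative peak's window is a candidate for the activity.  Several
co-eluting features usually belong to one compound — the protonated
molecule plus in-source fragments (water loss, deoxysugar loss) and
solvent adducts — so the assigned features are cross-annotated with the
exact-mass differences of those relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .alignment import DelayModel
from .features import Feature
from .plate import BioactivityPeak

__all__ = [
    "NEUTRAL_DELTAS",
    "BioactiveAssignment",
    "Relation",
    "map_bioactive_features",
    "annotate_insource_relations",
    "mark_network",
]

#: Exact neutral/adduct mass differences (Da) seen among co-eluting ions
#: of one compound.  Values are plain monoisotopic sums:
#: H2O 2x1.0078250319 + 15.9949146221; C6H10O2 (deoxysugar residue,
#: e.g. a dideoxyhexose) 6x12 + 10xH + 2xO; C6H10O3 likewise with 3 O;
#: MeCN (acetonitrile, C2H3N) for the [M+H+MeCN]+ solvent adduct.
NEUTRAL_DELTAS: dict[str, float] = {
    "water-loss": 18.010565,
    "sugar-loss-C6H10O2": 114.068080,
    "sugar-loss-C6H10O3": 130.062995,
    "MeCN-adduct": 41.026549,
}


@dataclass
class Relation:
    """A labeled mass relation between two assigned features."""

    from_feature: int  # heavier ion
    to_feature: int  # lighter ion
    label: str
    delta: float


@dataclass
class BioactiveAssignment:
    """Features co-eluting with one bioactivity peak.

    ``features`` is sorted by descending height; empty when the peak has
    no qualifying feature (reported, not dropped — a bioactive fraction
    can lack an ionizable feature).
    """

    peak: BioactivityPeak
    features: list[Feature] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)


def map_bioactive_features(
    features: list[Feature],
    peaks: list[BioactivityPeak],
    delay: DelayModel | None = None,
    rt_tolerance: float = 0.1,
) -> list[BioactiveAssignment]:
    """Assign features to bioactivity peaks by retention time.

    Peak windows are taken on the delay-corrected axis: if ``delay`` is
    given, each peak window is shifted by ``-delay`` onto the MS axis
    (pass ``None`` if the trace was already corrected with
    :func:`nanorapids.alignment.apply_delay`).  A feature joins a peak
    iff its apex lies in ``[start - tol, end + tol]``; overlapping peaks
    may share features.  Output sorted by peak, features by descending
    height.
    """
    shift = delay.delay if delay is not None else 0.0
    out: list[BioactiveAssignment] = []
    for pk in sorted(peaks, key=lambda p: p.start_time):
        lo = pk.start_time - shift - rt_tolerance
        hi = pk.end_time - shift + rt_tolerance
        assigned = [f for f in features if lo <= f.rt_apex <= hi]
        assigned.sort(key=lambda f: (-f.height, f.mz))
        out.append(BioactiveAssignment(peak=pk, features=assigned))
    return out


def annotate_insource_relations(
    assignment: BioactiveAssignment,
    deltas: dict[str, float] | None = None,
    mz_tol: float = 0.005,
) -> list[Relation]:
    """Label mass relations among the co-eluting features of one peak.

    For every ordered pair (heavier, lighter) the m/z difference is
    compared with each known delta; matches within ``mz_tol`` are
    labeled.  Chains arise naturally (a sugar loss followed by a water
    loss produces two pairwise labels).  The relation list is stored on
    the assignment and returned.
    """
    table = NEUTRAL_DELTAS if deltas is None else deltas
    feats = sorted(assignment.features, key=lambda f: -f.mz)
    rels: list[Relation] = []
    for i, hi in enumerate(feats):
        for lo in feats[i + 1:]:
            d = hi.mz - lo.mz
            for label, exact in table.items():
                if abs(d - exact) <= mz_tol:
                    rels.append(Relation(hi.id, lo.id, label, d))
    assignment.relations = rels
    return rels


def mark_network(
    g: nx.Graph, assignments: list[BioactiveAssignment]
) -> nx.Graph:
    """Flag assigned features as bioactive nodes (in place, idempotent).

    Unknown feature ids trigger a warning and are skipped — a bioactive
    feature may have been dropped upstream by the MS2-only row filter.
    """
    for asg in assignments:
        for f in asg.features:
            if f.id not in g:
                warnings.warn(
                    f"assignment references unknown network node {f.id}; skipped",
                    stacklevel=2,
                )
                continue
            g.nodes[f.id]["bioactive"] = True
            g.nodes[f.id]["bioactive_peak"] = asg.peak.peak_id
            g.nodes[f.id]["abundance"] = float(f.area)
    return g
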