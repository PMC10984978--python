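"""End-to-end orchestration of the screen: simulate (or load) a run,
build the bioactivity trace, align, detect features, network, and map
bioactive fractions to mass features."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as nio
from .alignment import DelayModel, apply_delay, estimate_delay
from .features import Feature, detect_features
from .mapping import (
    BioactiveAssignment,
    annotate_insource_relations,
    map_bioactive_features,
    mark_network,
)
from .network import build_network, spectral_families
from .plate import (
    BioactivityPeak,
    BioactivityTrace,
    build_trace,
    detect_bioactivity_peaks,
    normalize_plate,
)
from .simulate import (
    SyntheticCompound,
    SyntheticRunSpec,
    calibrant_compound,
    homolog_series,
    simulate_plate,
    simulate_run,
)
from .spectra import Scan

__all__ = [
    "base_peak_chromatogram",
    "default_screen_compounds",
    "ScreenResult",
    "run_screen",
    "estimate_delay_from_calibrant_run",
]


def base_peak_chromatogram(scans: list[Scan]) -> tuple[np.ndarray, np.ndarray]:
    """(times, max intensity per scan) over the MS1 scans."""
    ms1 = [s for s in scans if s.ms_level == 1]
    times = np.array([s.rt for s in ms1])
    bpc = np.array(
        [float(s.intensity.max()) if s.intensity.size else 0.0 for s in ms1]
    )
    return times, bpc


def default_screen_compounds() -> list[SyntheticCompound]:
    """The bundled validation scenario: eight bioactive lipopeptide-like
    ions (a CH2 homolog quartet with one late-eluting positional isomer,
    plus a second three-member homolog family) over inactive background
    compounds.

    Retention times and precursor m/z mirror an iturin/surfactin-type
    extract; the two families carry disjoint fragment cores, so they
    form two separate spectral families in the network.
    """
    iturin_core = ((198.09, 55.0), (327.15, 100.0), (443.19, 85.0),
                   (556.27, 45.0), (684.33, 30.0))
    surfactin_core = ((227.18, 70.0), (341.23, 100.0), (463.30, 60.0),
                      (594.36, 35.0))
    series_a = homolog_series(
        1029.5404, [16.32, 18.05, 19.22, 20.64],
        core_fragments=iturin_core, name="lipopeptide-A", apex=2.0e6,
    )
    # positional isomer: same m/z as the C16 member, later RT
    isomer = replace(series_a[3], name="lipopeptide-A-C16b", rt=20.95)
    series_b = homolog_series(
        1008.6698, [27.91, 28.84, 29.47],
        core_fragments=surfactin_core, name="lipopeptide-B", apex=1.5e6,
    )
    background = [
        SyntheticCompound(
            name="inactive-1", mz=431.2486, rt=8.4, apex=8.0e5,
            fragments=((123.04, 100.0), (207.10, 70.0), (305.16, 40.0)),
        ),
        SyntheticCompound(
            name="inactive-2", mz=611.3275, rt=12.7, apex=6.0e5,
            fragments=((155.08, 100.0), (289.14, 55.0), (421.21, 35.0)),
        ),
        SyntheticCompound(
            name="inactive-3", mz=725.4120, rt=24.2, apex=9.0e5,
            fragments=((171.10, 80.0), (333.17, 100.0), (507.26, 50.0)),
        ),
    ]
    return series_a + [isomer] + series_b + background


def estimate_delay_from_calibrant_run(
    spec: SyntheticRunSpec, rt: float = 5.0
) -> DelayModel:
    """Simulate a single-calibrant injection and estimate the delay."""
    cal = calibrant_compound(rt=rt)
    scans, _ = simulate_run(spec, [cal])
    plate = simulate_plate(spec, [cal])
    trace = build_trace(normalize_plate(plate, spec.layout), spec.layout)
    times, bpc = base_peak_chromatogram(scans)
    return estimate_delay(
        times, bpc, trace,
        well_time_offset=spec.layout.fraction_minutes / 2.0,
    )


@dataclass
class ScreenResult:
    """Everything one screen produces, in memory."""

    scans: list[Scan]
    truth: pd.DataFrame
    trace: BioactivityTrace
    corrected_trace: BioactivityTrace
    delay: DelayModel
    bio_peaks: list[BioactivityPeak]
    features: list[Feature]
    network: nx.Graph
    assignments: list[BioactiveAssignment]

    @property
    def bioactive_feature_ids(self) -> set[int]:
        return {f.id for a in self.assignments for f in a.features}


def run_screen(
    spec: SyntheticRunSpec | None = None,
    compounds: list[SyntheticCompound] | None = None,
    config: "nio.PipelineConfig | None" = None,
    estimate_delay_with_calibrant: bool = True,
) -> ScreenResult:
    """Run the whole pipeline on a synthetic screen.

    The tubing delay is estimated from a separate simulated calibrant
    injection (as on the real setup) unless the config supplies one.
    """
    cfg = config or nio.PipelineConfig()
    spec = spec or SyntheticRunSpec(seed=cfg.seed, layout=cfg.layout)
    compounds = compounds if compounds is not None else default_screen_compounds()

    scans, truth = simulate_run(spec, compounds)
    plate = simulate_plate(spec, compounds)
    trace = build_trace(normalize_plate(plate, spec.layout), spec.layout)

    if cfg.delay is not None:
        delay = DelayModel(delay=cfg.delay, calibrant_name="configured")
    elif estimate_delay_with_calibrant:
        delay = estimate_delay_from_calibrant_run(
            replace(spec, seed=spec.seed + 7)
        )
    else:
        delay = DelayModel(delay=0.0, calibrant_name="none")
    corrected = apply_delay(trace, delay)
    bio_peaks = detect_bioactivity_peaks(
        corrected, threshold=cfg.bio_threshold, min_width=cfg.bio_min_width
    )

    features = detect_features(scans, cfg.detection)
    spectra = [f.ms2 for f in features if f.ms2 is not None]
    net = build_network(
        spectra, features,
        cosine_threshold=cfg.cosine_threshold,
        min_matched=cfg.min_matched,
        fragment_tol=cfg.fragment_tol,
        precursor_tol=cfg.precursor_tol,
        top_k=cfg.top_k,
    )
    assignments = map_bioactive_features(
        features, bio_peaks, delay=None, rt_tolerance=cfg.rt_tolerance
    )
    for asg in assignments:
        annotate_insource_relations(asg, mz_tol=cfg.relation_mz_tol)
    mark_network(net, assignments)
    return ScreenResult(
        scans=scans, truth=truth, trace=trace, corrected_trace=corrected,
        delay=delay, bio_peaks=bio_peaks, features=features, network=net,
        assignments=assignments,
    )


def evaluate_bioactive_recovery(
    result: ScreenResult, mz_tol: float = 0.01, rt_tol: float = 0.1
) -> tuple[float, float, int]:
    """Precision/recall of bioactive-feature flagging vs generator truth.

    A flagged feature is a true positive if an injected *active*
    compound lies within ``mz_tol`` and ``rt_tol`` of it; an active is
    recovered if some flagged feature matches it.  Returns
    ``(precision, recall, n_flagged)``.
    """
    truth = result.truth
    actives = truth[truth["active"]]
    flagged = [f for f in result.features
               if f.id in result.bioactive_feature_ids]

    def matches(f, row) -> bool:
        return (abs(f.mz - row.mz) <= mz_tol
                and abs(f.rt_apex - row.rt) <= rt_tol)

    tp = sum(
        any(matches(f, row) for row in actives.itertuples()) for f in flagged
    )
    recovered = sum(
        any(matches(f, row) for f in flagged) for row in actives.itertuples()
    )
    precision = tp / len(flagged) if flagged else 0.0
    recall = recovered / len(actives) if len(actives) else 1.0
    return precision, recall, len(flagged)


def write_screen_artifacts(result: ScreenResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard artifact set of one screen to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["trace"] = nio.write_trace_csv(result.corrected_trace,
                                         outdir / "bioactivity_trace.csv")
    csv_path, mgf_path = nio.write_fbmn_bundle(result.features, outdir)
    paths["quant"] = csv_path
    paths["mgf"] = mgf_path
    paths["graphml"] = nio.write_graphml(result.network,
                                         outdir / "molecular_network.graphml")
    paths["edges"] = nio.write_edge_list(result.network, outdir / "edges.tsv")
    paths["assignments"] = nio.write_assignments_csv(
        result.assignments, outdir / "bioactive_assignments.csv"
    )
    paths["delay"] = nio.write_delay_report(result.delay,
                                            outdir / "delay_report.json")
    return paths
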