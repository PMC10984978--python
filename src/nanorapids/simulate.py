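"""Ground-truthed synthetic LC-MS/MS runs and matching plate readouts.

The generator emulates the screening setup the pipeline targets: a
41-minute reversed-phase gradient, positive-mode MS1 scans over
m/z 100-2000 with data-dependent MS2 on the three most intense ions,
and at-line nanofractionation into a 384-well plate at 6 s per well
with a fixed tubing delay between the MS detector and the fraction
collector.  Compounds elute as Gaussian peaks with A/A+1/A+2 isotope
satellites; active compounds additionally depress the viability
readout of the wells their elution window falls into.

Everything is driven by one seed, so a fixed seed yields byte-identical
scans and plates.  What the generator deliberately does *not* model:
chromatographic tailing, ion suppression, multiply-charged envelopes,
or well-to-well assay drift beyond multiplicative noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import MONOISOTOPIC_MASS, monoisotopic_mass, parse_formula
from .plate import PlateLayout, PlateRead, fraction_time
from .spectra import Scan

__all__ = [
    "SyntheticCompound",
    "SyntheticRunSpec",
    "simulate_run",
    "simulate_plate",
    "homolog_series",
    "calibrant_compound",
]

C13_DELTA = 1.00335
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SyntheticCompound:
    """One eluting ion with optional bioactivity.

    ``mz`` is the monoisotopic [M+H]+ m/z; supply ``formula`` (neutral)
    instead to derive it.  ``fragments`` are relative (mz, intensity)
    pairs used for data-dependent MS2.
    """

    name: str
    mz: float = 0.0
    formula: str | None = None
    rt: float = 10.0  # minutes
    sigma: float = 0.06  # Gaussian width, minutes
    apex: float = 1.0e6
    fragments: tuple[tuple[float, float], ...] = ()
    active: bool = False
    activity_depth: float = 0.0
    n_carbons: int | None = None

    def __post_init__(self) -> None:
        if self.formula is not None and self.mz == 0.0:
            f = parse_formula(self.formula)
            object.__setattr__(
                self, "mz", monoisotopic_mass(f) + MONOISOTOPIC_MASS["H"]
            )
            if self.n_carbons is None:
                object.__setattr__(self, "n_carbons", f["C"])
        if self.mz <= 0:
            raise ValueError("compound needs a positive m/z or a formula")
        if self.apex <= 0:
            raise ValueError("apex intensity must be positive")
        if self.active and not 0.0 < self.activity_depth <= 1.0:
            raise ValueError("active compounds need activity_depth in (0, 1]")

    @property
    def carbons(self) -> int:
        if self.n_carbons is not None:
            return self.n_carbons
        # crude carbon estimate from mass for isotope ratios
        return max(1, int(self.mz * 0.55 / 12.0))


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Acquisition and fractionation geometry of one synthetic run."""

    run_length: float = 41.0  # minutes, gradient program length
    ms1_interval: float = 1.25  # seconds between MS1 scans
    top_n: int = 3  # data-dependent MS2 per cycle
    ms2_trigger: float = 5.0e4  # min MS1 intensity to trigger MS2
    ms2_exclusion: float = 5.0  # seconds of dynamic exclusion
    noise_floor: float = 5.0e3  # additive chemical noise ceiling
    noise_peaks_per_scan: int = 20
    mz_range: tuple[float, float] = (100.0, 2000.0)
    seed: int = 0
    delay: float = 0.3  # minutes, bioassay trace lags MS trace
    layout: PlateLayout = field(default_factory=PlateLayout)
    baseline_fluorescence: float = 5.0e4
    plate_noise_cv: float = 0.02

    @property
    def n_ms1(self) -> int:
        return int(self.run_length * 60.0 / self.ms1_interval)


def homolog_series(
    base_mz: float,
    rts: list[float],
    core_fragments: tuple[tuple[float, float], ...] = (
        (250.10, 60.0), (370.18, 100.0), (450.21, 80.0), (520.25, 40.0),
    ),
    n_shifted: int = 3,
    apex: float = 2.0e6,
    name: str = "homolog",
    active: bool = True,
    activity_depth: float = 0.8,
    sigma: float = 0.06,
) -> list[SyntheticCompound]:
    """A CH2-spaced homolog series sharing a fragment core.

    Emulates lipopeptide families (iturin/surfactin-like): members k =
    0..n-1 have precursor m/z ``base_mz + k*14.01565`` and MS2 spectra
    consisting of the common core fragments plus ``n_shifted`` fragments
    that shift with the precursor — exactly the structure that makes the
    modified cosine link analogs through shifted peak matching.
    """
    ch2 = 14.01565
    out = []
    for k, rt in enumerate(rts):
        mz = base_mz + k * ch2
        shifted = tuple(
            (mz - 17.0265 - i * 99.07, 90.0 - 15.0 * i) for i in range(n_shifted)
        )
        out.append(
            SyntheticCompound(
                name=f"{name}-C{13 + k}",
                mz=mz,
                rt=rt,
                sigma=sigma,
                apex=apex,
                fragments=core_fragments + shifted,
                active=active,
                activity_depth=activity_depth,
            )
        )
    return out


def calibrant_compound(
    rt: float = 5.0, depth: float = 0.8, apex: float = 5.0e6
) -> SyntheticCompound:
    """Single-injection delay calibrant (nalidixic-acid-like, C12H12N2O3)."""
    return SyntheticCompound(
        name="calibrant",
        formula="C12H12N2O3",
        rt=rt,
        sigma=0.06,
        apex=apex,
        fragments=((187.06, 100.0), (159.07, 60.0), (131.06, 30.0)),
        active=True,
        activity_depth=depth,
    )


def _gauss(t: float, rt: float, sigma: float) -> float:
    z = (t - rt) / sigma
    return math.exp(-0.5 * z * z)


def simulate_run(
    spec: SyntheticRunSpec,
    compounds: list[SyntheticCompound],
) -> tuple[list[Scan], pd.DataFrame]:
    """Generate the scan sequence and the ground-truth table.

    MS1 scans are centroided stick spectra: for each compound the
    monoisotopic peak plus A+1 and A+2 satellites (1.1 % per carbon,
    binomial-style falloff), plus uniform chemical noise strictly below
    ``noise_floor``.  After each MS1 scan, up to ``top_n`` precursors
    above ``ms2_trigger`` (and not dynamically excluded) get an MS2
    scan built from the compound's fragment list.
    """
    rng = np.random.default_rng(spec.seed)
    scans: list[Scan] = []
    exclusion_until: dict[int, float] = {}
    scan_id = 0
    dt_min = spec.ms1_interval / 60.0
    for k in range(spec.n_ms1):
        t = k * dt_min
        mz_list: list[float] = []
        int_list: list[float] = []
        heights = []
        for ci, c in enumerate(compounds):
            h = c.apex * _gauss(t, c.rt, c.sigma)
            heights.append(h)
            if h < 1.0:
                continue
            r1 = 0.011 * c.carbons
            for iso, frac in ((0, 1.0), (1, r1), (2, r1 * r1 / 2.0)):
                hi = h * frac
                if hi >= 1.0:
                    mz_list.append(c.mz + iso * C13_DELTA)
                    int_list.append(hi)
        # chemical noise, strictly below the floor
        n_noise = spec.noise_peaks_per_scan
        if n_noise:
            noise_mz = rng.uniform(*spec.mz_range, size=n_noise)
            noise_int = rng.uniform(1.0, spec.noise_floor * 0.999, size=n_noise)
            mz_list.extend(noise_mz.tolist())
            int_list.extend(noise_int.tolist())
        mz_arr = np.asarray(mz_list)
        int_arr = np.asarray(int_list)
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        # merge pathological near-identical m/z (keeps mz strictly increasing)
        if mz_arr.size > 1:
            keep = np.concatenate([[True], np.diff(mz_arr) > 1e-9])
            for i in np.nonzero(~keep)[0]:
                int_arr[i - 1] += int_arr[i]
            mz_arr, int_arr = mz_arr[keep], int_arr[keep]
        scans.append(Scan(1, t, mz_arr, int_arr, centroided=True, scan_id=scan_id))
        scan_id += 1
        # data-dependent MS2: top-N intense, non-excluded precursors
        cands = [
            (heights[ci], ci) for ci in range(len(compounds))
            if heights[ci] >= spec.ms2_trigger
            and t >= exclusion_until.get(ci, -1.0)
        ]
        cands.sort(key=lambda x: (-x[0], x[1]))
        for slot, (h, ci) in enumerate(cands[: spec.top_n]):
            c = compounds[ci]
            frags = c.fragments or ((c.mz - 18.0106, 100.0),)
            fm = np.asarray([f[0] for f in frags])
            fi = np.asarray([f[1] for f in frags]) * (h / 100.0)
            order = np.argsort(fm, kind="stable")
            rt2 = t + (slot + 1) * dt_min / (spec.top_n + 1)
            scans.append(
                Scan(
                    2, rt2, fm[order], fi[order], centroided=True,
                    scan_id=scan_id, precursor_mz=c.mz,
                    precursor_charge=1, precursor_intensity=h,
                )
            )
            scan_id += 1
            exclusion_until[ci] = t + spec.ms2_exclusion / 60.0
    truth = pd.DataFrame(
        {
            "name": [c.name for c in compounds],
            "mz": [c.mz for c in compounds],
            "rt": [c.rt for c in compounds],
            "sigma": [c.sigma for c in compounds],
            "apex": [c.apex for c in compounds],
            "active": [c.active for c in compounds],
            "activity_depth": [c.activity_depth for c in compounds],
            "dip_time": [c.rt + spec.delay for c in compounds],
        }
    )
    return scans, truth


def _eluted_weight(c: SyntheticCompound, lo: float, hi: float) -> float:
    """Fraction of the compound's total elution falling in [lo, hi)."""
    a = (lo - c.rt) / (c.sigma * _SQRT2)
    b = (hi - c.rt) / (c.sigma * _SQRT2)
    return 0.5 * (math.erf(b) - math.erf(a))


def simulate_plate(
    spec: SyntheticRunSpec,
    compounds: list[SyntheticCompound],
) -> PlateRead:
    """Fluorescence plate matching the run's actives and delay.

    Wells start at the baseline with multiplicative noise.  For each
    active compound, the wells whose collection window (MS time shifted
    by the tubing delay) overlaps the elution peak are attenuated by
    ``activity_depth`` weighted by the eluted amount in that window
    (normalized so the fullest window carries the full depth).  The
    control column gets growth controls (rows A-H at baseline) and
    inhibition controls (rows I-P strongly reduced); controls never
    enter the sample traversal.
    """
    layout = spec.layout
    rng = np.random.default_rng(spec.seed + 1)
    grid = np.full((layout.rows, layout.columns), np.nan)
    noise = rng.normal(1.0, spec.plate_noise_cv,
                       size=(layout.rows, layout.columns))
    from .plate import serpentine_order  # local import to avoid cycle at init

    order = serpentine_order(layout)
    dt = layout.fraction_minutes
    for i, (r, c) in enumerate(order):
        t_coll = fraction_time(i, layout)
        # MS-axis window this well collected
        lo = t_coll - spec.delay
        hi = lo + dt
        factor = 1.0
        for comp in compounds:
            if not comp.active:
                continue
            w = _eluted_weight(comp, lo, hi)
            w_max = _eluted_weight(
                comp, comp.rt - dt / 2.0, comp.rt + dt / 2.0
            )
            if w_max > 0:
                factor *= 1.0 - comp.activity_depth * min(1.0, w / w_max)
        grid[r - 1, c - 1] = (
            spec.baseline_fluorescence * max(factor, 0.0) * max(noise[r - 1, c - 1], 0.0)
        )
    cc = layout.control_column - 1
    half = layout.rows // 2
    grid[:half, cc] = spec.baseline_fluorescence * np.maximum(noise[:half, cc], 0.0)
    grid[half:, cc] = 0.05 * spec.baseline_fluorescence * np.maximum(noise[half:, cc], 0.0)
    return PlateRead(grid)
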