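"""LC-MS feature detection: centroiding, chromatogram building,
local-minimum deconvolution, MS2 pairing, isotope grouping and
duplicate/row filters.

This chain re-creates, with open and documented semantics, the
MZmine-2.53-style pre-processing commonly used upstream of feature-based
molecular networking: mass peaks are picked per scan, strung into
extracted-ion chromatograms (EICs) by m/z proximity, split into
chromatographic peaks at local intensity minima, paired with
data-dependent MS2 scans, collapsed across isotopologues, deduplicated,
and finally restricted to rows that carry an MS2 spectrum.  It is an
independent reimplementation of the published parameterization, not a
bit-clone of the closed-source behaviors.

All m/z tolerances are absolute Daltons; retention times are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import FragmentSpectrum, Scan

__all__ = [
    "DetectionParams",
    "EIC",
    "Feature",
    "detect_mass_peaks",
    "build_chromatograms",
    "deconvolve_local_minimum",
    "pair_ms2",
    "group_isotopes",
    "filter_duplicates",
    "filter_rows_with_ms2",
    "detect_features",
]

#: 13C-12C mass difference used for isotopologue spacing.
C13_DELTA = 1.00335


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the detection chain.

    Defaults are the published high-resolution Orbitrap settings:
    MS1 centroid noise 1e4 (0 for MS2), chromatogram builder with
    minimum group size 10 / 0.001 Da tolerance / group intensity 1e4 /
    minimum height 5e4, local-minimum deconvolution (RT search 0.1 min,
    chromatographic threshold 90 %, min relative height 1 %, min
    absolute height 1e4, top/edge ratio 2, duration 0.05-3 min), MS2
    pairing 0.05 Da / 1 min, isotope grouping 0.001 Da / 0.1 min.
    """

    ms1_noise: float = 1.0e4
    ms2_noise: float = 0.0
    min_group_size: int = 10
    mz_tol: float = 0.001
    group_intensity_threshold: float = 1.0e4
    min_height: float = 5.0e4
    rt_search_range: float = 0.1
    chrom_threshold: float = 0.90
    min_rel_height: float = 0.01
    min_abs_height: float = 1.0e4
    top_edge_ratio: float = 2.0
    duration_min: float = 0.05
    duration_max: float = 3.0
    ms2_pair_mz: float = 0.05
    ms2_pair_rt: float = 1.0
    iso_mz_tol: float = 0.001
    iso_rt_tol: float = 0.1
    iso_charges: tuple[int, ...] = (1, 2)
    dup_mz_tol_1: float = 0.001
    dup_rt_tol_1: float = 0.05
    dup_mz_tol_2: float = 1.0
    dup_rt_tol_2: float = 0.05

    def __post_init__(self) -> None:
        if self.duration_min >= self.duration_max:
            raise ValueError("duration range must be ordered")
        for name in ("mz_tol", "min_height", "rt_search_range",
                     "ms2_pair_mz", "ms2_pair_rt", "iso_mz_tol",
                     "iso_rt_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EIC:
    """An extracted-ion chromatogram: RT-ordered points at one m/z."""

    representative_mz: float
    rts: np.ndarray
    mzs: np.ndarray
    intensities: np.ndarray
    scan_indices: np.ndarray


@dataclass
class Feature:
    """A deconvolved chromatographic peak, optionally with its MS2."""

    id: int
    mz: float
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float
    isotope_group: int | None = None
    is_monoisotopic: bool = True
    ms2: FragmentSpectrum | None = None
    n_ms2: int = 0
    sample: str = "sample"

    @property
    def duration(self) -> float:
        return self.rt_end - self.rt_start


def detect_mass_peaks(scan: Scan, noise: float) -> tuple[np.ndarray, np.ndarray]:
    """Pick mass peaks from one scan, returning (mz, intensity) arrays.

    Centroided scans pass through an intensity threshold only.  Profile
    scans are centroided at local maxima: each maximum above ``noise``
    contributes one centroid at the intensity-weighted mean m/z of its
    contiguous support (down to the neighbouring valleys).
    """
    mz, inten = scan.mz, scan.intensity
    if mz.size == 0:
        return np.empty(0), np.empty(0)
    if scan.centroided:
        keep = inten > noise
        return mz[keep], inten[keep]
    # profile mode: local maxima with weighted centroids
    out_mz, out_int = [], []
    n = mz.size
    i = 0
    while i < n:
        is_max = (i == 0 or inten[i] >= inten[i - 1]) and (
            i == n - 1 or inten[i] > inten[i + 1]
        )
        if is_max and inten[i] > noise:
            lo = i
            while lo > 0 and inten[lo - 1] < inten[lo]:
                lo -= 1
            hi = i
            while hi < n - 1 and inten[hi + 1] < inten[hi]:
                hi += 1
            seg_i = inten[lo:hi + 1]
            seg_m = mz[lo:hi + 1]
            out_mz.append(float(np.average(seg_m, weights=seg_i)))
            out_int.append(float(inten[i]))
            i = hi + 1
        else:
            i += 1
    return np.asarray(out_mz), np.asarray(out_int)


def build_chromatograms(
    scans: list[Scan], params: DetectionParams | None = None
) -> list[EIC]:
    """String per-scan centroids into EICs (ADAP-style greedy builder).

    Within each scan, centroids are taken highest-intensity first; each
    joins the open EIC whose representative m/z is nearest within
    ``mz_tol``, else seeds a new EIC.  Chromatograms untouched for more
    than one scan are closed (the group-size rule demands consecutive
    scans anyway).  An EIC is retained only if it has at least
    ``min_group_size`` points in consecutive scans above the group
    intensity threshold and a maximum above ``min_height``.
    """
    p = params or DetectionParams()
    rts = [s.rt for s in scans]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError("MS1 scans must be RT-ordered")

    max_gap = 1  # scans an EIC may miss before it is closed
    open_eics: list[dict] = []
    closed: list[dict] = []
    for scan_idx, scan in enumerate(scans):
        still_open = []
        for e in open_eics:
            (still_open if scan_idx - e["scan"][-1] <= max_gap else closed).append(e)
        open_eics = still_open
        mzs, ints = detect_mass_peaks(scan, p.ms1_noise)
        order = np.argsort(-ints, kind="stable")
        reps = (np.array([e["rep_mz"] for e in open_eics])
                if open_eics else np.empty(0))
        claimed: set[int] = set()
        for k in order:
            m, h = float(mzs[k]), float(ints[k])
            target = None
            if reps.size:
                d = np.abs(reps - m)
                cand = int(np.argmin(d))
                if d[cand] <= p.mz_tol and cand not in claimed:
                    target = cand
            if target is None:
                open_eics.append(
                    {"rep_mz": m, "rep_int": h, "rt": [scan.rt],
                     "mz": [m], "int": [h], "scan": [scan_idx]}
                )
                reps = np.append(reps, m)
                claimed.add(len(open_eics) - 1)
            else:
                e = open_eics[target]
                e["rt"].append(scan.rt)
                e["mz"].append(m)
                e["int"].append(h)
                e["scan"].append(scan_idx)
                claimed.add(target)
                if h > e["rep_int"]:
                    e["rep_int"] = h
                    e["rep_mz"] = m
                    reps[target] = m
    closed.extend(open_eics)

    out: list[EIC] = []
    for e in closed:
        ints = np.asarray(e["int"])
        scan_idx = np.asarray(e["scan"])
        if ints.max() < p.min_height:
            continue
        # longest run of consecutive scans above the group threshold
        above = ints > p.group_intensity_threshold
        best = run = 0
        prev = None
        for si, ok in zip(scan_idx, above):
            if ok and prev is not None and si == prev + 1:
                run += 1
            elif ok:
                run = 1
            else:
                run = 0
            best = max(best, run)
            prev = si
        if best < p.min_group_size:
            continue
        out.append(
            EIC(
                representative_mz=float(e["rep_mz"]),
                rts=np.asarray(e["rt"]),
                mzs=np.asarray(e["mz"]),
                intensities=ints,
                scan_indices=scan_idx,
            )
        )
    out.sort(key=lambda c: c.representative_mz)
    return out


def _split_points(eic: EIC, p: DetectionParams) -> list[int]:
    """Indices of local minima that are minimal within +-rt_search_range."""
    ints, rts = eic.intensities, eic.rts
    n = ints.size
    splits = []
    for i in range(1, n - 1):
        if not (ints[i] <= ints[i - 1] and ints[i] <= ints[i + 1]):
            continue
        window = (rts >= rts[i] - p.rt_search_range) & (
            rts <= rts[i] + p.rt_search_range
        )
        if ints[i] <= ints[window].min():
            splits.append(i)
    return splits


def deconvolve_local_minimum(
    eic: EIC, params: DetectionParams | None = None
) -> list[Feature]:
    """Split an EIC into chromatographic peaks at local minima.

    A candidate sub-peak survives iff its apex clears both the absolute
    (``min_abs_height``) and relative (``min_rel_height`` x EIC max)
    floors, its apex/edge ratio is at least ``top_edge_ratio`` on both
    sides, and its duration — measured over the peak body, the
    contiguous points around the apex above the
    ``1 - chrom_threshold`` intensity quantile of the segment — lies in
    the configured range.  Area is trapezoidal over the full segment.
    """
    p = params or DetectionParams()
    ints, rts, mzs = eic.intensities, eic.rts, eic.mzs
    if ints.size == 0:
        return []
    eic_max = float(ints.max())
    bounds = [0] + _split_points(eic, p) + [ints.size - 1]
    # a valley only resolves two peaks if both flanks clear the top/edge
    # ratio against it; weaker valleys merge their neighbours (shoulders)
    changed = True
    while changed and len(bounds) > 2:
        changed = False
        for k in range(1, len(bounds) - 1):
            v = float(ints[bounds[k]])
            left_max = float(ints[bounds[k - 1]:bounds[k] + 1].max())
            right_max = float(ints[bounds[k]:bounds[k + 1] + 1].max())
            if v > 0 and (left_max / v < p.top_edge_ratio
                          or right_max / v < p.top_edge_ratio):
                del bounds[k]
                changed = True
                break
    feats: list[Feature] = []
    for a, b in zip(bounds, bounds[1:]):
        seg = slice(a, b + 1)
        seg_int = ints[seg]
        if seg_int.size < 3:
            continue
        apex_rel = int(np.argmax(seg_int))
        apex = a + apex_rel
        height = float(ints[apex])
        if height < p.min_abs_height:
            continue
        if height < p.min_rel_height * eic_max:
            continue
        left_edge, right_edge = float(ints[a]), float(ints[b])
        if left_edge > 0 and height / left_edge < p.top_edge_ratio:
            continue
        if right_edge > 0 and height / right_edge < p.top_edge_ratio:
            continue
        # peak body: contiguous region around apex above the quantile
        q = float(np.quantile(seg_int, 1.0 - p.chrom_threshold))
        lo = apex_rel
        while lo > 0 and seg_int[lo - 1] >= q:
            lo -= 1
        hi = apex_rel
        while hi < seg_int.size - 1 and seg_int[hi + 1] >= q:
            hi += 1
        rt_start = float(rts[a + lo])
        rt_end = float(rts[a + hi])
        duration = rt_end - rt_start
        if not (p.duration_min <= duration <= p.duration_max):
            continue
        area = float(np.trapezoid(seg_int, rts[seg]))
        mz = float(np.average(mzs[seg], weights=seg_int))
        feats.append(
            Feature(
                id=0,
                mz=mz,
                rt_apex=float(rts[apex]),
                rt_start=rt_start,
                rt_end=rt_end,
                height=height,
                area=area,
            )
        )
    return feats


def pair_ms2(
    features: list[Feature],
    ms2_scans: list[Scan],
    params: DetectionParams | None = None,
) -> list[Feature]:
    """Attach data-dependent MS2 scans to features.

    An MS2 scan pairs with the feature whose m/z lies within
    ``ms2_pair_mz`` of the precursor and whose apex RT is within
    ``ms2_pair_rt``; ties break by smallest |dm/z| then smallest |dRT|.
    When several MS2 scans land on one feature, the one with the highest
    precursor intensity (falling back to summed fragment intensity)
    becomes the representative spectrum.
    """
    p = params or DetectionParams()
    best_per_feature: dict[int, tuple[float, Scan]] = {}
    counts: dict[int, int] = {}
    for scan in ms2_scans:
        if scan.precursor_mz is None:
            continue
        cands = []
        for idx, f in enumerate(features):
            dmz = abs(f.mz - scan.precursor_mz)
            drt = abs(f.rt_apex - scan.rt)
            if dmz <= p.ms2_pair_mz and drt <= p.ms2_pair_rt:
                cands.append((dmz, drt, idx))
        if not cands:
            continue
        _, _, idx = min(cands)
        counts[idx] = counts.get(idx, 0) + 1
        prio = (
            scan.precursor_intensity
            if scan.precursor_intensity is not None
            else float(scan.intensity.sum())
        )
        if idx not in best_per_feature or prio > best_per_feature[idx][0]:
            best_per_feature[idx] = (prio, scan)
    out = []
    for idx, f in enumerate(features):
        if idx in best_per_feature:
            spec = FragmentSpectrum.from_scan(best_per_feature[idx][1], f.id)
            out.append(replace(f, ms2=spec, n_ms2=counts[idx]))
        else:
            out.append(f)
    return out


def group_isotopes(
    features: list[Feature], params: DetectionParams | None = None
) -> list[Feature]:
    """Group co-eluting isotopologues and flag non-monoisotopic members.

    Features whose m/z differ by 1.00335/z (z in ``iso_charges``) within
    ``iso_mz_tol`` and whose apexes co-elute within ``iso_rt_tol`` join
    one isotope group; the lowest-m/z member is the monoisotopic
    representative.  Chains (A, A+1, A+2) group transitively.
    """
    p = params or DetectionParams()
    n = len(features)
    order = sorted(range(n), key=lambda i: features[i].mz)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for ii, i in enumerate(order):
        fi = features[i]
        for j in order[ii + 1:]:
            fj = features[j]
            dmz = fj.mz - fi.mz
            if dmz > C13_DELTA + p.iso_mz_tol:
                break
            if abs(fj.rt_apex - fi.rt_apex) > p.iso_rt_tol:
                continue
            if any(abs(dmz - C13_DELTA / z) <= p.iso_mz_tol
                   for z in p.iso_charges):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = list(features)
    for gid, members in enumerate(sorted(groups.values(),
                                         key=lambda m: features[m[0]].mz), 1):
        mono = min(members, key=lambda i: features[i].mz)
        for i in members:
            out[i] = replace(out[i], isotope_group=gid,
                             is_monoisotopic=(i == mono))
    return out


def _dedup_pass(
    feats: list[Feature], mz_tol: float, rt_tol: float
) -> list[Feature]:
    kept: list[Feature] = []
    for f in sorted(feats, key=lambda x: (-x.height, x.mz, x.rt_apex)):
        dup = any(
            abs(f.mz - k.mz) <= mz_tol and abs(f.rt_apex - k.rt_apex) <= rt_tol
            for k in kept
        )
        if not dup:
            kept.append(f)
    kept.sort(key=lambda x: (x.rt_apex, x.mz))
    return kept


def filter_duplicates(
    features: list[Feature], params: DetectionParams | None = None
) -> list[Feature]:
    """Remove duplicate rows in two sequential passes.

    Pass 1 ("single feature" style) merges rows within 0.001 Da and
    0.05 min; pass 2 ("old average" style) merges within 1 Da and
    0.05 min.  The taller row survives each merge; output order is by
    RT then m/z, deterministic.
    """
    p = params or DetectionParams()
    out = _dedup_pass(features, p.dup_mz_tol_1, p.dup_rt_tol_1)
    out = _dedup_pass(out, p.dup_mz_tol_2, p.dup_rt_tol_2)
    return out


def filter_rows_with_ms2(features: list[Feature]) -> list[Feature]:
    """Keep exactly the features that carry a paired MS2 spectrum."""
    return [f for f in features if f.ms2 is not None]


def detect_features(
    scans: list[Scan],
    params: DetectionParams | None = None,
    require_ms2: bool = True,
    sample: str = "sample",
) -> list[Feature]:
    """Run the full detection chain on one LC-MS/MS run.

    Returns the final feature table: deconvolved, MS2-paired,
    monoisotopic, deduplicated and (by default) restricted to rows with
    an MS2 spectrum.  Feature ids are assigned in (RT, m/z) order and
    are stable for a given input.
    """
    p = params or DetectionParams()
    ms1 = [s for s in scans if s.ms_level == 1]
    ms2 = [s for s in scans if s.ms_level == 2]
    feats: list[Feature] = []
    for eic in build_chromatograms(ms1, p):
        feats.extend(deconvolve_local_minimum(eic, p))
    feats.sort(key=lambda f: (f.rt_apex, f.mz))
    feats = group_isotopes(feats, p)
    feats = [f for f in feats if f.is_monoisotopic]
    feats = filter_duplicates(feats, p)
    for i, f in enumerate(feats, 1):
        f.id = i
        f.sample = sample
    feats = pair_ms2(feats, ms2, p)
    for f in feats:
        if f.ms2 is not None:
            f.ms2.feature_id = f.id
    if require_ms2:
        feats = filter_rows_with_ms2(feats)
    return feats
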