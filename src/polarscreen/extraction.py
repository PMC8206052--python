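"""Two-pass feature extraction for centroided LC-HRMS runs.

Pass 1 (untargeted): centroids are chained into extracted-ion chromatograms
(EICs), chromatographic peaks are detected above an absolute height threshold
(F1), co-eluting ion species whose m/z spacings match the common-organic-
molecule isotope model (tolerance 0.0025 Da + 7.0 ppm) or a configured adduct
shift are grouped into components with an inferred charge and neutral mass,
and components are binned across all runs by RT (F3, minutes) and mass
(F4, ppm) around running-median bin centers.  Bins below the post-untargeted
height filter (F5) are dropped.

Pass 2 (targeted/recursive): for every surviving feature and every run, an EIC
is re-extracted at the feature's median ion m/z +- F8 ppm — also in runs where
pass 1 found nothing — the peak closest to the feature's median RT is
integrated, the post-targeted (F6) and post-integration (F7) height filters
are applied, and all feature summaries are recomputed from the re-extracted
members.  The recursion both recovers peaks the untargeted pass missed and
makes the final feature list reproducible for repeated runs on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .core import (
    ADDUCT_SHIFTS,
    ISOTOPE_SPACING,
    PROTON_MASS,
    Feature,
    FeatureMember,
    SampleRun,
)

__all__ = [
    "FactorSettings",
    "ChromPeak",
    "IonComponent",
    "EIC",
    "build_eics",
    "detect_peaks",
    "group_ion_species",
    "align_features",
    "recursive_extraction",
    "extract_features",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FactorSettings:
    """The eight critical extraction factors F1-F8 plus fixed sub-tolerances.

    Defaults are the optimized robust setpoint of the workflow: F1 = 0 counts,
    F2 = 1, F3 = 0.87 min, F4 = 50 ppm, F5 = 0 counts, F6 = 5000 counts,
    F7 = 5000 counts, F8 = 10 ppm.
    """

    f1_abs_height_threshold: float = 0.0
    f2_max_charge: int = 1
    f3_rt_bin_tolerance: float = 0.87
    f4_mass_bin_tolerance_ppm: float = 50.0
    f5_post_untargeted_height_filter: float = 0.0
    f6_post_targeted_height_filter: float = 5000.0
    f7_post_integration_height_filter: float = 5000.0
    f8_eic_mz_tolerance_ppm: float = 10.0
    #: isotope peak-spacing tolerance, absolute Da + ppm of the ion m/z
    isotope_spacing_tolerance: tuple = (0.0025, 7.0)
    #: apex co-elution tolerance for ion grouping (min)
    coelution_rt_tolerance: float = 0.1
    #: adducts considered when grouping ion species (positive ESI)
    adducts: tuple = ("[M+H]+",)
    #: m/z tolerance for chaining centroids into untargeted EICs (ppm)
    untargeted_mz_tolerance_ppm: float = 20.0

    def __post_init__(self) -> None:
        numeric = (
            self.f1_abs_height_threshold,
            self.f3_rt_bin_tolerance,
            self.f4_mass_bin_tolerance_ppm,
            self.f5_post_untargeted_height_filter,
            self.f6_post_targeted_height_filter,
            self.f7_post_integration_height_filter,
            self.f8_eic_mz_tolerance_ppm,
        )
        if any(v < 0 for v in numeric):
            raise ValueError("factor settings must be non-negative")
        if self.f2_max_charge < 1:
            raise ValueError("maximum charge (F2) must be >= 1")
        if min(self.f3_rt_bin_tolerance, self.f4_mass_bin_tolerance_ppm,
               self.f8_eic_mz_tolerance_ppm) <= 0:
            raise ValueError("binning and EIC tolerances must be positive")


@dataclass
class EIC:
    """Extracted-ion chromatogram: co-sorted arrays of RT, m/z, intensity."""

    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class ChromPeak:
    """One integrated chromatographic peak in one sample."""

    sample_id: str
    apex_rt: float
    height: float
    area: float
    fwhm: float
    centroid_mz: float
    rt_start: float
    rt_end: float
    #: raw profile over the integration bounds (for peak-shape assessment)
    profile_rt: Optional[np.ndarray] = None
    profile_intensity: Optional[np.ndarray] = None


@dataclass
class IonComponent:
    """Co-eluting ion species (molecular ion, isotopes, adducts) of one sample."""

    sample_id: str
    peaks: list  # list[ChromPeak], sorted by m/z
    charge: int
    neutral_mass: float
    rt: float
    height: float
    has_isotope_pattern: bool = False

    @property
    def n_ions(self) -> int:
        return len(self.peaks)

    @property
    def mono_mz(self) -> float:
        return self.peaks[0].centroid_mz

    @property
    def mono_peak(self) -> ChromPeak:
        return self.peaks[0]


# --------------------------------------------------------------------------
# EIC construction
# --------------------------------------------------------------------------

def build_eics(run: SampleRun, mz_tolerance_ppm: float, max_scan_gap: int = 2) -> list[EIC]:
    """Greedily chain centroids across consecutive scans into EICs.

    Scans are the distinct RT values of the run.  A centroid joins the active
    EIC whose last m/z is nearest within ``+- mz_tolerance_ppm``, provided that
    EIC was last extended at most ``max_scan_gap`` scans ago; otherwise it
    starts a new EIC.  Each centroid belongs to exactly one EIC.
    """
    if len(run) == 0:
        return []
    rt = run.peaks["rt"].to_numpy()
    mz = run.peaks["mz"].to_numpy()
    inten = run.peaks["intensity"].to_numpy()

    scan_times, scan_index = np.unique(rt, return_inverse=True)
    order = np.lexsort((mz, scan_index))
    rt, mz, inten, scan_index = rt[order], mz[order], inten[order], scan_index[order]

    # active EICs tracked as parallel lists kept sorted by last m/z
    active_mz: list[float] = []
    active_last_scan: list[int] = []
    active_members: list[list[int]] = []
    finished: list[list[int]] = []

    boundaries = np.flatnonzero(np.diff(scan_index)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(rt)]))

    for s, e in zip(starts, ends):
        scan = int(scan_index[s])
        # retire stale EICs
        keep = [i for i, last in enumerate(active_last_scan) if scan - last <= max_scan_gap]
        if len(keep) != len(active_mz):
            retired = set(range(len(active_mz))) - set(keep)
            finished.extend(active_members[i] for i in retired)
            active_mz = [active_mz[i] for i in keep]
            active_last_scan = [active_last_scan[i] for i in keep]
            active_members = [active_members[i] for i in keep]

        claimed: set[int] = set()
        amz = np.asarray(active_mz)
        for idx in range(s, e):
            m = mz[idx]
            tol = mz_tolerance_ppm * 1e-6 * m
            best = -1
            if len(amz):
                j = int(np.searchsorted(amz, m))
                cand = [c for c in (j - 1, j) if 0 <= c < len(amz) and c not in claimed]
                if cand:
                    dists = [abs(amz[c] - m) for c in cand]
                    k = int(np.argmin(dists))
                    if dists[k] <= tol:
                        best = cand[k]
            if best >= 0:
                claimed.add(best)
                active_members[best].append(idx)
                active_last_scan[best] = scan
                # m/z of the trace is updated to the latest centroid
                active_mz[best] = m
            else:
                # insert new EIC keeping the active list sorted by m/z
                pos = int(np.searchsorted(np.asarray(active_mz), m))
                active_mz.insert(pos, m)
                active_last_scan.insert(pos, scan)
                active_members.insert(pos, [idx])
                claimed = {c + 1 if c >= pos else c for c in claimed}
            amz = np.asarray(active_mz)

    finished.extend(active_members)
    eics = []
    for members in finished:
        members = np.asarray(members)
        eics.append(
            EIC(
                rt=rt[members],
                mz=mz[members],
                intensity=inten[members],
                sample_id=run.sample_id,
            )
        )
    eics.sort(key=lambda e: (float(e.mz[0]), float(e.rt[0])))
    return eics


# --------------------------------------------------------------------------
# peak detection
# --------------------------------------------------------------------------

def detect_peaks(
    eic: EIC,
    f1_abs_height_threshold: float = 0.0,
    smooth_window: int = 3,
    keep_profile: bool = True,
) -> list[ChromPeak]:
    """Local-maximum peak detection on one EIC.

    The trace is lightly smoothed (moving average) for maximum finding; apex
    height is read from the raw trace and must strictly exceed the F1
    threshold.  Peak bounds are the prominence bases, FWHM is interpolated at
    half height, and the area is the trapezoid over the bounds.
    """
    n = len(eic)
    if n == 0:
        return []
    y = eic.intensity.astype(float)
    t = eic.rt
    if n < 3:
        apex = int(np.argmax(y))
        height = float(y[apex])
        if height <= f1_abs_height_threshold:
            return []
        dt = float(t[-1] - t[0]) if n > 1 else 0.004
        area = float(np.trapezoid(y, t)) if n > 1 else float(height * 0.004)
        return [
            ChromPeak(
                sample_id=eic.sample_id,
                apex_rt=float(t[apex]),
                height=height,
                area=area,
                fwhm=max(dt, 0.004),
                centroid_mz=float(np.average(eic.mz, weights=y)),
                rt_start=float(t[0]),
                rt_end=float(t[-1]),
                profile_rt=t.copy() if keep_profile else None,
                profile_intensity=y.copy() if keep_profile else None,
            )
        ]

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(y, kernel, mode="same")
    else:
        smoothed = y
    padded = np.concatenate(([0.0], smoothed, [0.0]))
    idx, _ = find_peaks(padded)
    idx = idx - 1
    if len(idx) == 0:
        return []

    dt = float(np.median(np.diff(t))) if n > 1 else 0.004
    widths_half = peak_widths(padded, idx + 1, rel_height=0.5)
    widths_base = peak_widths(padded, idx + 1, rel_height=0.97)

    peaks: list[ChromPeak] = []
    for k, i in enumerate(idx):
        lo = max(int(np.floor(widths_base[2][k] - 1)), 0)
        hi = min(int(np.ceil(widths_base[3][k] - 1)), n - 1)
        if hi <= lo:
            lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        apex = lo + int(np.argmax(y[lo : hi + 1]))
        height = float(y[apex])
        if height <= f1_abs_height_threshold:
            continue
        fwhm = max(float(widths_half[0][k]) * dt, dt)
        area = float(np.trapezoid(y[lo : hi + 1], t[lo : hi + 1]))
        seg = slice(lo, hi + 1)
        peaks.append(
            ChromPeak(
                sample_id=eic.sample_id,
                apex_rt=float(t[apex]),
                height=height,
                area=area,
                fwhm=fwhm,
                centroid_mz=float(np.average(eic.mz[seg], weights=np.maximum(y[seg], 1e-12))),
                rt_start=float(t[lo]),
                rt_end=float(t[hi]),
                profile_rt=t[seg].copy() if keep_profile else None,
                profile_intensity=y[seg].copy() if keep_profile else None,
            )
        )
    peaks.sort(key=lambda p: (p.centroid_mz, p.apex_rt))
    return peaks


# --------------------------------------------------------------------------
# ion-species grouping
# --------------------------------------------------------------------------

def _spacing_tolerance(mz: float, settings: FactorSettings) -> float:
    abs_da, ppm = settings.isotope_spacing_tolerance
    return abs_da + ppm * 1e-6 * mz


def group_ion_species(peaks: Sequence[ChromPeak], settings: FactorSettings) -> list[IonComponent]:
    """Merge co-eluting peaks related by isotope spacing or adduct shifts.

    Peaks whose apexes co-elute within the co-elution tolerance and whose m/z
    spacing matches ``k * 1.00336 / z`` (k = 1..3, z up to F2) within
    0.0025 Da + 7.0 ppm — or a configured adduct m/z difference — are merged
    into one component.  The neutral mass is inferred from the lowest-m/z ion
    assuming protonation at the inferred charge.  Unmatched peaks become
    single-ion components.
    """
    peaks = sorted(peaks, key=lambda p: (p.apex_rt, p.centroid_mz))
    if not peaks:
        return []
    n = len(peaks)
    parent = list(range(n))
    charge_of = [1] * n
    isotope_link = [False] * n

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    adduct_deltas = []
    shifts = [ADDUCT_SHIFTS[a] for a in settings.adducts if a in ADDUCT_SHIFTS]
    for i in range(len(shifts)):
        for j in range(i + 1, len(shifts)):
            adduct_deltas.append(abs(shifts[j] - shifts[i]))

    # cluster co-eluting peaks by chaining on apex RT
    cluster_start = 0
    clusters: list[range] = []
    for i in range(1, n + 1):
        if i == n or peaks[i].apex_rt - peaks[i - 1].apex_rt > settings.coelution_rt_tolerance:
            clusters.append(range(cluster_start, i))
            cluster_start = i

    for cluster in clusters:
        members = sorted(cluster, key=lambda i: peaks[i].centroid_mz)
        for a_pos, i in enumerate(members):
            mz_i = peaks[i].centroid_mz
            for j in members[a_pos + 1 :]:
                delta = peaks[j].centroid_mz - mz_i
                if delta > 3 * ISOTOPE_SPACING + 23.0:
                    break
                tol = _spacing_tolerance(mz_i, settings)
                matched = False
                for z in range(1, settings.f2_max_charge + 1):
                    for k in (1, 2, 3):
                        if abs(delta - k * ISOTOPE_SPACING / z) <= tol:
                            union(i, j)
                            charge_of[i] = charge_of[j] = z
                            isotope_link[i] = isotope_link[j] = True
                            matched = True
                            break
                    if matched:
                        break
                if not matched:
                    for d in adduct_deltas:
                        if abs(delta - d) <= tol:
                            union(i, j)
                            break

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    components: list[IonComponent] = []
    for indices in groups.values():
        group_peaks = sorted((peaks[i] for i in indices), key=lambda p: p.centroid_mz)
        charge = max(charge_of[i] for i in indices)
        has_iso = any(isotope_link[i] for i in indices)
        mono = group_peaks[0]
        tallest = max(group_peaks, key=lambda p: p.height)
        neutral = mono.centroid_mz * charge - charge * PROTON_MASS
        components.append(
            IonComponent(
                sample_id=mono.sample_id,
                peaks=group_peaks,
                charge=charge,
                neutral_mass=neutral,
                rt=tallest.apex_rt,
                height=tallest.height,
                has_isotope_pattern=has_iso,
            )
        )
    components.sort(key=lambda c: (c.neutral_mass, c.rt))
    return components


# --------------------------------------------------------------------------
# cross-run alignment (pass 1 binning)
# --------------------------------------------------------------------------

def align_features(
    components: Sequence[IonComponent], settings: FactorSettings
) -> list[Feature]:
    """Bin components across runs by RT (F3) and mass (F4) into features.

    Components are inserted in descending height order (ties: ascending mass,
    then RT); each joins the nearest bin whose running-median center lies
    within both tolerances, otherwise it opens a new bin.  Bin centers are
    re-computed as medians after every insertion.  Bins whose median height is
    below F5 are dropped.
    """
    order = sorted(
        range(len(components)),
        key=lambda i: (-components[i].height, components[i].neutral_mass, components[i].rt),
    )
    bin_members: list[list[IonComponent]] = []
    center_mass: list[float] = []
    center_rt: list[float] = []

    f3 = settings.f3_rt_bin_tolerance
    f4 = settings.f4_mass_bin_tolerance_ppm
    for i in order:
        comp = components[i]
        if bin_members:
            cm = np.asarray(center_mass)
            cr = np.asarray(center_rt)
            dmass_ppm = np.abs(comp.neutral_mass - cm) / cm * 1e6
            drt = np.abs(comp.rt - cr)
            ok = (dmass_ppm <= f4) & (drt <= f3)
            if ok.any():
                score = (dmass_ppm / f4) ** 2 + (drt / f3) ** 2
                score[~ok] = np.inf
                b = int(np.argmin(score))
                bin_members[b].append(comp)
                center_mass[b] = float(np.median([c.neutral_mass for c in bin_members[b]]))
                center_rt[b] = float(np.median([c.rt for c in bin_members[b]]))
                continue
        bin_members.append([comp])
        center_mass.append(comp.neutral_mass)
        center_rt.append(comp.rt)

    features: list[Feature] = []
    fid = 0
    for members in bin_members:
        heights = [c.height for c in members]
        if np.median(heights) < settings.f5_post_untargeted_height_filter:
            continue
        feature = Feature(feature_id=fid)
        for comp in members:
            feature.members.append(
                FeatureMember(
                    sample_id=comp.sample_id,
                    neutral_mass=comp.neutral_mass,
                    rt=comp.rt,
                    height=comp.height,
                    area=comp.mono_peak.area,
                    n_ions=comp.n_ions,
                    has_isotope_pattern=comp.has_isotope_pattern,
                    peak=comp.mono_peak,
                )
            )
        feature.refresh()
        feature.target_mass = feature.median_mass
        feature.target_mz = float(np.median([c.mono_mz for c in members]))
        feature.target_rt = feature.median_rt
        fid += 1
        feature.feature_id = fid
        features.append(feature)
    features.sort(key=lambda f: (f.median_mass, f.median_rt))
    for k, f in enumerate(features, start=1):
        f.feature_id = k
    return features


# --------------------------------------------------------------------------
# recursive (targeted) extraction — pass 2
# --------------------------------------------------------------------------

def _run_index(run: SampleRun):
    mz = run.peaks["mz"].to_numpy()
    order = np.argsort(mz, kind="mergesort")
    return (
        mz[order],
        run.peaks["rt"].to_numpy()[order],
        run.peaks["intensity"].to_numpy()[order],
    )


def recursive_extraction(
    features: Sequence[Feature],
    runs: Sequence[SampleRun],
    settings: FactorSettings,
) -> list[Feature]:
    """Targeted re-extraction of every feature in every run.

    For each (feature, run) pair an EIC at the feature's target ion m/z
    +- F8 ppm is assembled from the raw centroids, restricted to the RT window
    target RT +- F3, and the detected peak nearest the target RT is kept if it
    passes the post-targeted height filter (F6) and, after integration, the
    post-integration height filter (F7).  Feature summaries, including the
    per-run ion counts inherited from pass 1 where available, are then
    recomputed.  Features without any surviving member are dropped.
    """
    indexed = [(run, _run_index(run)) for run in runs]
    out: list[Feature] = []
    for feature in features:
        pass1 = {m.sample_id: m for m in feature.members}
        target_mz = feature.target_mz
        if not np.isfinite(target_mz):
            target_mz = feature.median_mass + PROTON_MASS
        tol = settings.f8_eic_mz_tolerance_ppm * 1e-6 * target_mz
        target_rt = feature.target_rt if np.isfinite(feature.target_rt) else feature.median_rt
        new_members: list[FeatureMember] = []
        for run, (mz_sorted, rt_sorted, int_sorted) in indexed:
            lo = int(np.searchsorted(mz_sorted, target_mz - tol))
            hi = int(np.searchsorted(mz_sorted, target_mz + tol, side="right"))
            if hi <= lo:
                continue
            rt_sel = rt_sorted[lo:hi]
            window = (rt_sel >= target_rt - settings.f3_rt_bin_tolerance) & (
                rt_sel <= target_rt + settings.f3_rt_bin_tolerance
            )
            if not window.any():
                continue
            rts = rt_sel[window]
            mzs = mz_sorted[lo:hi][window]
            ints = int_sorted[lo:hi][window]
            # collapse to one intensity per scan (sum of co-isolated centroids)
            order = np.argsort(rts, kind="mergesort")
            rts, mzs, ints = rts[order], mzs[order], ints[order]
            uniq, inverse = np.unique(rts, return_inverse=True)
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, ints)
            mz_weighted = np.zeros(len(uniq))
            np.add.at(mz_weighted, inverse, mzs * ints)
            with np.errstate(invalid="ignore"):
                mz_per_scan = np.where(summed > 0, mz_weighted / np.maximum(summed, 1e-300), target_mz)
            eic = EIC(rt=uniq, mz=mz_per_scan, intensity=summed, sample_id=run.sample_id)
            candidates = detect_peaks(eic, f1_abs_height_threshold=0.0)
            candidates = [p for p in candidates if p.height >= settings.f6_post_targeted_height_filter]
            if not candidates:
                continue
            best = min(candidates, key=lambda p: abs(p.apex_rt - target_rt))
            # post-integration height: Gaussian-equivalent height from the area
            sigma = best.fwhm / _FWHM_FACTOR
            integrated_height = best.area / (sigma * np.sqrt(2.0 * np.pi)) if sigma > 0 else best.height
            if min(best.height, integrated_height) < settings.f7_post_integration_height_filter:
                continue
            prior = pass1.get(run.sample_id)
            new_members.append(
                FeatureMember(
                    sample_id=run.sample_id,
                    neutral_mass=best.centroid_mz - PROTON_MASS,
                    rt=best.apex_rt,
                    height=best.height,
                    area=best.area,
                    n_ions=prior.n_ions if prior is not None else 1,
                    has_isotope_pattern=prior.has_isotope_pattern if prior is not None else False,
                    peak=best,
                )
            )
        if not new_members:
            continue
        refined = Feature(
            feature_id=feature.feature_id,
            members=new_members,
            target_mass=feature.target_mass,
        )
        refined.refresh()
        refined.target_mz = float(np.median([m.peak.centroid_mz for m in new_members]))
        refined.target_rt = refined.median_rt
        out.append(refined)
    # two pass-1 bins can converge onto (nearly) the same peaks during the
    # targeted pass; collapse features whose summaries coincide, keeping the
    # better-populated one
    out.sort(key=lambda f: (-len(f.members), -f.median_intensity, f.median_mass))
    unique: list[Feature] = []
    for f in out:
        redundant = any(
            abs(f.median_mass - u.median_mass) / u.median_mass * 1e6 < 1.0
            and abs(f.median_rt - u.median_rt) < 0.05
            for u in unique
        )
        if not redundant:
            unique.append(f)
    out = unique
    out.sort(key=lambda f: (f.median_mass, f.median_rt))
    for k, f in enumerate(out, start=1):
        f.feature_id = k
    return out


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def untargeted_components(run: SampleRun, settings: FactorSettings) -> list[IonComponent]:
    """Pass-1 per-run stages: EICs -> peak detection -> ion grouping."""
    eics = build_eics(run, settings.untargeted_mz_tolerance_ppm)
    peaks: list[ChromPeak] = []
    for eic in eics:
        peaks.extend(detect_peaks(eic, settings.f1_abs_height_threshold))
    return group_ion_species(peaks, settings)


def extract_features(runs: Sequence[SampleRun], settings: FactorSettings) -> list[Feature]:
    """Full two-pass extraction over a set of runs (deterministic)."""
    components: list[IonComponent] = []
    for run in runs:
        components.extend(untargeted_components(run, settings))
    pass1 = align_features(components, settings)
    return recursive_extraction(pass1, runs, settings)
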