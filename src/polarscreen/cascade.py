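"""Hidden-target identification chain for HILIC-eluting features.

The cascade only ever removes features: masses also present in the processed
pure-water blank are excluded (mass-only, no RT condition), features eluting
after the HILIC/RPLC transition are cut at 17.0 min (boundary inclusive —
metformin, the last polar standard, elutes exactly there), features seen in
fewer than three distinct water samples are dropped, the survivors are matched
against a compound database by accurate neutral mass +- 10 ppm, matches are
restricted to polar compounds (log D < 0 at pH 7, strict), and candidate
features must pass four peak-quality criteria.  Confirmation against a
reference standard requires |dRT| < 5% and |dm| < 5 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import (
    CompoundRecord,
    Feature,
    percent_rt_deviation,
    ppm_difference,
)

__all__ = [
    "FilterReport",
    "CandidateMatch",
    "QualityReport",
    "ConfirmationResult",
    "exclude_blank_masses",
    "filter_rt_window",
    "filter_detection_frequency",
    "match_database",
    "filter_logd",
    "assess_peak_quality",
    "filter_quality",
    "dedupe_candidates",
    "confirm_with_standard",
    "best_feature_for_standard",
    "spatial_report",
    "matches_to_table",
]


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the cascade (counts never increase)."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, note: str = "") -> None:
        if self.stages and n_in > self.stages[-1]["n_out"]:
            raise ValueError("cascade stages must not create features")
        if n_out > n_in:
            raise ValueError(f"stage {stage} increased the feature count")
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out, "note": note})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out", "note"])


@dataclass
class CandidateMatch:
    """A feature paired with a database compound within the mass tolerance."""

    feature: Feature
    record: CompoundRecord
    ppm: float
    passes_logd: Optional[bool] = None


def exclude_blank_masses(
    features: Sequence[Feature],
    blank_features: Sequence[Feature],
    mass_tolerance_ppm: float = 50.0,
    report: Optional[FilterReport] = None,
) -> list[Feature]:
    """Drop sample features whose median mass matches any blank mass.

    The exclusion is mass-only — a blank mass removes the feature regardless
    of its RT — and the tolerance defaults to the binning mass tolerance F4.
    """
    blank_masses = np.array(sorted(f.median_mass for f in blank_features))
    kept = []
    for f in features:
        if len(blank_masses):
            tol = mass_tolerance_ppm * 1e-6 * f.median_mass
            i = np.searchsorted(blank_masses, f.median_mass)
            near = [blank_masses[j] for j in (i - 1, i) if 0 <= j < len(blank_masses)]
            if near and min(abs(b - f.median_mass) for b in near) <= tol:
                continue
        kept.append(f)
    if report is not None:
        report.add("blank_exclusion", len(features), len(kept),
                   f"mass-only, +-{mass_tolerance_ppm:g} ppm")
    return kept


def filter_rt_window(
    features: Sequence[Feature],
    cutoff: float = 17.0,
    report: Optional[FilterReport] = None,
) -> list[Feature]:
    """Keep features with median RT <= cutoff (HILIC window, inclusive)."""
    kept = [f for f in features if f.median_rt <= cutoff]
    if report is not None:
        report.add("rt_window", len(features), len(kept), f"median RT <= {cutoff:g} min")
    return kept


def filter_detection_frequency(
    features: Sequence[Feature],
    min_samples: int = 3,
    report: Optional[FilterReport] = None,
) -> list[Feature]:
    """Keep features detected in at least ``min_samples`` distinct samples."""
    kept = [f for f in features if f.n_samples >= min_samples]
    if report is not None:
        report.add("detection_frequency", len(features), len(kept),
                   f">= {min_samples} samples")
    return kept


def match_database(
    features: Sequence[Feature],
    db: Sequence[CompoundRecord],
    tolerance_ppm: float = 10.0,
) -> list[CandidateMatch]:
    """All (feature, compound) pairs within ``+- tolerance_ppm`` accurate mass.

    One feature may match several compounds and one compound several features.
    Raises ``ValueError`` on an empty database.
    """
    db = list(db)
    if not db:
        raise ValueError("compound database is empty")
    db_sorted = sorted(db, key=lambda r: r.monoisotopic_mass)
    masses = np.array([r.monoisotopic_mass for r in db_sorted])
    matches: list[CandidateMatch] = []
    for f in features:
        tol = tolerance_ppm * 1e-6 * f.median_mass
        lo = int(np.searchsorted(masses, f.median_mass - tol))
        hi = int(np.searchsorted(masses, f.median_mass + tol, side="right"))
        for r in db_sorted[lo:hi]:
            ppm = ppm_difference(f.median_mass, r.monoisotopic_mass)
            assert abs(ppm) <= tolerance_ppm
            matches.append(CandidateMatch(feature=f, record=r, ppm=ppm))
    return matches


def filter_logd(
    matches: Sequence[CandidateMatch],
    threshold: float = 0.0,
    report: Optional[FilterReport] = None,
) -> list[CandidateMatch]:
    """Keep matches whose compound has log D(pH 7) strictly below ``threshold``.

    Records without a log D value cannot be assessed: they are flagged,
    excluded, and noted in the report.
    """
    kept: list[CandidateMatch] = []
    n_missing = 0
    for m in matches:
        logd = m.record.logd_ph7
        if logd is None or (isinstance(logd, float) and np.isnan(logd)):
            m.passes_logd = False
            n_missing += 1
            continue
        m.passes_logd = logd < threshold
        if m.passes_logd:
            kept.append(m)
    if report is not None:
        note = f"log D < {threshold:g} at pH 7"
        if n_missing:
            note += f"; {n_missing} match(es) dropped for missing log D"
        report.add(
            "logd_filter",
            len({id(m.feature) for m in matches}),
            len({id(m.feature) for m in kept}),
            note,
        )
    return kept


# --------------------------------------------------------------------------
# peak quality
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityReport:
    """The four acceptance criteria for a candidate feature."""

    mass_spread_ok: bool
    gaussian_ok: bool
    min_two_ions_ok: bool
    isotope_pattern_ok: bool

    @property
    def overall(self) -> bool:
        return (
            self.mass_spread_ok
            and self.gaussian_ok
            and self.min_two_ions_ok
            and self.isotope_pattern_ok
        )


def _gaussian_fit_r2(rt: np.ndarray, intensity: np.ndarray) -> float:
    if len(rt) < 4 or intensity.max() <= 0:
        return 0.0

    def gauss(t, height, mu, sigma):
        return height * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    p0 = (float(intensity.max()), float(rt[np.argmax(intensity)]),
          max(float(rt[-1] - rt[0]) / 4.0, 1e-3))
    try:
        popt, _ = curve_fit(gauss, rt, intensity, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        return 0.0
    resid = intensity - gauss(rt, *popt)
    sst = float(np.sum((intensity - intensity.mean()) ** 2))
    if sst == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / sst


def assess_peak_quality(
    feature: Feature,
    mass_spread_limit_ppm: float = 10.0,
    gaussian_r2_min: float = 0.8,
) -> QualityReport:
    """Evaluate the four acceptance criteria on one feature.

    mass spread: every member mass within ``+- mass_spread_limit_ppm`` of the
    median; Gaussian shape: R^2 of a Gaussian fit to the tallest member's
    profile at least ``gaussian_r2_min``; at least two ions in the composite
    spectrum; at least one member with an isotope partner.
    """
    masses = np.array([m.neutral_mass for m in feature.members])
    spread_ppm = (masses.max() - masses.min()) / feature.median_mass * 1e6
    spread_ok = bool(spread_ppm < mass_spread_limit_ppm)
    best_member = max(feature.members, key=lambda m: m.height)
    peak = best_member.peak
    if peak is not None and getattr(peak, "profile_rt", None) is not None:
        r2 = _gaussian_fit_r2(np.asarray(peak.profile_rt), np.asarray(peak.profile_intensity))
        gaussian_ok = bool(r2 >= gaussian_r2_min)
    else:
        gaussian_ok = False
    return QualityReport(
        mass_spread_ok=spread_ok,
        gaussian_ok=gaussian_ok,
        min_two_ions_ok=bool(feature.n_ions >= 2),
        isotope_pattern_ok=bool(feature.has_isotope_pattern),
    )


def filter_quality(
    matches: Sequence[CandidateMatch],
    report: Optional[FilterReport] = None,
    **kwargs,
) -> list[CandidateMatch]:
    """Drop matches whose feature fails the overall quality assessment."""
    verdicts: dict[int, bool] = {}
    kept = []
    for m in matches:
        key = id(m.feature)
        if key not in verdicts:
            verdicts[key] = assess_peak_quality(m.feature, **kwargs).overall
        if verdicts[key]:
            kept.append(m)
    if report is not None:
        report.add(
            "peak_quality",
            len({id(m.feature) for m in matches}),
            len({id(m.feature) for m in kept}),
            "four acceptance criteria",
        )
    return kept


# --------------------------------------------------------------------------
# candidate accounting, confirmation, spatial reporting
# --------------------------------------------------------------------------

def matches_to_table(matches: Sequence[CandidateMatch]) -> pd.DataFrame:
    """Candidate report in the documented layout (one row per match)."""
    rows = []
    for m in matches:
        rows.append(
            {
                "detected_median_mass": m.feature.median_mass,
                "detected_mean_rt_min": m.feature.median_rt,
                "n_samples": m.feature.n_samples,
                "rsd_rt_pct": (
                    m.feature.rt_span / m.feature.median_rt * 100.0
                    if m.feature.median_rt > 0
                    else 0.0
                ),
                "compound_name": m.record.name,
                "inchikey": m.record.inchikey,
                "rel_mass_diff_ppm": m.ppm,
                "logd_ph7": m.record.logd_ph7,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "detected_median_mass",
            "detected_mean_rt_min",
            "n_samples",
            "rsd_rt_pct",
            "compound_name",
            "inchikey",
            "rel_mass_diff_ppm",
            "logd_ph7",
        ],
    )


def dedupe_candidates(matches) -> tuple[int, int, pd.DataFrame]:
    """Count distinct candidate compounds and distinct features.

    Compounds are distinct by InChIKey; features by their (median mass,
    median RT) identity.  Accepts either a list of :class:`CandidateMatch` or
    a DataFrame with columns ``inchikey, detected_median_mass,
    detected_mean_rt_min``.  Returns ``(n_compounds, n_features, table)``.
    """
    if isinstance(matches, pd.DataFrame):
        table = matches
    else:
        table = matches_to_table(matches)
    if table.empty:
        return 0, 0, table
    n_compounds = table["inchikey"].nunique()
    n_features = len(
        table[["detected_median_mass", "detected_mean_rt_min"]].drop_duplicates()
    )
    return int(n_compounds), int(n_features), table


@dataclass(frozen=True)
class ConfirmationResult:
    """RT/mass agreement of a feature with its reference standard."""

    delta_rt_pct: float
    delta_mass_ppm: float

    @property
    def confirmed(self) -> bool:
        return abs(self.delta_rt_pct) < 5.0 and abs(self.delta_mass_ppm) < 5.0


def confirm_with_standard(
    feature_mass: float,
    feature_rt: float,
    reference_rt: float,
    reference_mass: float,
) -> ConfirmationResult:
    """Compare a detected feature with a measured reference standard.

    Confirmed iff the RT deviation is below 5% of the reference RT and the
    mass difference below 5 ppm (both strict).
    """
    return ConfirmationResult(
        delta_rt_pct=percent_rt_deviation(feature_rt, reference_rt),
        delta_mass_ppm=ppm_difference(feature_mass, reference_mass),
    )


def best_feature_for_standard(
    candidates: Sequence[tuple],
    reference_rt: float,
    reference_mass: float,
) -> tuple:
    """Pick the candidate (mass, rt) pair best matching the standard.

    When several features were assigned the same compound, the feature with
    the smallest |RT deviation| is designated best; ties go to the smallest
    |mass difference|.  Returns ``(index, ConfirmationResult)``.
    """
    if not candidates:
        raise ValueError("no candidate features supplied")
    results = [
        confirm_with_standard(mass, rt, reference_rt, reference_mass)
        for mass, rt in candidates
    ]
    best = min(
        range(len(results)),
        key=lambda i: (abs(results[i].delta_rt_pct), abs(results[i].delta_mass_ppm)),
    )
    return best, results[best]


def spatial_report(
    features: Sequence[Feature],
    manifest: pd.DataFrame,
    split_location: int,
) -> pd.DataFrame:
    """Per-feature detection counts and the downstream/upstream intensity ratio.

    Locations with id <= ``split_location`` count as upstream.  The ratio is
    median downstream member intensity over median upstream member intensity;
    features never detected upstream are flagged ``downstream_only`` and carry
    no ratio.  Raises on sample ids absent from the manifest.
    """
    meta = manifest.set_index("sample_id")
    rows = []
    for f in features:
        up, down = [], []
        by_date: dict[str, int] = {}
        for m in f.members:
            if m.sample_id not in meta.index:
                raise KeyError(f"sample {m.sample_id!r} not in manifest")
            loc = int(meta.loc[m.sample_id, "location_id"])
            date = str(meta.loc[m.sample_id, "campaign_date"])
            by_date[date] = by_date.get(date, 0) + 1
            (up if loc <= split_location else down).append(m.height)
        ratio = float(np.median(down) / np.median(up)) if up and down else np.nan
        rows.append(
            {
                "feature_id": f.feature_id,
                "median_mass": f.median_mass,
                "median_rt": f.median_rt,
                "n_upstream": len(up),
                "n_downstream": len(down),
                "downstream_only": bool(down and not up),
                "intensity_ratio": ratio,
                "detections_by_date": ";".join(f"{d}:{n}" for d, n in sorted(by_date.items())),
            }
        )
    return pd.DataFrame(rows)
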