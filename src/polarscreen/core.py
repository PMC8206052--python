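"""Elemental-formula arithmetic and shared domain types for LC-HRMS screening.

Conventions used throughout the package:

* masses are monoisotopic and expressed in daltons (Da);
* retention times (RT) are in minutes;
* signal intensities are detector counts;
* features carry *neutral* monoisotopic masses — singly protonated ions are
  converted by subtracting the proton mass — because the compound database
  stores neutral masses and matching happens on that scale;
* relative mass deviations are signed ppm, ``(observed - reference) /
  reference * 1e6``;
* values quoted in reports are rounded half-away-from-zero (so 1.75 ppm
  prints as 1.8 and -2.35 ppm as -2.4) while internal computation keeps full
  double precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ISOTOPE_SPACING",
    "ADDUCT_SHIFTS",
    "ElementalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "ppm_difference",
    "percent_rt_deviation",
    "round_reported",
    "CentroidPeak",
    "SampleRun",
    "CompoundRecord",
    "FeatureMember",
    "Feature",
]

# Most-abundant-isotope masses (Da), CODATA/IUPAC, fixed to 8+ decimals so that
# computed monoisotopic masses do not depend on any external library version.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "B": 11.00930540,
    "C": 12.0,
    "N": 14.00307400480,
    "O": 15.99491461956,
    "F": 18.99840322,
    "Na": 22.98976928,
    "Si": 27.97692653250,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Br": 78.91833710,
    "I": 126.90447300,
}

PROTON_MASS = 1.00727646688  # Da
ELECTRON_MASS = 0.00054857991  # Da
#: m/z spacing of the M+1 isotopologue per unit charge ("common organic
#: molecule" model used for isotope grouping).
ISOTOPE_SPACING = 1.00336

#: m/z shift of the ionized species relative to the neutral molecule for the
#: positive-ESI adducts considered here (charge 1).
ADDUCT_SHIFTS: Mapping[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,
    "[M+NH4]+": MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"] - ELECTRON_MASS,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count mapping of a neutral molecular formula.

    Counts are strictly positive integers; elements with zero count are simply
    absent.  The empty formula is allowed as the additive identity.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise FormulaError(f"count for {element} must be a positive integer, got {n!r}")
            clean[element] = int(n)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def to_string(self) -> str:
        """Canonical Hill-notation string: C, H, then other elements A-Z."""
        symbols = []
        if "C" in self.counts:
            symbols.append("C")
            if "H" in self.counts:
                symbols.append("H")
            symbols.extend(sorted(e for e in self.counts if e not in ("C", "H")))
        else:
            symbols.extend(sorted(self.counts))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in symbols
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation-like formula string, e.g. ``"C2H6N4O"``.

    An omitted count means 1.  Repeated element symbols are summed.  Raises
    :class:`FormulaError` for unknown symbols, explicit zero counts, or any
    text that is not a sequence of element tokens.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    stripped = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(stripped):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Neutral monoisotopic mass in Da (empty formula -> 0.0)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(n * MONOISOTOPIC_MASS[e] for e, n in formula.counts.items())


def ppm_difference(observed: float, reference: float) -> float:
    """Signed relative mass difference in ppm; ``reference`` must be > 0."""
    if reference <= 0:
        raise ValueError(f"reference mass must be positive, got {reference}")
    return (observed - reference) / reference * 1e6


def percent_rt_deviation(observed: float, reference: float) -> float:
    """Signed RT deviation in percent of the reference RT (must be > 0)."""
    if reference <= 0:
        raise ValueError(f"reference RT must be positive, got {reference}")
    return (observed - reference) / reference * 100.0


def round_reported(value: float, ndigits: int = 1) -> float:
    """Round half-away-from-zero, as table values are quoted."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# campaign data containers
# --------------------------------------------------------------------------

PEAK_COLUMNS = ("rt", "mz", "intensity")


@dataclass(frozen=True)
class CentroidPeak:
    """One centroided (m/z, RT, intensity) point in one sample run."""

    mz: float
    rt: float
    intensity: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be non-negative, got {self.rt}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass
class SampleRun:
    """A single LC-HRMS run: metadata plus its centroid peak list.

    Peaks are held as a DataFrame with columns ``rt, mz, intensity`` sorted by
    (rt, mz); this is the in-memory form every extraction stage operates on.
    """

    sample_id: str
    location_id: int = 0
    campaign_date: str = ""
    is_blank: bool = False
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.peaks, columns=list(PEAK_COLUMNS)).astype(float)
        self.peaks = df.sort_values(["rt", "mz"], kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_centroids(cls, sample_id: str, centroids: Iterable[CentroidPeak], **meta) -> "SampleRun":
        rows = [(p.rt, p.mz, p.intensity) for p in centroids]
        return cls(sample_id, peaks=pd.DataFrame(rows, columns=list(PEAK_COLUMNS)), **meta)

    def iter_peaks(self) -> Iterable[CentroidPeak]:
        for row in self.peaks.itertuples(index=False):
            yield CentroidPeak(mz=row.mz, rt=row.rt, intensity=row.intensity, sample_id=self.sample_id)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CompoundRecord:
    """One entry of the local compound database.

    ``logd_ph7`` is the octanol-water distribution coefficient at pH 7 as
    supplied by the database; it is never predicted here.  When a formula is
    given, the stored monoisotopic mass must agree with it within 1 mDa.
    """

    name: str
    inchikey: str
    monoisotopic_mass: float
    logd_ph7: Optional[float] = None
    formula: Optional[ElementalFormula] = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"monoisotopic mass must be positive ({self.name})")
        if self.formula is not None and self.formula:
            expected = monoisotopic_mass(self.formula)
            if abs(expected - self.monoisotopic_mass) > 0.001:
                raise ValueError(
                    f"{self.name}: stored mass {self.monoisotopic_mass} disagrees with "
                    f"formula {self.formula.to_string()} ({expected:.4f})"
                )


@dataclass
class FeatureMember:
    """Per-sample contribution to a feature: one integrated chromatographic peak."""

    sample_id: str
    neutral_mass: float
    rt: float
    height: float
    area: float = 0.0
    n_ions: int = 1
    has_isotope_pattern: bool = False
    peak: object = None  # ChromPeak of the monoisotope ion, if available


@dataclass
class Feature:
    """A cross-sample compound bin.

    Summary statistics are the medians over the member peaks; ``target_mass``
    is the neutral mass the targeted (recursive) extraction pass aimed at.
    """

    feature_id: int
    members: list = field(default_factory=list)
    target_mass: float = np.nan
    target_mz: float = np.nan
    target_rt: float = np.nan

    # derived summaries (filled by refresh())
    median_mass: float = np.nan
    median_rt: float = np.nan
    median_intensity: float = np.nan
    n_samples: int = 0
    rt_span: float = 0.0
    mass_rsd_pct: float = 0.0
    n_ions: int = 0
    has_isotope_pattern: bool = False

    def refresh(self) -> "Feature":
        """Recompute all summary statistics from the current members."""
        if not self.members:
            self.median_mass = self.median_rt = self.median_intensity = np.nan
            self.n_samples = 0
            self.rt_span = self.mass_rsd_pct = 0.0
            self.n_ions = 0
            self.has_isotope_pattern = False
            return self
        masses = np.array([m.neutral_mass for m in self.members])
        rts = np.array([m.rt for m in self.members])
        heights = np.array([m.height for m in self.members])
        self.median_mass = float(np.median(masses))
        self.median_rt = float(np.median(rts))
        self.median_intensity = float(np.median(heights))
        self.n_samples = len({m.sample_id for m in self.members})
        self.rt_span = float(rts.max() - rts.min())
        if len(masses) > 1:
            self.mass_rsd_pct = float(np.std(masses, ddof=1) / np.mean(masses) * 100.0)
        else:
            self.mass_rsd_pct = 0.0
        self.n_ions = int(max(m.n_ions for m in self.members))
        self.has_isotope_pattern = any(m.has_isotope_pattern for m in self.members)
        return self

    @property
    def sample_ids(self) -> list[str]:
        return sorted({m.sample_id for m in self.members})

    def member_for(self, sample_id: str) -> Optional[FeatureMember]:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        return None


def features_to_frame(features: Sequence[Feature]) -> pd.DataFrame:
    """Tabulate features in the documented report layout."""
    rows = []
    for f in features:
        rows.append(
            {
                "feature_id": f.feature_id,
                "median_mass": f.median_mass,
                "median_rt": f.median_rt,
                "median_intensity": f.median_intensity,
                "n_samples": f.n_samples,
                "rt_span": f.rt_span,
                "mass_rsd_pct": f.mass_rsd_pct,
                "n_ions": f.n_ions,
                "has_isotope_pattern": f.has_isotope_pattern,
                "sample_ids": ";".join(f.sample_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "median_mass",
            "median_rt",
            "median_intensity",
            "n_samples",
            "rt_span",
            "mass_rsd_pct",
            "n_ions",
            "has_isotope_pattern",
            "sample_ids",
        ],
    )
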