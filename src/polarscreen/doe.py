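"""Plackett-Burman screening of the extraction factors with a robust setpoint.

The eight extraction factors F1-F8 are varied over a two-level Plackett-Burman
base design (optionally with center-point replicates), feature extraction is
run per design row, and six response statistics are computed from each run's
feature list:

R1  median RT span of the peaks binned into a feature (min)
R2  median relative standard deviation of masses within a feature (%)
R3  fraction of single-ion features
R4  median |median mass - target mass| of the recursive pass (ppm)
R5  number of probe features with an erroneously integrated peak (of 10)
R6  number of probe features with a missed peak (of 10)

Each response is fitted by ordinary least squares on the coded factors (main
effects only — a screening design supports no interactions), diagnosed by R^2
and leave-one-out Q^2, and the fitted models drive a Derringer-Suich
desirability search for a *robust* setpoint: the factor-grid point of maximal
overall desirability whose Monte-Carlo predicted responses exceed their
specification limits with probability at most the acceptance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Feature, ppm_difference
from .extraction import FactorSettings, extract_features

__all__ = [
    "FactorSpec",
    "DesignPlan",
    "ResponseVector",
    "ProbeFeature",
    "ProbeSet",
    "FittedResponseModel",
    "DesirabilitySpec",
    "RobustSetpointResult",
    "RESPONSE_NAMES",
    "default_factor_specs",
    "generate_screening_design",
    "settings_from_row",
    "compute_responses",
    "evaluate_design",
    "fit_response_models",
    "desirability",
    "overall_desirability",
    "specs_from_responses",
    "find_robust_setpoint",
    "factor_contributions",
    "probe_from_ledger",
]

RESPONSE_NAMES = ("r1_median_rt_span", "r2_median_mass_rsd", "r3_single_ion_fraction",
                  "r4_median_target_mass_diff", "r5_erroneous_integrations", "r6_missed_peaks")

#: cyclic first rows of the Plackett-Burman two-level designs (1946)
PB_GENERATORS: Mapping[int, str] = {
    12: "++-+++---+-",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}


@dataclass(frozen=True)
class FactorSpec:
    """One extraction factor with its native low/high bounds for the design."""

    name: str
    low: float
    high: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")

    def to_native(self, coded: float) -> float:
        value = (self.low + self.high) / 2.0 + coded * (self.high - self.low) / 2.0
        return float(round(value)) if self.integer else float(value)


def default_factor_specs() -> list[FactorSpec]:
    """Default screening ranges for F1-F8 (counts, charge, min, ppm)."""
    return [
        FactorSpec("f1_abs_height_threshold", 0.0, 20000.0),
        FactorSpec("f2_max_charge", 1, 2, integer=True),
        FactorSpec("f3_rt_bin_tolerance", 0.1, 1.5),
        FactorSpec("f4_mass_bin_tolerance_ppm", 5.0, 50.0),
        FactorSpec("f5_post_untargeted_height_filter", 0.0, 20000.0),
        FactorSpec("f6_post_targeted_height_filter", 0.0, 20000.0),
        FactorSpec("f7_post_integration_height_filter", 0.0, 20000.0),
        FactorSpec("f8_eic_mz_tolerance_ppm", 2.0, 20.0),
    ]


@dataclass
class DesignPlan:
    """Runs x factors design in coded units (-1/0/+1) with center flags."""

    coded: pd.DataFrame  # index: run ids, columns: factor names
    factors: list  # list[FactorSpec], same order as columns
    center_flags: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    def native(self) -> pd.DataFrame:
        data = {
            spec.name: [spec.to_native(c) for c in self.coded[spec.name]]
            for spec in self.factors
        }
        return pd.DataFrame(data, index=self.coded.index)


def generate_screening_design(
    factors: Sequence[FactorSpec],
    n_center: int = 4,
    base: Optional[int] = None,
) -> DesignPlan:
    """Build a PB base design plus ``n_center`` all-zero center rows.

    ``base`` selects the PB run count (12, 20 or 24); by default the smallest
    base accommodating the factors is chosen.  The workflow preset for eight
    factors is ``base=24, n_center=4`` — an experimental plan of 28 runs.
    """
    factors = list(factors)
    k = len(factors)
    if base is None:
        for candidate in sorted(PB_GENERATORS):
            if candidate - 1 >= k:
                base = candidate
                break
    if base not in PB_GENERATORS:
        raise ValueError(f"unsupported PB base {base}; choose from {sorted(PB_GENERATORS)}")
    if k > base - 1:
        raise ValueError(f"PB-{base} supports at most {base - 1} factors, got {k}")
    gen = np.array([1 if ch == "+" else -1 for ch in PB_GENERATORS[base]])
    rows = [np.roll(gen, i) for i in range(base - 1)]
    rows.append(-np.ones(base - 1, dtype=int))
    matrix = np.array(rows)[:, :k]
    if n_center:
        matrix = np.vstack([matrix, np.zeros((n_center, k), dtype=int)])
    run_ids = [f"N{i + 1}" for i in range(len(matrix))]
    coded = pd.DataFrame(matrix, index=run_ids, columns=[f.name for f in factors], dtype=float)
    center = np.zeros(len(matrix), dtype=bool)
    center[base:] = True
    return DesignPlan(coded=coded, factors=factors, center_flags=center)


def settings_from_row(row: Mapping[str, float], **fixed) -> FactorSettings:
    """Native design-row values -> FactorSettings (integer charge rounded)."""
    values = dict(row)
    if "f2_max_charge" in values:
        values["f2_max_charge"] = int(round(values["f2_max_charge"]))
    return FactorSettings(**values, **fixed)


# --------------------------------------------------------------------------
# responses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseVector:
    r1_median_rt_span: float
    r2_median_mass_rsd: float
    r3_single_ion_fraction: float
    r4_median_target_mass_diff: float
    r5_erroneous_integrations: int
    r6_missed_peaks: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in RESPONSE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in RESPONSE_NAMES}


@dataclass(frozen=True)
class ProbeFeature:
    """Ground-truth coordinates of one probe compound across the samples."""

    probe_id: str
    neutral_mass: float
    base_rt: float
    #: sample_id -> (apex_rt, rt_start, rt_end, height)
    truth: Mapping[str, tuple]


@dataclass(frozen=True)
class ProbeSet:
    """Exactly ten reference features spanning broad mass and RT ranges."""

    entries: tuple

    def __post_init__(self) -> None:
        if len(self.entries) != 10:
            raise ValueError(f"a probe set holds exactly 10 features, got {len(self.entries)}")

    def __iter__(self):
        return iter(self.entries)


def probe_from_ledger(
    ledger: pd.DataFrame,
    sample_ids: Sequence[str],
    n: int = 10,
) -> ProbeSet:
    """Select ``n`` widely spread, frequently detected probe compounds.

    Monoisotope ([M+H]+) ledger rows of non-noise, non-contaminant compounds
    restricted to ``sample_ids`` are grouped per compound; the compounds seen
    in the most samples are ranked first, and an even spread over the mass
    axis is taken to cover broad mass and RT ranges.
    """
    sub = ledger[
        (~ledger["is_noise"])
        & (~ledger["is_contaminant"])
        & (ledger["ion_label"] == "[M+H]+")
        & (ledger["sample_id"].isin(list(sample_ids)))
    ]
    stats = (
        sub.groupby("compound_id")
        .agg(n_samples=("sample_id", "nunique"), mz=("mz", "median"))
        .sort_values(["n_samples", "mz"], ascending=[False, True])
    )
    eligible = stats[stats["n_samples"] >= max(2, int(stats["n_samples"].max() * 0.5))]
    if len(eligible) < n:
        eligible = stats
    if len(eligible) < n:
        raise ValueError(f"not enough planted compounds for a {n}-feature probe set")
    by_mass = eligible.sort_values("mz")
    pick_idx = np.unique(np.linspace(0, len(by_mass) - 1, n).round().astype(int))
    i = 0
    while len(pick_idx) < n:  # fill duplicates from the remaining pool
        if i not in pick_idx:
            pick_idx = np.sort(np.append(pick_idx, i))
        i += 1
    chosen = by_mass.index[pick_idx][:n]

    entries = []
    for cid in chosen:
        rows = sub[sub["compound_id"] == cid]
        truth = {
            r.sample_id: (r.apex_rt, r.rt_start, r.rt_end, r.height)
            for r in rows.itertuples(index=False)
        }
        entries.append(
            ProbeFeature(
                probe_id=cid,
                neutral_mass=float(rows["mz"].median() - 1.00727646688),
                base_rt=float(rows["apex_rt"].median()),
                truth=truth,
            )
        )
    return ProbeSet(entries=tuple(entries))


def _match_probe(feature_list: Sequence[Feature], probe: ProbeFeature,
                 mass_tol_ppm: float = 30.0, rt_tol: float = 1.5) -> Optional[Feature]:
    best, best_score = None, np.inf
    for f in feature_list:
        dppm = abs(ppm_difference(f.median_mass, probe.neutral_mass))
        drt = abs(f.median_rt - probe.base_rt)
        if dppm <= mass_tol_ppm and drt <= rt_tol:
            score = (dppm / mass_tol_ppm) ** 2 + (drt / rt_tol) ** 2
            if score < best_score:
                best, best_score = f, score
    return best


def compute_responses(features: Sequence[Feature], probe: ProbeSet) -> ResponseVector:
    """Score one extraction run against the probe ground truth.

    R5 counts probe features for which at least one integrated member peak
    does not overlap the true peak (true apex outside the integration bounds);
    R6 counts probe features with at least one sample where the ground truth
    has a peak but no member was extracted.  An empty feature list is an
    error: R3 and R4 are undefined.
    """
    if not features:
        raise ValueError("empty feature list: responses R3/R4 are undefined")
    rt_spans = [f.rt_span for f in features]
    rsds = [f.mass_rsd_pct for f in features]
    single = sum(1 for f in features if f.n_ions == 1)
    target_diff = [
        abs(ppm_difference(f.median_mass, f.target_mass))
        for f in features
        if np.isfinite(f.target_mass) and f.target_mass > 0
    ]
    r5 = 0
    r6 = 0
    for entry in probe:
        feature = _match_probe(features, entry)
        erroneous = False
        missed = False
        if feature is None:
            missed = True
        else:
            for sample_id, (apex, _start, _end, _height) in entry.truth.items():
                member = feature.member_for(sample_id)
                if member is None:
                    missed = True
                    continue
                peak = member.peak
                if peak is not None and not (peak.rt_start <= apex <= peak.rt_end):
                    erroneous = True
        r5 += int(erroneous)
        r6 += int(missed)
    return ResponseVector(
        r1_median_rt_span=float(np.median(rt_spans)),
        r2_median_mass_rsd=float(np.median(rsds)),
        r3_single_ion_fraction=float(single / len(features)),
        r4_median_target_mass_diff=float(np.median(target_diff)) if target_diff else 0.0,
        r5_erroneous_integrations=int(r5),
        r6_missed_peaks=int(r6),
    )


def evaluate_design(plan: DesignPlan, runs, probe: ProbeSet, **fixed) -> pd.DataFrame:
    """Run feature extraction for every design row and tabulate R1-R6."""
    rows = []
    native = plan.native()
    for run_id, row in native.iterrows():
        settings = settings_from_row(row.to_dict(), **fixed)
        features = extract_features(runs, settings)
        rows.append({"run_id": run_id, **compute_responses(features, probe).as_dict()})
    return pd.DataFrame(rows).set_index("run_id")


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

@dataclass
class FittedResponseModel:
    """OLS main-effects model of one response on the coded factors."""

    response: str
    intercept: float
    coefficients: pd.Series  # indexed by factor name, coded units
    residual_variance: float
    r_squared: float
    q_squared: float

    def predict(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(coded)
        return self.intercept + coded @ self.coefficients.to_numpy()


def fit_response_models(plan: DesignPlan, responses: pd.DataFrame) -> dict:
    """Fit one OLS model per response column; R^2 and leave-one-out Q^2.

    Q^2 = 1 - PRESS/SST with PRESS from the closed-form leave-one-out
    residuals e_i / (1 - h_i).  Raises on a singular design matrix or when
    there are fewer than terms + 2 runs.
    """
    X = np.column_stack([np.ones(plan.n_runs), plan.coded.to_numpy()])
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} runs to fit {p} terms, got {n}")
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError("singular design matrix")
    xtx_inv = np.linalg.inv(xtx)
    H = X @ xtx_inv @ X.T
    h = np.diag(H)
    models: dict[str, FittedResponseModel] = {}
    for name in responses.columns:
        y = responses[name].to_numpy(dtype=float)
        if len(y) != n:
            raise ValueError("responses must cover every design run")
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        q2 = 1.0 - press / sst if sst > 0 else 1.0
        models[name] = FittedResponseModel(
            response=name,
            intercept=float(beta[0]),
            coefficients=pd.Series(beta[1:], index=plan.coded.columns),
            residual_variance=sse / (n - p) if n > p else 0.0,
            r_squared=r2,
            q_squared=q2,
        )
    return models


# --------------------------------------------------------------------------
# desirability and the robust setpoint
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesirabilitySpec:
    """Minimization spec of one response: fully desirable at/below ``target``,
    unacceptable at/above ``limit``; linear Derringer-Suich ramp between."""

    target: float
    limit: float
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if not self.target < self.limit:
            raise ValueError("target must be < limit")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


def desirability(value: float, spec: DesirabilitySpec) -> float:
    """Derringer-Suich desirability of one response value, in [0, 1]."""
    if value <= spec.target:
        return 1.0
    if value >= spec.limit:
        return 0.0
    return float(((spec.limit - value) / (spec.limit - spec.target)) ** spec.exponent)


def overall_desirability(values: Sequence[float], specs: Sequence[DesirabilitySpec]) -> float:
    """Geometric mean of the per-response desirabilities."""
    ds = np.array([desirability(v, s) for v, s in zip(values, specs)])
    if (ds == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(ds))))


def specs_from_responses(
    responses: pd.DataFrame, target_pct: float = 10.0, limit_pct: float = 90.0
) -> dict:
    """Per-response percentile specification limits over the design runs.

    Degenerate responses (constant over the design) get a small positive band
    above the target so the spec remains well-formed.
    """
    specs = {}
    for name in responses.columns:
        y = responses[name].to_numpy(dtype=float)
        target = float(np.percentile(y, target_pct))
        limit = float(np.percentile(y, limit_pct))
        if limit <= target:
            pad = max(abs(target) * 0.05, 1e-6)
            limit = target + pad
        specs[name] = DesirabilitySpec(target=target, limit=limit)
    return specs


@dataclass
class RobustSetpointResult:
    factor_values: dict  # native units
    coded_values: dict
    predicted_responses: dict
    acceptance_probability: dict  # P(response > limit) per response
    desirability: float
    acceptable: bool
    contributions: dict = field(default_factory=dict)
    warning: Optional[str] = None


def find_robust_setpoint(
    models: Mapping[str, FittedResponseModel],
    specs: Mapping[str, DesirabilitySpec],
    factors: Sequence[FactorSpec],
    resolution: int = 8,
    iterations: int = 1000,
    acceptance: float = 0.01,
    seed: int = 0,
) -> RobustSetpointResult:
    """Exhaustive design-space search for the robust setpoint.

    Every factor is discretized to ``resolution`` coded levels in [-1, +1];
    at each grid point each response is predicted and perturbed by
    ``iterations`` Monte-Carlo draws of Gaussian noise with the model residual
    variance.  A point is acceptable when, for every response, the fraction of
    draws above the specification limit is at most ``acceptance``.  The
    setpoint is the acceptable point of maximal overall desirability; ties go
    to the innermost point (greatest minimum noise-scaled distance to the
    specification boundary).  If no point is acceptable the best-desirability
    point is returned with a warning.
    """
    names = list(models)
    factor_names = [f.name for f in factors]
    betas = np.column_stack([models[n].coefficients.reindex(factor_names).to_numpy() for n in names])
    intercepts = np.array([models[n].intercept for n in names])
    sds = np.array([np.sqrt(max(models[n].residual_variance, 0.0)) for n in names])
    limits = np.array([specs[n].limit for n in names])
    targets = np.array([specs[n].target for n in names])
    exponents = np.array([specs[n].exponent for n in names])

    rng = np.random.default_rng(seed)
    noise_sorted = [np.sort(rng.normal(0.0, sd, iterations)) if sd > 0 else None for sd in sds]

    levels = np.linspace(-1.0, 1.0, resolution)
    k = len(factor_names)
    # chunk the k-dimensional grid: enumerate leading factors, vectorize the rest
    lead = 0
    while resolution ** (k - lead) > 200_000:
        lead += 1
    tail_grid = np.array(
        np.meshgrid(*([levels] * (k - lead)), indexing="ij")
    ).reshape(k - lead, -1).T if k > lead else np.zeros((1, 0))

    best = None  # (acceptable, desirability, margin, coded)
    from itertools import product

    for head in product(levels, repeat=lead):
        coded = np.empty((len(tail_grid), k))
        coded[:, :lead] = head
        coded[:, lead:] = tail_grid
        preds = intercepts + coded @ betas  # (points, responses)
        exceed = np.zeros_like(preds)
        for j, sorted_noise in enumerate(noise_sorted):
            if sorted_noise is None:
                exceed[:, j] = (preds[:, j] > limits[j]).astype(float)
            else:
                thr = limits[j] - preds[:, j]
                cnt = iterations - np.searchsorted(sorted_noise, thr, side="right")
                exceed[:, j] = cnt / iterations
        acceptable = (exceed <= acceptance).all(axis=1)
        with np.errstate(invalid="ignore"):
            ramp = np.clip((limits - preds) / (limits - targets), 0.0, 1.0) ** exponents
        d_all = np.where((ramp <= 0).any(axis=1), 0.0, np.exp(np.log(np.maximum(ramp, 1e-300)).mean(axis=1)))
        margin = ((limits - preds) / np.where(sds > 0, sds, 1.0)).min(axis=1)
        for i in range(len(coded)):
            key = (bool(acceptable[i]), float(d_all[i]), float(margin[i]))
            if best is None or key > best[0]:
                best = (key, coded[i].copy())

    (acc, d_best, _margin), coded_best = best
    preds_best = intercepts + coded_best @ betas
    exceed_best = {}
    for j, name in enumerate(names):
        if noise_sorted[j] is None:
            exceed_best[name] = float(preds_best[j] > limits[j])
        else:
            thr = limits[j] - preds_best[j]
            exceed_best[name] = float(
                (iterations - np.searchsorted(noise_sorted[j], thr, side="right")) / iterations
            )
    native = {f.name: f.to_native(c) for f, c in zip(factors, coded_best)}
    return RobustSetpointResult(
        factor_values=native,
        coded_values=dict(zip(factor_names, coded_best)),
        predicted_responses=dict(zip(names, preds_best)),
        acceptance_probability=exceed_best,
        desirability=float(d_best),
        acceptable=bool(acc),
        warning=None if acc else "no grid point met the acceptance limit; "
                                 "returning the best-desirability point",
    )


def factor_contributions(
    models: Mapping[str, FittedResponseModel],
    specs: Optional[Mapping[str, DesirabilitySpec]] = None,
) -> dict:
    """Percentage contribution of each factor, aggregated over the responses.

    Each coded main-effect coefficient is scaled by the response's
    specification band (limit - target) so responses of different units are
    comparable, absolute scaled effects are summed per factor, and the result
    is normalized to 100%.  Invariant to run-order permutation of the design.
    """
    factor_names = None
    shares = None
    for name, model in models.items():
        if factor_names is None:
            factor_names = list(model.coefficients.index)
            shares = np.zeros(len(factor_names))
        scale = 1.0
        if specs is not None and name in specs:
            scale = specs[name].limit - specs[name].target
        if scale <= 0:
            scale = 1.0
        shares += np.abs(model.coefficients.reindex(factor_names).to_numpy()) / scale
    total = shares.sum()
    if total == 0:
        return {f: 0.0 for f in factor_names}
    return {f: float(100.0 * s / total) for f, s in zip(factor_names, shares)}
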