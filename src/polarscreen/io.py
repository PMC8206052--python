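"""Readers and writers for the plain-text interchange formats.

Centroid tables are per-sample TSV files with columns ``sample_id, rt_min,
mz, intensity``; the campaign manifest, ground-truth ledger, feature lists and
candidate reports are TSV as well.  Two reference tables ship with the
package: the published candidate list (39 query ids, 46 features, 64 distinct
compounds) and the three reference-standard confirmations.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CompoundRecord, Feature, SampleRun, features_to_frame, parse_formula
from .simulate import Campaign

__all__ = [
    "write_campaign",
    "read_campaign",
    "read_sample_table",
    "write_features",
    "load_candidate_table",
    "load_confirmed_standards",
    "load_compound_database",
    "read_compound_database",
]

CENTROID_COLUMNS = ["sample_id", "rt_min", "mz", "intensity"]


def write_campaign(campaign: Campaign, out_dir: str | Path) -> list[Path]:
    """Write per-sample centroid tables, the manifest, and the ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for run in campaign.runs:
        table = pd.DataFrame(
            {
                "sample_id": run.sample_id,
                "rt_min": run.peaks["rt"],
                "mz": run.peaks["mz"],
                "intensity": run.peaks["intensity"],
            }
        )
        path = out / f"{run.sample_id}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)
    campaign.manifest().to_csv(out / "manifest.tsv", sep="\t", index=False)
    campaign.ledger.to_csv(out / "ledger.tsv", sep="\t", index=False, float_format="%.6f")
    return written


def read_sample_table(path: str | Path, **meta) -> SampleRun:
    """Read one per-sample centroid table into a :class:`SampleRun`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CENTROID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else Path(path).stem
    peaks = df.rename(columns={"rt_min": "rt"})[["rt", "mz", "intensity"]]
    return SampleRun(sample_id=sample_id, peaks=peaks, **meta)


def read_campaign(directory: str | Path) -> tuple[list[SampleRun], pd.DataFrame, Optional[pd.DataFrame]]:
    """Read all sample tables listed in a directory's manifest.

    Returns ``(runs, manifest, ledger-or-None)``.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    runs = []
    for row in manifest.itertuples(index=False):
        run = read_sample_table(
            directory / f"{row.sample_id}.tsv",
            location_id=int(row.location_id),
            campaign_date=str(row.campaign_date),
            is_blank=bool(row.is_blank),
        )
        runs.append(run)
    ledger_path = directory / "ledger.tsv"
    ledger = pd.read_csv(ledger_path, sep="\t") if ledger_path.exists() else None
    return runs, manifest, ledger


def write_features(features: Sequence[Feature], path: str | Path) -> pd.DataFrame:
    frame = features_to_frame(features)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return frame


# --------------------------------------------------------------------------
# packaged reference tables
# --------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("polarscreen.data").joinpath(name)


def load_candidate_table() -> pd.DataFrame:
    """The published candidate list: one row per (feature, compound) match."""
    with resources.as_file(_data_path("table2_candidates.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_confirmed_standards() -> pd.DataFrame:
    """The three reference-standard confirmations.

    Note: the guanylurea InChIKey printed with the confirmations
    (BKMMTJMQCTUHRP...) differs from the one in the candidate list
    (SQSPRWMERUQXNE...), where BKMMTJMQCTUHRP... names 2-amino-1-propanol.
    Both tables are kept verbatim; consumers matching by InChIKey across the
    two tables should be aware of the conflict.
    """
    with resources.as_file(_data_path("table3_confirmed.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_compound_database() -> list[CompoundRecord]:
    """Compound records derived from the packaged reference tables.

    Confirmed standards contribute exact formulas and monoisotopic masses;
    for the remaining candidate-list compounds, the reference mass is
    back-calculated from the detected median mass and the printed relative
    mass difference.  One record per distinct InChIKey.
    """
    confirmed = load_confirmed_standards()
    records: dict[str, CompoundRecord] = {}
    for row in confirmed.itertuples(index=False):
        records[row.inchikey] = CompoundRecord(
            name=row.name,
            inchikey=row.inchikey,
            monoisotopic_mass=float(row.monoisotopic_mass),
            logd_ph7=float(row.logd_ph7),
            formula=parse_formula(row.formula),
        )
    table = load_candidate_table()
    for row in table.itertuples(index=False):
        if row.inchikey in records:
            continue
        reference = row.detected_median_mass / (1.0 + row.rel_mass_diff_ppm * 1e-6)
        records[row.inchikey] = CompoundRecord(
            name=row.compound_name,
            inchikey=row.inchikey,
            monoisotopic_mass=round(float(reference), 4),
            logd_ph7=float(row.logd_ph7),
        )
    return list(records.values())


def read_compound_database(path: str | Path) -> list[CompoundRecord]:
    """Read a user-supplied compound table.

    Expected delimiter-separated columns: ``name, inchikey, formula,
    monoisotopic_mass, logd_ph7`` (formula may be empty).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "inchikey", "monoisotopic_mass", "logd_ph7"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        formula = None
        raw = getattr(row, "formula", None)
        if isinstance(raw, str) and raw.strip():
            formula = parse_formula(raw)
        logd = getattr(row, "logd_ph7")
        records.append(
            CompoundRecord(
                name=str(row.name),
                inchikey=str(row.inchikey),
                monoisotopic_mass=float(row.monoisotopic_mass),
                logd_ph7=None if pd.isna(logd) else float(logd),
                formula=formula,
            )
        )
    return records
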