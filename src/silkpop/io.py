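"""Readers and writers for the tabular cohort and result formats.

The input schema mirrors a Skyline transition-results export after
integration: one row per (patient, protein, peptide, charge, replicate,
time point) with integrated light (pl) and heavy (ph) channel signals.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .qnb import RIAObservation

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["patient", "protein", "peptide", "charge", "replicate",
                    "time_h", "pl", "ph"]
KEY_COLUMNS = ["patient", "protein", "peptide", "charge", "replicate", "time_h"]

__all__ = ["read_cohort", "write_results", "cohort_observations", "REQUIRED_COLUMNS"]


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a long-format cohort table.

    Computes the ria column where absent, drops rows with pl+ph == 0
    (undefined ratio) with a logged count, and fails loudly on missing
    columns, non-numeric fields, or duplicated keys.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in ("time_h", "pl", "ph"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in column {col!r}") from exc
        if df[col].isna().any():
            raise ValueError(f"non-numeric (NaN) values in column {col!r}")
    if (df["time_h"] < 0).any() or (df[["pl", "ph"]] < 0).any().any():
        raise ValueError("time_h, pl and ph must all be >= 0")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        key = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise ValueError(f"duplicated key row: {key}")
    undefined = (df["pl"] + df["ph"]) <= 0
    if undefined.any():
        logger.warning("dropping %d rows with pl+ph == 0 (undefined RIA)",
                       int(undefined.sum()))
        df = df.loc[~undefined].reset_index(drop=True)
    if "ria" not in df.columns:
        df["ria"] = df["ph"] / (df["pl"] + df["ph"])
    return df


def cohort_observations(df: pd.DataFrame):
    """Group a cohort table into (patient, protein) -> list[RIAObservation]."""
    groups = {}
    for (pat, prot), g in df.groupby(["patient", "protein"], sort=True):
        groups[(str(pat), str(prot))] = [
            RIAObservation(
                patient_id=str(pat), protein_id=str(prot),
                peptide_id=str(r.peptide), time=float(r.time_h),
                pl=float(r.pl), ph=float(r.ph), replicate=int(r.replicate),
            )
            for r in g.itertuples()
        ]
    return groups


def write_results(results: pd.DataFrame, path, diagnostics: dict | None = None,
                  provenance: dict | None = None) -> None:
    """Write a results table plus a JSON side-car for diagnostics/provenance.

    Column order is preserved deterministically and floats written at full
    precision so a read-back reproduces the values exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False, float_format="%.17g")
    sidecar = {}
    if diagnostics is not None:
        sidecar["diagnostics"] = diagnostics
    if provenance is not None:
        sidecar["provenance"] = provenance
    if sidecar:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
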