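"""Dataset-inclusion rules for candidate EMDB/PDB entries.

Filtering operates on a local metadata table (no network access):

1. drop entries without a corresponding atomic biological assembly;
2. drop entries missing a resolution determined by the FSC 0.143 cut-off;
3. among entries sharing one assembly (same pdb_id), keep a single
   representative — the best (lowest) resolution, ties broken by the
   lexicographically smallest EMDB accession;

plus the resolution window (default 1–4 Å) of the high-resolution selection.

A record whose ``resolution_method`` is blank is *kept* by rule 2 as long as
a resolution is present: an unknown method cannot be shown not to be
FSC-0.143.  Rule 2 rejects only methods that explicitly state something else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["MapRecord", "curate", "read_metadata", "write_curated"]

RULE_NO_ASSEMBLY = "rule1_no_assembly"
RULE_NO_FSC0143 = "rule2_no_fsc0143_resolution"
RULE_REDUNDANT = "rule3_redundant"
RULE_WINDOW = "resolution_window"


@dataclass
class MapRecord:
    """One candidate dataset entry."""

    emdb_id: str
    pdb_id: str | None = None
    resolution: float | None = None
    has_assembly: bool = True
    resolution_method: str | None = None

    def __post_init__(self) -> None:
        if not self.emdb_id:
            raise ValueError("emdb_id must be non-empty")
        if isinstance(self.pdb_id, float) and math.isnan(self.pdb_id):
            self.pdb_id = None
        if self.resolution is not None and (
            isinstance(self.resolution, float) and math.isnan(self.resolution)
        ):
            self.resolution = None


def _method_is_fsc0143(method: str | None) -> bool:
    if method is None or (isinstance(method, float) and math.isnan(method)) or not str(method).strip():
        return True  # unknown method: cannot prove it is not FSC-0.143
    return "0.143" in str(method)


def curate(
    records,
    res_min: float = 1.0,
    res_max: float = 4.0,
) -> tuple[list[MapRecord], dict[str, str]]:
    """Apply the inclusion rules; returns (kept records, rejection reasons).

    Reasons are keyed by ``emdb_id`` and name the rule that fired first.
    Kept records preserve input order and have unique ``pdb_id``.
    """
    records = list(records)
    reasons: dict[str, str] = {}
    survivors: list[MapRecord] = []
    for rec in records:
        if not rec.pdb_id or not rec.has_assembly:
            reasons[rec.emdb_id] = RULE_NO_ASSEMBLY
        elif rec.resolution is None or not _method_is_fsc0143(rec.resolution_method):
            reasons[rec.emdb_id] = RULE_NO_FSC0143
        elif not (res_min <= rec.resolution <= res_max):
            reasons[rec.emdb_id] = RULE_WINDOW
        else:
            survivors.append(rec)

    # rule 3: one representative per assembly — best resolution, then smallest accession
    best: dict[str, MapRecord] = {}
    for rec in survivors:
        cur = best.get(rec.pdb_id)
        if cur is None:
            best[rec.pdb_id] = rec
        elif (rec.resolution, rec.emdb_id) < (cur.resolution, cur.emdb_id):
            reasons[cur.emdb_id] = RULE_REDUNDANT
            best[rec.pdb_id] = rec
        else:
            reasons[rec.emdb_id] = RULE_REDUNDANT
    kept = [rec for rec in survivors if best.get(rec.pdb_id) is rec]
    return kept, reasons


def read_metadata(path) -> list[MapRecord]:
    """Load candidate records from a CSV with the standard header."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(MapRecord(
            emdb_id=str(row["emdb_id"]),
            pdb_id=None if pd.isna(row.get("pdb_id")) else str(row["pdb_id"]),
            resolution=None if pd.isna(row.get("resolution")) else float(row["resolution"]),
            has_assembly=bool(row.get("has_assembly", True)),
            resolution_method=None if pd.isna(row.get("resolution_method")) else str(row["resolution_method"]),
        ))
    return records


def write_curated(path, records, reasons: dict[str, str] | None = None) -> None:
    """Write records (kept and/or rejected) back to CSV with reasons."""
    reasons = reasons or {}
    rows = [{
        "emdb_id": r.emdb_id,
        "pdb_id": r.pdb_id,
        "resolution": r.resolution,
        "has_assembly": r.has_assembly,
        "resolution_method": r.resolution_method,
        "rejection_reason": reasons.get(r.emdb_id, ""),
    } for r in records]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
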