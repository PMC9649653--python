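"""CSV readers/writers for the analysis stages.

All interchange is UTF-8 CSV with a decimal point.  Output files carry
provenance comment lines (``# key=value``) sufficient to re-run the step;
readers skip ``#`` comments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .hdx import CentroidSeries, PepticPeptide
from .kinetics import AssayConditions, ProgressCurve
from .survival import SurvivalRecord


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", encoding="utf-8")


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: Optional[Dict[str, object]] = None
) -> None:
    """Write a CSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# egfr19={__version__}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def write_run_log(
    path: str | Path, command: str, options: Dict[str, object]
) -> None:
    log = {"tool": "egfr19", "version": __version__, "command": command,
           "options": options}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(log, indent=2, default=str), encoding="utf-8")


# --- variant lists ----------------------------------------------------------

def read_variant_list(path: str | Path) -> pd.DataFrame:
    """Variant list CSV: column ``descriptor`` plus optional extras."""
    df = read_table(path)
    if "descriptor" not in df.columns:
        if df.shape[1] == 1:  # headerless single column fallback
            df.columns = ["descriptor"]
        else:
            raise ValueError("variant list needs a 'descriptor' column")
    return df


# --- kinetics ---------------------------------------------------------------

def read_progress_curve(
    csv_path: str | Path, conditions: AssayConditions
) -> ProgressCurve:
    """Progress-curve CSV with columns ``time_s, signal``."""
    df = read_table(csv_path)
    if not {"time_s", "signal"}.issubset(df.columns):
        raise ValueError("progress curve CSV needs columns time_s, signal")
    return ProgressCurve(
        times_s=df["time_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        conditions=conditions,
    )


def read_conditions(path: str | Path) -> AssayConditions:
    """Flat ``key=value`` sidecar with assay conditions."""
    kv: Dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        kv[k.strip()] = v.strip()
    return AssayConditions(
        tkd_conc_nM=float(kv["tkd_conc_nM"]),
        atp_conc_uM=float(kv["atp_conc_uM"]),
        peptide_conc_uM=float(kv["peptide_conc_uM"]),
        inhibitor_name=kv.get("inhibitor_name") or None,
        inhibitor_conc_nM=float(kv.get("inhibitor_conc_nM", 0.0)),
    )


def read_dose_response(path: str | Path) -> np.ndarray:
    """Dose–response CSV with columns ``inhibitor_nM, rate_pct``."""
    df = read_table(path)
    if not {"inhibitor_nM", "rate_pct"}.issubset(df.columns):
        raise ValueError("dose-response CSV needs columns inhibitor_nM, rate_pct")
    return df[["inhibitor_nM", "rate_pct"]].to_numpy(float)


def read_cheng_prusoff(path: str | Path) -> np.ndarray:
    """Cheng–Prusoff series CSV with columns ``atp_uM, ic50_nM``."""
    df = read_table(path)
    if not {"atp_uM", "ic50_nM"}.issubset(df.columns):
        raise ValueError("Cheng-Prusoff CSV needs columns atp_uM, ic50_nM")
    return df[["atp_uM", "ic50_nM"]].to_numpy(float)


# --- HDX --------------------------------------------------------------------

def read_hdx_cluster(path: str | Path) -> List[CentroidSeries]:
    """DynamX-cluster-style CSV with columns
    ``sequence, start, end, charge, state, exposure_s, replicate,
    centroid_mass_da``.

    Rows with ``exposure_s == 0`` define the undeuterated reference ``m_0``;
    rows with ``state == "FD"`` define the fully-deuterated reference
    ``m_f``.  One :class:`CentroidSeries` is returned per
    (peptide span, charge, replicate).
    """
    df = read_table(path)
    need = {"sequence", "start", "end", "charge", "state", "exposure_s",
            "replicate", "centroid_mass_da"}
    if not need.issubset(df.columns):
        raise ValueError(f"HDX cluster CSV needs columns {sorted(need)}")
    out: List[CentroidSeries] = []
    for (seq, start, end, charge), grp in df.groupby(
        ["sequence", "start", "end", "charge"]
    ):
        pep = PepticPeptide(
            sequence=seq, start_res=int(start), end_res=int(end), charge=int(charge)
        )
        fd = grp[grp["state"].astype(str).str.upper() == "FD"]
        m0_rows = grp[(grp["exposure_s"] == 0)
                      & (grp["state"].astype(str).str.upper() != "FD")]
        if fd.empty or m0_rows.empty:
            raise ValueError(
                f"peptide {start}-{end} z={charge}: missing m_0 and/or FD reference"
            )
        m0 = float(m0_rows["centroid_mass_da"].mean())
        mf = float(fd["centroid_mass_da"].mean())
        labeled = grp[(grp["exposure_s"] > 0)
                      & (grp["state"].astype(str).str.upper() != "FD")]
        for rep, rep_grp in labeled.groupby("replicate"):
            rep_grp = rep_grp.sort_values("exposure_s")
            out.append(
                CentroidSeries(
                    peptide=pep,
                    timepoints_s=tuple(rep_grp["exposure_s"].astype(float)),
                    m_t=tuple(rep_grp["centroid_mass_da"].astype(float)),
                    m_0=m0,
                    m_f=mf,
                    replicate_id=int(rep),
                )
            )
    return out


def read_envelope(path: str | Path) -> pd.DataFrame:
    """Two-column ``mz, intensity`` CSV for one peptide/timepoint."""
    df = read_table(path)
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ValueError("envelope CSV needs columns mz, intensity")
    return df


# --- survival ---------------------------------------------------------------

def read_cohort(path: str | Path) -> List[SurvivalRecord]:
    """Cohort CSV with columns ``id, variant_descriptor, time_months, event``
    (``profile`` may be given instead of/alongside the descriptor)."""
    df = read_table(path)
    need = {"id", "time_months", "event"}
    if not need.issubset(df.columns):
        raise ValueError("cohort CSV needs columns id, time_months, event")
    records = []
    for _, row in df.iterrows():
        records.append(
            SurvivalRecord(
                id=str(row["id"]),
                time_months=float(row["time_months"]),
                event=int(row["event"]),
                profile=int(row["profile"]) if "profile" in df.columns
                and not pd.isna(row.get("profile")) else None,
                variant_descriptor=str(row["variant_descriptor"])
                if "variant_descriptor" in df.columns
                and not pd.isna(row.get("variant_descriptor")) else None,
            )
        )
    return records


def write_cohort(
    records: Sequence[SurvivalRecord], path: str | Path,
    provenance: Optional[Dict[str, object]] = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "variant_descriptor": r.variant_descriptor,
                "time_months": r.time_months,
                "event": r.event,
                "profile": r.profile,
            }
            for r in records
        ]
    )
    write_table(df, path, provenance)
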