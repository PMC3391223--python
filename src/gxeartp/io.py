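"""Readers and writers for the pipeline's text formats.

Dosage panels travel as MACH-style dose/info file pairs: the dose file has one
row per individual (``ID->ID ML_DOSE d1 d2 ...``, space-separated, three
decimal places, ``NA`` for missing calls); the companion info file is headed
``SNP Al1 Al2 Freq1 MAF Quality Rsq`` with three extension columns
(``Chr Position Genotyped``) carrying coordinates that the classic format does
not record.  Cohort and gene-region tables are plain tab-separated files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cohort import COVARIATE_COLUMNS, EXPOSURE_COLUMNS, OUTCOME_COLUMNS, DosagePanel, SnpSpec

__all__ = [
    "write_dosage_panel",
    "read_dosage_panel",
    "write_cohort_table",
    "read_cohort_table",
    "load_config",
    "save_config",
]

_INFO_HEADER = ["SNP", "Al1", "Al2", "Freq1", "MAF", "Quality", "Rsq"]
_INFO_EXTRA = ["Chr", "Position", "Genotyped"]


def write_dosage_panel(panel: DosagePanel, dose_path: str | Path, info_path: str | Path) -> None:
    """Write a panel as a MACH-style dose/info file pair (3-decimal dosages)."""
    with open(dose_path, "w") as fh:
        for iid, row in zip(panel.individual_ids, panel.dosages):
            fields = ["NA" if np.isnan(d) else f"{d:.3f}" for d in row]
            fh.write(f"{iid}->{iid} ML_DOSE " + " ".join(fields) + "\n")
    with open(info_path, "w") as fh:
        fh.write("\t".join(_INFO_HEADER + _INFO_EXTRA) + "\n")
        for s in panel.snps:
            fh.write(
                "\t".join(
                    [
                        s.snp_id,
                        s.allele1,
                        s.allele2,
                        f"{s.maf:.4f}",
                        f"{min(s.maf, 1.0 - s.maf):.4f}",
                        f"{s.rsq:.4f}",
                        f"{s.rsq:.4f}",
                        str(s.chromosome),
                        str(s.position),
                        "1" if s.genotyped else "0",
                    ]
                )
                + "\n"
            )


def read_dosage_panel(dose_path: str | Path, info_path: str | Path) -> DosagePanel:
    """Read a MACH-style dose/info file pair written by :func:`write_dosage_panel`."""
    info = pd.read_csv(info_path, sep="\t")
    missing = [c for c in _INFO_HEADER if c not in info.columns]
    if missing:
        raise ValueError(f"info file lacks required columns: {missing}")
    has_extra = all(c in info.columns for c in _INFO_EXTRA)
    snps = []
    for i, row in info.iterrows():
        snps.append(
            SnpSpec(
                snp_id=str(row["SNP"]),
                chromosome=str(row["Chr"]) if has_extra else "NA",
                position=int(row["Position"]) if has_extra else i + 1,
                allele1=str(row["Al1"]),
                allele2=str(row["Al2"]),
                maf=float(row["Freq1"]) if float(row["Freq1"]) <= 0.5 else 1.0 - float(row["Freq1"]),
                rsq=float(row["Rsq"]),
                genotyped=bool(int(row["Genotyped"])) if has_extra else float(row["Rsq"]) >= 1.0,
            )
        )
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(dose_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0].split("->", 1)[0])
            if parts[1].upper() not in {"ML_DOSE", "DOSE"}:
                raise ValueError(f"unexpected dose-file token {parts[1]!r}")
            rows.append(np.array([np.nan if p == "NA" else float(p) for p in parts[2:]]))
    dosages = np.vstack(rows)
    if dosages.shape[1] != len(snps):
        raise ValueError("dose and info files disagree on SNP count")
    return DosagePanel(individual_ids=ids, snps=snps, dosages=dosages)


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the per-individual outcome/covariate/exposure table as TSV."""
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path, require_complete: bool = True) -> pd.DataFrame:
    """Read a cohort table; by default reject missing values in analysis columns.

    The analysis is complete-case: every covariate, exposure and outcome column
    present in the file must be fully observed unless ``require_complete`` is
    turned off.
    """
    cohort = pd.read_csv(path, sep="\t")
    for col in ("study_area", "smoking_status"):
        if col in cohort.columns:
            cohort[col] = cohort[col].astype("category")
    if require_complete:
        analysis_cols = [
            c
            for c in (*COVARIATE_COLUMNS, *EXPOSURE_COLUMNS, *OUTCOME_COLUMNS)
            if c in cohort.columns
        ]
        bad = cohort[analysis_cols].isna().any()
        if bad.any():
            raise ValueError(
                f"missing values in analysis columns: {list(bad[bad].index)}"
            )
    return cohort


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat YAML configuration (simulation parameters, seed, paths)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
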