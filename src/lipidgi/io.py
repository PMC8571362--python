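"""Schema-validated table I/O and run manifests.

All pipeline tables are plain delimited text: tab-separated canonical,
comma accepted, UTF-8, mandatory header row, ``NA`` as the missing-value
token.  Every pipeline run writes a manifest recording the command,
configuration, input checksums and seed, so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "read_table", "write_table", "RunManifest", "write_manifest"]


def _check_binary(df, col, errors):
    bad = df[col].dropna()
    bad = bad[~bad.isin([0, 1])]
    if len(bad):
        errors.append(f"column {col!r}: non-binary value at row {bad.index[0] + 2}")


def _check_positive(df, col, errors):
    bad = df[col].dropna()
    bad = bad[bad <= 0]
    if len(bad):
        errors.append(f"column {col!r}: non-positive value at row {bad.index[0] + 2}")


def _check_range(lo, hi):
    def check(df, col, errors):
        bad = df[col].dropna()
        bad = bad[(bad < lo) | (bad > hi)]
        if len(bad):
            errors.append(
                f"column {col!r}: value outside [{lo}, {hi}] at row {bad.index[0] + 2}"
            )
    return check


#: Named table schemas: required columns and per-column range checks.
#: Dosage tables are validated separately (variable SNP columns).
SCHEMAS = {
    "phenotypes": {
        "required": ["sample_id", "LDLc", "HDLc", "TG", "TC", "CAD",
                     "age", "sex", "smoking", "alcohol", "BMI",
                     "lipid_medication"] + [f"PC{i}" for i in range(1, 11)],
        "checks": {
            "LDLc": _check_positive, "HDLc": _check_positive,
            "TG": _check_positive, "TC": _check_positive,
            "CAD": _check_binary, "sex": _check_binary,
            "smoking": _check_binary, "alcohol": _check_binary,
            "lipid_medication": _check_binary,
        },
    },
    "ptv_calls": {"required": ["sample_id", "gene", "variant_id"], "checks": {}},
    "dosages": {"required": ["sample_id"], "checks": {}, "dosage_matrix": True},
    "prs_weights": {"required": ["snp", "chrom", "pos", "weight"], "checks": {}},
    "gene_snp_map": {"required": ["gene", "snp", "chrom", "start", "end"], "checks": {}},
    "screen_layout": {
        "required": ["array_id", "spot_id", "gene_a", "gene_b", "role"],
        "checks": {},
    },
    "screen_measurements": {
        "required": ["array_id", "spot_id", "image_id", "replicate",
                     "mean_cell_intensity", "cell_count", "sharpness", "background"],
        "checks": {
            "mean_cell_intensity": _check_range(0, float("inf")),
            "cell_count": _check_range(0, float("inf")),
        },
    },
    "scan_results": {"required": ["pair", "trait", "classification"], "checks": {}},
    "screen_results": {"required": ["pair", "interaction_value", "p_ab_fdr"],
                       "checks": {}},
}

_LAYOUT_ROLES = {"negative-control", "transfection-control",
                 "positive-control", "treatment"}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    The delimiter is auto-detected between tab and comma (tab canonical).
    Raises ``ValueError`` naming the offending column or row on a schema
    violation; an empty file is an explicit error, not an empty success.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_text(encoding="utf-8").lstrip("﻿")
    if not head.strip():
        raise ValueError(f"{path}: no records")
    first_line = head.splitlines()[0]
    sep = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no records")

    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    errors: list[str] = []
    for col, check in spec["checks"].items():
        check(df, col, errors)
    if spec.get("dosage_matrix"):
        snp_cols = [c for c in df.columns if c != "sample_id"]
        if not snp_cols:
            errors.append("dosage table has no SNP columns")
        for col in snp_cols:
            _check_range(0, 2)(df, col, errors)
    if schema == "screen_layout":
        bad = df.loc[~df["role"].isin(_LAYOUT_ROLES), "role"]
        if len(bad):
            errors.append(f"column 'role': unknown role {bad.iloc[0]!r} "
                          f"at row {bad.index[0] + 2}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    logger.info("read %s: %d rows (%s schema)", path, len(df), schema)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as tab-separated UTF-8 with 'NA' for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per pipeline run."""

    command: str
    config: dict
    config_hash: str
    inputs: dict          # path -> sha256
    outputs: list
    seed: Optional[int]
    package_version: str
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())


def write_manifest(
    out_path,
    command: str,
    config: dict,
    inputs: Sequence,
    outputs: Sequence,
    seed: Optional[int] = None,
) -> Path:
    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = RunManifest(
        command=command,
        config=config,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        inputs={str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        outputs=[str(p) for p in outputs],
        seed=seed,
        package_version=__version__,
    )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(asdict(manifest), indent=2, default=str))
    return out_path
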