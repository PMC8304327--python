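"""Readers and writers for the tabular dialects the pipeline consumes.

Two upstream dialects are supported:

* a Skyline-style *transition report*: one row per extracted fragment-ion
  chromatogram area, with the peptide sequence carrying inline phospho
  notation (``pS``/``pT``; bracketed mass notation ``S[+80]`` is converted
  on input);
* a MaxQuant-style ``proteinGroups`` table: one row per protein group with
  decoy/contaminant flags, peptide/spectral counts, and per-sample iBAQ
  and/or normalized H/L ratio columns.

All tables are TSV, UTF-8, "." decimal separator. Intensity values of 0 are
treated as missing on input (the upstream software writes 0 for
not-quantified). Residue coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import hashlib
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hsp90cl")

__all__ = [
    "read_transition_report",
    "read_protein_groups",
    "write_protein_groups",
    "read_bait_fasta",
    "normalize_phospho_notation",
    "ibaq_columns",
    "ratio_columns",
    "identification_columns",
    "write_table",
    "read_table",
    "load_config",
    "config_digest",
]

#: canonical transition-report columns -> accepted header aliases (lowercased)
TRANSITION_ALIASES = {
    "modified_sequence": ["modified_sequence", "modified sequence",
                          "peptide modified sequence"],
    "precursor_charge": ["precursor_charge", "precursor charge"],
    "fragment_ion": ["fragment_ion", "fragment ion"],
    "label_channel": ["label_channel", "label", "isotope label type"],
    "sample_id": ["sample_id", "sample", "replicate name"],
    "replicate": ["replicate", "replicate index"],
    "area": ["area", "total area", "total area fragment"],
}

_BRACKET_PHOSPHO = re.compile(r"([STY])\[\+(?:80|79\.9\d*)\]")


def normalize_phospho_notation(sequence: str) -> str:
    """Convert bracketed phospho mass notation (``S[+80]``, ``S[+79.966]``)
    to the canonical inline form (``pS``)."""
    return _BRACKET_PHOSPHO.sub(lambda m: "p" + m.group(1), sequence)


def _resolve_columns(columns, aliases) -> dict:
    lower = {c.lower(): c for c in columns}
    mapping, missing = {}, []
    for canonical, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[lower[name]] = canonical
                break
        else:
            missing.append(canonical)
    if missing:
        raise ValueError(
            "transition report is missing mandatory column(s): "
            + ", ".join(missing)
        )
    return mapping


def read_transition_report(path) -> pd.DataFrame:
    """Read a transition report into the canonical fragment-area table.

    Returns a DataFrame with columns ``modified_sequence``,
    ``precursor_charge``, ``fragment_ion``, ``label_channel``, ``sample_id``,
    ``replicate``, ``area``. Unparseable areas become NaN and are logged;
    an empty file yields an empty table with a warning; a missing mandatory
    column raises ``ValueError`` naming it.
    """
    path = Path(path)
    try:
        # keep_default_na=False so sentinel strings like "NA" reach the
        # numeric parser (and get logged) instead of silently becoming NaN
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
    except pd.errors.EmptyDataError:
        logger.warning("empty transition report: %s", path)
        return pd.DataFrame(columns=list(TRANSITION_ALIASES))
    df = df.rename(columns=_resolve_columns(df.columns, TRANSITION_ALIASES))
    df = df[list(TRANSITION_ALIASES)]
    if df.empty:
        logger.warning("transition report has a header but no rows: %s", path)

    df["modified_sequence"] = df["modified_sequence"].map(
        normalize_phospho_notation)
    if (df["modified_sequence"].fillna("") == "").any():
        raise ValueError("transition report contains empty peptide sequences")

    df["label_channel"] = df["label_channel"].str.lower()
    bad = ~df["label_channel"].isin(["light", "heavy"])
    if bad.any():
        raise ValueError(
            f"unknown label_channel value(s): {sorted(df.loc[bad, 'label_channel'].unique())}"
        )

    df["precursor_charge"] = pd.to_numeric(df["precursor_charge"]).astype(int)
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)

    raw_area = df["area"]
    df["area"] = pd.to_numeric(raw_area, errors="coerce")
    coerced = df["area"].isna() & raw_area.notna() & (raw_area.str.strip() != "")
    for idx in df.index[coerced]:
        logger.warning("row %d: unparseable area %r treated as missing",
                       idx, raw_area[idx])
    if (df["area"] < 0).any():
        raise ValueError("transition report contains negative areas")
    return df


# ---------------------------------------------------------------------------
# MaxQuant-style proteinGroups

_PG_FLAGS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "only_by_site",
}
_PG_COUNTS = {
    "Unique peptides": "unique_peptides",
    "Peptides": "peptides",
    "MS/MS count": "msms_count",
}


def ibaq_columns(df: pd.DataFrame) -> list:
    """Per-sample iBAQ columns (``iBAQ <sample>``), excluding the total."""
    return [c for c in df.columns if c.startswith("iBAQ ")]


def ratio_columns(df: pd.DataFrame) -> list:
    """Per-sample normalized H/L ratio columns."""
    return [c for c in df.columns if c.startswith("Ratio H/L normalized ")]


def identification_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c.startswith("Identification type ")]


def read_protein_groups(path) -> pd.DataFrame:
    """Read a MaxQuant-style proteinGroups TSV.

    "+"/"" flag columns are parsed to booleans; iBAQ and ratio cells of 0 or
    blank become NaN (missing); identification-type columns become boolean
    identified-by-MS/MS flags. Raises ``ValueError`` when the table has
    neither iBAQ nor ratio columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = next((c for c in ("Protein IDs", "Majority protein IDs")
                   if c in df.columns), None)
    if id_col is None:
        raise ValueError("proteinGroups table lacks a 'Protein IDs' column")
    out = pd.DataFrame({"protein_ids": df[id_col]})
    out["gene_names"] = df["Gene names"] if "Gene names" in df.columns else ""
    for col, name in _PG_FLAGS.items():
        out[name] = df.get(col, "").fillna("").str.strip() == "+" \
            if col in df.columns else False
    for col, name in _PG_COUNTS.items():
        if col not in df.columns:
            raise ValueError(f"proteinGroups table lacks the '{col}' column")
        out[name] = pd.to_numeric(df[col]).fillna(0).astype(int)

    quant_cols = ibaq_columns(df) + ratio_columns(df)
    if not quant_cols:
        raise ValueError(
            "proteinGroups table has no quantification columns "
            "(expected 'iBAQ <sample>' or 'Ratio H/L normalized <sample>')"
        )
    for col in quant_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        vals[vals == 0] = np.nan  # MaxQuant writes 0 for not-quantified
        out[col] = vals
    for col in identification_columns(df):
        out[col] = df[col].fillna("").str.strip() == "By MS/MS"
    return out


def write_protein_groups(groups: pd.DataFrame, path) -> None:
    """Write a parsed protein-group table back in the MaxQuant dialect.

    Inverse of :func:`read_protein_groups` up to the missing-value
    convention (NaN quantities become 0, boolean flags become "+"/"",
    identification flags become "By MS/MS"/"By matching").
    """
    out = pd.DataFrame({"Protein IDs": groups["protein_ids"],
                        "Gene names": groups["gene_names"]})
    for col, name in _PG_FLAGS.items():
        out[col] = np.where(groups[name].astype(bool), "+", "")
    for col, name in _PG_COUNTS.items():
        out[col] = groups[name].astype(int)
    for col in ibaq_columns(groups) + ratio_columns(groups):
        out[col] = groups[col].fillna(0.0)
    for col in identification_columns(groups):
        out[col] = np.where(groups[col].astype(bool), "By MS/MS",
                            "By matching")
    write_table(out, path)


def read_bait_fasta(path) -> tuple[str, str]:
    """Read the bait protein FASTA (single record): returns (header, sequence).

    Residue coordinates elsewhere in the package are 1-based positions on
    this sequence.
    """
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    raise ValueError("bait FASTA must contain exactly one record")
                header = line[1:]
            else:
                chunks.append(line)
    if header is None or not chunks:
        raise ValueError("bait FASTA is empty or malformed")
    return header, "".join(chunks).upper()


# ---------------------------------------------------------------------------
# generic table / config plumbing

def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a result table as TSV with a stable float format (so identical
    inputs and seed give byte-identical outputs)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def config_digest(path) -> str:
    """SHA-256 of the config file, recorded in run provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
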