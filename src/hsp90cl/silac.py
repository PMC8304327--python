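"""Peptide-level SILAC quantification and ratio-triplet assembly.

Fragment-ion chromatogram areas are summed per peptide and channel; the
heavy/light ratio of the phosphopeptide (x), its unmodified counterpart
(y), and the whole protein (z, the median ratio of the normalization
peptides) form the (x, y, z) triplet the occupancy algebra consumes.

Scale invariance: multiplying all areas of one replicate by a constant
changes no ratio and no triplet.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, two_sample_t
from .simulate import PrmPanel

logger = logging.getLogger("hsp90cl")

__all__ = [
    "peptide_areas_from_transitions",
    "protein_reference_ratio",
    "assemble_ratio_triplets",
    "normalized_abundance",
    "stress_contrast",
]


def peptide_areas_from_transitions(records: pd.DataFrame) -> pd.DataFrame:
    """Sum fragment areas into per-peptide, per-channel quantities.

    Areas are summed over fragment ions (and charge states) within each
    (peptide, sample, replicate, channel). A peptide with no non-missing
    fragment in a channel gets a missing area there and a flag; the H/L
    ratio is defined only when both channel areas are positive.

    Returns columns ``modified_sequence, sample_id, replicate, area_light,
    area_heavy, hl_ratio, flag``.
    """
    if records.empty:
        return pd.DataFrame(columns=[
            "modified_sequence", "sample_id", "replicate",
            "area_light", "area_heavy", "hl_ratio", "flag"])
    sums = (records
            .groupby(["modified_sequence", "sample_id", "replicate",
                      "label_channel"])["area"]
            .sum(min_count=1)
            .unstack("label_channel"))
    for channel in ("light", "heavy"):
        if channel not in sums.columns:
            sums[channel] = np.nan
    out = sums.reset_index().rename(
        columns={"light": "area_light", "heavy": "area_heavy"})
    valid = (out["area_light"] > 0) & (out["area_heavy"] > 0)
    out["hl_ratio"] = np.where(valid, out["area_heavy"] / out["area_light"],
                               np.nan)
    out["flag"] = np.select(
        [out["area_light"].isna() | (out["area_light"] <= 0),
         out["area_heavy"].isna() | (out["area_heavy"] <= 0)],
        ["light_missing", "heavy_missing"], default="ok")
    return out[["modified_sequence", "sample_id", "replicate",
                "area_light", "area_heavy", "hl_ratio", "flag"]]


def protein_reference_ratio(quants: pd.DataFrame,
                            normalization_peptides: Sequence[str]
                            ) -> pd.DataFrame:
    """The whole-protein H/L ratio z per (sample, replicate).

    z is the median of the normalization peptides' H/L ratios — robust to
    one aberrant peptide. Raises ``ValueError`` for a replicate with no
    valid normalization ratio.

    Returns columns ``sample_id, replicate, z, n_norm_peptides``.
    """
    norm = quants[quants["modified_sequence"].isin(set(normalization_peptides))]
    if norm.empty:
        raise ValueError("no normalization peptides found in the quant table")
    rows = []
    for (sample, rep), grp in norm.groupby(["sample_id", "replicate"]):
        ratios = grp["hl_ratio"].dropna()
        if ratios.empty:
            raise ValueError(
                f"no valid normalization-peptide ratio for sample "
                f"{sample!r} replicate {rep}: z is undefined")
        rows.append((sample, rep, float(ratios.median()), len(ratios)))
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "z",
                                       "n_norm_peptides"])


def assemble_ratio_triplets(quants: pd.DataFrame,
                            panel: PrmPanel | Mapping[str, Sequence],
                            z_table: pd.DataFrame) -> pd.DataFrame:
    """Join phospho/unmodified peptide ratios with z into (x, y, z) triplets.

    ``panel`` maps each site to its (phosphopeptide, unmodified counterpart)
    sequence pairs; each backbone variant (with/without missed cleavage)
    yields its own triplet per replicate. Incomplete triplets are dropped
    with a logged reason.

    Returns columns ``site_id, phosphopeptide, sample_id, replicate,
    x, y, z``.
    """
    mapping = panel.as_mapping() if isinstance(panel, PrmPanel) else dict(panel)
    ratio = {(r.modified_sequence, r.sample_id, r.replicate): r.hl_ratio
             for r in quants.itertuples()}
    known_seqs = set(quants["modified_sequence"])
    rows = []
    for _, zrow in z_table.iterrows():
        key = (zrow.sample_id, zrow.replicate)
        for site, pairs in mapping.items():
            for phospho, unmod in pairs:
                for seq, name in ((phospho, "phosphopeptide"),
                                  (unmod, "unmodified counterpart")):
                    if seq not in known_seqs:
                        logger.warning("site %s: %s %r absent from quant "
                                       "table, skipped", site, name, seq)
                        break
                else:
                    x = ratio.get((phospho, *key), np.nan)
                    y = ratio.get((unmod, *key), np.nan)
                    if not np.isfinite(x):
                        logger.info("site %s rep %s: phosphopeptide ratio "
                                    "missing, triplet dropped", site, key[1])
                        continue
                    if not np.isfinite(y):
                        logger.info("site %s rep %s: unmodified counterpart "
                                    "missing, triplet dropped", site, key[1])
                        continue
                    rows.append((site, phospho, zrow.sample_id,
                                 zrow.replicate, x, y, zrow.z))
    return pd.DataFrame(rows, columns=[
        "site_id", "phosphopeptide", "sample_id", "replicate", "x", "y", "z"])


# ---------------------------------------------------------------------------
# stress-response comparison (input-normalized phosphopeptide abundance)

def normalized_abundance(phospho_area, input_protein_abundance):
    """Phosphopeptide area normalized by the input protein abundance,
    compensating for up-/down-regulation of the protein itself."""
    phospho_area = np.asarray(phospho_area, dtype=float)
    input_protein_abundance = np.asarray(input_protein_abundance, dtype=float)
    if np.any(~(input_protein_abundance > 0)):
        raise ValueError("input protein abundance must be > 0 for every sample")
    return phospho_area / input_protein_abundance


def stress_contrast(data: pd.DataFrame, control: str = "control",
                    equal_var: bool = True) -> pd.DataFrame:
    """Treated-vs-control contrast of normalized phosphopeptide abundance.

    ``data`` columns: ``site_id, condition, replicate, phospho_area,
    input_abundance``. Per (site, condition != control): fold change of mean
    normalized abundance over the control mean, a two-sided t-test across
    replicates, and BH adjustment over all site x condition contrasts.
    """
    df = data.copy()
    df["normalized"] = normalized_abundance(df["phospho_area"],
                                            df["input_abundance"])
    rows = []
    for site, site_df in df.groupby("site_id"):
        ctrl = site_df.loc[site_df["condition"] == control, "normalized"]
        if ctrl.empty:
            raise ValueError(f"no control condition {control!r} for site {site}")
        for cond, grp in site_df.groupby("condition"):
            if cond == control:
                continue
            fold = grp["normalized"].mean() / ctrl.mean()
            t, p = two_sample_t(grp["normalized"], ctrl, equal_var=equal_var)
            rows.append((site, cond, fold, t, p))
    out = pd.DataFrame(rows, columns=["site_id", "condition", "fold_change",
                                      "t", "p"])
    out["adj_p"] = bh_adjust(out["p"])
    return out
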