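"""Limited-proteolysis conformational readouts.

Gel lanes from a trypsin dose series are quantified per peptide and band.
Two ratios summarize cleavage:

* fraction full-length — band-A intensity at a dose relative to band A at
  dose 0 (band A holds the intact protein);
* band-vs-lane — band-A intensity over the summed intensity of all
  analyzed bands in the lane; peptides C-terminal of the dominant cleavage
  site lose their cleaved share to a fragment that can migrate below the
  analyzed range, which shifts this ratio.

Peptides are grouped as before/after/spanning the cleavage site (default
K607, a reported major tryptic site in the bait's C domain); spanning
peptides are excluded from group statistics. Genotype and side comparisons
use Welch t-tests on per-peptide ratios (peptides are pseudo-replicates; a
caveat documented in the methods note) with BH across doses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_adjust, two_sample_t

logger = logging.getLogger("hsp90cl")

__all__ = [
    "fraction_full_length",
    "band_vs_lane_ratio",
    "assign_cleavage_side",
    "compare_genotypes",
    "summarize_ratios",
]

DEFAULT_CLEAVAGE_SITE = 607
FULL_LENGTH_BAND = "A"


def fraction_full_length(matrix: pd.DataFrame) -> pd.DataFrame:
    """Band-A intensity relative to the dose-0 band-A baseline.

    One row per (genotype, dose, peptide). Peptides with a zero or missing
    baseline are excluded with a log entry. At dose 0 the ratio is 1 by
    construction.
    """
    band_a = matrix[matrix["band"] == FULL_LENGTH_BAND]
    baseline = (band_a[band_a["dose"] == 0]
                .set_index(["genotype", "peptide"])["intensity"])
    rows = []
    for r in band_a.itertuples():
        base = baseline.get((r.genotype, r.peptide), np.nan)
        if not np.isfinite(base) or base <= 0:
            logger.warning("peptide %s (%s): zero/missing dose-0 baseline, "
                           "excluded", r.peptide, r.genotype)
            continue
        rows.append((r.genotype, r.dose, r.peptide, r.intensity / base))
    return pd.DataFrame(rows, columns=["genotype", "dose", "peptide",
                                       "ratio"])


def band_vs_lane_ratio(matrix: pd.DataFrame) -> pd.DataFrame:
    """Band-A intensity over the summed intensity of the analyzed lane.

    The lane total is band A plus all other *analyzed* bands (bands flagged
    ``analyzed=False`` migrate outside the quantified range and do not
    contribute). Ratio is in [0, 1]; peptides absent from every analyzed
    band are returned with a NaN ratio and flagged undefined.
    """
    analyzed = matrix[matrix.get("analyzed", True) == True]  # noqa: E712
    rows = []
    for (genotype, dose, peptide), d in analyzed.groupby(
            ["genotype", "dose", "peptide"]):
        total = d["intensity"].sum()
        in_a = d.loc[d["band"] == FULL_LENGTH_BAND, "intensity"].sum()
        if not np.isfinite(total) or total <= 0:
            rows.append((genotype, dose, peptide, np.nan, "undefined"))
            continue
        rows.append((genotype, dose, peptide, in_a / total, "ok"))
    return pd.DataFrame(rows, columns=["genotype", "dose", "peptide",
                                       "ratio", "flag"])


def assign_cleavage_side(spans: pd.DataFrame,
                         site: int = DEFAULT_CLEAVAGE_SITE) -> pd.DataFrame:
    """Classify peptides as before/after/spanning the cleavage site.

    Tryptic cleavage occurs after residue ``site`` (1-based), so a peptide
    ending at or before ``site`` is entirely on the N-side ("before"), one
    starting after ``site`` on the C-side ("after"), anything else spans
    the cut and is excluded from group statistics downstream.
    """
    spans = spans.drop_duplicates(subset="peptide")
    side = np.select(
        [spans["end"] < site + 1, spans["start"] > site],
        ["before", "after"], default="spanning")
    return pd.DataFrame({"peptide": spans["peptide"].to_numpy(),
                         "side": side, "site": site})


def summarize_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style summary (median, quartiles, n) per genotype x dose."""
    rows = []
    for (genotype, dose), d in ratios.groupby(["genotype", "dose"]):
        vals = d["ratio"].dropna()
        rows.append((genotype, dose, vals.median(),
                     vals.quantile(0.25), vals.quantile(0.75), len(vals)))
    return pd.DataFrame(rows, columns=["genotype", "dose", "median",
                                       "q1", "q3", "n"])


def compare_genotypes(ratios: pd.DataFrame, group_col: str = "genotype",
                      groups: tuple = ("WT", "AA"),
                      min_peptides: int = 3) -> pd.DataFrame:
    """Per-dose two-sided Welch t-test between two groups of per-peptide
    ratios (genotypes, or before/after cleavage-site sides), BH across
    doses. Doses with fewer than ``min_peptides`` peptides in either group
    are skipped with a reason. Signed mean differences are reported; no
    direction is assumed.
    """
    g1, g2 = groups
    rows = []
    for dose, d in ratios.groupby("dose"):
        a = d.loc[d[group_col] == g1, "ratio"].dropna()
        b = d.loc[d[group_col] == g2, "ratio"].dropna()
        if len(a) < min_peptides or len(b) < min_peptides:
            rows.append((dose, np.nan, np.nan, np.nan,
                         "too_few_peptides"))
            continue
        t, p = two_sample_t(a, b, equal_var=False)
        rows.append((dose, float(a.mean() - b.mean()), t, p, ""))
    out = pd.DataFrame(rows, columns=["dose", "mean_diff", "t", "p", "note"])
    out["adj_p"] = bh_adjust(out["p"])
    return out
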