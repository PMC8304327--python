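"""Phosphosite occupancy from heavy/light ratio triplets.

The two-channel experiment mixes a native (light) sample of occupancy
``p_L`` with a phosphatase-treated heavy reference of residual occupancy
``p_H`` at protein ratio ``rho``. The measurable H/L ratios are then

    x = rho * p_H / p_L          (phosphopeptide)
    y = rho * (1 - p_H) / (1 - p_L)   (unmodified counterpart)
    z = rho                      (whole protein, from normalization peptides)

Inverting this model gives the closed form implemented here:

    a = (z - y) / (x - z)        occ_light = a / (a + 1) = p_L
    b = a * (x / y)              occ_heavy = b / (b + 1) = p_H

``occ_light`` is algebraically identical to ``(z - y) / (x - y)``, which is
asserted as a cross-check. The ``b`` step follows from substituting the
model into ``a``: a = p_L/(1-p_L), and x/y = [p_H(1-p_L)]/[p_L(1-p_H)], so
a*(x/y) = p_H/(1-p_H).

Degeneracy: at x == z the phospho-form ratio matches the whole-protein
ratio and ``a`` diverges; such triplets are flagged invalid. Noise can push
estimates outside [0, 1]; they are reported unclamped with a flag (silent
clamping would bias group means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, two_sample_t

__all__ = [
    "OccupancyEstimate",
    "compute_occupancy",
    "occupancy_table",
    "co_occupancy_bounds",
    "phosphate_stoichiometry",
    "summarize_and_compare",
]

#: relative |x - z| below which the triplet is considered degenerate
X_EQUALS_Z_TOL = 1e-6

#: out-of-range excess beyond which flagged estimates are excluded from summaries
SUMMARY_EXCESS_TOL = 0.05


@dataclass(frozen=True)
class OccupancyEstimate:
    """Per-triplet occupancy estimate with intermediates and validity."""
    a: float
    b: float
    occ_light: float
    occ_heavy: float
    valid: bool
    flag: str  # ok | x_equals_z | out_of_range | incomplete
    site_id: str = ""
    phosphopeptide: str = ""
    replicate: int | None = None


def compute_occupancy(x: float, y: float, z: float,
                      site_id: str = "", phosphopeptide: str = "",
                      replicate: int | None = None) -> OccupancyEstimate:
    """Occupancy of the light and heavy samples from one (x, y, z) triplet.

    Raises ``ValueError`` on non-positive or non-finite ratios. Returns an
    invalid estimate flagged ``x_equals_z`` when |x - z|/z < 1e-6, and an
    ``out_of_range``-flagged (but unclamped) estimate when noise drives an
    occupancy outside [0, 1].
    """
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"ratio {name} must be positive and finite, got {v}")
    meta = dict(site_id=site_id, phosphopeptide=phosphopeptide,
                replicate=replicate)
    if abs(x - z) / z < X_EQUALS_Z_TOL:
        return OccupancyEstimate(np.nan, np.nan, np.nan, np.nan,
                                 valid=False, flag="x_equals_z", **meta)
    a = (z - y) / (x - z)
    b = a * (x / y)
    occ_light = a / (a + 1.0)
    occ_heavy = b / (b + 1.0)
    flag = "ok"
    if not (0.0 <= occ_light <= 1.0) or not (0.0 <= occ_heavy <= 1.0):
        flag = "out_of_range"
    return OccupancyEstimate(a, b, occ_light, occ_heavy, valid=True,
                             flag=flag, **meta)


def occupancy_table(triplets: pd.DataFrame) -> pd.DataFrame:
    """Vectorize ``compute_occupancy`` over a triplet table.

    ``triplets`` columns: ``site_id, phosphopeptide, sample_id, replicate,
    x, y, z`` (the silac module's output). Returns the same keys plus
    ``a, b, occ_light, occ_heavy, valid, flag``.
    """
    rows = []
    for t in triplets.itertuples():
        est = compute_occupancy(t.x, t.y, t.z, site_id=t.site_id,
                                phosphopeptide=t.phosphopeptide,
                                replicate=t.replicate)
        rows.append((t.site_id, t.phosphopeptide, t.sample_id, t.replicate,
                     est.a, est.b, est.occ_light, est.occ_heavy,
                     est.valid, est.flag))
    return pd.DataFrame(rows, columns=[
        "site_id", "phosphopeptide", "sample_id", "replicate",
        "a", "b", "occ_light", "occ_heavy", "valid", "flag"])


def co_occupancy_bounds(p1: float, p2: float) -> tuple[float, float, float]:
    """Frechet bounds on the fraction of molecules modified at both sites.

    Given marginal occupancies ``p1`` and ``p2``, the joint double-occupancy
    fraction lies in [max(0, p1+p2-1), min(p1, p2)]; the independence point
    ``p1*p2`` is returned as well. E.g. two sites at 95% each imply at least
    90% doubly modified molecules (and at most 95% if fully coupled).

    Returns ``(lower, upper, independent)``.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return max(0.0, p1 + p2 - 1.0), min(p1, p2), p1 * p2


def phosphate_stoichiometry(occupancies) -> float:
    """Moles of phosphate per mole of protein: the sum of site occupancies
    (e.g. two sites at 0.95 carry 1.9 mol phosphate/mol protein)."""
    total = 0.0
    for p in occupancies:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"occupancy must be in [0, 1], got {p}")
        total += p
    return total


def _usable(estimates: pd.DataFrame) -> pd.DataFrame:
    """Valid estimates, keeping out-of-range values only within the excess
    tolerance (larger excursions are excluded, smaller ones kept unclamped
    so group means stay unbiased)."""
    keep = estimates["valid"] & (
        (estimates["flag"] != "out_of_range")
        | estimates["occ_light"].between(-SUMMARY_EXCESS_TOL,
                                         1.0 + SUMMARY_EXCESS_TOL))
    return estimates[keep]


def summarize_and_compare(estimates: pd.DataFrame,
                          group_col: str = "sample_id",
                          reference_group: str | None = None,
                          value_col: str = "occ_light",
                          equal_var: bool = True) -> pd.DataFrame:
    """Per-(site, peptide variant, group) occupancy summaries with optional
    between-group tests.

    Mean and sample sd (n-1 denominator; sd is NaN for n < 2) per group.
    When ``reference_group`` is given, each other group is compared to it
    with a two-sided two-sample t-test (Student by default), and p-values
    are BH-adjusted across the peptide variants tested together; the
    reference group itself gets an NA p-value.
    """
    usable = _usable(estimates)
    rows = []
    for (site, pep, grp), d in usable.groupby(
            ["site_id", "phosphopeptide", group_col]):
        vals = d[value_col].to_numpy()
        n = len(vals)
        rows.append({"site_id": site, "phosphopeptide": pep, group_col: grp,
                     "mean": float(np.mean(vals)) if n else np.nan,
                     "sd": float(np.std(vals, ddof=1)) if n >= 2 else np.nan,
                     "n": n, "p": np.nan})
    # groups where every estimate was invalid still get an n=0 row
    for (site, pep, grp), d in estimates.groupby(
            ["site_id", "phosphopeptide", group_col]):
        if not any(r["site_id"] == site and r["phosphopeptide"] == pep
                   and r[group_col] == grp for r in rows):
            rows.append({"site_id": site, "phosphopeptide": pep,
                         group_col: grp, "mean": np.nan, "sd": np.nan,
                         "n": 0, "p": np.nan})
    summary = pd.DataFrame(rows)

    if reference_group is not None:
        for i, row in summary.iterrows():
            if row[group_col] == reference_group or row["n"] < 2:
                continue
            sel = ((usable["site_id"] == row["site_id"])
                   & (usable["phosphopeptide"] == row["phosphopeptide"]))
            ref = usable[sel & (usable[group_col] == reference_group)]
            if len(ref) < 2:
                continue
            tgt = usable[sel & (usable[group_col] == row[group_col])]
            _, p = two_sample_t(tgt[value_col], ref[value_col],
                                equal_var=equal_var)
            summary.loc[i, "p"] = p
    summary["adj_p"] = bh_adjust(summary["p"])
    return summary.sort_values(["site_id", "phosphopeptide",
                                group_col]).reset_index(drop=True)
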