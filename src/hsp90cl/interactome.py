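"""Differential AP-MS interactome analysis.

Pipeline: QC/count/presence filtering of protein groups, control-only
imputation of missing intensities (down-shifted Gaussian, the de-facto
AP-MS convention), bait normalization for isotope-ratio data, per-group
t-tests with Benjamini-Hochberg correction, interactor calling, and a
hypergeometric over-representation test for annotation terms.

Quantities are handled in log2 throughout; natural-scale iBAQ or H/L ratio
columns are converted on ingest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "filter_protein_groups",
    "quantity_matrix",
    "impute_controls",
    "bait_normalize",
    "call_interactors",
    "enrichment_test",
]

MIN_UNIQUE_PEPTIDES = 2
MIN_PEPTIDES = 4
MIN_MSMS_COUNT = 6


def _sample_cols(groups: pd.DataFrame, design: pd.DataFrame, prefix: str):
    cols = {}
    for s in design["sample_id"]:
        col = f"{prefix} {s}"
        if col not in groups.columns:
            raise ValueError(f"sample column {col!r} declared in the design "
                             "is absent from the protein-group table")
        cols[s] = col
    return cols


def filter_protein_groups(groups: pd.DataFrame, design: pd.DataFrame,
                          mode: str = "labelfree"):
    """Apply the QC, count and presence filters.

    Removed: decoy (reverse), contaminant, and only-identified-by-site
    groups; groups with fewer than 2 unique peptides, 4 peptides, or 6
    MS/MS counts in total; and groups failing the presence rule —
    label-free: not MS/MS-identified in every replicate of at least one
    condition; silac: not identified in all replicates.

    Returns ``(kept, removal_log)`` where the log has one row per removed
    group with the first rule it failed.
    """
    id_cols = _sample_cols(groups, design, "Identification type")
    reasons = pd.Series("", index=groups.index)

    def mark(mask, reason):
        unset = (reasons == "") & mask
        reasons[unset] = reason

    mark(groups["reverse"].astype(bool), "decoy")
    mark(groups["contaminant"].astype(bool), "contaminant")
    mark(groups["only_by_site"].astype(bool), "only_by_site")
    mark(groups["unique_peptides"] < MIN_UNIQUE_PEPTIDES, "unique_peptides")
    mark(groups["peptides"] < MIN_PEPTIDES, "peptides")
    mark(groups["msms_count"] < MIN_MSMS_COUNT, "msms_count")

    identified = groups[[id_cols[s] for s in design["sample_id"]]].astype(bool)
    identified.columns = list(design["sample_id"])
    if mode == "labelfree":
        # identified in all replicates of at least one condition
        ok = pd.Series(False, index=groups.index)
        for _, cond in design.groupby("condition"):
            ok |= identified[list(cond["sample_id"])].all(axis=1)
        mark(~ok, "presence")
    elif mode == "silac":
        mark(~identified.all(axis=1), "presence")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    kept = groups[reasons == ""].reset_index(drop=True)
    removal_log = pd.DataFrame({
        "protein_ids": groups.loc[reasons != "", "protein_ids"],
        "reason": reasons[reasons != ""],
    }).reset_index(drop=True)
    return kept, removal_log


def quantity_matrix(groups: pd.DataFrame, design: pd.DataFrame,
                    mode: str = "labelfree") -> pd.DataFrame:
    """log2 quantity matrix (groups x samples) from iBAQ (label-free) or
    normalized H/L ratio (silac) columns; missing stays NaN."""
    prefix = "iBAQ" if mode == "labelfree" else "Ratio H/L normalized"
    cols = _sample_cols(groups, design, prefix)
    mat = pd.DataFrame(
        {s: np.log2(groups[c].astype(float)) for s, c in cols.items()})
    mat.index = pd.Index(groups["protein_ids"], name="protein_ids")
    return mat


def impute_controls(matrix: pd.DataFrame, control_samples,
                    seed: int = 0, shift: float = 1.8, width: float = 0.3,
                    min_observed: int = 20):
    """Impute missing values in negative-control columns only.

    Missing entries of each control column are drawn from
    ``Normal(mu_s - shift*sigma_s, (width*sigma_s)^2)`` where ``mu_s`` and
    ``sigma_s`` are the observed mean and sd of that column — the standard
    down-shifted Gaussian that places imputed values at the detection-limit
    tail so bait-vs-control t-tests are defined for control-absent
    interactors. Non-control columns are never touched.

    Returns ``(imputed, mask)``; ``mask`` is True exactly at imputed cells.
    """
    control_samples = list(control_samples)
    if not control_samples:
        raise ValueError("control sample list is empty")
    missing_cols = [c for c in control_samples if c not in matrix.columns]
    if missing_cols:
        raise ValueError(f"control samples absent from matrix: {missing_cols}")
    observed_all = matrix.to_numpy()
    n_obs = np.isfinite(observed_all).sum()
    if n_obs < min_observed:
        raise ValueError(
            f"only {n_obs} observed values; need >= {min_observed} to "
            "estimate imputation moments")
    rng = np.random.default_rng(seed)
    global_mu = np.nanmean(observed_all)
    global_sd = np.nanstd(observed_all, ddof=1)

    out = matrix.copy()
    mask = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for col in control_samples:
        vals = matrix[col]
        obs = vals.dropna()
        if obs.empty:
            import logging
            logging.getLogger("hsp90cl").warning(
                "control column %r has no observed values; falling back to "
                "global moments", col)
            mu, sd = global_mu, global_sd
        else:
            mu, sd = obs.mean(), obs.std(ddof=1) if len(obs) > 1 else global_sd
        miss = vals.isna()
        out.loc[miss, col] = rng.normal(mu - shift * sd, width * sd,
                                        int(miss.sum()))
        mask.loc[miss, col] = True
    return out, mask


def bait_normalize(matrix: pd.DataFrame, bait_group: str) -> pd.DataFrame:
    """Align per-replicate log2 ratios on the bait protein.

    Subtracts the bait's log2 ratio from every group within each replicate
    column, so the bait sits exactly at 0 and any constant per-replicate
    offset (e.g. mixing imbalance) cancels.
    """
    if bait_group not in matrix.index:
        raise ValueError(f"bait group {bait_group!r} not in matrix")
    bait = matrix.loc[bait_group]
    missing = [c for c in matrix.columns if not np.isfinite(bait[c])]
    if missing:
        raise ValueError(
            f"bait {bait_group!r} is not quantified in replicate(s): {missing}")
    return matrix.sub(bait, axis=1)


def _row_tests(index, comparison: str, a: np.ndarray,
               b: np.ndarray | None) -> pd.DataFrame:
    """Row-wise Student t-tests (two-sample when ``b`` is given, one-sample
    vs 0 otherwise), with the degenerate-variance convention of
    :mod:`hsp90cl._stats` applied per row."""
    def row_mean(m, n):
        return np.where(n > 0,
                        np.where(np.isfinite(m), m, 0.0).sum(axis=1)
                        / np.maximum(n, 1), np.nan)

    def row_var_zero(m, mean, n):
        dev = np.where(np.isfinite(m), m - mean[:, None], 0.0)
        return (dev ** 2).sum(axis=1) == 0

    n_a = np.isfinite(a).sum(axis=1)
    mean_a = row_mean(a, n_a)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if b is None:
            testable = n_a >= 2
            t, p = stats.ttest_1samp(a, 0.0, axis=1, nan_policy="omit")
            diff = mean_a
            var_zero = row_var_zero(a, mean_a, n_a)
            equal_means = mean_a == 0.0
        else:
            n_b = np.isfinite(b).sum(axis=1)
            testable = (n_a >= 2) & (n_b >= 2)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=True,
                                   nan_policy="omit")
            mean_b = row_mean(b, n_b)
            diff = mean_a - mean_b
            var_zero = (row_var_zero(a, mean_a, n_a)
                        & row_var_zero(b, mean_b, n_b))
            equal_means = diff == 0.0
    t = np.asarray(t, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    deg = testable & var_zero
    t[deg & equal_means], p[deg & equal_means] = 0.0, 1.0
    p[deg & ~equal_means] = 0.0
    t[deg & ~equal_means] = np.sign(diff[deg & ~equal_means]) * np.inf
    t[~testable] = p[~testable] = diff[~testable] = np.nan
    return pd.DataFrame({
        "protein_ids": index, "comparison": comparison,
        "mean_log2_diff": diff, "t": t, "p": p,
        "note": np.where(testable, "", "too_few_replicates")})


def call_interactors(matrix: pd.DataFrame, design: pd.DataFrame,
                     mode: str = "labelfree", alpha: float = 0.05,
                     min_abs_log2: float = 3.0,
                     display_log2: float = 0.4) -> pd.DataFrame:
    """Test each protein group and call interactors.

    Label-free: for each bait condition, a two-sample Student t-test of the
    condition's log2 iBAQ values against the control samples, BH across all
    tested groups; ``specific`` requires adjusted p < ``alpha`` and
    |mean log2 difference| >= ``min_abs_log2`` (default 3, i.e. 8-fold).

    SILAC: a one-sample Student t-test of the bait-normalized log2 H/L
    ratios against 0 per group (each replicate carries both conditions in
    one ratio), BH across groups; ``regulated`` requires adjusted
    p < ``alpha``. ``display_log2`` only classifies the direction column.

    Returns one row per (group, comparison) with ``mean_log2_diff, t, p,
    adj_p, specific, direction``.
    """
    if mode == "labelfree":
        controls = design.loc[design["is_control"], "sample_id"].tolist()
        if not controls:
            raise ValueError("label-free design declares no control samples")
        bait_conditions = [c for c in design["condition"].unique()
                           if not design.loc[design["condition"] == c,
                                             "is_control"].any()]
        b = matrix[controls].to_numpy(dtype=float)
        frames = []
        for cond in bait_conditions:
            samples = design.loc[design["condition"] == cond,
                                 "sample_id"].tolist()
            a = matrix[samples].to_numpy(dtype=float)
            frames.append(_row_tests(matrix.index, f"{cond}_vs_control",
                                     a, b))
        out = pd.concat(frames, ignore_index=True)
        out["adj_p"] = np.nan
        for comp, idx in out.groupby("comparison").groups.items():
            out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p"])
        out["specific"] = ((out["adj_p"] < alpha)
                           & (out["mean_log2_diff"].abs() >= min_abs_log2))
        out["direction"] = "none"
        return out

    if mode == "silac":
        out = _row_tests(matrix.index, "WT_vs_AA",
                         matrix.to_numpy(dtype=float), None)
        out["adj_p"] = bh_adjust(out["p"])
        out["specific"] = out["adj_p"] < alpha  # "regulated" in this mode
        # H/L = WT/AA: positive mean ratio means more bound to WT
        out["direction"] = np.select(
            [out["specific"] & (out["mean_log2_diff"] >= display_log2),
             out["specific"] & (out["mean_log2_diff"] <= -display_log2)],
            ["up_in_WT", "up_in_AA"], default="none")
        return out

    raise ValueError(f"unknown mode {mode!r}")


def enrichment_test(hits, background, annotations) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation terms.

    For each term with annotated set ``K`` within the ``background``
    population ``N`` and ``k`` of the ``n`` hits annotated, the upper-tail
    p-value P(X >= k) is computed and BH-adjusted across terms. The
    GeneRatio ``k/K`` (hits with the term over background proteins with the
    term) is reported for plotting.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    N, n = len(background), len(hits)
    rows = []
    for term, members in annotations.items():
        members = set(members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, (k / K) if K else np.nan, p))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N",
                                      "gene_ratio", "p"])
    out["adj_p"] = bh_adjust(out["p"])
    return out.sort_values("p").reset_index(drop=True)
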