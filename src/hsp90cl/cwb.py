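"""Capillary-western (CWB) quantitative estimators.

Signals are instrument-exported scalars. Because only a fraction of each
compartment is loaded on the instrument, signals are first scaled to the
whole sample (``total = signal / fraction_analyzed``); the absolute ratio
``total_CM / (total_CM + total_lysate)`` is then the fraction of the
protein found in the conditioned medium. Subtracting the mean absolute
ratio of a non-secreted control protein (beta-actin) removes the baseline
of accidental release, leaving the regulated secreted fraction.

The ATP/ADP active-site probe readout normalizes the desthiobiotin signal
by the HA-tag signal of the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import two_sample_t

__all__ = [
    "absolute_ratio",
    "absolute_ratio_table",
    "secreted_fraction",
    "SecretionEstimate",
    "probe_binding",
]


def absolute_ratio(cm_signal: float, cm_fraction: float,
                   input_signal: float, input_fraction: float) -> float:
    """Fraction of the protein in the conditioned medium.

    Each signal is scaled to the totality of its sample before the ratio
    ``total_CM / (total_CM + total_input)`` is formed; the result is
    invariant to rescaling both signals by a common constant. Returns NaN
    when both totals are zero.
    """
    for name, fa in (("cm_fraction", cm_fraction),
                     ("input_fraction", input_fraction)):
        if not (0.0 < fa <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {fa}")
    if cm_signal < 0 or input_signal < 0:
        raise ValueError("signals must be nonnegative")
    total_cm = cm_signal / cm_fraction
    total_input = input_signal / input_fraction
    if total_cm + total_input == 0:
        return np.nan
    return total_cm / (total_cm + total_input)


def absolute_ratio_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pair CM and lysate rows and compute per-replicate absolute ratios.

    ``measurements`` columns: ``target, compartment, construct, replicate,
    signal, fraction_analyzed`` (compartments "CM" and "lysate"). Returns
    one row per (target, construct, replicate) with the absolute ratio.
    """
    wide = measurements.pivot_table(
        index=["target", "construct", "replicate"],
        columns="compartment", values=["signal", "fraction_analyzed"],
        aggfunc="first")
    rows = []
    for (target, construct, rep), r in wide.iterrows():
        ratio = absolute_ratio(r[("signal", "CM")],
                               r[("fraction_analyzed", "CM")],
                               r[("signal", "lysate")],
                               r[("fraction_analyzed", "lysate")])
        rows.append((target, construct, rep, ratio))
    return pd.DataFrame(rows, columns=["target", "construct", "replicate",
                                       "absolute_ratio"])


@dataclass(frozen=True)
class SecretionEstimate:
    construct: str
    mean: float
    sd: float
    n: int
    baseline: float


def secreted_fraction(ha_ratios: pd.DataFrame, actin_ratios: pd.DataFrame,
                      compare: tuple | None = ("WT", "AA"),
                      pooled_baseline: bool = True,
                      equal_var: bool = True):
    """Baseline-corrected secreted fraction per construct, with a t-test.

    ``ha_ratios`` / ``actin_ratios``: per-replicate absolute ratios
    (columns ``construct, replicate, absolute_ratio``). The baseline is the
    mean actin absolute ratio, pooled across constructs by default (the
    accidental-release level is a property of the protocol, not of the
    construct; per-construct baselines are available with
    ``pooled_baseline=False``). Per-replicate corrected values are HA ratio
    minus baseline — negative values are reported, not clamped.

    Returns ``(estimates, p_value)``: a list of ``SecretionEstimate`` and
    the two-sided Student t-test p-value between the two ``compare``
    constructs on the corrected values (None when not requested).
    """
    if actin_ratios.empty:
        raise ValueError("no actin measurements: baseline is undefined")
    global_baseline = float(actin_ratios["absolute_ratio"].mean())

    corrected = {}
    estimates = []
    for construct, d in ha_ratios.groupby("construct"):
        if pooled_baseline:
            baseline = global_baseline
        else:
            own = actin_ratios.loc[actin_ratios["construct"] == construct,
                                   "absolute_ratio"]
            baseline = float(own.mean()) if len(own) else global_baseline
        vals = (d["absolute_ratio"] - baseline).to_numpy()
        corrected[construct] = vals
        estimates.append(SecretionEstimate(
            construct=construct, mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
            n=len(vals), baseline=baseline))

    p_value = None
    if compare is not None and all(c in corrected for c in compare):
        _, p_value = two_sample_t(corrected[compare[0]],
                                  corrected[compare[1]],
                                  equal_var=equal_var)
    return estimates, p_value


def probe_binding(measurements: pd.DataFrame,
                  compare: tuple = ("WT", "AA"),
                  equal_var: bool = True):
    """Desthiobiotin signal normalized by HA-tag signal, per construct and
    nucleotide, with a per-nucleotide Student t-test between constructs.

    ``measurements`` columns: ``target`` ("desthiobiotin"/"HA"),
    ``construct, nucleotide, replicate, signal``. Replicates with an HA
    signal of 0 are invalid and excluded (flagged in the returned
    per-replicate table); the others are unaffected.

    Returns ``(per_replicate, summary)``; ``summary`` has one row per
    (construct, nucleotide) with mean, sd, n, and the comparison p-value
    attached per nucleotide.
    """
    wide = measurements.pivot_table(
        index=["construct", "nucleotide", "replicate"],
        columns="target", values="signal", aggfunc="first").reset_index()
    for col in ("desthiobiotin", "HA"):
        if col not in wide.columns:
            raise ValueError(f"measurements lack {col!r} rows")
    invalid = ~(wide["HA"] > 0)
    wide["normalized"] = np.where(invalid, np.nan,
                                  wide["desthiobiotin"] / wide["HA"])
    wide["flag"] = np.where(invalid, "ha_signal_zero", "ok")

    rows = []
    for (construct, nucleotide), d in wide.groupby(["construct",
                                                    "nucleotide"]):
        vals = d["normalized"].dropna()
        rows.append((construct, nucleotide, vals.mean(),
                     vals.std(ddof=1) if len(vals) >= 2 else np.nan,
                     len(vals)))
    summary = pd.DataFrame(rows, columns=["construct", "nucleotide",
                                          "mean", "sd", "n"])
    summary["p_vs_other"] = np.nan
    for nucleotide, d in wide.groupby("nucleotide"):
        a = d.loc[d["construct"] == compare[0], "normalized"].dropna()
        b = d.loc[d["construct"] == compare[1], "normalized"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            _, p = two_sample_t(a, b, equal_var=equal_var)
            summary.loc[summary["nucleotide"] == nucleotide, "p_vs_other"] = p
    return wide, summary
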