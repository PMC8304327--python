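"""Forward simulators for every assay in the pipeline, with known truth.

Each simulator emits (i) a table in exactly the dialect the corresponding
reader/analysis stage consumes and (ii) a machine-readable truth table, so
every downstream estimator can be tested end-to-end without external data.

The four generative models:

* **PRM occupancy** — a two-state phospho/non-phospho mixing model. The
  light channel is the native sample with per-site occupancy ``p``; the
  heavy channel is the phosphatase-treated reference with residual occupancy
  ``q`` (near 0) mixed at protein ratio ``rho`` (heavy/light). For peptide
  species *k* and channel *c*, the expected fragment area is
  ``A_c * w_k * f_k(occ_c) * eps_k * phi_frag`` with ``A_light=1``,
  ``A_heavy=rho``, ``w_k`` the missed-cleavage species fraction (shared
  between channels: the channels are mixed before digestion), ``f_k`` the
  phospho-form fraction under the channel's occupancy, ``eps_k`` a
  per-species log-normal ionization factor identical across channels, and
  fixed fragment proportions. Observed areas carry independent
  multiplicative log-normal noise.
* **co-IP protein groups** — label-free: log2 iBAQ values normal around
  condition means, true interactors enriched in bait conditions and missing
  in negative controls with a configurable probability; SILAC: one
  bait-anchored normalized H/L ratio per replicate. Decoy and contaminant
  rows and count-filter failures are injected.
* **limited proteolysis** — a single dominant tryptic cleavage site. The
  full-length fraction ``F(dose)`` per genotype is configured directly;
  cleaved molecules split into an N-side fragment band and a small C-side
  fragment band that (by default) migrates below the analyzed lane range.
* **capillary western (CWB)** — secreted fraction plus a baseline of
  accidental release for the tagged protein; baseline only for the actin
  control; signals scaled by the analyzed fraction of each compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptidePair",
    "PrmPanel",
    "PrmTruth",
    "CoipTruth",
    "ProteolysisTruth",
    "CwbTruth",
    "default_prm_panel",
    "default_band_panel",
    "simulate_prm_experiment",
    "simulate_coip_tables",
    "simulate_proteolysis_bands",
    "simulate_cwb_signals",
]

FRAGMENT_IONS = ("y7", "y5", "b3")
FRAGMENT_PROPORTIONS = (0.5, 0.3, 0.2)  # fixed per peptide, no fragment noise correlation


# ---------------------------------------------------------------------------
# PRM occupancy experiment

@dataclass(frozen=True)
class PeptidePair:
    """One peptide species pair reporting on a phosphosite.

    ``weight`` is the fraction of the protein pool digested into this
    backbone variant (missed-cleavage species); weights of the variants of
    one site need not sum to 1 (the remainder is unobserved species).
    """
    site: str
    phospho: str
    unmodified: str
    charge: int = 2
    weight: float = 1.0


@dataclass(frozen=True)
class PrmPanel:
    pairs: tuple[PeptidePair, ...]
    normalization: tuple[str, ...]

    def sites(self) -> list:
        seen = []
        for p in self.pairs:
            if p.site not in seen:
                seen.append(p.site)
        return seen

    def as_mapping(self) -> dict:
        """site -> list of (phospho, unmodified) sequence pairs."""
        out: dict = {}
        for p in self.pairs:
            out.setdefault(p.site, []).append((p.phospho, p.unmodified))
        return out


def default_prm_panel() -> PrmPanel:
    """The human Hsp90beta charged-linker panel.

    Two tryptic backbone variants per site (with and without missed
    cleavage, the incomplete digestion being caused by the acidic linker
    sequence) plus normalization peptides outside the linker used for the
    whole-protein H/L ratio.
    """
    return PrmPanel(
        pairs=(
            PeptidePair("S226", "EIpSDDEAEEEK", "EISDDEAEEEK", 2, 0.55),
            PeptidePair("S226", "EKEIpSDDEAEEEK", "EKEISDDEAEEEK", 2, 0.35),
            PeptidePair("S255", "IEDVGpSDEEDDSGK", "IEDVGSDEEDDSGK", 2, 0.55),
            PeptidePair("S255", "IEDVGpSDEEDDSGKDKK", "IEDVGSDEEDDSGKDKK", 3, 0.35),
        ),
        normalization=("SIYYITGESK", "YIDQEELNK", "NPDDITNEEYGEFYK"),
    )


@dataclass(frozen=True)
class PrmTruth:
    """Ground truth for the two-channel occupancy experiment.

    occupancy_light
        per-site phospho occupancy of the native (light) sample, in [0, 1].
    occupancy_heavy
        per-site residual occupancy of the phosphatase-treated heavy
        reference; default 0.01 (dephosphorylation is near-complete but not
        assumed perfect).
    mixing_ratio
        heavy/light protein amount rho > 0.
    noise_sd
        log-scale multiplicative noise sd on observed areas.
    """
    occupancy_light: Mapping[str, float]
    occupancy_heavy: Mapping[str, float] | float = 0.01
    mixing_ratio: float = 1.0
    noise_sd: float = 0.1
    n_replicates: int = 3
    sample_id: str = "synthetic"
    ionization_sd: float = 0.5

    def heavy_for(self, site: str) -> float:
        if isinstance(self.occupancy_heavy, Mapping):
            return float(self.occupancy_heavy[site])
        return float(self.occupancy_heavy)


def _check_prob(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return float(value)


def simulate_prm_experiment(truth: PrmTruth, panel: PrmPanel | None = None,
                            seed: int = 0):
    """Simulate a transition report under the two-state mixing model.

    Returns ``(transitions, truth_table)``: a fragment-area table in the
    reader dialect and a truth table with one row per site
    (``site, occupancy_light, occupancy_heavy, mixing_ratio``).
    """
    panel = panel or default_prm_panel()
    if not panel.normalization:
        raise ValueError("panel must include normalization peptides "
                         "(the whole-protein ratio z is undefined without them)")
    if truth.mixing_ratio <= 0:
        raise ValueError(f"mixing_ratio must be > 0, got {truth.mixing_ratio}")
    if truth.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for site in panel.sites():
        _check_prob(truth.occupancy_light[site], f"occupancy_light[{site}]")
        _check_prob(truth.heavy_for(site), f"occupancy_heavy[{site}]")

    rng = np.random.default_rng(seed)
    rho = truth.mixing_ratio
    rows = []

    def emit(sequence, charge, species_amounts, replicate, eps):
        # species_amounts: {channel: expected peptide amount before ionization}
        for channel, amount in species_amounts.items():
            for frag, phi in zip(FRAGMENT_IONS, FRAGMENT_PROPORTIONS):
                noise = np.exp(rng.normal(0.0, truth.noise_sd)) \
                    if truth.noise_sd > 0 else 1.0
                rows.append((sequence, charge, frag, channel,
                             truth.sample_id, replicate,
                             amount * eps * phi * noise))

    for replicate in range(1, truth.n_replicates + 1):
        for pair in panel.pairs:
            p = truth.occupancy_light[pair.site]
            q = truth.heavy_for(pair.site)
            # one ionization factor per molecular species, shared by channels
            eps_p = np.exp(rng.normal(0.0, truth.ionization_sd))
            eps_u = np.exp(rng.normal(0.0, truth.ionization_sd))
            emit(pair.phospho, pair.charge,
                 {"light": pair.weight * p, "heavy": rho * pair.weight * q},
                 replicate, eps_p)
            emit(pair.unmodified, pair.charge,
                 {"light": pair.weight * (1 - p),
                  "heavy": rho * pair.weight * (1 - q)},
                 replicate, eps_u)
        for norm in panel.normalization:
            eps_n = np.exp(rng.normal(0.0, truth.ionization_sd))
            emit(norm, 2, {"light": 1.0, "heavy": rho}, replicate, eps_n)

    transitions = pd.DataFrame(rows, columns=[
        "modified_sequence", "precursor_charge", "fragment_ion",
        "label_channel", "sample_id", "replicate", "area"])
    truth_table = pd.DataFrame({
        "site": panel.sites(),
        "occupancy_light": [truth.occupancy_light[s] for s in panel.sites()],
        "occupancy_heavy": [truth.heavy_for(s) for s in panel.sites()],
        "mixing_ratio": rho,
    })
    return transitions, truth_table


# ---------------------------------------------------------------------------
# co-IP protein-group tables

@dataclass(frozen=True)
class CoipTruth:
    """Ground truth for the differential AP-MS simulation.

    Label-free design: 3 conditions (WT bait, AA bait, untagged control)
    x 6 replicates (two experiments of three). SILAC design: one
    heavy(WT)/light(AA) ratio per replicate, 4 replicates.
    """
    n_true_interactors: int = 50
    n_background: int = 200
    enrichment_log2: float = 4.0       # bait conditions over control
    wt_aa_shift_log2: float = 0.5      # interactor excess in AA over WT
    control_missing_rate: float = 0.9  # P(interactor missing in a control sample)
    noise_sd_log2: float = 0.5         # label-free log2 iBAQ scatter
    silac_noise_sd_log2: float = 0.1   # duplex ratios are far more precise
    baseline_log2_ibaq: float = 25.0
    frac_fail_counts: float = 0.05     # background failing the count filters
    frac_fail_presence: float = 0.05   # background missing in >=1 replicate everywhere
    n_decoys: int = 8
    n_contaminants: int = 8
    n_replicates_labelfree: int = 6
    n_replicates_silac: int = 4
    bait_id: str = "BAIT_HSP90AB1"
    bait_log2_offset: float = 0.7      # uncorrected bait H/L (mixing imbalance)

    def __post_init__(self):
        if self.n_replicates_labelfree <= 0 or self.n_replicates_silac <= 0:
            raise ValueError("replicate counts must be positive")
        _check_prob(self.control_missing_rate, "control_missing_rate")


LABELFREE_CONDITIONS = ("WT", "AA", "ctrl")


def coip_design(truth: CoipTruth, mode: str) -> pd.DataFrame:
    """Sample design table matching the simulated columns."""
    if mode == "labelfree":
        rows = [(f"{c}_{r}", c, r, c == "ctrl")
                for c in LABELFREE_CONDITIONS
                for r in range(1, truth.n_replicates_labelfree + 1)]
    elif mode == "silac":
        rows = [(f"rep{r}", "WTvsAA", r, False)
                for r in range(1, truth.n_replicates_silac + 1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate",
                                       "is_control"])


def _passing_counts(rng, n):
    unique = rng.integers(2, 20, n)
    peptides = unique + rng.integers(2, 10, n)
    msms = peptides * rng.integers(2, 6, n)
    return unique, peptides, np.maximum(msms, 6)


def _failing_counts(rng, n):
    """Each row fails at least one of the count thresholds."""
    unique = rng.integers(2, 6, n)
    peptides = unique + rng.integers(2, 6, n)
    msms = np.maximum(peptides, 6)
    which = rng.integers(0, 3, n)
    unique = np.where(which == 0, 1, unique)
    peptides = np.where(which == 1, 3, np.maximum(peptides, 4))
    unique = np.where(which == 1, np.minimum(unique, 3), unique)
    msms = np.where(which == 2, 5, msms)
    return unique, peptides, msms


def simulate_coip_tables(truth: CoipTruth, mode: str = "labelfree",
                         seed: int = 0):
    """Simulate a proteinGroups-style table plus its truth table.

    Returns ``(groups, truth_table, design)`` where ``groups`` matches the
    ``read_protein_groups`` output schema and ``truth_table`` has columns
    ``protein_ids, is_interactor, enrichment_log2, silac_shift_log2,
    passes_counts``.
    """
    design = coip_design(truth, mode)
    rng = np.random.default_rng(seed)
    n_int, n_bg = truth.n_true_interactors, truth.n_background
    ids = ([truth.bait_id]
           + [f"INT{i:04d}" for i in range(n_int)]
           + [f"BG{i:04d}" for i in range(n_bg)])
    is_interactor = np.array([False] + [True] * n_int + [False] * n_bg)
    n = len(ids)

    unique, peptides, msms = _passing_counts(rng, n)
    n_fail = int(round(truth.frac_fail_counts * n_bg))
    fail_idx = 1 + n_int + rng.choice(n_bg, n_fail, replace=False)
    if n_fail:
        fu, fp, fm = _failing_counts(rng, n_fail)
        unique[fail_idx], peptides[fail_idx], msms[fail_idx] = fu, fp, fm
    unique[0], peptides[0], msms[0] = 40, 55, 400  # bait

    groups = pd.DataFrame({
        "protein_ids": ids,
        "gene_names": [i.split("_")[-1] for i in ids],
        "reverse": False, "contaminant": False, "only_by_site": False,
        "unique_peptides": unique, "peptides": peptides, "msms_count": msms,
    })

    n_fail_pres = int(round(truth.frac_fail_presence * n_bg))
    pres_fail = np.zeros(n, dtype=bool)
    if n_fail_pres:
        cand = np.setdiff1d(1 + n_int + np.arange(n_bg), fail_idx)
        pres_fail[rng.choice(cand, min(n_fail_pres, cand.size), replace=False)] = True

    if mode == "labelfree":
        base = truth.baseline_log2_ibaq
        for _, s in design.iterrows():
            mean = np.full(n, base, dtype=float)
            if s.condition in ("WT", "AA"):
                mean[is_interactor] += truth.enrichment_log2
                if s.condition == "AA":
                    mean[is_interactor] += truth.wt_aa_shift_log2
            mean[0] = base + 10  # bait dominates its own IPs
            vals = rng.normal(mean, truth.noise_sd_log2)
            identified = np.ones(n, dtype=bool)
            if s.is_control:
                drop = rng.random(n) < truth.control_missing_rate
                drop &= is_interactor
                identified &= ~drop
            # presence-failing background: missing in one replicate everywhere
            if s.replicate == 1:
                identified &= ~pres_fail
            vals = np.where(identified, vals, np.nan)
            groups[f"iBAQ {s.sample_id}"] = np.exp2(vals)
            groups[f"Identification type {s.sample_id}"] = identified
        silac_shift = np.zeros(n)
    elif mode == "silac":
        # H/L = WT/AA; interactors more abundant in AA => negative log2 shift
        silac_shift = np.where(is_interactor, -truth.wt_aa_shift_log2, 0.0)
        silac_shift[0] = 0.0
        for _, s in design.iterrows():
            vals = rng.normal(truth.bait_log2_offset + silac_shift,
                              truth.silac_noise_sd_log2)
            vals[0] = truth.bait_log2_offset + rng.normal(0.0, 0.02)
            identified = np.ones(n, dtype=bool)
            if s.replicate == 1:
                identified &= ~pres_fail
            vals = np.where(identified, vals, np.nan)
            groups[f"Ratio H/L normalized {s.sample_id}"] = np.exp2(vals)
            groups[f"Identification type {s.sample_id}"] = identified
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # decoy and contaminant rows: sparse low-count junk
    junk = []
    for i in range(truth.n_decoys):
        junk.append(("REV__P%05d" % i, True, False))
    for i in range(truth.n_contaminants):
        junk.append(("CON__P%05d" % i, False, True))
    junk_rows = []
    for pid, rev, con in junk:
        row = {c: (np.nan if c.startswith(("iBAQ", "Ratio")) else False)
               for c in groups.columns}
        row.update(protein_ids=pid, gene_names="", reverse=rev,
                   contaminant=con, only_by_site=False,
                   unique_peptides=int(rng.integers(1, 3)),
                   peptides=int(rng.integers(1, 4)),
                   msms_count=int(rng.integers(1, 6)))
        junk_rows.append(row)
    groups = pd.concat([groups, pd.DataFrame(junk_rows)], ignore_index=True)

    truth_table = pd.DataFrame({
        "protein_ids": ids,
        "is_interactor": is_interactor,
        "enrichment_log2": np.where(is_interactor, truth.enrichment_log2, 0.0),
        "silac_shift_log2": silac_shift,
        "passes_counts": ~np.isin(np.arange(n), fail_idx),
    })
    return groups, truth_table, design


# ---------------------------------------------------------------------------
# limited proteolysis

@dataclass(frozen=True)
class ProteolysisTruth:
    """Dose-response of full-length fraction remaining, per genotype.

    Default fractions follow the observed wild-type vs phospho-dead (AA)
    behaviour: at 7 and 14 ng/uL trypsin the full-length fraction drops to
    0.35/0.10 (WT) and 0.22/0.06 (AA).
    """
    full_length_fraction: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {
            "WT": {0.0: 1.0, 7.0: 0.35, 14.0: 0.10},
            "AA": {0.0: 1.0, 7.0: 0.22, 14.0: 0.06},
        })
    cleavage_site: int = 607
    protein_length: int = 724
    noise_sd: float = 0.05
    intensity_scale: float = 1e6
    small_fragment_analyzed: bool = False  # the C-side product runs below the lane cut


def default_band_panel(protein_length: int = 724) -> pd.DataFrame:
    """Peptide spans tiling the bait from the N-domain to the C-terminus.

    Sequences are synthetic placeholder labels; only the residue spans
    matter to the band arithmetic.
    """
    spans = [(42, 55), (60, 74), (95, 110), (140, 152), (180, 196),
             (230, 244), (280, 291), (330, 345), (380, 398), (420, 433),
             (470, 486), (510, 525), (550, 566), (580, 594),
             (600, 615),                      # spans the cleavage site
             (620, 635), (645, 661), (668, 679)]
    rows = [("pep_%03d_%03d" % (s, e), s, e) for s, e in spans
            if e <= protein_length]
    return pd.DataFrame(rows, columns=["peptide", "start", "end"])


def simulate_proteolysis_bands(truth: ProteolysisTruth | None = None,
                               panel: pd.DataFrame | None = None,
                               seed: int = 0):
    """Simulate per-band peptide intensities across trypsin doses.

    Returns ``(matrix, truth_table)``. ``matrix`` columns: peptide, start,
    end, genotype, dose, band, analyzed, intensity. Band "A" holds the
    full-length protein; band "N70" the N-side cleavage product; band
    "C12" the small C-side product (marked not analyzed by default, i.e.
    it migrates below the lane's analysis range).
    """
    truth = truth or ProteolysisTruth()
    panel = panel if panel is not None else default_band_panel(truth.protein_length)
    if (panel["start"] < 1).any() or (panel["end"] > truth.protein_length).any():
        raise ValueError("peptide span outside protein length")
    if (panel["start"] > panel["end"]).any():
        raise ValueError("peptide span has start > end")
    for genotype, fracs in truth.full_length_fraction.items():
        if 0.0 not in fracs and 0 not in fracs:
            raise ValueError(f"dose set for {genotype} must include 0")

    rng = np.random.default_rng(seed)
    site = truth.cleavage_site

    def noisy(x):
        if truth.noise_sd <= 0:
            return x
        return x * np.exp(rng.normal(0.0, truth.noise_sd))

    rows, truth_rows = [], []
    for genotype, fracs in truth.full_length_fraction.items():
        base = {p: truth.intensity_scale * np.exp(rng.normal(0.0, 0.3))
                for p in panel["peptide"]}
        for dose, F in sorted(fracs.items()):
            truth_rows.append((genotype, dose, F))
            for _, pep in panel.iterrows():
                amount_full = base[pep.peptide] * F
                rows.append((pep.peptide, pep.start, pep.end, genotype, dose,
                             "A", True, noisy(amount_full)))
                if dose <= 0 or F >= 1.0:
                    continue
                amount_cut = base[pep.peptide] * (1.0 - F)
                if pep.end <= site:            # N-side of the cut
                    rows.append((pep.peptide, pep.start, pep.end, genotype,
                                 dose, "N70", True, noisy(amount_cut)))
                elif pep.start > site:         # C-side small fragment
                    rows.append((pep.peptide, pep.start, pep.end, genotype,
                                 dose, "C12", truth.small_fragment_analyzed,
                                 noisy(amount_cut)))
                # peptides spanning the cut are destroyed in cleaved molecules

    matrix = pd.DataFrame(rows, columns=[
        "peptide", "start", "end", "genotype", "dose", "band", "analyzed",
        "intensity"])
    truth_table = pd.DataFrame(truth_rows, columns=[
        "genotype", "dose", "full_length_fraction"])
    return matrix, truth_table


# ---------------------------------------------------------------------------
# capillary western secretion signals

@dataclass(frozen=True)
class CwbTruth:
    """Ground truth for the secretion assay.

    ``secreted_fraction`` is the regulated secreted fraction per construct;
    ``baseline_release`` the accidental-release fraction seen by the
    non-secreted actin control (and added to the tagged protein's CM
    fraction).
    """
    secreted_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.016, "AA": 0.045})
    baseline_release: float = 0.03
    noise_sd: float = 0.1
    n_replicates: int = 3
    fraction_analyzed: Mapping[str, float] = field(
        default_factory=lambda: {"CM": 0.2, "lysate": 0.02})
    total_signal: float = 1000.0


def simulate_cwb_signals(truth: CwbTruth | None = None, seed: int = 0):
    """Simulate CWB signal rows for HA-tagged protein and actin control.

    Returns ``(measurements, truth_table)`` with measurement columns
    ``target, compartment, construct, nucleotide, replicate, signal,
    fraction_analyzed``.
    """
    truth = truth or CwbTruth()
    for comp, fa in truth.fraction_analyzed.items():
        if not (0.0 < fa <= 1.0):
            raise ValueError(f"fraction_analyzed[{comp}] must be in (0, 1], got {fa}")
    b = _check_prob(truth.baseline_release, "baseline_release")
    rng = np.random.default_rng(seed)

    def noisy(x):
        if truth.noise_sd <= 0:
            return x
        return x * np.exp(rng.normal(0.0, truth.noise_sd))

    rows = []
    for construct, s in truth.secreted_fraction.items():
        _check_prob(s, f"secreted_fraction[{construct}]")
        for rep in range(1, truth.n_replicates + 1):
            cm_frac = s + b
            for target, cm_amount in (("HA", cm_frac), ("actin", b)):
                for comp, amount in (("CM", cm_amount), ("lysate", 1.0 - cm_amount)):
                    fa = truth.fraction_analyzed[comp]
                    rows.append((target, comp, construct, "none", rep,
                                 noisy(truth.total_signal * amount * fa), fa))
    measurements = pd.DataFrame(rows, columns=[
        "target", "compartment", "construct", "nucleotide", "replicate",
        "signal", "fraction_analyzed"])
    truth_table = pd.DataFrame({
        "construct": list(truth.secreted_fraction),
        "secreted_fraction": list(truth.secreted_fraction.values()),
        "baseline_release": b,
    })
    return measurements, truth_table
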