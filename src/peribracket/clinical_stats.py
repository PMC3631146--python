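"""Microbial and periodontal statistics of the peri-bracket cohort.

Bacterial load is estimated from serial 10-fold dilution plating of 50 ul
aliquots (plates countable below 300 colonies), log10-transformed and
summarised per site (BO/BG/BL/BR) at the bracket (T1) and archwire (T2)
visits, with the pre-bonding baseline (T0) sampled at the bracket area.
Site means are compared pairwise within patients; longitudinal gingival
index (GI) changes use the Wilcoxon signed-rank test and pocket depth (PD)
changes the paired t-test, with p < 0.05 taken as significant.

Records are pandas DataFrames with columns ``patient_id``, ``timepoint``
(T0/T1/T2), ``site`` (BRACKET_AREA at T0, else BO/BG/BL/BR), ``log10_cfu``,
``gi``, ``pd``.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import (
    BelowDetectionError,
    DegenerateInputError,
    SchemaError,
    UncountablePlateError,
)

SITES = ("BO", "BG", "BL", "BR")
SITE_PAIRS = tuple(itertools.combinations(SITES, 2))
TIMEPOINTS = ("T0", "T1", "T2")
BASELINE_SITE = "BRACKET_AREA"

#: plates with this many colonies or more are uncountable
MAX_COUNTABLE = 300
#: aliquot volume plated per dilution, ml (50 ul)
ALIQUOT_ML = 0.05

RECORD_COLUMNS = ("patient_id", "timepoint", "site", "log10_cfu", "gi", "pd")


# ---------------------------------------------------------------- CFU


def estimate_log10_cfu(
    colony_count: int,
    dilution_exponent: int,
    aliquot_volume: float = ALIQUOT_ML,
) -> float:
    """log10 CFU per ml from one countable plate.

    A plate at dilution 10^-k grown from an ``aliquot_volume`` ml aliquot
    with ``colony_count`` colonies estimates a density of
    count * 10^k / volume CFU per ml of transport medium.
    """
    if dilution_exponent < 0:
        raise ValueError("dilution_exponent must be >= 0")
    if aliquot_volume <= 0:
        raise ValueError("aliquot_volume must be > 0")
    if colony_count >= MAX_COUNTABLE:
        raise UncountablePlateError(
            f"{colony_count} colonies >= {MAX_COUNTABLE}: plate uncountable, "
            "use the next dilution"
        )
    if colony_count <= 0:
        raise BelowDetectionError("no colonies: density below detection")
    return math.log10(colony_count * 10.0**dilution_exponent / aliquot_volume)


def estimate_from_dilution_series(
    counts: Sequence[tuple[int, int]], aliquot_volume: float = ALIQUOT_ML
) -> float:
    """Estimate log10 CFU/ml from a (dilution_exponent, count) series.

    Uses the first countable plate (0 < count < 300) in order of
    increasing dilution, mirroring bench practice.
    """
    for k, count in sorted(counts):
        if 0 < count < MAX_COUNTABLE:
            return estimate_log10_cfu(count, k, aliquot_volume)
    raise BelowDetectionError("no countable plate in the dilution series")


# ---------------------------------------------------------------- summaries


def _require_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise SchemaError(f"records missing columns {sorted(missing)}")
    return records


def summarize_sites(
    records: pd.DataFrame, variable: str = "log10_cfu"
) -> pd.DataFrame:
    """Mean, sample SD (n-1) and n per (timepoint, site) group.

    Groups are ordered T0 baseline first, then BO, BG, BL, BR within each
    timepoint.
    """
    _require_records(records)
    site_order = (BASELINE_SITE,) + SITES
    rows = []
    for tp in TIMEPOINTS:
        for site in site_order:
            grp = records.loc[
                (records["timepoint"] == tp) & (records["site"] == site),
                variable,
            ].dropna()
            if grp.empty:
                continue
            if len(grp) < 2:
                raise DegenerateInputError(
                    f"group ({tp}, {site}) has fewer than 2 records"
                )
            rows.append(
                {
                    "timepoint": tp,
                    "site": site,
                    "mean": float(grp.mean()),
                    "sd": float(grp.std(ddof=1)),
                    "n": int(len(grp)),
                }
            )
    if not rows:
        raise DegenerateInputError("no populated (timepoint, site) groups")
    return pd.DataFrame(rows)


def overall_mean(summaries: pd.DataFrame, timepoint: str) -> float:
    """Unweighted mean of the four peri-bracket site means at a timepoint."""
    sel = summaries[summaries["timepoint"] == timepoint]
    present = set(sel["site"])
    missing = set(SITES) - present
    if missing:
        raise DegenerateInputError(
            f"missing sites {sorted(missing)} at {timepoint}"
        )
    means = sel.set_index("site").loc[list(SITES), "mean"]
    return float(means.mean())


def site_differences(
    data: pd.DataFrame, timepoint: str, variable: str = "log10_cfu"
) -> pd.DataFrame:
    """Pairwise between-site differences at one timepoint.

    ``data`` may be patient-level records (difference of within-patient
    values, with SD and a paired-t p-value) or a summary table from
    ``summarize_sites`` (difference of means only, SD/p set to NaN).
    Pairs are reported in the fixed order BO-BG, BO-BL, BO-BR, BG-BL,
    BG-BR, BL-BR.
    """
    is_summary = {"mean", "sd", "n"} <= set(data.columns)
    rows = []
    if is_summary:
        sel = data[data["timepoint"] == timepoint].set_index("site")
        if not set(SITES) <= set(sel.index):
            raise DegenerateInputError(f"missing sites at {timepoint}")
        for a, b in SITE_PAIRS:
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "difference": float(sel.loc[a, "mean"] - sel.loc[b, "mean"]),
                    "sd": np.nan,
                    "p_value": np.nan,
                }
            )
    else:
        _require_records(data)
        sel = data[data["timepoint"] == timepoint]
        wide = sel.pivot_table(
            index="patient_id", columns="site", values=variable
        )
        if not set(SITES) <= set(wide.columns):
            raise DegenerateInputError(f"missing sites at {timepoint}")
        if wide[list(SITES)].isna().any().any():
            raise SchemaError(
                f"unpaired records at {timepoint}: every patient needs all "
                "four sites for paired differences"
            )
        for a, b in SITE_PAIRS:
            d = wide[a] - wide[b]
            try:
                _, p = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
            except DegenerateInputError:
                p = np.nan  # constant differences: test undefined
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "difference": float(d.mean()),
                    "sd": float(d.std(ddof=1)),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- tests


def paired_t(sample_a, sample_b) -> tuple[float, float]:
    """Classical paired t-test: t on within-pair differences, two-sided p.

    Raises ``DegenerateInputError`` when every difference is identical
    (zero variance), where the statistic is undefined.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("samples must be equal-length 1-D with n >= 2")
    d = a - b
    if np.allclose(d, d[0], rtol=0.0, atol=0.0):
        raise DegenerateInputError("all paired differences identical")
    res = st.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed(sample_a, sample_b) -> tuple[float, float]:
    """Wilcoxon signed-rank test (W+ statistic, two-sided p).

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  The p-value is exact (full enumeration of the 2^n sign
    assignments of the observed ranks) for n <= 12 and a normal
    approximation with tie-corrected variance and 0.5 continuity
    correction above.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be equal-length 1-D")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = st.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if n <= 12:
        # exact permutation distribution of W+ over all sign assignments
        signs = (
            np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        ) & 1  # (2^n, n) bits
        w_all = signs @ ranks
        p = float(
            np.mean(np.abs(w_all - mu) >= abs(w_pos - mu) - 1e-12)
        )
    else:
        sigma = math.sqrt(float((ranks**2).sum()) / 4.0)
        z = (abs(w_pos - mu) - 0.5) / sigma
        p = float(2.0 * st.norm.sf(max(z, 0.0)))
    return w_pos, min(p, 1.0)


# ---------------------------------------------------------------- Table 2


def _per_patient(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    """One value per (patient, timepoint); site rows must agree."""
    grp = records.groupby(["patient_id", "timepoint"])[variable]
    if (grp.nunique(dropna=False) > 1).any():
        raise SchemaError(
            f"{variable} differs across site rows of one patient visit"
        )
    return grp.first().unstack("timepoint")


def longitudinal_report(records: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal GI / PD summary across T0, T1, T2.

    Means and SDs per timepoint plus pairwise p-values (GI by Wilcoxon
    signed-rank, PD by paired t) for T0-T1, T0-T2, T1-T2.  Degenerate
    comparisons (no variation) are reported as NaN rather than aborting
    the report.  Patients must be identical across the three timepoints.
    """
    _require_records(records)
    missing_tp = set(TIMEPOINTS) - set(records["timepoint"])
    if missing_tp:
        raise SchemaError(f"missing timepoints {sorted(missing_tp)}")
    patient_sets = {
        tp: frozenset(records.loc[records["timepoint"] == tp, "patient_id"])
        for tp in TIMEPOINTS
    }
    if len(set(patient_sets.values())) != 1:
        raise SchemaError("patient pairing broken across timepoints")

    rows = []
    for variable, test in (("gi", wilcoxon_signed), ("pd", paired_t)):
        wide = _per_patient(records, variable)
        row = {"variable": variable}
        for tp in TIMEPOINTS:
            row[f"{tp}_mean"] = float(wide[tp].mean())
            row[f"{tp}_sd"] = float(wide[tp].std(ddof=1))
        for tp_a, tp_b in (("T0", "T1"), ("T0", "T2"), ("T1", "T2")):
            try:
                _, p = test(wide[tp_b].to_numpy(), wide[tp_a].to_numpy())
            except DegenerateInputError:
                p = np.nan
            row[f"p_{tp_a}_{tp_b}"] = p
            row[f"sig_{tp_a}_{tp_b}"] = bool(p < 0.05) if np.isfinite(p) else False
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
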