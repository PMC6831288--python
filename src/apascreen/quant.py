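"""Relative quantification and NUDT21-responsiveness classification.

Long/total ratios come from qPCR of two amplicons per gene: ``long``
(specific to the extended 3'UTR isoform) and ``total`` (a region common to
all isoforms). Ct values convert to relative abundances as ``base**(-Ct)``
(base = PCR efficiency, 2 for a perfectly efficient reaction, i.e. the
2^-ddCT convention), and R = abundance_long / abundance_total. A gene is
classified NUDT21-responsive when its mean ratio rises under overexpression
and falls under knockdown: R(OE) >= min_fold * R(control) and R(KD) <=
R(control) / min_fold for all (or any) knockdowns. Replicate groups are
additionally compared with a two-sided Mann-Whitney rank-sum test, reported
alongside but not gating the call by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

EXACT_RANK_TEST_MAX_N = 12


def ddct_relative(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
    base: float = 2.0,
) -> float:
    """Relative expression by the ddCT method: base**-ddCT.

    ddCT = (Ct_target - Ct_reference) - (Ct_target_cal - Ct_reference_cal),
    with the reference a housekeeping gene and the calibrator the control
    sample.
    """
    values = (ct_target, ct_reference, ct_target_cal, ct_reference_cal)
    if not all(math.isfinite(v) for v in values):
        raise ValueError(f"non-finite Ct value in {values}")
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return float(base ** (-ddct))


def ct_to_abundance(ct, base: float = 2.0):
    """Invert the amplification model: abundance = base**(-Ct)."""
    return np.power(base, -np.asarray(ct, dtype=float))


def long_total_ratio(
    value_long: float, value_total: float, value_kind: str = "abundance",
    base: float = 2.0,
) -> float:
    """R = abundance_long / abundance_total for one replicate.

    Ct inputs are converted to abundances first. A zero total abundance
    leaves R undefined (NaN) with a warning; the caller drops the replicate.
    """
    if value_kind == "Ct":
        a_long = float(ct_to_abundance(value_long, base))
        a_total = float(ct_to_abundance(value_total, base))
    elif value_kind == "abundance":
        a_long, a_total = float(value_long), float(value_total)
    else:
        raise ValueError(f"unknown value_kind {value_kind!r}")
    if a_total == 0:
        warnings.warn("total abundance is zero; ratio undefined, replicate dropped")
        return float("nan")
    return a_long / a_total


@dataclass
class RatioProfile:
    """Per-gene replicate long/total ratios by condition."""

    gene_id: str
    ratios: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, condition: str) -> float:
        return float(np.mean(self.ratios[condition]))

    def sd(self, condition: str) -> float:
        return float(np.std(self.ratios[condition], ddof=1)) if len(
            self.ratios[condition]
        ) > 1 else 0.0


def ratio_profiles(
    expr: pd.DataFrame, base: float = 2.0
) -> list[RatioProfile]:
    """Build per-gene ratio profiles from a tidy expression table.

    Expected columns: gene_id, condition, replicate, amplicon (long/total),
    value_kind (Ct/abundance), value. Replicates missing either amplicon or
    with zero total abundance are dropped with a warning.
    """
    required = {"gene_id", "condition", "replicate", "amplicon", "value_kind", "value"}
    missing = required - set(expr.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    profiles: dict[str, RatioProfile] = {}
    wide = expr.pivot_table(
        index=["gene_id", "condition", "replicate", "value_kind"],
        columns="amplicon",
        values="value",
        aggfunc="first",
    ).reset_index()
    for col in ("long", "total"):
        if col not in wide.columns:
            raise ValueError(f"expression table has no {col!r} amplicon rows")
    for row in wide.itertuples(index=False):
        if pd.isna(row.long) or pd.isna(row.total):
            warnings.warn(
                f"replicate {row.gene_id}/{row.condition}/{row.replicate} "
                "missing an amplicon; dropped"
            )
            continue
        r = long_total_ratio(row.long, row.total, row.value_kind, base)
        if math.isnan(r):
            continue
        prof = profiles.setdefault(row.gene_id, RatioProfile(row.gene_id))
        prof.ratios.setdefault(row.condition, []).append(r)
    return [profiles[g] for g in sorted(profiles)]


def _exact_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p for the Mann-Whitney U (tie-tolerant).

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments with |U - n1*n2/2| at least as extreme as observed.
    """
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(pooled)
    center = n1 * n2 / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(tuple(range(n1))) - center)
    total = 0
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


def rank_test(group_a, group_b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Uses exhaustive permutation enumeration (exact, tie-tolerant) when the
    combined sample size is <= 12, and the tie-corrected normal
    approximation otherwise. Completely tied data gives p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.all(np.concatenate([a, b]) == a[0]):
        return 1.0
    if len(a) + len(b) <= EXACT_RANK_TEST_MAX_N:
        return _exact_rank_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def classify_responsive(
    profile: RatioProfile,
    min_fold: float = 1.2,
    require_all_kd: bool = True,
    control: str = "control",
    oe: str = "OE",
    rank_p: bool = True,
) -> tuple[bool, dict]:
    """Judge one gene's ratio profile against the OE-up / KD-down pattern.

    Returns (responsive, stats) where stats carries per-condition mean
    ratios, fold changes versus control, and Mann-Whitney p-values when each
    group has >= 3 replicates. p-values are reported, not gating.
    """
    for cond in (control, oe):
        if cond not in profile.ratios:
            raise ValueError(f"gene {profile.gene_id}: missing condition {cond!r}")
    kd_conditions = sorted(
        c for c in profile.ratios if c not in (control, oe)
    )
    if not kd_conditions:
        raise ValueError(f"gene {profile.gene_id}: no knockdown condition present")

    mean_ctrl = profile.mean(control)
    info: dict = {"mean_ratio": {control: mean_ctrl}, "fold_vs_control": {}, "p": {}}
    # "increased"/"decreased" are strict directions; min_fold adds a margin
    mean_oe = profile.mean(oe)
    oe_ok = mean_oe > mean_ctrl and mean_oe >= min_fold * mean_ctrl
    kd_ok_flags = []
    for cond in [oe] + kd_conditions:
        m = profile.mean(cond)
        info["mean_ratio"][cond] = m
        info["fold_vs_control"][cond] = m / mean_ctrl if mean_ctrl > 0 else float("inf")
        if (
            rank_p
            and len(profile.ratios[cond]) >= 3
            and len(profile.ratios[control]) >= 3
        ):
            info["p"][cond] = rank_test(profile.ratios[cond], profile.ratios[control])
    for cond in kd_conditions:
        m = info["mean_ratio"][cond]
        kd_ok_flags.append(m < mean_ctrl and m <= mean_ctrl / min_fold)
    kd_ok = all(kd_ok_flags) if require_all_kd else any(kd_ok_flags)
    responsive = bool(oe_ok and kd_ok)
    info["direction_consistent"] = responsive
    return responsive, info


def quantify_experiment(
    expr: pd.DataFrame,
    base: float = 2.0,
    min_fold: float = 1.2,
    require_all_kd: bool = True,
    control: str = "control",
    oe: str = "OE",
    rank_p: bool = True,
) -> pd.DataFrame:
    """Full table-level pipeline: ratios, folds, p-values, responsive flag."""
    rows = []
    for prof in ratio_profiles(expr, base=base):
        responsive, info = classify_responsive(
            prof,
            min_fold=min_fold,
            require_all_kd=require_all_kd,
            control=control,
            oe=oe,
            rank_p=rank_p,
        )
        row = {"gene_id": prof.gene_id, "responsive": responsive}
        for cond, m in info["mean_ratio"].items():
            row[f"ratio_{cond}"] = m
        for cond, f in info["fold_vs_control"].items():
            row[f"fold_{cond}"] = f
        for cond, p in info["p"].items():
            row[f"p_{cond}"] = p
        rows.append(row)
    return pd.DataFrame(rows).sort_values("gene_id", ignore_index=True)
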