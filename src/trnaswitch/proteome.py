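"""Peptide-table statistics for mistranslation detection and differential
abundance.

Works on a peptides x samples log2-intensity matrix with per-peptide variant
labels (``base``, ``T>K``, ``T>M``).  The analysis chain is: valid-value
filtering (a feature needs at least ``min_valid`` observed values in at
least one sample group), left-censored imputation around the detection
limit, amino-acid substitution fractions against a control strain, a
distribution-shift test for threonine-containing peptides, and a two-sided
moderated t-test with an S0 background-variance constant and
permutation-based FDR in the SAM lineage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

VARIANT_BASE = "base"
VARIANT_TK = "T>K"
VARIANT_TM = "T>M"


@dataclass
class PeptideQuantTable:
    """Log2 peptide intensities with sample grouping and variant labels.

    ``values``: peptides x samples, NaN for missing.  ``meta`` has one row
    per peptide with columns ``sequence``, ``protein``, ``variant_class``
    and ``site``.  ``groups`` maps each sample column to its strain label.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share a peptide index")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[self.values.columns]

    def samples_of(self, strain: str) -> list[str]:
        return list(self.groups.index[self.groups == strain])

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.groups))


def read_peptide_table(table_path, groups_path) -> PeptideQuantTable:
    """Read the TSV peptide table (empty cell = missing) and group map."""
    df = pd.read_csv(table_path, sep="\t", comment="#")
    meta_cols = ["sequence", "protein", "variant_class", "site"]
    meta = df[meta_cols].copy()
    values = df.drop(columns=meta_cols).astype(float)
    gm = pd.read_csv(groups_path, sep="\t", comment="#")
    groups = pd.Series(gm["strain"].values, index=gm["sample"].values)
    return PeptideQuantTable(values=values, meta=meta, groups=groups)


def filter_valid(
    table: PeptideQuantTable, min_valid: int = 3
) -> tuple[PeptideQuantTable, int]:
    """Keep rows with >= min_valid observed values in at least one group.

    Returns the filtered table and the number of rows removed.
    """
    import logging

    keep = pd.Series(False, index=table.values.index)
    for strain in table.strains:
        cols = table.samples_of(strain)
        if len(cols) < min_valid:
            logging.getLogger(__name__).warning(
                "group %s has only %d samples; the %d-valid rule can never "
                "be met within it", strain, len(cols), min_valid,
            )
        keep |= table.values[cols].notna().sum(axis=1) >= min_valid
    removed = int((~keep).sum())
    return (
        PeptideQuantTable(
            values=table.values.loc[keep].copy(),
            meta=table.meta.loc[keep].copy(),
            groups=table.groups,
        ),
        removed,
    )


def impute_lod(
    table: PeptideQuantTable,
    downshift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> PeptideQuantTable:
    """Impute missing log2 intensities from a left-shifted normal.

    Per sample, missing values are drawn from
    Normal(mean - downshift*sd, (width*sd)^2) of that sample's observed
    values — the conventional detection-limit imputation for label-free
    proteomics.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    for col in values.columns:
        obs = values[col].dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {col}: need >= 2 observed values")
        n_missing = int(values[col].isna().sum())
        if n_missing == 0:
            continue
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        values.loc[values[col].isna(), col] = draws
    return PeptideQuantTable(values=values, meta=table.meta, groups=table.groups)


# --- substitution fractions --------------------------------------------------

def substitution_fraction(
    table: PeptideQuantTable,
    strain: str,
    substitution: str,
    mode: Literal["count", "intensity"] = "count",
) -> Optional[float]:
    """Fraction of substituted peptide signal in a strain.

    Count mode: substituted peptide observations over substituted plus base
    observations at substitutable sites (base peptides containing Thr).
    Intensity mode: the same with summed (linear) intensities.  Returns None
    when the denominator is zero.
    """
    cols = table.samples_of(strain)
    if not cols:
        raise KeyError(f"no samples for strain {strain!r}")
    is_sub = table.meta["variant_class"] == substitution
    is_base = (table.meta["variant_class"] == VARIANT_BASE) & \
        table.meta["sequence"].str.contains("T")
    sub_block = table.values.loc[is_sub, cols]
    base_block = table.values.loc[is_base, cols]
    if mode == "count":
        sub = float(sub_block.notna().sum().sum())
        base = float(base_block.notna().sum().sum())
    elif mode == "intensity":
        sub = float(np.exp2(sub_block).sum().sum())
        base = float(np.exp2(base_block).sum().sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = sub + base
    if denom == 0:
        return None
    return sub / denom


def ratio_vs_control(
    table: PeptideQuantTable,
    strain: str,
    control: str,
    substitution: str,
    mode: Literal["count", "intensity"] = "count",
) -> Optional[float]:
    """Substitution fraction of a strain over that of the control strain.

    The null expectation (no excess mistranslation) is a ratio of 1.
    """
    f_strain = substitution_fraction(table, strain, substitution, mode)
    f_control = substitution_fraction(table, control, substitution, mode)
    if f_strain is None or f_control in (None, 0.0):
        return None
    return f_strain / f_control


# --- threonine distribution shift --------------------------------------------

@dataclass(frozen=True)
class ShiftResult:
    median_shift: float
    ks_statistic: float
    p_value: float


def thr_shift(
    log2fc_all: Sequence[float],
    log2fc_subset: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ShiftResult:
    """Test for a location shift of a peptide subset (e.g. Thr-containing).

    ``median_shift`` = median(subset) - median(all).  The KS statistic
    compares the subset with its complement; its permutation p-value
    reshuffles subset membership.  Mistranslation away from Thr predicts a
    negative shift (subset moved down / left).
    """
    from scipy.stats import ks_2samp

    all_vals = np.asarray(log2fc_all, float)
    sub_vals = np.asarray(log2fc_subset, float)
    if sub_vals.size == 0:
        raise ValueError("empty subset")
    shift = float(np.median(sub_vals) - np.median(all_vals))
    if sub_vals.size == all_vals.size:
        return ShiftResult(median_shift=shift, ks_statistic=0.0, p_value=1.0)
    # complement by multiset subtraction on sorted order
    comp = _complement(all_vals, sub_vals)
    ks = float(ks_2samp(sub_vals, comp).statistic)
    null_d = _ks_null(all_vals, sub_vals.size, n_permutations, seed)
    p = (np.sum(null_d >= ks - 1e-12) + 1) / (n_permutations + 1)
    return ShiftResult(median_shift=shift, ks_statistic=ks, p_value=float(p))


def _ks_null(values: np.ndarray, k: int, n_permutations: int, seed: int
             ) -> np.ndarray:
    """Null KS statistics for random subset membership, vectorized.

    Membership is exchangeable, so a uniform arrangement of k ones over the
    value-sorted axis is equivalent to shuffling membership over items.  The
    ECDF difference is evaluated only at positions where the sorted value
    changes (tie handling identical to the two-sample KS definition).
    """
    rng = np.random.default_rng(seed)
    v = np.sort(values)
    n = v.size
    valid = np.ones(n, bool)
    valid[:-1] = v[:-1] != v[1:]  # last index of each tie run
    z = np.zeros((n_permutations, n))
    z[:, :k] = 1.0
    rng = np.random.default_rng(seed)
    z = rng.permuted(z, axis=1)
    cum_sub = np.cumsum(z, axis=1) / k
    cum_comp = np.cumsum(1.0 - z, axis=1) / (n - k)
    diff = np.abs(cum_sub - cum_comp)[:, valid]
    return diff.max(axis=1)


def _complement(all_vals: np.ndarray, sub_vals: np.ndarray) -> np.ndarray:
    counts: dict[float, int] = {}
    for v in sub_vals:
        counts[v] = counts.get(v, 0) + 1
    out = []
    for v in all_vals:
        if counts.get(v, 0) > 0:
            counts[v] -= 1
        else:
            out.append(v)
    if len(out) != all_vals.size - sub_vals.size:
        raise ValueError("subset is not contained in the full set")
    return np.asarray(out)


# --- moderated t with permutation FDR ----------------------------------------

def moderated_t_s0(
    group_a: Sequence[float], group_b: Sequence[float], s0: float = 1.0
) -> float:
    """Two-sample t statistic with an S0 background-variance constant.

    t = (mean_a - mean_b) / (se_pooled + s0).  With s0 = 0 this is the
    ordinary two-sample (pooled-variance) t statistic; s0 > 0 damps large
    statistics arising from accidentally tiny variances.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se = math.sqrt(pooled_var * (1 / a.size + 1 / b.size))
    if se == 0 and s0 == 0:
        raise ZeroDivisionError("degenerate variance with s0 = 0")
    return float((a.mean() - b.mean()) / (se + s0))


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    mean_a: float
    mean_b: float
    t_moderated: float
    q_value: float
    significant: bool


def _t_for_labels(data: np.ndarray, mask_a: np.ndarray, s0: float) -> np.ndarray:
    """Row-wise moderated t for one label assignment (vectorized)."""
    a = data[:, mask_a]
    b = data[:, ~mask_a]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    return (a.mean(axis=1) - b.mean(axis=1)) / (se + s0)


def permutation_fdr(
    data: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    s0: float = 1.0,
    fdr: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[DifferentialResult]:
    """SAM-style q-values for row-wise moderated t statistics.

    The null distribution pools |t| over group-label permutations (all
    distinct assignments when there are at most 2000, otherwise sampled).
    For each row, q = median over permutations of the number of null |t|
    at or above its |t|, divided by the number of observed |t| at or above
    it, monotonized so q never decreases as |t| decreases, and capped at 1.
    ``significant`` marks q <= fdr.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive for a well-defined statistic")
    cols = list(samples_a) + list(samples_b)
    mat = data[cols].to_numpy(float)
    if np.isnan(mat).any():
        raise ValueError("run imputation before testing: NaNs present")
    na = len(samples_a)
    n = len(cols)
    base_mask = np.zeros(n, bool)
    base_mask[:na] = True
    t_obs = _t_for_labels(mat, base_mask, s0)

    all_assignments = [
        np.array([i in combo for i in range(n)])
        for combo in itertools.combinations(range(n), na)
    ]
    if len(all_assignments) <= 2000:
        masks = all_assignments
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_assignments), size=n_permutations, replace=False)
        masks = [all_assignments[i] for i in idx]

    abs_obs = np.abs(t_obs)
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    n_rows = len(sorted_abs)
    # per permutation: count of null |t| >= each observed cutoff
    null_counts = np.empty((len(masks), n_rows))
    for m, mask in enumerate(masks):
        t_null = np.abs(_t_for_labels(mat, mask, s0))
        t_null.sort()
        # for cutoff c: nulls >= c
        null_counts[m] = t_null.size - np.searchsorted(t_null, sorted_abs, "left")
    median_fp = np.median(null_counts, axis=0)
    observed_positives = np.arange(1, n_rows + 1)
    fdr_at_cutoff = np.minimum(median_fp / observed_positives, 1.0)
    # q of a row = min FDR over all cutoffs that still include it
    # (suffix minimum over descending |t|); monotone in the |t| ranking
    q_sorted = np.minimum.accumulate(fdr_at_cutoff[::-1])[::-1]
    q = np.empty(n_rows)
    q[order] = q_sorted

    ma = mat[:, base_mask].mean(axis=1)
    mb = mat[:, ~base_mask].mean(axis=1)
    return [
        DifferentialResult(
            feature_id=str(fid),
            mean_a=float(ma[i]),
            mean_b=float(mb[i]),
            t_moderated=float(t_obs[i]),
            q_value=float(q[i]),
            significant=bool(q[i] <= fdr),
        )
        for i, fid in enumerate(data.index)
    ]
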