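"""Codon usage accounting and the heat-shock codon-demand statistic.

The demand statistic asks whether the genes most induced on a temperature
shift are enriched for a focal codon (here typically Thr ACG, read by a
single tRNA species): it is the ratio of the mean relative focal-codon
frequency over the top-N induced genes to the mean over all genes, per time
point.  Relative frequency is computed within each amino acid's synonymous
family (the share of ACG among the four Thr codons).  Kruskal-Wallis tests
compare groups per time point, and 2^-ddCt arithmetic converts qPCR Ct
values to fold changes against household genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GeneticCode, STANDARD_CODE, normalize_rna

ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGU", repeat=3)
)


class FrameError(ValueError):
    """CDS length is not a multiple of 3."""


def codon_counts(cds: str, strict: bool = False) -> dict[str, int]:
    """Frame-0 codon counts of a CDS (DNA or RNA input accepted)."""
    seq = normalize_rna(cds)
    if len(seq) % 3:
        raise FrameError(f"CDS length {len(seq)} not divisible by 3")
    if strict:
        if not seq.startswith("AUG"):
            raise ValueError("strict mode requires an AUG start")
        if seq[-3:] not in ("UAA", "UAG", "UGA"):
            raise ValueError("strict mode requires a stop codon at the end")
    counts = dict.fromkeys(ALL_CODONS, 0)
    for k in range(0, len(seq), 3):
        counts[seq[k:k + 3]] += 1
    return counts


def relative_codon_frequency(
    counts: Mapping[str, int], codon: str, code: GeneticCode = STANDARD_CODE
) -> Optional[float]:
    """Share of ``codon`` among its synonymous family in one gene.

    Returns None when the amino acid does not occur in the gene (the share
    is undefined, not zero).
    """
    codon = normalize_rna(codon)
    aa = code[codon]
    family = [c for c in ALL_CODONS if code[c] == aa]
    total = sum(counts.get(c, 0) for c in family)
    if total == 0:
        return None
    return counts.get(codon, 0) / total


def absolute_codon_frequency(counts: Mapping[str, int], codon: str) -> float:
    """Per-1000-codons frequency of ``codon`` in one gene."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty CDS")
    return 1000.0 * counts.get(normalize_rna(codon), 0) / total


@dataclass(frozen=True)
class DemandStatistic:
    """Per-time-point focal-codon demand of the most-induced genes."""

    timepoint: str
    focal_codon: str
    ratio: Optional[float]      # None when undefined in either set
    n_top: int
    top_gene_ids: tuple[str, ...]
    top_mean: Optional[float]
    background_mean: Optional[float]


def demand_ratio(
    expression: pd.DataFrame,
    usage: Mapping[str, Mapping[str, int]],
    focal_codon: str,
    n_top: int = 25,
    code: GeneticCode = STANDARD_CODE,
    exclude_top_from_background: bool = False,
) -> list[DemandStatistic]:
    """Demand statistic per time point.

    ``expression`` is genes x time points (log2 fold change vs the reference
    time point); ``usage`` maps gene id -> codon counts.  For each time
    point the top ``n_top`` genes by descending log2FC are selected (ties at
    the boundary broken by gene_id), and the ratio of mean relative
    focal-codon frequency in that set vs all genes (or all other genes when
    ``exclude_top_from_background``) is reported.  Genes lacking the focal
    amino acid contribute to neither mean.
    """
    focal_codon = normalize_rna(focal_codon)
    missing = set(expression.index) - set(usage)
    if missing:
        raise KeyError(f"genes without codon usage: {sorted(missing)[:5]}")
    if n_top > len(expression.index):
        raise ValueError("n_top exceeds the number of genes")
    freqs = {
        g: relative_codon_frequency(usage[g], focal_codon, code)
        for g in expression.index
    }
    out = []
    for tp in expression.columns:
        ranked = sorted(
            expression.index, key=lambda g: (-expression.at[g, tp], g)
        )
        top = ranked[:n_top]
        background = (
            ranked[n_top:] if exclude_top_from_background else list(expression.index)
        )
        top_vals = [freqs[g] for g in top if freqs[g] is not None]
        bg_vals = [freqs[g] for g in background if freqs[g] is not None]
        if not top_vals or not bg_vals or np.mean(bg_vals) == 0:
            ratio = top_mean = bg_mean = None
            if top_vals:
                top_mean = float(np.mean(top_vals))
            if bg_vals:
                bg_mean = float(np.mean(bg_vals))
        else:
            top_mean = float(np.mean(top_vals))
            bg_mean = float(np.mean(bg_vals))
            ratio = top_mean / bg_mean
        out.append(DemandStatistic(
            timepoint=str(tp), focal_codon=focal_codon, ratio=ratio,
            n_top=n_top, top_gene_ids=tuple(top), top_mean=top_mean,
            background_mean=bg_mean,
        ))
    return out


SIGNIFICANCE_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                           (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star notation (ns above 0.05)."""
    for cut, stars in SIGNIFICANCE_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected), degrees of freedom, and p-value.

    p comes from the chi-square approximation with k-1 degrees of freedom.
    All-identical values give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def ddct_fold_change(
    ct_target_sample: float,
    ct_refs_sample: Sequence[float],
    ct_target_control: float,
    ct_refs_control: Sequence[float],
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - mean Ct(reference genes); ddCt is the sample dCt
    minus the control (reference strain) dCt; fold change is 2^-ddCt.
    Reference genes are aggregated by arithmetic mean of Ct, equivalent to a
    geometric mean of abundances at amplification efficiency 2.
    """
    if not ct_refs_sample or not ct_refs_control:
        raise ValueError("need at least one reference gene")
    dct_sample = ct_target_sample - float(np.mean(ct_refs_sample))
    dct_control = ct_target_control - float(np.mean(ct_refs_control))
    return float(2.0 ** (-(dct_sample - dct_control)))
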