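"""Cohort-level burden statistics and amplicon concordance.

Per-subject mutation burdens (total, nonsynonymous-expressed, synonymous)
are compared between groups with the Mann-Whitney U test; age and depth
associations use Kendall rank correlation (robust at cohort sizes of a few
dozen); the amplicon check classifies a panel call as confirmed or artifact
from its VAF fold change in independent amplicon re-sequencing and its
presence in reference DNA.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .calls import VariantCall, nonsynonymous
from .panel import Subject


def burden_table(calls: list[VariantCall], subjects: list[Subject]) -> pd.DataFrame:
    """Per-subject burden summary from a post-filter (passing) call set.

    ``n_total`` counts all passing mutations (any consequence, any gene);
    ``n_nonsyn_expressed`` / ``n_syn_expressed`` restrict to CD8-expressed
    genes, matching the group-comparison subsets.  ``vafs`` holds the
    subject's full passing VAF list; ``mean_vaf`` averages the
    nonsynonymous-expressed subset.
    """
    per: dict[str, list[VariantCall]] = defaultdict(list)
    for c in calls:
        per[c.subject_id].append(c)
    rows = []
    for s in subjects:
        mine = per.get(s.subject_id, [])
        nonsyn_expr = [c for c in nonsynonymous(mine) if c.expressed_in_cd8]
        syn_expr = [c for c in mine if c.consequence == "synonymous_SNV" and c.expressed_in_cd8]
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "median_depth": s.median_depth,
                "n_total": len(mine),
                "n_nonsyn_expressed": len(nonsyn_expr),
                "n_syn_expressed": len(syn_expr),
                "mean_vaf": float(np.mean([c.vaf for c in nonsyn_expr])) if nonsyn_expr else np.nan,
                "vafs": [c.vaf for c in mine],
            }
        )
    return pd.DataFrame(rows)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided MWU p: exact for combined n <= 20 without ties, else tie-corrected normal."""
    if len(np.unique(np.concatenate([x, y]))) == 1:
        return 1.0  # degenerate: all values identical
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def group_compare(burdens: pd.DataFrame, field: str) -> float:
    """Two-sided Mann-Whitney U p for ``field`` between case and control subjects."""
    x = burdens.loc[burdens["group"] == "case", field].to_numpy(float)
    y = burdens.loc[burdens["group"] == "control", field].to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 subjects per group")
    return _mannwhitney(x, y)


def sex_compare(burdens: pd.DataFrame, field: str) -> float:
    """Two-sided Mann-Whitney U p for ``field`` between female and male subjects."""
    x = burdens.loc[burdens["sex"] == "F", field].to_numpy(float)
    y = burdens.loc[burdens["sex"] == "M", field].to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 subjects per sex")
    return _mannwhitney(x, y)


def age_burden_association(burdens: pd.DataFrame) -> tuple[float, float]:
    """Kendall tau and p for depth-normalised mutation burden vs age.

    The burden is ``n_total / median_depth`` (deeper samples detect more
    mutations, so the raw count confounds age with depth).
    """
    if len(burdens) < 10:
        raise ValueError("need >= 10 subjects")
    norm = burdens["n_total"].to_numpy(float) / burdens["median_depth"].to_numpy(float)
    age = burdens["age"].to_numpy(float)
    if np.ptp(norm) == 0:
        return 0.0, 1.0
    res = stats.kendalltau(age, norm)
    return float(res.statistic), float(res.pvalue)


def depth_count_association(burdens: pd.DataFrame) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) between median depth and mutation count."""
    depth = burdens["median_depth"].to_numpy(float)
    n = burdens["n_total"].to_numpy(float)
    if np.ptp(n) == 0 or np.ptp(depth) == 0:
        return 0.0, 1.0
    res = stats.kendalltau(depth, n)
    return float(res.statistic), float(res.pvalue)


def vaf_age_compare(
    burdens: pd.DataFrame,
    young_range: tuple[float, float] = (23.0, 29.0),
    old_range: tuple[float, float] = (41.0, 57.0),
) -> tuple[float, float, float]:
    """Mean VAF of pooled per-mutation VAFs in a young vs an old age band.

    Returns (mean_young, mean_old, two-sided Mann-Whitney p).  Allelic
    fraction is a surrogate of clone size, so an age-increasing clone size
    shows up as a higher mean VAF in the older band.
    """
    def pooled(lo: float, hi: float) -> np.ndarray:
        sel = burdens[(burdens["age"] >= lo) & (burdens["age"] <= hi)]
        vals = [v for lst in sel["vafs"] for v in lst]
        return np.array(vals, dtype=float)

    young = pooled(*young_range)
    old = pooled(*old_range)
    if len(young) == 0 or len(old) == 0:
        raise ValueError("empty age band")
    return float(young.mean()), float(old.mean()), _mannwhitney(young, old)


def amplicon_concordance(
    panel_vaf: float, amplicon_vaf: float, reference_dna_vaf: float
) -> tuple[float, str]:
    """Classify a variant from amplicon re-sequencing concordance.

    A true somatic variant reproduces its panel VAF in amplicons (fold change
    near 1) and is absent from reference DNA; a library artifact collapses in
    amplicons and/or shows up in reference DNA at a similar fraction.
    Verdicts: ``confirmed`` (fold >= 0.5 and amplicon VAF > 3x reference),
    ``artifact`` (fold < 0.2 or amplicon VAF <= 1.5x reference), else
    ``indeterminate``.
    """
    for name, v in (("panel_vaf", panel_vaf), ("amplicon_vaf", amplicon_vaf),
                    ("reference_dna_vaf", reference_dna_vaf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    if panel_vaf == 0:
        raise ValueError("panel_vaf must be > 0")
    fold = amplicon_vaf / panel_vaf
    if fold >= 0.5 and amplicon_vaf > 3.0 * reference_dna_vaf:
        return fold, "confirmed"
    if fold < 0.2 or amplicon_vaf <= 1.5 * reference_dna_vaf:
        return fold, "artifact"
    return fold, "indeterminate"
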