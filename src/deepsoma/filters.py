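"""The somatic-call filter cascade and its sensitivity calibration.

Every candidate call is evaluated against every enabled filter (no
short-circuiting), so the verdict vector is independent of filter order; a
call PASSes iff every verdict passes.  The cascade favours specificity:
germline removal by allelic fraction and by cross-sample occurrence, a depth
gate, segmental-duplication and cluster masks, mapping-quality parity,
Fisher strand-bias, population-frequency exclusion, and the context-aware
binomial artifact test whose significance threshold is calibrated so that
the substitution spectrum of passing somatic calls stays similar to the
germline spectrum of the same data.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calls import INDEL_CONSEQUENCES, VariantCall
from .noise import ContextNoiseModel, GermlineMask, binomial_noise_test
from .panel import Subject
from .seq import SIX_CLASSES, six_class

log = logging.getLogger(__name__)

FILTER_ORDER = (
    "upstream",
    "depth",
    "germline_self",
    "germline_cohort",
    "segdup",
    "cluster",
    "mapq_parity",
    "strand_bias",
    "pop_af",
    "binomial_noise",
)

# the grid's loose end sits at 1e-3: with a 3-read candidate floor at ~2000x
# and ~1e-4 background, alpha = 1e-2 would admit every minimum-evidence
# candidate (their tail p is ~1.5e-3), i.e. no artifact test at all
DEFAULT_ALPHA_GRID = (1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class FilterThresholds:
    """All knobs of the cascade, with documented defaults.

    ``min_depth`` and ``max_pop_af`` follow the published rules (somatic
    calls only above 100x; exclusion above 1e-5 population frequency in
    either unfiltered database).  The remaining numbers implement rules the
    method states without a value: the germline allelic-fraction cutoff sits
    below the heterozygote sampling band at >100x; the cluster filter fails
    any call with more than ``cluster_max_variants`` same-subject calls
    within ``cluster_window_bp``; mapping-quality parity tolerates a 5-Phred
    deficit on variant reads; the Fisher strand test uses a stringent alpha
    so balanced low-VAF calls are not over-filtered; ``binomial_alpha`` is
    the pre-calibration default and is normally replaced by
    :func:`calibrate_sensitivity`.
    """

    min_depth: int = 100
    max_pop_af: float = 1e-5
    germline_vaf_low: float = 0.35
    cluster_window_bp: int = 100
    cluster_max_variants: int = 2
    strand_bias_alpha: float = 0.001
    mapq_max_deficit: float = 5.0
    binomial_alpha: float = 1e-6
    reject_upstream_nonpass: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0 or not 0 <= self.max_pop_af <= 1:
            raise ValueError("min_depth/max_pop_af out of range")
        if not 0 < self.germline_vaf_low <= 0.5:
            raise ValueError("germline_vaf_low must be in (0, 0.5]")
        if self.cluster_window_bp < 1 or self.cluster_max_variants < 1:
            raise ValueError("cluster parameters out of range")
        if not 0 < self.strand_bias_alpha < 1 or not 0 < self.binomial_alpha < 1:
            raise ValueError("test alphas must be in (0, 1)")
        if self.mapq_max_deficit < 0:
            raise ValueError("mapq_max_deficit must be >= 0")


def _fisher_twosided(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for 2x2 tables [[a, b], [c, d]].

    Enumerates the hypergeometric support of the a-cell at fixed margins and
    sums every table whose probability does not exceed the observed one
    (the standard two-sided convention, with a small relative tolerance for
    floating-point ties).  The support per call is bounded by the variant
    read count, which deep-panel candidates keep small.
    """
    from scipy.special import gammaln

    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    r1, c1, n = a + b, a + c, a + b + c + d
    kmin = np.maximum(0, r1 + c1 - n)
    kmax = np.minimum(r1, c1)
    sizes = kmax - kmin + 1
    idx = np.repeat(np.arange(len(a)), sizes)
    k = np.concatenate([np.arange(lo, hi + 1) for lo, hi in zip(kmin, kmax)])

    def logpmf(kk, nn, cc1, rr1):
        return (
            gammaln(cc1 + 1) - gammaln(kk + 1) - gammaln(cc1 - kk + 1)
            + gammaln(nn - cc1 + 1) - gammaln(rr1 - kk + 1) - gammaln(nn - cc1 - rr1 + kk + 1)
            - (gammaln(nn + 1) - gammaln(rr1 + 1) - gammaln(nn - rr1 + 1))
        )

    lp = logpmf(k, n[idx], c1[idx], r1[idx])
    lp_obs = logpmf(a, n, c1, r1)
    include = lp <= lp_obs[idx] + 1e-7
    p = np.zeros(len(a))
    np.add.at(p, idx[include], np.exp(lp[include]))
    return np.minimum(p, 1.0)


def strand_bias_test(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher exact p for strand asymmetry of variant vs reference reads."""
    if min(alt_fwd, alt_rev, ref_fwd, ref_rev) < 0:
        raise ValueError("negative strand counts")
    if alt_fwd + alt_rev < 1:
        raise ValueError("need at least one variant read")
    return float(
        _fisher_twosided(
            np.array([alt_fwd]), np.array([alt_rev]), np.array([ref_fwd]), np.array([ref_rev])
        )[0]
    )


def _in_intervals(chrom: str, pos: int, intervals: list[tuple[str, int, int]]) -> bool:
    """pos is 1-based; intervals are 0-based half-open."""
    p0 = pos - 1
    return any(c == chrom and start <= p0 < end for c, start, end in intervals)


def _cluster_fail_set(
    calls: list[VariantCall],
    window: int,
    max_variants: int,
    neighbor: np.ndarray | None = None,
) -> set[int]:
    """Indices of calls with more than ``max_variants`` same-subject neighbors within ±window.

    ``neighbor`` marks which calls count as cluster members (plausible
    variants); candidates that are themselves explained by background noise
    do not make their neighborhood look mismapped.  Every call still gets a
    verdict: a call fails when the number of neighbor calls within the
    window (counting itself when it is one) exceeds ``max_variants``.
    """
    if neighbor is None:
        neighbor = np.ones(len(calls), dtype=bool)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for i, c in enumerate(calls):
        by_key[(c.subject_id, c.chrom)].append((c.pos, i))
    fails: set[int] = set()
    for items in by_key.values():
        items.sort()
        pos = np.array([p for p, _ in items])
        nb = np.array([neighbor[i] for _, i in items])
        npos = pos[nb]
        if len(npos) == 0:
            continue
        lo = np.searchsorted(npos, pos - window, side="left")
        hi = np.searchsorted(npos, pos + window, side="right")
        for (p, idx), count in zip(items, hi - lo):
            if count > max_variants:
                fails.add(idx)
    return fails


def apply_filters(
    calls: list[VariantCall],
    site_counts: dict[str, pd.DataFrame] | None,
    noise: ContextNoiseModel | dict[str, ContextNoiseModel],
    segdup_mask: list[tuple[str, int, int]] | None = None,
    cohort_germline: GermlineMask | None = None,
    expressed_genes: set[str] | None = None,
    thresholds: FilterThresholds | None = None,
) -> list[VariantCall]:
    """Populate every call's verdict vector and return the same list.

    ``noise`` is either a pooled :class:`ContextNoiseModel` or a per-sample
    mapping keyed by subject id (the per-sample tabulation is the default
    pipeline behaviour).  When ``site_counts`` is supplied, every call must
    have a matching site row; a missing row is an error.  ``expressed_genes``
    only refreshes the ``expressed_in_cd8`` annotation — expression is an
    analysis-subset criterion downstream, not a cascade verdict.  Missing
    population frequencies are treated as 0 (novel variant) with a logged
    count.
    """
    thresholds = thresholds or FilterThresholds()
    segdup_mask = segdup_mask or []
    cohort_germline = cohort_germline or GermlineMask()

    if site_counts is not None:
        indexed = {
            sid: set(zip(df["chrom"], df["pos"].astype(int))) for sid, df in site_counts.items()
        }
        for c in calls:
            if c.subject_id not in indexed or (c.chrom, c.pos) not in indexed[c.subject_id]:
                raise ValueError(f"no site counts for call {c.subject_id} {c.locus_id}")

    # binomial noise p first: the cluster filter counts only calls that the
    # noise test does not explain away as neighbors
    snv_idx = [
        i
        for i, c in enumerate(calls)
        if c.is_snv and c.consequence not in INDEL_CONSEQUENCES
    ]
    for c in calls:
        c.noise_p = None  # the 192-cell table models substitutions only; indels bypass
    if snv_idx:
        rates = np.empty(len(snv_idx))
        for j, i in enumerate(snv_idx):
            c = calls[i]
            model = noise[c.subject_id] if isinstance(noise, dict) else noise
            rates[j] = model.rate(c.context, c.alt)
        counts = np.array([calls[i].alt_count for i in snv_idx])
        depths = np.array([calls[i].depth for i in snv_idx])
        sf = stats.binom.sf(counts - 1, depths, rates)
        for j, i in enumerate(snv_idx):
            calls[i].noise_p = float(sf[j]) if counts[j] > 0 else 1.0

    if calls:
        p_strand = _fisher_twosided(
            np.array([c.alt_fwd for c in calls]),
            np.array([c.alt_rev for c in calls]),
            np.array([c.ref_fwd for c in calls]),
            np.array([c.ref_rev for c in calls]),
        )
    n_missing_af = 0
    for i, c in enumerate(calls):
        if expressed_genes is not None and c.gene is not None:
            c.expressed_in_cd8 = c.gene in expressed_genes
        v: dict[str, bool] = {}
        v["upstream"] = (
            c.upstream_filter in ("PASS", ".", "") or not thresholds.reject_upstream_nonpass
        )
        v["depth"] = c.depth > thresholds.min_depth
        v["germline_self"] = c.vaf < thresholds.germline_vaf_low
        v["germline_cohort"] = (c.chrom, c.pos) not in cohort_germline
        v["segdup"] = not _in_intervals(c.chrom, c.pos, segdup_mask)
        v["mapq_parity"] = c.mean_mapq_alt >= c.mean_mapq_ref - thresholds.mapq_max_deficit
        v["strand_bias"] = p_strand[i] >= thresholds.strand_bias_alpha
        af = c.pop_af
        if af is None:
            n_missing_af += 1
            af = 0.0
        v["pop_af"] = af <= thresholds.max_pop_af
        v["binomial_noise"] = c.noise_p is None or c.noise_p < thresholds.binomial_alpha
        c.verdicts = v
    _set_cluster_verdicts(calls, thresholds)
    if n_missing_af:
        log.info("pop_af missing on %d calls; treated as novel (AF=0)", n_missing_af)
    return calls


def _set_cluster_verdicts(calls: list[VariantCall], thresholds: FilterThresholds) -> None:
    neighbor = np.array([c.verdicts.get("binomial_noise", True) for c in calls], dtype=bool)
    fails = _cluster_fail_set(
        calls, thresholds.cluster_window_bp, thresholds.cluster_max_variants, neighbor
    )
    for i, c in enumerate(calls):
        c.verdicts["cluster"] = i not in fails


def rethreshold_binomial(
    calls: list[VariantCall], alpha: float, thresholds: FilterThresholds | None = None
) -> list[VariantCall]:
    """Re-apply the binomial verdict at a new alpha using the stored noise p.

    Cluster verdicts are recomputed too, since cluster neighbors are the
    calls the noise test leaves unexplained.
    """
    thresholds = thresholds or FilterThresholds()
    for c in calls:
        if "binomial_noise" in c.verdicts:
            c.verdicts["binomial_noise"] = c.noise_p is None or c.noise_p < alpha
    _set_cluster_verdicts(calls, thresholds)
    return calls


def collect_germline_calls(
    site_counts: pd.DataFrame,
    subject_id: str,
    vaf_low: float = 0.35,
    min_depth: int = 100,
) -> list[VariantCall]:
    """Germline SNV calls of one sample: alleles at VAF >= ``vaf_low``.

    Captures heterozygotes (VAF ~0.5) and homozygous-alt sites (VAF ~1); the
    result feeds both the cohort germline mask and the reference substitution
    spectrum for sensitivity calibration.
    """
    df = site_counts
    out: list[VariantCall] = []
    depth = df["depth"].to_numpy(np.int64)
    for base in "ACGT":
        n = df[f"n_{base}"].to_numpy(np.int64)
        sel = (df["ref"].to_numpy() != base) & (depth >= min_depth) & (n >= vaf_low * depth)
        for row in df.loc[sel].itertuples():
            out.append(
                VariantCall(
                    subject_id=subject_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=base,
                    depth=int(row.depth),
                    alt_count=int(getattr(row, f"n_{base}")),
                    context=row.context,
                )
            )
    return out


def germline_mask_from_calls(germline_calls: list[VariantCall]) -> GermlineMask:
    return GermlineMask({(c.chrom, c.pos) for c in germline_calls})


def substitution_spectrum(calls: list[VariantCall], unique_loci: bool = False) -> np.ndarray:
    """Counts over the 6 strand-collapsed substitution classes (SNVs only).

    With ``unique_loci`` each distinct (chrom, pos, ref, alt) counts once —
    appropriate for germline variants, which recur across cohort samples and
    would otherwise be counted once per carrier.
    """
    counts = dict.fromkeys(SIX_CLASSES, 0)
    seen: set[tuple] = set()
    for c in calls:
        if not c.is_snv:
            continue
        if unique_loci:
            if c.locus in seen:
                continue
            seen.add(c.locus)
        counts[six_class(c.ref, c.alt)] += 1
    return np.array([counts[k] for k in SIX_CLASSES], dtype=float)


def calibrate_sensitivity(
    somatic_candidates: list[VariantCall],
    germline_calls: list[VariantCall],
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    spectrum_p_threshold: float = 0.05,
    ct_inflation_max: float = 1.5,
) -> float:
    """Choose the binomial alpha whose passing-call spectrum matches germline.

    Walks ``alpha_grid`` in descending order and returns the largest alpha
    for which (i) the passing somatic 6-class substitution spectrum does not
    differ from the germline spectrum of the same data (chi-square test of
    homogeneity on the two count vectors, p > ``spectrum_p_threshold`` —
    the germline spectrum is itself a finite sample, so a two-sample test
    rather than goodness-of-fit against its point estimate) and (ii) the
    somatic C>T(G>A) fraction does not exceed the germline fraction by more
    than ``ct_inflation_max``-fold.  Relaxing sensitivity past this point
    floods the call set with deamination-type C>T artifacts.  Candidates
    must already carry verdicts and stored noise p-values from
    :func:`apply_filters`; only calls passing every filter other than the
    alpha-dependent ones (binomial, cluster) enter the spectrum.  Returns
    the most stringent grid value with a warning when no alpha satisfies
    the criterion.
    """
    if len(germline_calls) < 50:
        raise ValueError(f"need >= 50 germline calls for a spectrum, got {len(germline_calls)}")
    # distinct germline variants only: shared sites recur across cohort samples
    germ = substitution_spectrum(germline_calls, unique_loci=True)
    germ_prop = germ / germ.sum()
    ct_index = SIX_CLASSES.index("C>T")

    usable = [
        c
        for c in somatic_candidates
        if c.is_snv
        and c.noise_p is not None
        and all(
            ok for name, ok in c.verdicts.items() if name not in ("binomial_noise", "cluster")
        )
    ]
    grid = sorted(alpha_grid, reverse=True)
    for alpha in grid:
        passing = [c for c in usable if c.noise_p < alpha]
        obs = substitution_spectrum(passing)
        total = obs.sum()
        if total == 0:
            continue
        keep = (obs + germ) > 0
        chi_p = stats.chi2_contingency(np.stack([obs[keep], germ[keep]])).pvalue
        ct_ok = obs[ct_index] / total <= ct_inflation_max * germ_prop[ct_index]
        if chi_p > spectrum_p_threshold and ct_ok:
            return float(alpha)
    warnings.warn(
        "no alpha in the grid matched the germline spectrum; returning the most stringent",
        stacklevel=2,
    )
    return float(grid[-1])


def attrition_table(calls: list[VariantCall]) -> pd.DataFrame:
    """Per-filter fail counts plus the pass total, shaped like a filter-criteria listing."""
    rows = []
    for name in FILTER_ORDER:
        n_fail = sum(1 for c in calls if not c.verdicts.get(name, True))
        rows.append({"filter": name, "n_failing": n_fail})
    rows.append({"filter": "PASS", "n_failing": sum(1 for c in calls if c.passed)})
    return pd.DataFrame(rows)


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else 0.0


def classify_consequence_summary(
    calls: list[VariantCall], subjects: list[Subject] | None = None
) -> dict[str, dict[str, object]]:
    """Per-group summary of discovered mutations (counts, percentages, VAF stats).

    Mirrors the usual case/control comparison table: mutation-type split
    (stop codon, frameshift and non-frameshift indel, splice, SNV),
    CADD>=20 and PolyPhen fractions over classifiable SNVs, COSMIC and novel
    fractions, VAF median/mean/range and mutated-gene count.  Groups come
    from ``subjects``; without them all calls form a single "all" group.
    """
    group_of = {s.subject_id: s.group for s in subjects} if subjects else {}
    groups: dict[str, list[VariantCall]] = defaultdict(list)
    for c in calls:
        groups[group_of.get(c.subject_id, "all")].append(c)

    out: dict[str, dict[str, object]] = {}
    for gname, gcalls in sorted(groups.items()):
        n = len(gcalls)
        per_subj = defaultdict(int)
        for c in gcalls:
            per_subj[c.subject_id] += 1
        counts = {
            "stopgain": sum(c.consequence == "stopgain" for c in gcalls),
            "frameshift_indel": sum(c.consequence == "frameshift_indel" for c in gcalls),
            "nonframeshift_indel": sum(c.consequence == "nonframeshift_indel" for c in gcalls),
            "splice": sum(c.consequence == "splice" for c in gcalls),
            "snv": sum(c.consequence == "nonsynonymous_SNV" for c in gcalls),
        }
        vafs = np.array([c.vaf for c in gcalls]) if n else np.array([0.0])
        cosmic_n = sum(c.cosmic for c in gcalls)
        known_af = sum(
            1 for c in gcalls if c.pop_af is not None and 0 < c.pop_af <= 1e-5
        )
        novel_n = sum(
            1 for c in gcalls if not c.cosmic and not (c.pop_af is not None and c.pop_af > 0)
        )
        classifiable = [
            c
            for c in gcalls
            if c.consequence == "nonsynonymous_SNV" and c.cadd is not None and c.polyphen is not None
        ]
        n_classif = len(classifiable)
        cadd20 = sum(c.cadd >= 20 for c in classifiable)
        pp_dp = sum(c.polyphen in ("D", "P") for c in classifiable)
        pp_b = sum(c.polyphen == "B" for c in classifiable)
        summary: dict[str, object] = {
            "n_total": n,
            "n_subjects": len(per_subj),
            "per_subject_median": float(np.median(list(per_subj.values()))) if per_subj else 0.0,
            "per_subject_min": min(per_subj.values(), default=0),
            "per_subject_max": max(per_subj.values(), default=0),
            "vaf_median_pct": round(float(np.median(vafs)) * 100, 2) if n else 0.0,
            "vaf_mean_pct": round(float(np.mean(vafs)) * 100, 2) if n else 0.0,
            "vaf_min_pct": round(float(vafs.min()) * 100, 2) if n else 0.0,
            "vaf_max_pct": round(float(vafs.max()) * 100, 2) if n else 0.0,
            "n_mutated_genes": len({c.gene for c in gcalls if c.gene}),
            "novel_n": novel_n,
            "novel_pct": _pct(novel_n, n),
            "cosmic_n": cosmic_n,
            "cosmic_pct": _pct(cosmic_n, n),
            "rare_population_n": known_af,
            "rare_population_pct": _pct(known_af, n),
            "cadd20_n": cadd20,
            "cadd20_denominator": n_classif,
            "cadd20_pct": _pct(cadd20, n_classif),
            "polyphen_dp_n": pp_dp,
            "polyphen_dp_pct": _pct(pp_dp, n_classif),
            "polyphen_b_n": pp_b,
            "polyphen_b_pct": _pct(pp_b, n_classif),
        }
        for key, cnt in counts.items():
            summary[f"{key}_n"] = cnt
            summary[f"{key}_pct"] = _pct(cnt, n)
        out[gname] = summary
    return out


def summary_frame(summary: dict[str, dict[str, object]]) -> pd.DataFrame:
    """Summary dict as a metrics-by-group table for reporting."""
    return pd.DataFrame(summary)
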