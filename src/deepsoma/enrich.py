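"""Gene-level mutation enrichment via a size-normalised Poisson test.

Under uniform per-base scatter of the cohort's mutations over the panel, a
gene of target length L collects Poisson(lambda) mutations with
lambda = N_total * L / panel_total.  The upper tail P(X >= k) flags genes
carrying more mutations than their size predicts — the signature of positive
selection of mutant clones.  Raw p-values are reported and ranked (a
Bonferroni column is emitted for reference only).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .calls import VariantCall
from .panel import Panel, Subject


def poisson_gene_test(k: int, gene_length: int, panel_total: int, n_total: int) -> tuple[float, float]:
    """Expected count lambda and exact Poisson upper tail P(X >= k).

    ``k`` counts mutations (not subjects) in the gene cohort-wide;
    ``gene_length`` is the gene's summed target size in bp.  k = 0 gives
    p = 1 (the whole distribution).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0 < gene_length <= panel_total:
        raise ValueError("need 0 < gene_length <= panel_total")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    lam = n_total * gene_length / panel_total
    p = 1.0 if k == 0 else float(stats.poisson.sf(k - 1, lam))
    return lam, p


def enrichment_table(
    calls: list[VariantCall],
    panel: Panel,
    subjects: list[Subject] | None = None,
    n_total: int | None = None,
    min_subjects: int = 2,
) -> pd.DataFrame:
    """Per-gene enrichment results ranked by ascending p.

    One row per gene with at least one mutation; columns gene, k, lambda, p,
    p_bonferroni, n_subjects, n_cases, n_controls, significant (the
    significance view: >= ``min_subjects`` mutated subjects and raw p < 0.05).
    ``n_total`` defaults to the size of the supplied call set, which should be
    one consequence class (nonsynonymous or synonymous) post-filter.
    """
    group_of = {s.subject_id: s.group for s in subjects} if subjects else {}
    n_total = n_total if n_total is not None else len(calls)
    by_gene: dict[str, list[VariantCall]] = defaultdict(list)
    for c in calls:
        if c.gene is None:
            raise ValueError(f"call {c.locus_id} has no gene annotation")
        if c.gene not in panel:
            raise KeyError(f"gene {c.gene!r} absent from panel")
        by_gene[c.gene].append(c)

    rows = []
    n_genes_tested = len(panel.genes)
    for gene, gcalls in by_gene.items():
        k = len(gcalls)
        lam, p = poisson_gene_test(k, panel.gene(gene).target_length, panel.total_target, n_total)
        subj = {c.subject_id for c in gcalls}
        rows.append(
            {
                "gene": gene,
                "k": k,
                "lambda": lam,
                "p": p,
                "p_bonferroni": min(1.0, p * n_genes_tested),
                "n_subjects": len(subj),
                "n_cases": sum(group_of.get(s) == "case" for s in subj),
                "n_controls": sum(group_of.get(s) == "control" for s in subj),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "k", "lambda", "p", "p_bonferroni", "n_subjects", "n_cases", "n_controls"],
    )
    df = df.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    df["significant"] = (df["n_subjects"] >= min_subjects) & (df["p"] < 0.05)
    return df


def significant_genes(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["significant"]].reset_index(drop=True)


def recurrent_variant_report(calls: list[VariantCall], subjects: list[Subject] | None = None) -> pd.DataFrame:
    """Identical variants (chrom, pos, ref, alt) shared by more than one subject."""
    group_of = {s.subject_id: s.group for s in subjects} if subjects else {}
    by_locus: dict[tuple, list[VariantCall]] = defaultdict(list)
    for c in calls:
        by_locus[c.locus].append(c)
    rows = []
    for locus, lcalls in sorted(by_locus.items()):
        subj = sorted({c.subject_id for c in lcalls})
        if len(subj) < 2:
            continue
        rows.append(
            {
                "chrom": locus[0],
                "pos": locus[1],
                "ref": locus[2],
                "alt": locus[3],
                "gene": lcalls[0].gene,
                "n_subjects": len(subj),
                "subjects": ",".join(subj),
                "groups": ",".join(group_of.get(s, "?") for s in subj),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "n_subjects", "subjects", "groups"],
    )


def expected_lambdas(panel: Panel, n_total: int) -> pd.Series:
    """Per-gene lambda over the whole panel; sums to ``n_total`` by construction."""
    lam = np.array([g.target_length for g in panel.genes], dtype=float)
    lam *= n_total / panel.total_target
    return pd.Series(lam, index=panel.gene_ids, name="lambda")
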