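"""Size-normalised Poisson test for genes enriched with somatic mutations.

Plants a 20x elevated per-base mutation rate in one gene and shows that the
enrichment table ranks it first with a small Poisson tail p, while equally
sized unboosted genes stay near their expected counts.
"""

import numpy as np

from deepsoma import VariantCall, enrichment_table, make_panel, poisson_gene_test

panel = make_panel(100, 2000, seed=1)
lengths = np.array([g.target_length for g in panel.genes], dtype=float)
weights = lengths.copy()
weights[0] *= 20.0  # the positively selected gene

rng = np.random.default_rng(5)
ks = rng.multinomial(225, weights / weights.sum())
calls = []
pos = 0
for gi, k in enumerate(ks):
    for _ in range(k):
        calls.append(
            VariantCall(
                subject_id=f"S{(pos // 3) % 12}", chrom="chr1", pos=1000 + 13 * pos,
                ref="C", alt="T", depth=2000, alt_count=20, alt_fwd=10, alt_rev=10,
                ref_fwd=990, ref_rev=990, gene=panel.genes[gi].gene_id,
                consequence="nonsynonymous_SNV",
            )
        )
        pos += 1

table = enrichment_table(calls, panel)
print(table.head(5).to_string(index=False))
lam, p = poisson_gene_test(2, 5000, 5_000_000, 225)
print(
    f"\nreference arithmetic: a 5 kb gene in a 5 Mb panel with 225 cohort mutations"
    f"\nexpects lambda = {lam:.3f}; observing k = 2 gives Poisson tail p = {p:.4f}"
)
print(
    "The boosted gene tops the ranking: its observed count is far above the\n"
    "length-proportional expectation, the signature of clonal selection."
)
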