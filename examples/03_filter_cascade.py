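"""Run the full somatic filter cascade against planted truth.

Simulates a cohort, applies every filter (germline, depth, strand bias,
cluster, mapping quality, population frequency, context-aware binomial noise
test) and scores the passing calls against the truth set at two operating
points: the stringent default alpha and the spectrum-calibrated alpha.
"""

from deepsoma import PipelineConfig, run_pipeline
from deepsoma.filters import attrition_table


def score(res):
    truth_keys = res.cohort.truth.somatic_keys()
    germ_loci = res.cohort.truth.germline_loci()
    tp = sum(1 for c in res.pass_calls if (c.subject_id, c.chrom, c.pos) in truth_keys)
    leaks = sum(1 for c in res.pass_calls if (c.chrom, c.pos) in germ_loci)
    return tp, len(res.pass_calls) - tp, leaks


base = dict(
    n_cases=3, n_controls=3, panel_n_genes=25, depth_lo=2000, depth_hi=3000,
    include_germline_in_candidates=True, seed=42,
)
stringent = run_pipeline(PipelineConfig(calibrate=False, **base))
calibrated = run_pipeline(PipelineConfig(calibrate=True, **base))

print(attrition_table(stringent.filtered_calls).to_string(index=False))
n_planted = len(stringent.cohort.truth.somatic)
for label, res, alpha in (
    ("default alpha 1e-06   ", stringent, 1e-6),
    (f"calibrated alpha {calibrated.calibrated_alpha:g}", calibrated, None),
):
    tp, fp, leaks = score(res)
    print(
        f"{label}: {tp:3d}/{n_planted} planted clones recovered, "
        f"{fp:3d} noise calls pass, {leaks} germline leaks"
    )
print(
    "\nThe stringent default is specificity-first (almost nothing but planted\n"
    "clones passes); the spectrum-calibrated point is the loosest threshold whose\n"
    "passing calls still look germline-like in substitution spectrum — it buys\n"
    "sensitivity for the weakest clones at the cost of class-uniform noise passes."
)
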