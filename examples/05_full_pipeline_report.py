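"""End-to-end run with the markdown report and edge-wise census.

Runs every stage on a mid-sized synthetic cohort (including normalized
rich-club curves at a reduced null-ensemble size) and prints the report:
hubs, ANOVA tables with significance stars, asymmetry tests, and the
census of edges with significant group/hemisphere/asymmetry effects per
rich-club / feeder / local class.
"""

from hemirc import CohortSpec, RunConfig, report, run_pipeline

spec = CohortSpec(n_nc=20, n_bd=20, seed=5)
bundle = run_pipeline(RunConfig(cohort_spec=spec, n_null=25, seed=5))

print(report(bundle))

census = bundle["edge_census"]
grp = census[census.effect == "group"]
print(
    "Reading the census: of the three connection classes, feeder and "
    "local edges carry most of the injected group effect, while "
    f"rich-club edges stay comparatively stable "
    f"({grp.set_index('class')['proportion_pct'].round(1).to_dict()} % aberrant)."
)
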