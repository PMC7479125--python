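"""Simulate a DTI-like cohort and write it to disk.

Builds the default synthetic cohort — 55 controls and 49 bipolar-
disorder patients, 90-region FA/fiber-count matrix pairs with a planted
7-hub rich club — and writes matrices, manifest and phenotypes in the
formats the I/O layer reads back.
"""

import tempfile
from pathlib import Path

from hemirc import CohortSpec, generate_cohort, write_cohort

spec = CohortSpec(seed=1)
cohort = generate_cohort(spec)

outdir = Path(tempfile.mkdtemp(prefix="hemirc_cohort_"))
manifest = write_cohort(cohort, outdir)

t = cohort.phenotypes.table
print(f"cohort written to {outdir}")
print(f"subjects: {len(t)} ({(t.group == 'NC').sum()} NC, {(t.group == 'BD').sum()} BD)")
print(f"planted hub positions (per hemisphere): {[int(p) for p in cohort.hub_positions]}")
print(t.head(4).to_string(index=False))
# Each row is one subject: group membership, the age/sex/handedness
# covariates, and (for patients) YMRS mania and HAMD depression scores
# that track the injected degree-asymmetry severity.
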