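"""Generate an ADNI-1-like synthetic cohort and inspect its structure.

The generator draws 229 CN / 382 MCI / 187 AD subjects whose demographics
and neuropsychological scores follow the published per-class summary
statistics, then assigns a stratified 70/10/20 train/validation/test split.
"""
import numpy as np

import popgraph_stager as pg

config = pg.CohortConfig(seed=1)
cohort = pg.generate_cohort(config)

print(f"cohort size: {len(cohort)}")
for diagnosis in ("CN", "MCI", "AD"):
    n = cohort.diagnoses.count(diagnosis)
    print(f"  {diagnosis}: {n} subjects")

splits = {name: sum(v == name for v in cohort.split.values())
          for name in ("train", "val", "test")}
print(f"split sizes: {splits}")

df = cohort.to_dataframe()
print("\nper-class MMSE and CDR-SB (sample mean +/- SD vs calibration):")
for diagnosis in ("CN", "MCI", "AD"):
    rows = df[df.diagnosis == diagnosis]
    print(f"  {diagnosis}: MMSE {rows.MMSE.mean():.1f} +/- {rows.MMSE.std():.1f},"
          f"  CDR-SB {rows.CDR_SB.mean():.1f} +/- {rows.CDR_SB.std():.1f}")

# The numbers above should track the calibration table (e.g. AD MMSE
# 23.3 +/- 2.0, CN CDR-SB 0.0 +/- 0.1): the cohort is statistically, not
# individually, realistic.
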