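"""CASP-style Z-score ranking from a raw metric table.

Builds a small synthetic assessment table (3 groups x 2 domains x the 10
assessor metrics), standardizes each (domain, metric) across groups with
the two-pass outlier-excluding Z-score, and aggregates with the
assessor weights 1/6 (GDT-HA, reLLG, ASE), 1/16 (LDDT, AA, SG, SCerror)
and 1/12 (Molprobity, BBerror, DipDiff) — which sum to 1 per domain.
"""

import numpy as np
import pandas as pd

from foldeval import MetricTable, ZScoreConfig, rank_groups
from foldeval.evaluation import ASSESSOR_METRIC_WEIGHTS, LOWER_IS_BETTER

rng = np.random.default_rng(0)
groups = {"alpha": 1.0, "beta": 0.0, "gamma": -1.0}  # skill offsets

rows = []
for group, skill in groups.items():
    for domain in ("D1", "D2"):
        for metric in ASSESSOR_METRIC_WEIGHTS:
            base = 50.0 + 10.0 * skill + rng.normal(0, 2.0)
            if metric in LOWER_IS_BETTER:
                base = 100.0 - base  # smaller raw value = better model
            rows.append((group, domain, metric, base))

table = MetricTable(pd.DataFrame(rows,
                                 columns=["group", "domain", "metric", "value"]))
ranking = rank_groups(table, ZScoreConfig())
print(ranking.to_string(index=False))
print("\nsum_z aggregates per-domain Z-scores with the assessor weights; "
      "with 2 domains a group one sd above the mean everywhere would score "
      "2.0.  Lower-is-better metrics are flipped before standardizing.")
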