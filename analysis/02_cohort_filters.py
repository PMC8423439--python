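#!/usr/bin/env python
"""Apply the cohort-construction filters and report what survives.

Reads the selected cohort back from disk, applies the sample-missingness
filter (remove > 96% missing), the European coordinate box, period
assignment from carbon-dated ages, and the ancient/modern variant
intersection, reporting per-period counts. Writes results/cohort_counts.tsv.
"""

import sys, os
sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, cohort_dir, ensure_dirs

import pandas as pd

from paleoprs import pipeline
from paleoprs.periods import PERIOD_ORDER


def main() -> None:
    ensure_dirs()
    rows = []
    for name in ("selected", "neutral"):
        d = cohort_dir(name)
        cfg = pipeline.RunConfig(
            ancient_prefix=os.path.join(d, "ancient"),
            modern_prefix=os.path.join(d, "modern"),
            meta_path=os.path.join(d, "samples.tsv"),
            sumstats_paths={"trait": os.path.join(d, "sumstats_trait.tsv")},
            out_dir=os.path.join(d, "unused"),
        )
        panel, meta = pipeline.load_cohort(cfg)
        counts = meta["period"].value_counts()
        print(f"[{name}] retained {panel.n_samples} samples x {panel.n_variants} variants")
        for period in PERIOD_ORDER:
            if period in counts:
                print(f"    {period:<14} {counts[period]}")
                rows.append({"cohort": name, "period": period, "n": int(counts[period])})
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "cohort_counts.tsv"),
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
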