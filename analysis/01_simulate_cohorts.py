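#!/usr/bin/env python
"""Generate the two study cohorts (selected trait vs neutral control).

Writes EIGENSTRAT trios (ancient/modern), sample metadata, and GWAS-style
summary statistics for each cohort under scratch/cohorts/<name>/.
"""

import sys, os
sys.path.insert(0, os.path.dirname(__file__))
from common import COHORTS, cohort_dir, ensure_dirs

from paleoprs.simulate import generate_panel


def main() -> None:
    ensure_dirs()
    for name, config in COHORTS.items():
        sim = generate_panel(config, out_dir=cohort_dir(name))
        n_anc = int((sim.meta["period"] != "Modern").sum())
        n_mod = sim.panel.n_samples - n_anc
        print(f"[{name}] {n_anc} ancient + {n_mod} modern samples, "
              f"{sim.panel.n_variants} variants, "
              f"{config.n_trait_variants} trait QTLs, "
              f"s = {config.selection_coeff} -> {cohort_dir(name)}")


if __name__ == "__main__":
    main()
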