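"""Per-unit selectivity on the reference session: singleton-vs-nonsalient
modulation indices with a Wilcoxon test and rank effect size, and
omega-squared PEV classification into target / singleton / mixed /
nonselective units.

Runs the unit_stats pipeline stage against results/session and reports the
summary statistics the stage computes.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from popsaliency import pipeline, selectivity as sel

OUT = Path("results")


def main():
    cfg = pipeline.RunConfig(seed=1, n_units=100, n_trials_per_condition=40)
    pipeline.run(cfg, OUT / "run", stages=("simulate", "preprocess", "unit_stats"))
    stats_df = pd.read_csv(OUT / "run" / "unit_stats.csv")
    mi = stats_df["modulation_index"].dropna()
    w = stats.wilcoxon(mi)
    z = stats.norm.isf(w.pvalue / 2) * np.sign(np.median(mi))
    r = sel.rank_effect_size(z, len(mi))
    print(
        f"modulation index: median {mi.median():+.3f} "
        f"(Wilcoxon p={w.pvalue:.3g}, z={z:+.2f}, r={r:+.2f}, n={len(mi)})"
    )
    frac = stats_df["selectivity_class"].value_counts(normalize=True)
    print("selectivity classes:")
    print((100 * frac).round(1).to_string())
    stats_df.to_csv(OUT / "unit_stats.csv", index=False)


if __name__ == "__main__":
    main()
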