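"""Rank-based comparison of models on the packaged literature tables.

Applies the Friedman omnibus test and the Nemenyi critical difference to
the per-participant VAF values reported for the EEG wrist-perturbation
benchmark.
"""

from evostack import friedman_test, load_results_fixture, nemenyi_test
from evostack.fixtures import friedman_subset

for horizon in (1, 3):
    table = load_results_fixture(horizon)
    sub = table[table["model"].isin(friedman_subset(horizon))]
    wide = sub.pivot(index="participant", columns="model", values="vaf")
    fr = friedman_test(wide, better="higher")
    ne = nemenyi_test(wide, alpha=0.05, better="higher")
    print(f"horizon {horizon}: FD = {fr.statistic:.2f} (df {fr.df}), "
          f"p = {fr.pvalue:.3g}, CD = {ne.cd:.3f}")
    ranks = ne.mean_ranks.sort_values()
    for model, r in ranks.items():
        print(f"  {model:<12} mean rank {r:5.2f}")
# Lower mean rank = better VAF across participants. Two models differ
# significantly when their mean ranks are more than CD apart.
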