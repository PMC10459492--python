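"""Build the NARX design matrix for one trial and show its anatomy.

Each row predicts y(t) from five output lags, three input lags and six
engineered input features, all strictly causal (no sample at time >= t is
used).
"""

from evostack import FeatureSpec, MultisineSpec, make_benchmark
from evostack.features import build_design

participant = make_benchmark(1, MultisineSpec(seconds=1.0), seed=3)[0]
design = build_design(participant.train[0], FeatureSpec())

print(f"trial length {len(participant.train[0])} -> "
      f"{len(design)} usable rows (burn-in {FeatureSpec().burn_in})")
print("regressor columns:", ", ".join(design.X.columns))
print("\nfirst row (target t =", int(design.provenance['t'].iloc[0]), "):")
print(design.X.iloc[0].round(4).to_string())
print(f"target y(t) = {design.y[0]:.4f}")
# y_lag*/u_lag* are raw delayed samples; u_mean_w/u_std_w/u_skew_w summarize
# the last three inputs; u_diff12, u_cube and u_slog are nonlinear
# transforms of u(t-1).
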