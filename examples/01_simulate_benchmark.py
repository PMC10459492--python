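"""Generate a synthetic participant and inspect the study protocol shape.

Builds one participant of the synthetic EEG-style benchmark: seven
random-phase multisine perturbation signals driving a Wiener-type
nonlinear system with noise calibrated to a realistic achievable VAF.
"""

import numpy as np

from evostack import MultisineSpec, make_benchmark

participant = make_benchmark(1, MultisineSpec(seconds=2.0), seed=7)[0]

print(f"participant {participant.participant}")
print(f"  signals: {len(participant.trials)} "
      f"(train {[t.signal_id for t in participant.train]}, "
      f"test {participant.test.signal_id})")
print(f"  samples per signal: {len(participant.test)} at "
      f"{participant.test.fs:.0f} Hz")
sys = participant.system
print(f"  system: a1={sys.a1:.3f} a2={sys.a2:.3f} b1={sys.b1:.3f} "
      f"c3={sys.c3:.3f} sigma={sys.sigma:.3f}")
print(f"  achievable one-step VAF (noise bound): {participant.oracle_vaf:.2f}%")
print(f"  output sd: {np.std(participant.test.y):.3f}")
# The noise bound is the best VAF any one-step predictor can reach given
# the measurement-noise floor; the pipeline is judged against it.
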