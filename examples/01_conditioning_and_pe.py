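"""Simulate a probabilistic taste-conditioning run and its prediction errors.

Builds a sequence with 100 sucrose-CS trials at 20% violation (leaving the 80
expected sucrose receipts used by the connectivity analysis), runs the
Rescorla-Wagner delta rule, and prints how surprise differs between violated
and expected trials.
"""

import numpy as np

from tastepe import RWModel, compute_pe_trace, generate_trial_sequence

seq = generate_trial_sequence(n_sucrose_cs=100, n_neutral_cs=100,
                              n_saliva_cs=50, p_violation=0.2, seed=7)
trace = compute_pe_trace(seq, RWModel(alpha=0.7))

viol = np.array([t.is_violation for t in seq])
print(f"trials: {len(seq)}  violations: {viol.sum()}")
print(f"expected sucrose receipts: {seq.n_expected_receipts('sucrose')}")
print(f"mean |PE| on violated trials:  {trace.abs_delta[viol].mean():.3f}")
print(f"mean |PE| on expected trials:  {trace.abs_delta[~viol].mean():.3f}")

# Violated outcomes are surprising, so they carry the larger learning signal;
# the |PE| series is the parametric modulator for the BOLD model.
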