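"""How wrong can the intention oracle be?

The oracle is only a model of what the user intends.  This script trains the
cursor decoder while the signal actually driving the neural activity deviates
from the oracle in three ways — isotropic intention noise, a fixed linear
bias, and a distance-dependent arc rotation — and prints the asymptotic loss
under each.
"""

import numpy as np
from scipy.stats import special_ortho_group

from imitatebci import MismatchSpec, UpdateSpec, cursor_preset
from imitatebci.analysis import asymptotic_sse, run_sessions, success_rate, summarize_sessions

REPEATS, SEED = 5, 21
spec = UpdateSpec(rule="ftl")

conditions = {
    "none": MismatchSpec(),
    "noise 100%": MismatchSpec(kind="noise", noise_pct=100.0),
    "linear (random rotation)": MismatchSpec(kind="linear", M=special_ortho_group.rvs(3, random_state=0)),
    "arc 45 deg": MismatchSpec(kind="arc", phi_max=45.0),
}

print(f"{'mismatch':>26} {'asymptotic SSE':>15} {'success':>8}")
for name, mm in conditions.items():
    runs = run_sessions(cursor_preset(update=spec, mismatch=mm), REPEATS, SEED)
    df = summarize_sessions(runs)
    print(f"{name:>26} {asymptotic_sse(df):>15.2f} {success_rate(df, 20):>8.2f}")

print(
    "\nA fixed linear bias is invisible: the decoder simply learns to undo it,\n"
    "so the loss matches the no-mismatch run.  Random intention noise and the\n"
    "distance-dependent arc cannot be undone by any fixed linear decoder and\n"
    "degrade the loss gradually — yet the task still gets done."
)
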