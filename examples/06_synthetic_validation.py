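"""Desk-scale synthetic validation: growth recovery under model "noise".

Runs the two shipped growth combinations -- longitudinally dominated
(alpha_f = 0.9, alpha_n = 0.3) and transversely dominated (alpha_f = 0.1,
alpha_n = 0.3).  Targets are generated on a refined mesh with 5x more
pseudo-time increments than the inversion model, so recovery is tested
against forward-model discretization error rather than an inverse crime.
Expect ~15-20 minutes on one CPU.
"""

import numpy as np

from cardiogrowth import BOSettings
from cardiogrowth.experiments import default_desk_cases, records_to_frame, run_validation_suite

records = run_validation_suite(default_desk_cases(), bo_settings=BOSettings(seed=1))
frame = records_to_frame(records)
print(frame[["alpha_f_gt", "alpha_n_gt", "alpha_f_pred", "alpha_n_pred", "normalized_error", "final_dice"]].to_string(index=False))
errs = frame["normalized_error"].dropna()
print(f"\nmean normalized error: {100 * errs.mean():.1f}%")
print(f"minimum final DICE:    {100 * frame['final_dice'].min():.1f}%")
# A mean error of a few percent with DICE > 90% at the optimum mirrors the
# regime in which two-parameter kinematic growth is identifiable from
# shape overlap alone.
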