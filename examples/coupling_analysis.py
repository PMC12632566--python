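"""Theta-phase coupling of high-gamma amplitude and articulatory change.

For one sensorimotor site: the Tort modulation index (24 phase bins of
15 deg) of the high-gamma envelope and of the articulatory-change (AC)
series, each with a circular-shift surrogate p-value.  High-gamma should
peak shortly after the theta trough and AC about a quarter cycle later.
"""

import numpy as np

from thetaspeech import pipelines, synthgen

cfg = synthgen.SessionConfig(duration_s=60.0, n_channels=4, seed=5,
                             error_trial_fraction=0.0)
ses = synthgen.make_session(cfg)

out = pipelines.site_coupling_summary(ses, channel=0, n_surrogates=500,
                                      seed=0)
hg, ac = out["hg"], out["ac"]
print(f"HG-PAC:      MI = {hg.mi:.4f}, p = {hg.p_value:.4f}, "
      f"preferred phase = {np.degrees(hg.preferred_phase):.0f} deg "
      f"(injected {np.degrees(cfg.pac_phase):.0f})")
print(f"Theta-AC:    MI = {ac.mi:.4f}, p = {ac.p_value:.4f}, "
      f"preferred phase = {np.degrees(ac.preferred_phase):.0f} deg "
      f"(injected {np.degrees(cfg.ac_preferred_phase):.0f})")
print(f"AC - HG offset: {out['ac_minus_hg_deg']:.0f} deg "
      "(movement follows the population-activity burst by ~a quarter cycle)")
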