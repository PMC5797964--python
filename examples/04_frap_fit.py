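"""FRAP: normalize a bleach-recovery trace and fit the half-time.

The trace is normalized so the single pre-bleach frame reads 1 and the
first post-bleach frame reads 0, then fitted with the single-exponential
recovery model F(t) = A * (1 - exp(-k t)); t_half = ln2 / k summarizes
microtubule turnover at the bleached spindle pole.
"""

import oospindle as oo

# control-like and overexpression-like conditions, 5 s frames over 125 s
for label, t_half in (("control", 62.0), ("overexpression", 55.0)):
    trace = oo.simulate_frap_trace(t_half=t_half, interval=5.0, duration=125.0,
                                   noise_sd=0.02, seed=1)
    fit = oo.fit_frap(trace)
    print(f"{label:15s} true t_half {t_half:5.1f} s -> "
          f"fitted {fit.t_half:5.1f} s (k = {fit.k:.4f} /s, "
          f"plateau A = {fit.plateau:.2f}, rss = {fit.rss:.4f})")
# A near 1 means full recovery (no immobile fraction); the two conditions
# differ by ~10% in half-time, i.e. similar microtubule turnover.
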