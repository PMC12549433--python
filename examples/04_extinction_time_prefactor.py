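"""Full extinction-time asymptotics tau ~ (K / sqrt(N)) exp(N A).

For multitype birth-death processes with equal birth rates, matching the
WKB body against the linearised solution near the origin yields the
complete prefactor.  We compare against the exact truncated-chain value
over a range of population scales.
"""

import numpy as np

import qsdwkb as q

built = q.make_logistic(k=1, lam=3.0, mu=1.0, kappa=4.0)
w = q.WKB(built.model)
A = w.log_tau_leading()
print(f"extinction exponent A = {A:.6f}")
print(f"{'N':>5} {'tau_exact':>12} {'tau_full':>12} {'ratio':>8} "
      f"{'ln(tau)/N':>10}")
for N in (20, 40, 80):
    chain = q.build_truncated(built.model, N)
    _, alpha = q.exact_qsd(chain)
    tau_exact = 1.0 / alpha
    tau_full = q.tau_full(built.model, N, wkb=w)
    print(f"{N:>5} {tau_exact:>12.4g} {tau_full:>12.4g} "
          f"{tau_full / tau_exact:>8.4f} {np.log(tau_exact) / N:>10.5f}")
print("the ratio approaches 1 and ln(tau)/N approaches A as N grows —")
print("the prefactor corrects the raw exponential estimate by orders of "
      "magnitude at moderate N")
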