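"""Decide which reversibility criteria a model satisfies.

The WKB machinery applies only to processes whose rates satisfy asymptotic
analogues of Kolmogorov's cycle criterion.  For the two-group movement model
the leading-order condition holds precisely when lam1 nu1 = lam2 nu2; here
we check a balanced and an unbalanced instance.
"""

import qsdwkb as q

balanced = q.make_two_group(mu=2.9, kappa=0.1, lam1=1.0, lam2=2.0,
                            nu1=2.0, nu2=1.0)
unbalanced = q.make_two_group(mu=2.9, kappa=0.1, lam1=1.0, lam2=2.0,
                              nu1=3.0, nu2=1.0)

for built in (balanced, unbalanced):
    lam1, lam2 = built.config["params"]["lam1"], built.config["params"]["lam2"]
    nu1, nu2 = built.config["params"]["nu1"], built.config["params"]["nu2"]
    rep = q.full_report(built.model, n_samples=32, seed=0)
    print(f"lam1*nu1 = {lam1 * nu1:g}, lam2*nu2 = {lam2 * nu2:g}")
    for name in ("cycle", "theta_consistent", "theta_irrotational",
                 "cycle0", "theta0_consistent", "theta0_irrotational"):
        v = getattr(rep, name)
        print(f"  {name:20s} {v.status:8s} residual={v.worst_residual:.2e}")
    print("  usable results:", ", ".join(rep.applicable_results()) or "none")
    print()

# A PASS residual is at rounding level; the FAIL residual for the unbalanced
# model equals |ln(lam2 nu2 / lam1 nu1)|, the imbalance around the jump cycle.
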