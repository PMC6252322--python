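"""Population PK fit on a small synthetic trial.

Generates a 12-subject trial at the published truth, then re-estimates
the three-compartment model by Laplace-approximate maximum likelihood
from deliberately perturbed starting values.
"""

import time
from dataclasses import replace

from remipkpd.nlme import fit_population
from remipkpd.published import published_bis, published_moaas, published_pk
from remipkpd.synthdata import StudyDesign, generate_trial

pk = published_pk()
design = StudyDesign(cohorts=((0.075, 3), (0.15, 3), (0.25, 3), (0.45, 3)))
table = generate_trial(design, pk, published_bis(), published_moaas(), rng_seed=7)

init = replace(pk, v1=pk.v1 * 1.3, cl=pk.cl / 1.3, v2=pk.v2 * 1.3,
               q2=pk.q2 / 1.3, v3=pk.v3 * 1.3, q3=pk.q3 / 1.3)
t0 = time.time()
fit = fit_population(table, "pk", init=init, maxiter=100,
                     optimizer_options={"gtol": 0.05})
print(f"fit in {time.time()-t0:.0f}s, OFV {fit.ofv:.1f}, AIC {fit.aic:.1f} "
      f"({fit.convergence})")
print(f"{'parameter':10s} {'estimate':>9s} {'truth':>7s}")
for name in ("v1", "cl", "v2", "q2", "v3", "q3"):
    print(f"{name:10s} {fit.estimates[name]:9.3f} {getattr(pk, name):7.3f}")
print(f"{'sigma':10s} {fit.estimates['sigma']:9.3f} {pk.sigma_prop:7.3f}")
print()
print("Estimates land close to the generating values even from a 30%")
print("perturbed start; with only 12 subjects some spread in the")
print("peripheral-compartment parameters is expected.")
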