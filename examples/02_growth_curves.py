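"""Fit logistic growth curves to chick mass series and test group effects.

Simulates the brood-size-manipulation experiment (1 vs 3 chick nests,
resident vs relocated parents), fits W_t = A / (1 + exp(K (I - t))) to
each chick by least squares, and models the fitted growth rate K with a
mixed model (brood size x sex x parental origin, random year / parent /
nest / chick).
"""

import colonyforage as cf

cfg = cf.SimulationConfig(seed=11)
records, truth = cf.simulate_growth(cfg)
params = cf.fit_all_chicks(records, seed=11)
ok = params[params["converged"]]
print(f"{len(params)} chicks, {len(ok)} with usable growth curves "
      f"(died-young chicks lack the 4 points needed)")
print()
print("mean fitted K (1/day) by origin and brood size:")
print(ok.groupby(["origin", "brood_size"])["K"].mean().round(3))
print()
models = cf.analyse_growth(params)
print("mixed-model term table for K:")
print(models["K"]["terms"].round(4).to_string(index=False))
print()
print("The brood size x origin interaction reflects the generator's truth: "
      "chicks of\nrelocated parents grow slower only in high-demand "
      "(3-chick) nests.")
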