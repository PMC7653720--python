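"""Fit an Ornstein-Uhlenbeck movement model and estimate an AKDE home range.

The OU fit gives the position autocorrelation timescale tau and hence an
effective sample size n_eff = tracking span / tau; the kernel bandwidth
uses n_eff instead of the raw fix count, so autocorrelated tracks are
smoothed more. Isopleths are highest-density regions at 25/50/75/95%.
"""

import colonyforage as cf

cfg = cf.SimulationConfig(
    seed=3, n_birds_per_group={"zb_zb": 1, "vl_vl": 0, "zb_vl": 0},
    groups=("zb_zb",), n_days=8)
ds = cf.simulate_tracks(cfg)
bird = ds.birds["bird_id"].iloc[0]
traj = ds.fixes[ds.fixes["bird_id"] == bird]

fit = cf.fit_ou(traj)
print(f"bird {bird}: {fit.n} fixes over "
      f"{fit.times_h[-1] - fit.times_h[0]:.0f} h")
print(f"  tau = {fit.tau_pos:.2f} h  ->  n_eff = {fit.n_eff:.0f} "
      f"effective fixes (vs {fit.n} nominal)")
print(f"  home-range centre (km, local plane): "
      f"({fit.mu[0]:.1f}, {fit.mu[1]:.1f})")

hr = cf.akde(fit, cell_km=0.5)
for frac in (0.25, 0.5, 0.75, 0.95):
    print(f"  {int(frac * 100):>2d}% isopleth area: "
          f"{hr.isopleth_area(frac):8.1f} km^2")
print()
print("Areas grow with the probability mass enclosed; the 95% isopleth is "
      "the\nconventional 'home range'. n_eff << n signals strong "
      "autocorrelation: the bird's\n3-min fixes are far from independent "
      "samples of its space use.")
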