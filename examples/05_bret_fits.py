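"""NanoBRET quantification: milliBRET units and dose-response fits."""

import numpy as np

import phosdim as P

# milliBRET from raw emissions
print(f"milliBRET(a610=35, d450=20000) = {P.millibret(35.0, 20000.0):.2f} mBU")

# acceptor-DNA titration -> one-site total binding (quadruplicate 3-fold series)
doses = np.tile(np.concatenate([[0.0], 50.0 * 3.0 ** -np.arange(8)[::-1]]), 4)
_, y = P.simulate_bret_series(
    "one_site", {"bmax": 12.0, "kd": 2.5, "ns": 0.04}, doses, noise_sd=0.5, seed=0
)
fit = P.fit_one_site_total(doses, y)
print(f"one-site fit: Bmax={fit.bmax:.2f} (true 12), Kd={fit.kd:.2f} (true 2.5), "
      f"NS={fit.ns:.3f} (true 0.04)")

# compound dose-response -> 4PL on log10 molar dose
x_log = np.tile(np.linspace(-9, -4, 12), 4)
_, y2 = P.simulate_bret_series(
    "4pl", {"bottom": 8.0, "top": 95.0, "log_x50": -6.8, "hill": 1.1},
    x_log, noise_sd=3.0, seed=0,
)
fit2 = P.fit_4pl(x_log, y2, mode="EC50")
print(f"4PL fit: EC50 = {fit2.x50 * 1e9:.0f} nM (true {10**-6.8 * 1e9:.0f} nM), "
      f"Hill = {fit2.hill:.2f}")
print("Kd measures acceptor-donor affinity in the titration; EC50 the potency "
      "of a compound at shifting the dimer BRET signal.")
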