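"""Delta-rho dynamics over a simulated conversion time course.

Correlation between two features can flip sign along a nitrogen-
starvation course (e.g. from joint degradation to conversion); the
delta-rho map (max rho - min rho across time points) localizes these
dynamic hot spots.
"""

import numpy as np

import irca
from irca.phenotypes import PhenotypeDef, phenotype_matrix
from irca.preprocess import standardize_ramanome

series = irca.simulate_series("pst", np.array([0.0, 24.0, 96.0, 192.0]),
                              n_cells=60, seed=11)[0]

defs = [PhenotypeDef(n, "peak", {"wavenumber": w}) for n, w in [
    ("protein_1003", 1003), ("starch_940", 940),
    ("lipid_1441", 1441), ("nucleic_783", 783)]]

cms = []
for ram, t in zip(series.ramanomes, series.time_points):
    std = standardize_ramanome(ram)
    cm = irca.correlation_matrix(phenotype_matrix(std, defs),
                                 [d.name for d in defs])
    rho, _ = cm.pair("starch_940", "lipid_1441")
    print(f"t = {t:5.0f} h: rho(starch, lipid) = {rho:+.3f}")
    cms.append(cm)

dm = irca.delta_rho(cms)
iu = np.triu_indices(len(defs), k=1)
order = np.argsort(dm.delta[iu])[::-1]
print("\ndelta-rho ranking (largest = most dynamic pair):")
for k in order:
    i, j = iu[0][k], iu[1][k]
    print(f"  {defs[i].name} -- {defs[j].name}: "
          f"delta-rho = {dm.delta[i, j]:.2f}")
print("the starch-lipid pair dominates because its planted correlation "
      "moves from 0 to -0.8 as the conversion switches on")
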