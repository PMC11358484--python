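"""Parsimonious DCE-MRI model selection on the standard three-region phantom.

Generates a noisy phantom whose stripes follow the Patlak, 2CFM and 2CFM-O
models, converts signal to gadolinium concentration, fits all three models
per voxel, and selects the minimum-AICc model.  Prints how often the
generating model wins and how well F_T (the filtration coefficient driving
GFR) is recovered.
"""

import numpy as np

from renalmri.pk_fitting import fit_roi, voxel_quality_summary
from renalmri.synthetic import make_dce_phantom, standard_phantom_spec
from renalmri.tracer_kinetics import concentration_from_signal

ph = make_dce_phantom(standard_phantom_spec(snr=20.0, seed=0))
conc = np.zeros_like(ph["signal"])
for idx in np.argwhere(ph["mask"]):
    curve, _ = concentration_from_signal(ph["signal"][tuple(idx)],
                                         ph["acq"], ph["grid"])
    conc[tuple(idx)] = curve.values

res = fit_roi(conc, ph["mask"], ph["aif"], c3=ph["c3"], grid=ph["grid"])

codes = {"patlak": 1, "2cfm": 2, "2cfmo": 3}
truth = np.vectorize(codes.get)(ph["truth"]["model_map"])[ph["mask"]]
sel = res["choice_map"].values[ph["mask"]]
rel = (res["ft_map"].values[ph["mask"]] - ph["truth"]["ft_map"][ph["mask"]]) \
    / ph["truth"]["ft_map"][ph["mask"]]

print(f"voxels fitted:                 {int(ph['mask'].sum())}")
print(f"generating model selected:     {100 * np.mean(sel == truth):.1f}% of voxels")
print(f"F_T relative RMSE:             {100 * np.sqrt(np.nanmean(rel**2)):.1f}%")
print(f"voxels with R2 > 0.70 (pars.): {voxel_quality_summary(res['r2_map']):.1f}%")
print()
print("A high selection rate means AICc reliably identifies which kinetic")
print("regime generated each voxel; the F_T error is what propagates into GFR.")
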