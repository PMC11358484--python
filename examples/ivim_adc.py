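"""Mono-exponential ADC and segmented IVIM fitting of a 13-b-value series.

Builds a noisy ROI-averaged renal-cortex DWI series with known diffusion
parameters, fits both models and prints the recovered values next to truth.
"""

from renalmri.diffusion import IVIMParams, fit_adc, fit_ivim_segmented
from renalmri.synthetic import make_dwi_series

truth = IVIMParams(D=0.0015, Dstar=0.05, f=0.29, S0=1000.0)
gen = make_dwi_series(truth, snr=30.0, seed=42)

adc = fit_adc(gen["series"])
ivim = fit_ivim_segmented(gen["series"])

print(f"ADC  (mono-exponential): {adc.ADC:.5f} mm^2/s")
print(f"D    (true diffusion):   {ivim.D:.5f} mm^2/s   (truth {truth.D})")
print(f"D*   (pseudodiffusion):  {ivim.Dstar:.4f} mm^2/s   (truth {truth.Dstar})")
print(f"f    (perfusion frac.):  {ivim.f:.3f}         (truth {truth.f})")
print()
print("ADC exceeds D because the mono-exponential fit absorbs the fast")
print("perfusion component; D* and f are the least stable IVIM parameters.")
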