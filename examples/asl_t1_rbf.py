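"""FAIR-ASL: T1 fitting of a selective/global inversion-recovery pair and
renal blood flow from the T1 difference.

Selective (slice-only) inversion lets fresh unlabeled blood flow in, which
shortens the apparent T1 relative to global inversion; the difference in
relaxation rates times the blood-tissue partition coefficient gives RBF.
"""

from renalmri.relaxometry import fit_t1, rbf_from_t1
from renalmri.synthetic import make_ir_series

# ROI-averaged IR series are very clean (SNR ~ hundreds); RBF rests on a
# small T1 difference, so it demands exactly that kind of data
gen = make_ir_series(t1_selective=1150.0, t1_global=1220.0, snr=500.0, seed=7)

t1_sel = fit_t1(gen["selective"])
t1_glob = fit_t1(gen["global"])
rbf = rbf_from_t1(t1_sel.T1, t1_glob.T1, lambda_partition=0.9)
rbf_true = rbf_from_t1(1150.0, 1220.0, lambda_partition=0.9)

print(f"T1 selective: {t1_sel.T1:7.1f} ms   (truth 1150)")
print(f"T1 global:    {t1_glob.T1:7.1f} ms   (truth 1220)")
print(f"RBF:          {rbf.RBF:7.1f} ml/min/100 g   (truth {rbf_true.RBF:.1f})")
print()
print("Healthy mouse renal cortex sits near 300-400 ml/min/100 g; unilateral")
print("ischemia-reperfusion injury depresses RBF in the clamped kidney.")
print("Because RBF rides on a small 1/T1 difference, percent-level T1 noise")
print("translates into tens of ml/min/100 g of RBF uncertainty.")
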