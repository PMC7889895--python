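"""Estimate an uphill interprotein electron-transfer rate with the empirical
tunneling ruler.

A high-potential iron-sulfur donor (+340 mV) reduces a low-potential heme
(+10 mV): the step is 0.33 eV endergonic.  With an edge-to-edge distance of
6.5 A, reorganization energy 0.7 eV and packing density 0.77, the ruler's
detailed-balance branch prices the uphill step at roughly 10^5 per second —
fast enough that, when the measured turnover is orders of magnitude slower,
complex formation rather than tunneling must be rate-limiting.
"""

from redoxpath.ruler import delta_g, et_rate

dg = delta_g(e_donor=0.340, e_acceptor=0.010)
print(f"driving force      : {dg:+.3f} eV (positive = uphill)")

log10_k, k = et_rate(R=6.5, delta_g_ev=dg, lambda_reorg=0.7, rho=0.77)
print(f"log10 rate         : {log10_k:.2f}")
print(f"rate               : {k:.2e} s^-1")

rev_log10, rev_k = et_rate(R=6.5, delta_g_ev=-dg, lambda_reorg=0.7, rho=0.77)
print(f"reverse (downhill) : {rev_k:.2e} s^-1")
print(f"ratio check        : log10(k_fwd/k_rev) = {log10_k - rev_log10:.2f} "
      f"= -dG/0.06 = {-dg / 0.06:.2f}")

print("\ndistance sensitivity at fixed energetics:")
for r in (3.6, 6.5, 10.0, 14.0):
    l10, kk = et_rate(R=r, delta_g_ev=dg, lambda_reorg=0.7, rho=0.77)
    print(f"  R = {r:5.1f} A  ->  k = {kk:9.2e} s^-1")
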