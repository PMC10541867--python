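"""When does patchiness help growth?  The two-subregion thought experiment.

A patch is split into two equal halves with concentrations r +/- dr and
b +/- db.  Averaging the Monod growth of the halves (heterogeneous
estimate) versus computing one Monod growth from the averaged
concentrations (mean-field estimate) differ by a closed-form gap that is
positive exactly when (k + r) * db > b * dr.
"""

from planktonpatch import TwoBoxState, growth_gap, growth_heterogeneous, growth_mean_field

nu, k = 1.0, 2.0
state = TwoBoxState(r=1.0, b=1.0, dr=0.5, db=0.5)

het = growth_heterogeneous(state, nu, k)
mf = growth_mean_field(state, nu, k)
gap = growth_gap(state, nu, k)

print(f"heterogeneous growth: {het:.6f} umol m^-3 day^-1")
print(f"mean-field growth:    {mf:.6f} umol m^-3 day^-1")
print(f"gap:                  {gap:+.6f}  (identity check: {het - mf:+.6f})")
print(f"positivity condition (k+r)*db > b*dr: {(k + state.r) * state.db} > {state.b * state.dr}")

# A balanced positive deviation of both tracers (positive covariance)
# makes the heterogeneous patch grow ~11% faster than its well-mixed
# counterpart here; flip db negative and the gap changes sign.
state_anti = TwoBoxState(r=1.0, b=1.0, dr=0.5, db=-0.5)
print(f"anti-correlated gap:  {growth_gap(state_anti, nu, k):+.6f}")
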