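"""Scaled dose-response campaign: termination rate vs light intensity and
pulse length over a 5-member ensemble of spiral phases.

The full published-scale campaign (many LI x PL pairs x 25 initial
conditions) is cluster-scale; this desk-scale grid shows the monotone
surface: rates rise with both irradiance and pulse length, from 0 in the
sub-threshold row to 1 far above threshold.  Expect a few minutes runtime.
"""

from optospiral.experiments import dose_response
from optospiral.tissue import TissueParams, init_spiral, make_ensemble

params = TissueParams()
print("initiating spiral...")
base = init_spiral(params, settle_time=600.0)
ensemble = make_ensemble(base, params, n=5)
print("running 3 x 3 x 5 trials...")
table = dose_response([10.0, 40.0, 100.0], [50.0, 150.0, 500.0],
                      ensemble, params)
print(table.to_string(index=False))
print("\nrate = terminated fraction of the ensemble; sem = binomial standard error.")
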