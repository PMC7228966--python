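"""How far and how fast can one chamber of senders signal to a receiver?

Builds the channel lattice, simulates the quorum-sensing sender-receiver
circuit at several separations, and reports steady output, response times
and the distance at which the signal effectively dies out.
"""

import numpy as np

from chamberlink import circuit as cir
from chamberlink import lattice as lat

params = cir.CircuitParameters()

print("Steady receiver output (RFP) versus chamber separation")
for L in (25.0, 50.0, 100.0, 250.0):
    geom = lat.build_lattice(L, 1.0)
    ss = cir.steady_state_response(params, geom, ara=0.1)
    print(f"  {L:6.0f} um : RFP_p = {ss['RFP_p']:.2f}, "
          f"receiver AHL = {ss['AHL_receiver']:.4f}")

print("\nDistance sensitivity (25 um / 250 um steady output):"
      f" {cir.distance_sensitivity(params, ara=0.1):.2f}")

trajs = cir.simulate_step_response(params, (25.0, 250.0),
                                   cir.InputSignal("step", 0.1), t_end=3000.0)
t25 = cir.response_time(trajs[25.0].times, trajs[25.0].RFP_p, 0.0)
t250 = cir.response_time(trajs[250.0].times, trajs[250.0].RFP_p, 0.0)
print(f"\nTime to half of the steady response: {t25:.1f} min at 25 um, "
      f"{t250:.1f} min at 250 um (difference {t250 - t25:.1f} min)")

reach = cir.transmission_distance(params, ara=0.1, threshold=0.01)
print(f"\nTransmission distance (output falls to 1% of near-contact): "
      f"{reach:.0f} um")

# the AHL steady profile decays exponentially along the channel
geom = lat.build_lattice(250.0, 1.0)
ss = cir.steady_state_response(params, geom, ara=0.1)
lam = lat.fit_decay_length(geom.positions_um()[1:80], ss["AHL_profile"][1:80])
print(f"AHL decay length along a 250 um channel: {lam:.0f} um, consistent "
      f"with sqrt(D/gamma) = {np.sqrt(params.D1 / params.gamma_AHL):.0f} um "
      f"given that the channel is shorter than one decay length")
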