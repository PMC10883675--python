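"""Sweep stimulation amplitude and report the simulated response.

Reproduces the rheobase-gating behaviour: a 166 ms train (170 us, 300 Hz)
produces no effective current — hence no phosphene — at 20 uA and below.
"""
from cortiphos import DynamicsParams
from cortiphos.dynamics import brightness
from cortiphos.fitting import simulate_train_activation

dynamics = DynamicsParams()
print("amplitude -> peak tissue activation and gated brightness")
for amp in range(0, 130, 10):
    A = simulate_train_activation(amp, 170.0, 300.0, 0.166, dynamics)
    b = float(brightness(A, dynamics.theta50, dynamics.lambda_b, dynamics.A50))
    note = "silent (below rheobase + duty-cycle gate)" if A == 0 else ""
    print(f"  {amp:4d} uA : A = {A:9.3e}  brightness = {b:9.3e}  {note}")
print("\nThe largest silent amplitude on this grid is 20 uA: the rheobase")
print("current (23.9 uA) is subtracted before the duty cycle scales the rest.")
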