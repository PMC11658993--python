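"""Drive a 30 Hz oscillation from a stationary down state.

The single node at external inputs (1, 1) rests in a stable low-activity
fixed point.  The synchronization Fourier cost with a 30 Hz target
(period 33.3 time units at 1 unit = 1 ms) rewards spectral power at the
target frequency; gradient descent on the adjoint gradient finds a
periodic control that makes the node oscillate at exactly that frequency.
"""

from oscontrol.tasks import induce_oscillation

result, f_dominant, F_F_zero = induce_oscillation()

print(f"termination: {result.termination} "
      f"after {len(result.history)} iterations")
print(f"energy cost F_E           = {result.F_E:10.2f}")
print(f"Fourier cost w*F_F        = {result.final_weight * result.F_X:10.2f}"
      f"   (zero control: {result.final_weight * F_F_zero:.2e})")
print(f"dominant frequency        = {f_dominant:10.4f} cycles/unit "
      f"(target 0.03 = 30 Hz)")
print("\nThe Fourier cost improves by many orders of magnitude over the")
print("uncontrolled fixed point, and the controlled activity oscillates")
print("within one spectral bin of the target frequency.")
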