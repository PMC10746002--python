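"""Analog-circuit realization of the model.

Maps the dimensionless parameters onto op-amp integrator component values
(resistances in kOhm, capacitance in nF) and converts the dimensionless
drive frequencies into physical ones via the time-scaling factor
tau0 = 1/(R C) = 10,000 1/s.
"""

from memhr import ModelParams, map_to_circuit, component_table, scale_frequency

circ = map_to_circuit(ModelParams(k=1.0))
print(component_table(circ).to_string(index=False))

print(f"\nbase integrator: R = {circ.R:g} kOhm, C = {circ.C:g} nF "
      f"-> tau0 = {circ.tau0:g} 1/s")
for f in (0.5, 0.002, 0.02, 0.04, 0.07):
    print(f"dimensionless f = {f:6.3f}  ->  {scale_frequency(f):7.1f} Hz")

print("\nMeaning: one dimensionless time unit corresponds to 0.1 ms in the "
      "physical circuit, so the fast drive tone f1=0.5 becomes a 5 kHz "
      "source; every resistor solves one coefficient identity of the "
      "model equations.")
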