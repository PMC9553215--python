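# A compressed single-cycle session: fill to 100 µl, void to a 25% residual.
fill_rate: 400.0          # µl/min (compressed; a real pump runs ~20 µl/min)
capacity_threshold: 100.0 # µl
residual_fraction: 0.25
void_conductance: 2.0     # µl/s/cmH2O peak urethral conductance
initial_volume: 80.0      # µl at t = 0
duration: 22.0            # s
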