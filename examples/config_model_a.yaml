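# Telegraph gene with weak autoactivation, dimensional rates.
# Time is nondimensionalised by the protein decay rate p_d.
model: A
rates:
  c_f: 0.5     # gene activation rate
  c_b: 1.0     # gene deactivation rate
  p_b: 2.0     # protein production rate (active gene)
  p_d: 1.0     # protein decay rate
regulation:
  type: autoactivation
  rate: 0.05   # feedback rate a; delta = a / p_d
chi:
  mode: markov
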