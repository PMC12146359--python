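# Recovery-rate grid for the `violencedyn sweep` subcommand.
gammas: [0.0, 0.1, 0.2, 0.5, 1.0]
deltas: [0.0, 0.1, 0.3]
recovery_years: [2020, 2023]
horizon: 2034
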