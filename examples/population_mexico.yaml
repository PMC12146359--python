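# Total population of Mexico (millions) at the national census /
# intercensal-survey years, used as anchors for piecewise-linear
# interpolation of the population trajectory.  Values past the last
# anchor are linearly extrapolated (needed through 2034).
population_anchors:
  - {year: 2010, millions: 112.34}   # 2010 census: 112,336,538
  - {year: 2015, millions: 119.53}   # 2015 intercensal survey: 119,530,753
  - {year: 2020, millions: 126.01}   # 2020 census: 126,014,024
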