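# Summer surface-layer end-members for the three water-mass mixing model.
season: summer
layer: surface
members:
  - name: CDW
    season: summer
    layer: surface
    station: b1
    lon: 122.36
    lat: 30.07
    depth: 5
    T_mean: 28.26
    T_sd: 0.66
    S_mean: 27.28
    S_sd: 0.14
    NOx: 27.10
    DIP: 0.89
  - name: TSW
    season: summer
    layer: surface
    station: Y3
    lon: 119.80
    lat: 24.84
    depth: 5
    T_mean: 29.39
    T_sd: 0.05
    S_mean: 33.73
    S_sd: 0.02
    NOx: 0.23
    DIP: 0.01
  - name: KSSW
    season: summer
    layer: subsurface
    station: "376"
    lon: 126.33
    lat: 26.74
    depth: 200
    T_mean: 18.9
    T_sd: 0.1
    S_mean: 34.7
    S_sd: 0.1
    NOx: 3.69
    DIP: 0.55
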