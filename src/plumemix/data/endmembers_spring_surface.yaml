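# Spring surface-layer end-members for the three water-mass mixing model
# (CDW: Changjiang Diluted Water; TSW: Taiwan Strait Water; KSSW: Kuroshio
# Subsurface Water). T/S are mean +/- SD; nutrients in umol/L.
season: spring
layer: surface
members:
  - name: CDW
    season: spring
    layer: surface
    station: b1
    lon: 122.36
    lat: 30.07
    depth: 5
    T_mean: 17.67
    T_sd: 0.01
    S_mean: 26.85
    S_sd: 0.05
    NOx: 32.43
    DIP: 0.23
  - name: TSW
    season: spring
    layer: surface
    station: TWS3
    lon: 119.67
    lat: 25.00
    depth: 5
    T_mean: 23.05
    T_sd: 0.14
    S_mean: 34.12
    S_sd: 0.11
    NOx: 0.03
    DIP: 0.01
  - name: KSSW
    season: spring
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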