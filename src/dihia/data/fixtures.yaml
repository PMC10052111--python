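# Seed-fixed generator configurations for registry-like urinary fixtures.
#
# Synthetic stand-ins for the non-public biomonitoring registry: each entry
# was calibrated (analytic mixture reasoning plus a small randomised search
# at build time, then frozen) so that the fixture's n, quantifiable fraction
# and GM/P95 summary fall within the published sector bands.  The seeds are
# part of the fixture definition; regeneration is byte-identical.
construction:
  MDA:
    n: 48
    loq: 0.1
    seed: 2800
    background_gm: 0.0263
    background_gsd: 1.7863
    exposed_fraction: 0.6874
    exposed_gm: 0.7064
    exposed_gsd: 2.2464
  TDA:
    n: 8
    loq: 0.3
    seed: 84385
    background_gm: 0.0271
    background_gsd: 1.8962
    exposed_fraction: 0.0
    exposed_gm: 1.0
    exposed_gsd: 3.0
  HDA:
    n: 8
    loq: 0.3
    seed: 92135
    background_gm: 0.1087
    background_gsd: 2.1001
    exposed_fraction: 0.5276
    exposed_gm: 1.6314
    exposed_gsd: 5.4504
motor_vehicle:
  MDA:
    n: 54
    loq: 0.5
    seed: 43322
    background_gm: 0.184
    background_gsd: 2.2267
    exposed_fraction: 0.1004
    exposed_gm: 2.9285
    exposed_gsd: 3.2573
  TDA:
    n: 40
    loq: 0.4
    seed: 62924
    background_gm: 0.1588
    background_gsd: 1.8002
    exposed_fraction: 0.0394
    exposed_gm: 2.7141
    exposed_gsd: 5.0407
  HDA:
    n: 43
    loq: 0.5
    seed: 27173
    background_gm: 0.1256
    background_gsd: 1.702
    exposed_fraction: 0.2371
    exposed_gm: 3.0939
    exposed_gsd: 5.4242
polyurethane:
  MDA:
    n: 82
    loq: 0.5
    seed: 3361
    background_gm: 0.1229
    background_gsd: 2.2709
    exposed_fraction: 0.406
    exposed_gm: 0.5033
    exposed_gsd: 2.5577
  TDA:
    n: 70
    loq: 0.3
    seed: 135122
    background_gm: 0.0207
    background_gsd: 1.909
    exposed_fraction: 0.2842
    exposed_gm: 0.2813
    exposed_gsd: 1.202
  HDA:
    n: 35
    loq: 0.5
    seed: 81458
    background_gm: 0.0885
    background_gsd: 1.6949
    exposed_fraction: 0.2938
    exposed_gm: 0.9665
    exposed_gsd: 5.9032
assembly:
  MDA:
    n: 177
    loq: 0.3
    seed: 119176
    background_gm: 0.0533
    background_gsd: 1.5625
    exposed_fraction: 0.3268
    exposed_gm: 0.2888
    exposed_gsd: 1.8074
  TDA:
    n: 98
    loq: 0.15
    seed: 299628
    background_gm: 0.0138
    background_gsd: 1.3743
    exposed_fraction: 0.1375
    exposed_gm: 0.2462
    exposed_gsd: 2.1507
  HDA:
    n: 92
    loq: 0.4
    seed: 140433
    background_gm: 0.0675
    background_gsd: 2.3172
    exposed_fraction: 0.182
    exposed_gm: 0.6715
    exposed_gsd: 4.056
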