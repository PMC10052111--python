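# Demo pipeline configuration: reconstruct all twelve sector/metabolite
# fixtures and run the health impact assessment, with a reduced Monte Carlo
# budget so the whole chain completes in seconds.
pipeline:
  sectors:
    construction:
      MDA: {source: fixture}
    motor_vehicle:
      MDA: {source: fixture}
      HDA: {source: fixture}
    polyurethane:
      MDA: {source: fixture}
      TDA: {source: fixture}
      HDA: {source: fixture}
    assembly:
      MDA: {source: fixture}
      TDA: {source: fixture}
      HDA: {source: fixture}
  exclusions:
    - {sector: construction, analyte: TDI}
    - {sector: construction, analyte: HDI}
    - {sector: motor_vehicle, analyte: TDI}
reconstruction:
  n_mc: 2000
  mh_iterations: 300
  mh_burn_in: 100
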