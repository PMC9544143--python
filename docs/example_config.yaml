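# Example pipeline configuration. Exactly one input source: either
# `input.synthetic` (simulated experiment) or `input.file` (canonical CSV,
# optionally with a `dialect` header mapping).
input:
  synthetic:
    richness_counts: {1: 15, 4: 9, 16: 9}
    treatments: [control, insecticide, foliar_fungicide, soil_fungicide, all_pesticides]
    years: [2010, 2011, 2012, 2013, 2014]
    curve:            # double-logistic base curve (monoculture reference)
      B: 0.05         # bare-ground baseline NDVI
      A: 0.45         # seasonal amplitude
      t_g: 140        # green-up midpoint (day of year)
      g: 0.15         # green-up rate (1/day)
      t_s: 230        # senescence midpoint (day of year)
      s: 0.10         # senescence rate (1/day)
    effects: reference    # or a mapping with amplitude_mult / phenology_shift
                          # / senescence_mult / amplitude_treat_mult
    variance:
      sd_year: 0.03       # SDs of additive random intercepts on amplitude A
      sd_plot: 0.03
      sd_subplot: 0.02
      sd_resid: 0.03      # residual NDVI observation noise
    schedule:
      start_doy: 105      # biweekly April-August campaign
      end_doy: 240
      interval_days: 14
      jitter_days: 2
      miss_prob: 0.0

partition_mode: median_doy   # median_doy | median_count | peak_doy
coverage:
  min_per_half: 2            # observations required on each side of the boundary
  boundary_doy: null         # null -> per-year median observed day
responses: [indvi_total, indvi_early, indvi_late,
            greenup_slope, senescence_slope, peak_doy]
seed: 7
out_dir: greenwave-run
log_level: INFO
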