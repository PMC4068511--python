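# mmdose future v1
# dose_min_mg: 100
# dose_max_mg: 20000
# dose_step_mg: 10
record,time_h,duration_h,conc_mg_L,weight
TEMPLATE,24.0,4.0,,
TEMPLATE,32.0,4.0,,
TEMPLATE,40.0,4.0,,
TEMPLATE,48.0,4.0,,
TARGET,56.0,,41.6,
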