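# mmdose past v1
# patient_id: demo01
# crcl_ml_min: 81.0
# weight_kg: 69.0
record,time_h,duration_h,amount_mg,conc_mg_L
DOSE,0.0,0.5,4000,
DOSE,8.0,0.5,4000,
DOSE,16.0,0.5,4000,
OBS,0.5,,,120.5
OBS,6.0,,,14.8
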