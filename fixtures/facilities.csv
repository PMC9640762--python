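facility_id,district,facility_type,x,y,assessed,refers_to,running_water,decontamination_buckets,safety_boxes,soap,removal_days_per_week,n_trained_removal,n_trained_ultrasound,syringes,local_anesthetic,sterile_band_aids,scalpel_with_blade,curved_forceps,straight_forceps,antiseptic,cotton_balls,sterile_gauze,vasectomy_forceps,ultrasound_machine,sterile_towels,examination_table,sterile_surgical_drape,sterile_equipment_tray,autoclave
D01,DAKAR_CENTRE,HEALTH_CENTER_I,500.0,0.0,1,D03,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
D02,DAKAR_CENTRE,HEALTH_CENTER_I,1000.0,0.0,1,,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
D03,DAKAR_CENTRE,HEALTH_CENTER_I,1500.0,0.0,1,,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,0,1,1
D04,DAKAR_CENTRE,HEALTH_CENTER_I,2000.0,0.0,1,D03,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,0,1,1
D05,DAKAR_CENTRE,HEALTH_CENTER_I,0.0,400.0,1,D03,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,1,1,1,0,1,1
D06,DAKAR_CENTRE,HEALTH_POST,500.0,400.0,1,D03,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
D07,DAKAR_CENTRE,HEALTH_POST,1000.0,400.0,1,D03,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
D08,DAKAR_CENTRE,HEALTH_POST,1500.0,400.0,1,D03,1,1,1,1,5,1,0,1,1,1,1,1,1,1,1,1,0,0,1,1,1,1,0
D09,DAKAR_CENTRE,HEALTH_CENTER_I,2000.0,400.0,1,,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,0,0,1,1,1,1,1
D10,DAKAR_CENTRE,HEALTH_POST,0.0,800.0,1,,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,0,0,1,1,1,1,0
D11,DAKAR_CENTRE,HEALTH_POST,500.0,800.0,1,,1,1,1,1,5,1,0,0,1,0,0,0,1,1,1,1,0,0,0,1,0,1,0
D12,DAKAR_CENTRE,HEALTH_POST,1000.0,800.0,1,,1,1,1,1,5,2,0,0,1,0,0,0,1,1,1,1,0,0,0,1,0,1,0
D13,DAKAR_CENTRE,HEALTH_POST,1500.0,800.0,1,,1,1,1,1,5,2,0,1,0,1,1,1,0,1,1,1,0,0,0,1,0,1,0
K01,KOLDA,HEALTH_POST,32500.0,0.0,1,K00,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
K02,KOLDA,HEALTH_POST,35000.0,0.0,1,K00,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,0,1,1,1,0,1,1
K03,KOLDA,HEALTH_POST,37500.0,0.0,1,K00,1,1,1,1,5,2,1,1,1,1,1,1,1,1,1,1,0,1,1,1,0,1,1
K04,KOLDA,HEALTH_CENTER_II,40000.0,0.0,1,,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K05,KOLDA,HEALTH_POST,42500.0,0.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K06,KOLDA,HEALTH_POST,30000.0,2000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K07,KOLDA,HEALTH_POST,32500.0,2000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K08,KOLDA,HEALTH_POST,35000.0,2000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K09,KOLDA,HEALTH_POST,37500.0,2000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K10,KOLDA,HEALTH_POST,40000.0,2000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K11,KOLDA,HEALTH_POST,42500.0,2000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K12,KOLDA,HEALTH_POST,30000.0,4000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K13,KOLDA,HEALTH_POST,32500.0,4000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K14,KOLDA,HEALTH_POST,35000.0,4000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K15,KOLDA,HEALTH_POST,37500.0,4000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K16,KOLDA,HEALTH_POST,40000.0,4000.0,1,K04,1,1,1,1,5,2,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K17,KOLDA,HEALTH_POST,42500.0,4000.0,1,,1,1,1,1,5,1,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1
K18,KOLDA,HEALTH_POST,30000.0,6000.0,1,,1,1,1,1,5,1,0,1,1,1,1,1,1,1,1,1,0,0,1,1,0,1,0
K19,KOLDA,HEALTH_POST,32500.0,6000.0,1,K04,0,1,1,1,5,1,0,1,1,1,1,1,1,1,1,1,0,0,1,1,0,1,0
K20,KOLDA,HEALTH_POST,35000.0,6000.0,1,K04,0,1,1,1,5,1,0,1,1,1,1,1,1,1,1,1,0,0,0,1,0,1,0
K21,KOLDA,HEALTH_POST,37500.0,6000.0,1,K04,0,1,1,1,5,1,0,1,1,1,1,1,1,1,1,1,0,0,0,1,0,1,0
K22,KOLDA,HEALTH_POST,40000.0,6000.0,1,K04,1,1,1,1,5,1,0,0,1,1,0,1,1,1,1,1,0,0,0,1,0,1,0
K23,KOLDA,HEALTH_POST,42500.0,6000.0,1,K04,1,1,1,1,5,1,0,1,0,1,1,1,1,1,1,1,0,0,0,1,0,1,0
K24,KOLDA,HEALTH_POST,30000.0,8000.0,1,K04,1,1,1,1,5,1,0,1,0,1,1,1,0,1,1,1,0,0,0,1,0,1,0
K25,KOLDA,HEALTH_POST,32500.0,8000.0,1,K04,1,1,1,1,5,1,0,1,1,0,1,1,1,1,1,1,0,0,0,1,0,1,0
K26,KOLDA,HEALTH_POST,35000.0,8000.0,1,,1,1,1,1,5,1,0,1,1,1,0,1,1,1,1,1,0,0,0,1,0,1,0
K00,KOLDA,HOSPITAL,31000.0,9000.0,0,,,,,,,,,,,,,,,,,,,,,,,,
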