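{
 "general_items": [
  "running_water",
  "decontamination_buckets",
  "safety_boxes",
  "soap"
 ],
 "min_removal_days": 5,
 "min_trained_removal": 1,
 "min_trained_ultrasound": 1,
 "equipment_regular": {
  "required": [
   "syringes",
   "local_anesthetic",
   "sterile_band_aids",
   "scalpel_with_blade",
   "curved_forceps",
   "straight_forceps"
  ],
  "any_of": [
   [
    "sterile_gauze"
   ],
   [
    "antiseptic",
    "cotton_balls"
   ]
  ]
 },
 "equipment_difficult_extra": [
  "vasectomy_forceps",
  "ultrasound_machine",
  "sterile_towels",
  "examination_table",
  "sterile_surgical_drape",
  "sterile_equipment_tray"
 ]
}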