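# Laparoscopic Roux-en-Y gastric bypass (LRYGB) phase/step annotation schema.
# 12 phases, 46 steps, hierarchically structured; facultative elements may
# legitimately be absent from an individual procedure.
name: lrygb-v1
idle_label: idle
phases:
  - {id: 1, name: "Preparation", facultative: false}
  - {id: 2, name: "Gastric pouch creation", facultative: false}
  - {id: 3, name: "Omentum division", facultative: true}
  - {id: 4, name: "Gastrojejunal anastomosis", facultative: false}
  - {id: 5, name: "Anastomotic test", facultative: true}
  - {id: 6, name: "Jejunal separation", facultative: false}
  - {id: 7, name: "Petersen space closure", facultative: true}
  - {id: 8, name: "Jejunojejunal anastomosis", facultative: false}
  - {id: 9, name: "Mesenteric defect closure", facultative: true}
  - {id: 10, name: "Cleaning and coagulation", facultative: true}
  - {id: 11, name: "Disassembling", facultative: false}
  - {id: 12, name: "Other intervention", facultative: true}
steps:
  - {id: 1, name: "Trocar placement", facultative: false, parent_phase_id: 1}
  - {id: 2, name: "Abdominal cavity exploration", facultative: false, parent_phase_id: 1}
  - {id: 3, name: "Liver retractor placement", facultative: true, parent_phase_id: 1}
  - {id: 4, name: "Dissection of angle of His", facultative: false, parent_phase_id: 2}
  - {id: 5, name: "Opening of lesser omentum", facultative: false, parent_phase_id: 2}
  - {id: 6, name: "Retrogastric dissection", facultative: false, parent_phase_id: 2}
  - {id: 7, name: "Horizontal stapling of stomach", facultative: false, parent_phase_id: 2}
  - {id: 8, name: "Vertical stapling of stomach", facultative: true, parent_phase_id: 2}
  - {id: 9, name: "Gastric pouch inspection", facultative: true, parent_phase_id: 2}
  - {id: 10, name: "Omentum elevation", facultative: false, parent_phase_id: 3}
  - {id: 11, name: "Division of greater omentum", facultative: false, parent_phase_id: 3}
  - {id: 12, name: "Hemostasis of omentum", facultative: true, parent_phase_id: 3}
  - {id: 13, name: "Identification of Treitz ligament", facultative: false, parent_phase_id: 4}
  - {id: 14, name: "Measurement of biliary limb", facultative: false, parent_phase_id: 4}
  - {id: 15, name: "Gastrotomy", facultative: false, parent_phase_id: 4}
  - {id: 16, name: "Jejunotomy", facultative: false, parent_phase_id: 4}
  - {id: 17, name: "Stapled gastrojejunostomy", facultative: true, parent_phase_id: 4}
  - {id: 18, name: "Closure of gastrojejunostomy enterotomy", facultative: true, parent_phase_id: 4}
  - {id: 19, name: "Gastrojejunostomy reinforcement", facultative: true, parent_phase_id: 4}
  - {id: 20, name: "Clamping of jejunum", facultative: false, parent_phase_id: 5}
  - {id: 21, name: "Leak test with dye or air", facultative: false, parent_phase_id: 5}
  - {id: 22, name: "Suction and verification", facultative: true, parent_phase_id: 5}
  - {id: 23, name: "Mesenteric window creation", facultative: false, parent_phase_id: 6}
  - {id: 24, name: "Stapled jejunal division", facultative: false, parent_phase_id: 6}
  - {id: 25, name: "Jejunal staple line inspection", facultative: true, parent_phase_id: 6}
  - {id: 26, name: "Exposure of Petersen space", facultative: false, parent_phase_id: 7}
  - {id: 27, name: "Suture closure of Petersen space", facultative: true, parent_phase_id: 7}
  - {id: 28, name: "Measurement of alimentary limb", facultative: false, parent_phase_id: 8}
  - {id: 29, name: "Alignment of jejunal limbs", facultative: false, parent_phase_id: 8}
  - {id: 30, name: "Enterotomy of biliary limb", facultative: false, parent_phase_id: 8}
  - {id: 31, name: "Enterotomy of alimentary limb", facultative: false, parent_phase_id: 8}
  - {id: 32, name: "Stapled jejunojejunostomy", facultative: true, parent_phase_id: 8}
  - {id: 33, name: "Closure of jejunojejunostomy enterotomy", facultative: true, parent_phase_id: 8}
  - {id: 34, name: "Jejunojejunostomy inspection", facultative: true, parent_phase_id: 8}
  - {id: 35, name: "Exposure of mesenteric defect", facultative: false, parent_phase_id: 9}
  - {id: 36, name: "Suture closure of mesenteric defect", facultative: true, parent_phase_id: 9}
  - {id: 37, name: "Irrigation of abdominal cavity", facultative: false, parent_phase_id: 10}
  - {id: 38, name: "Hemostasis verification", facultative: false, parent_phase_id: 10}
  - {id: 39, name: "Suction of fluids", facultative: true, parent_phase_id: 10}
  - {id: 40, name: "Liver retractor removal", facultative: false, parent_phase_id: 11}
  - {id: 41, name: "Trocar removal", facultative: false, parent_phase_id: 11}
  - {id: 42, name: "Fascia closure", facultative: true, parent_phase_id: 11}
  - {id: 43, name: "Adhesiolysis", facultative: false, parent_phase_id: 12}
  - {id: 44, name: "Hiatal hernia repair", facultative: false, parent_phase_id: 12}
  - {id: 45, name: "Concurrent cholecystectomy", facultative: true, parent_phase_id: 12}
  - {id: 46, name: "Other unlisted action", facultative: true, parent_phase_id: 12}
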