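{
  "language": "neutral",
  "filler": [
    "Patient remained stable on a regular diet.",
    "Vitals were within normal limits throughout the day.",
    "Physiotherapy session completed without incident.",
    "Renal function panel unremarkable this morning.",
    "Patient mobilized in the corridor with assistance.",
    "Discharge planning discussed with the family.",
    "Blood pressure controlled on current regimen.",
    "Appetite improving and sleep adequate."
  ],
  "negation": [
    "No bleeding observed during the stay.",
    "No hemorrhage reported on examination.",
    "Stools negative for occult blood.",
    "No sign of bleeding at the puncture site."
  ],
  "active_mb": [
    "Massive hemorrhage with hemodynamic shock requiring urgent resuscitation.",
    "Major gastrointestinal bleed with exsanguination risk and emergency transfusion.",
    "Severe intracranial hemorrhage confirmed on imaging with rapid deterioration.",
    "Profuse hematemesis with hypotension needing massive transfusion protocol.",
    "Life threatening retroperitoneal hemorrhage with hemoglobin collapse.",
    "Catastrophic bleed into the thorax requiring immediate surgical control."
  ],
  "active_crnmb": [
    "Mild epistaxis controlled with local compression.",
    "Minor bleeding from the gum margins noted overnight.",
    "Small subcutaneous hematoma at the injection site.",
    "Moderate hematuria without hemodynamic compromise.",
    "Limited rectal bleeding settled spontaneously.",
    "Slight oozing from the wound edge dressed once."
  ],
  "antecedent": [
    "History of bleeding episode one year before admission.",
    "Prior hemorrhage documented in the previous hospitalization.",
    "Past melena reported several months ago.",
    "Known previous ulcer bleed treated endoscopically in the past.",
    "Old intracranial bleed noted in the antecedents."
  ]
}
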