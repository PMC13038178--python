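{
  "name": "QLQ-C30",
  "version": "3.0",
  "description": "EORTC QLQ-C30 v3.0: 30 items, 15 scales (5 functional, 3 multi-item symptom, 6 single-item symptom, 1 global health). Items 1-28 scored 1-4, items 29-30 scored 1-7. Linear transform to 0-100 per the EORTC scoring manual.",
  "items": {
    "q1": [1, 4], "q2": [1, 4], "q3": [1, 4], "q4": [1, 4], "q5": [1, 4],
    "q6": [1, 4], "q7": [1, 4], "q8": [1, 4], "q9": [1, 4], "q10": [1, 4],
    "q11": [1, 4], "q12": [1, 4], "q13": [1, 4], "q14": [1, 4], "q15": [1, 4],
    "q16": [1, 4], "q17": [1, 4], "q18": [1, 4], "q19": [1, 4], "q20": [1, 4],
    "q21": [1, 4], "q22": [1, 4], "q23": [1, 4], "q24": [1, 4], "q25": [1, 4],
    "q26": [1, 4], "q27": [1, 4], "q28": [1, 4], "q29": [1, 7], "q30": [1, 7]
  },
  "scales": [
    {"name": "physical_functioning", "direction": "functional", "items": ["q1", "q2", "q3", "q4", "q5"], "range": 3},
    {"name": "role_functioning", "direction": "functional", "items": ["q6", "q7"], "range": 3},
    {"name": "emotional_functioning", "direction": "functional", "items": ["q21", "q22", "q23", "q24"], "range": 3},
    {"name": "cognitive_functioning", "direction": "functional", "items": ["q20", "q25"], "range": 3},
    {"name": "social_functioning", "direction": "functional", "items": ["q26", "q27"], "range": 3},
    {"name": "global_health", "direction": "global", "items": ["q29", "q30"], "range": 6},
    {"name": "fatigue", "direction": "symptom", "items": ["q10", "q12", "q18"], "range": 3},
    {"name": "nausea_vomiting", "direction": "symptom", "items": ["q14", "q15"], "range": 3},
    {"name": "pain", "direction": "symptom", "items": ["q9", "q19"], "range": 3},
    {"name": "dyspnoea", "direction": "symptom", "items": ["q8"], "range": 3},
    {"name": "insomnia", "direction": "symptom", "items": ["q11"], "range": 3},
    {"name": "appetite_loss", "direction": "symptom", "items": ["q13"], "range": 3},
    {"name": "constipation", "direction": "symptom", "items": ["q16"], "range": 3},
    {"name": "diarrhoea", "direction": "symptom", "items": ["q17"], "range": 3},
    {"name": "financial_difficulties", "direction": "symptom", "items": ["q28"], "range": 3}
  ]
}
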