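{
  "name": "NQ-2021",
  "description": "Nutrition Quotient for Adults (2021 revision), 18 checklist items in three domains: Balance (intake frequency of recommended food groups), Moderation (frequency of unhealthy foods and eating behaviours, reverse-keyed), Practice (healthy eating habits). Domain scores and the weighted total are standardized to 0-100. The item-to-domain allocation here is a synthetic stand-in with the published domain structure (18 items / 3 domains); the official Korean Nutrition Society item map and weights are licensed separately and are not bundled.",
  "items": {
    "nq01": {"range": [1, 5], "reverse": false},
    "nq02": {"range": [1, 5], "reverse": false},
    "nq03": {"range": [1, 5], "reverse": false},
    "nq04": {"range": [1, 5], "reverse": false},
    "nq05": {"range": [1, 5], "reverse": false},
    "nq06": {"range": [1, 5], "reverse": false},
    "nq07": {"range": [1, 5], "reverse": false},
    "nq08": {"range": [1, 5], "reverse": false},
    "nq09": {"range": [1, 5], "reverse": true},
    "nq10": {"range": [1, 5], "reverse": true},
    "nq11": {"range": [1, 5], "reverse": true},
    "nq12": {"range": [1, 5], "reverse": true},
    "nq13": {"range": [1, 5], "reverse": true},
    "nq14": {"range": [1, 5], "reverse": true},
    "nq15": {"range": [1, 5], "reverse": false},
    "nq16": {"range": [1, 5], "reverse": false},
    "nq17": {"range": [1, 5], "reverse": false},
    "nq18": {"range": [1, 5], "reverse": false}
  },
  "domains": {
    "balance": ["nq01", "nq02", "nq03", "nq04", "nq05", "nq06", "nq07", "nq08"],
    "moderation": ["nq09", "nq10", "nq11", "nq12", "nq13", "nq14"],
    "practice": ["nq15", "nq16", "nq17", "nq18"]
  },
  "total_scale": "nutritional_score",
  "aliases": {"implementation": "practice"}
}
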