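{
  "description": "Default equal-weight configuration for NQ-2021 scoring. This is a synthetic stand-in: the official Korean Nutrition Society weighting algorithm is not publicly bundled, so all item and domain weights default to 1.0. Scores produced with this file are internally consistent but not comparable to published NQ-2021 norms.",
  "item_weights": {
    "nq01": 1.0, "nq02": 1.0, "nq03": 1.0, "nq04": 1.0, "nq05": 1.0,
    "nq06": 1.0, "nq07": 1.0, "nq08": 1.0, "nq09": 1.0, "nq10": 1.0,
    "nq11": 1.0, "nq12": 1.0, "nq13": 1.0, "nq14": 1.0, "nq15": 1.0,
    "nq16": 1.0, "nq17": 1.0, "nq18": 1.0
  },
  "domain_weights": {"balance": 1.0, "moderation": 1.0, "practice": 1.0}
}
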