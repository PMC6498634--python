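{
  "description": "Published summary counts for the Lazio region ED aggression cohort (2003-2015): women who sought at least one ED visit for aggression, stratified by presence of a violence diagnosis in the ED history (WVV = women victims of violence). Demographic blocks count women; arrival/outcome/triage blocks count ED visits.",
  "cohort": {"n_women": 124691, "n_wvv": 580, "n_visits_wvv": 4062, "n_visits_other": 396307},
  "women": {
    "age_group": {
      "15-24": {"wvv": 153, "other": 18296},
      "25-34": {"wvv": 192, "other": 31877},
      "35-54": {"wvv": 214, "other": 59194},
      "55-70": {"wvv": 21, "other": 14744}
    },
    "nationality": {
      "italian": {"wvv": 316, "other": 62063},
      "foreign": {"wvv": 263, "other": 27796},
      "missing": {"wvv": 1, "other": 34252}
    },
    "residence": {
      "metro_rome": {"wvv": 361, "other": 64396},
      "outside": {"wvv": 219, "other": 59715}
    },
    "repeated_aggression": {
      "no": {"wvv": 385, "other": 104129},
      "yes": {"wvv": 195, "other": 19984}
    },
    "repeated_other_trauma": {
      "no": {"wvv": 95, "other": 100570},
      "yes": {"wvv": 485, "other": 23543}
    }
  },
  "visits": {
    "arrival": {
      "ambulance": {"wvv": 1228, "other": 60323},
      "self": {"wvv": 2689, "other": 331290},
      "helicopter": {"wvv": 39, "other": 1343},
      "other": {"wvv": 106, "other": 3104}
    },
    "outcome": {
      "admitted": {"wvv": 419, "other": 33526},
      "refused_admission": {"wvv": 369, "other": 26700},
      "left_without_visit": {"wvv": 610, "other": 30378},
      "death": {"wvv": 0, "other": 83},
      "other": {"wvv": 2664, "other": 305620}
    },
    "triage": {
      "red": {"wvv": 147, "other": 1587},
      "yellow": {"wvv": 851, "other": 35488},
      "green": {"wvv": 2737, "other": 307561},
      "white": {"wvv": 299, "other": 48259},
      "missing": {"wvv": 28, "other": 3370},
      "not_executed": {"wvv": 0, "other": 42}
    }
  }
}
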