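[
  {
    "rule_id": "after_school",
    "kind": "schedule",
    "predicate": {
      "days": ["monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday"],
      "start": "17:00",
      "end": "18:00"
    },
    "goal_variables": [{"variable": "physical_activity", "direction": "increase"}],
    "refractory_minutes": 60
  },
  {
    "rule_id": "weekend_morning",
    "kind": "schedule",
    "predicate": {"days": ["saturday", "sunday"], "start": "10:00", "end": "11:00"},
    "goal_variables": [{"variable": "physical_activity", "direction": "increase"}],
    "refractory_minutes": 60
  }
]
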