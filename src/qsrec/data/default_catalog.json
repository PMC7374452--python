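{
  "variables": {
    "age": "number",
    "sedentary_minutes": "number",
    "location_category": "string",
    "diet_tier": "string",
    "physical_activity": "number",
    "nutrition_knowledge": "number",
    "motivation": "number"
  },
  "actions": [
    {
      "action_id": "active_game_session",
      "category": "active_game",
      "preconditions": [],
      "goals": [{"variable": "physical_activity", "operation": "increase", "value": 20}],
      "content": {"title": "Play an exergame session", "duration_min": 20}
    },
    {
      "action_id": "healthy_restaurant_tip",
      "category": "nutrition_education",
      "preconditions": [
        {"variable": "location_category", "comparator": "in_set", "value": ["restaurant", "home"]}
      ],
      "goals": [{"variable": "nutrition_knowledge", "operation": "increase", "value": 1}],
      "content": {"title": "Healthy food restaurants and meals nearby"}
    },
    {
      "action_id": "outdoor_play",
      "category": "physical_activity",
      "preconditions": [],
      "goals": [{"variable": "physical_activity", "operation": "increase", "value": 25}],
      "content": {"title": "Healthy locations: play outside"}
    },
    {
      "action_id": "pirate_mission_reminder",
      "category": "motivation",
      "preconditions": [],
      "goals": [{"variable": "motivation", "operation": "increase", "value": 1}],
      "content": {"title": "A new pirate mission awaits!"}
    },
    {
      "action_id": "walk_to_park",
      "category": "physical_activity",
      "preconditions": [
        {"variable": "sedentary_minutes", "comparator": "ge", "value": 30}
      ],
      "goals": [{"variable": "physical_activity", "operation": "increase", "value": 30}],
      "content": {"title": "Physical activities: walk to the park"}
    }
  ]
}
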