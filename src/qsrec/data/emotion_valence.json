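{
  "joy": "positive",
  "happiness": "positive",
  "fun": "positive",
  "tranquility": "positive",
  "surprise": "neutral",
  "boredom": "negative",
  "sadness": "negative",
  "anger": "negative",
  "fear": "negative",
  "nervousness": "negative"
}
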