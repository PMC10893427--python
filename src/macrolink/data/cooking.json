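{
  "classes": [
    "take",
    "wash",
    "cut",
    "put",
    "mix",
    "open",
    "pour",
    "peel"
  ],
  "sequences": [
    [
      "take",
      "wash",
      "cut",
      "put",
      "take",
      "cut",
      "put",
      "open",
      "pour",
      "mix",
      "put"
    ],
    [
      "take",
      "wash",
      "cut",
      "put",
      "take",
      "peel",
      "cut",
      "put",
      "open",
      "mix",
      "put"
    ],
    [
      "take",
      "wash",
      "cut",
      "put",
      "open",
      "take",
      "cut",
      "put",
      "pour",
      "mix",
      "put"
    ],
    [
      "take",
      "open",
      "pour",
      "take",
      "peel",
      "cut",
      "put",
      "pour",
      "mix"
    ],
    [
      "take",
      "open",
      "pour",
      "open",
      "pour",
      "take",
      "cut",
      "put",
      "mix"
    ],
    [
      "take",
      "open",
      "pour",
      "take",
      "wash",
      "cut",
      "put",
      "pour",
      "mix"
    ],
    [
      "take",
      "wash",
      "peel",
      "cut",
      "put",
      "take",
      "wash",
      "cut",
      "put",
      "take",
      "peel",
      "cut",
      "put",
      "mix"
    ]
  ]
}
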