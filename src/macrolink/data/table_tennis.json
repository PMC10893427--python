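{
  "classes": [
    "drive_fh",
    "drive_bh",
    "loop_fh",
    "loop_bh",
    "block_fh",
    "block_bh",
    "push_fh",
    "push_bh"
  ],
  "sequences": [
    [
      "drive_fh"
    ],
    [
      "drive_bh"
    ],
    [
      "loop_fh"
    ],
    [
      "loop_bh"
    ],
    [
      "block_fh"
    ],
    [
      "block_bh"
    ],
    [
      "push_fh"
    ],
    [
      "push_bh"
    ],
    [
      "loop_bh",
      "loop_fh"
    ],
    [
      "loop_fh",
      "loop_bh",
      "loop_fh"
    ],
    [
      "push_bh",
      "block_fh",
      "loop_bh",
      "block_bh"
    ],
    [
      "drive_bh",
      "drive_fh",
      "loop_bh",
      "block_fh",
      "block_bh"
    ],
    [
      "loop_bh",
      "push_fh",
      "block_bh",
      "loop_fh",
      "loop_bh",
      "block_fh"
    ],
    [
      "drive_bh",
      "drive_fh",
      "push_bh",
      "loop_fh",
      "drive_bh",
      "drive_bh",
      "loop_fh"
    ],
    [
      "loop_fh",
      "push_bh",
      "loop_fh",
      "block_bh",
      "block_fh",
      "drive_bh",
      "drive_fh",
      "loop_bh"
    ],
    [
      "drive_bh",
      "loop_fh",
      "drive_bh",
      "push_bh",
      "drive_fh",
      "loop_bh",
      "push_fh",
      "block_bh",
      "drive_fh"
    ],
    [
      "push_bh",
      "drive_fh",
      "block_bh",
      "loop_fh",
      "block_bh",
      "drive_fh",
      "drive_bh",
      "push_fh",
      "drive_fh",
      "push_bh"
    ],
    [
      "push_bh",
      "drive_fh"
    ],
    [
      "push_fh",
      "drive_bh",
      "drive_fh"
    ],
    [
      "block_fh",
      "block_bh",
      "loop_fh",
      "drive_fh"
    ],
    [
      "push_bh",
      "push_fh",
      "block_bh",
      "drive_fh",
      "drive_bh"
    ],
    [
      "drive_fh",
      "loop_bh",
      "loop_fh",
      "push_bh",
      "push_fh",
      "loop_fh"
    ],
    [
      "block_fh",
      "block_bh",
      "drive_bh",
      "drive_fh",
      "block_bh",
      "block_fh",
      "drive_bh"
    ],
    [
      "loop_bh",
      "drive_fh",
      "loop_bh",
      "drive_fh",
      "loop_bh",
      "drive_fh",
      "drive_bh",
      "push_fh"
    ],
    [
      "loop_bh",
      "push_fh",
      "loop_bh",
      "drive_fh",
      "push_bh",
      "block_fh",
      "block_bh",
      "loop_bh",
      "push_fh"
    ],
    [
      "loop_bh",
      "push_fh",
      "loop_bh",
      "block_bh",
      "loop_fh",
      "block_fh",
      "push_bh",
      "drive_fh",
      "block_bh",
      "drive_fh"
    ],
    [
      "push_fh",
      "block_bh"
    ],
    [
      "push_bh",
      "drive_fh",
      "block_bh"
    ],
    [
      "loop_bh",
      "block_fh",
      "drive_bh",
      "push_fh"
    ],
    [
      "drive_fh",
      "push_bh",
      "loop_fh",
      "loop_bh",
      "drive_fh"
    ],
    [
      "drive_bh",
      "block_fh",
      "block_bh",
      "drive_fh",
      "push_bh",
      "push_fh"
    ],
    [
      "block_fh",
      "push_bh",
      "drive_fh",
      "drive_bh",
      "drive_fh",
      "loop_bh",
      "loop_fh"
    ],
    [
      "push_bh",
      "drive_fh",
      "push_bh",
      "push_fh",
      "push_bh",
      "push_fh",
      "drive_bh",
      "block_fh"
    ],
    [
      "loop_fh",
      "drive_bh",
      "push_fh",
      "drive_bh",
      "loop_fh",
      "loop_bh",
      "push_fh",
      "loop_bh",
      "loop_fh"
    ],
    [
      "drive_bh",
      "drive_fh",
      "block_fh",
      "push_bh",
      "loop_fh",
      "block_bh",
      "drive_fh",
      "loop_bh",
      "push_bh",
      "push_fh"
    ],
    [
      "block_bh",
      "loop_fh"
    ],
    [
      "loop_fh",
      "drive_fh",
      "loop_bh"
    ],
    [
      "push_fh",
      "loop_bh",
      "push_fh",
      "block_bh"
    ],
    [
      "push_fh",
      "loop_bh",
      "drive_fh",
      "drive_bh",
      "drive_bh"
    ],
    [
      "push_bh",
      "drive_bh",
      "block_fh",
      "push_fh",
      "push_bh",
      "block_fh"
    ],
    [
      "drive_bh",
      "drive_fh",
      "loop_bh",
      "loop_fh",
      "loop_bh",
      "push_bh",
      "block_fh"
    ],
    [
      "push_bh",
      "drive_fh",
      "push_bh",
      "block_fh",
      "drive_bh",
      "block_fh",
      "drive_bh",
      "block_fh"
    ],
    [
      "push_bh",
      "loop_fh",
      "loop_bh",
      "drive_fh",
      "block_bh",
      "block_fh",
      "drive_fh",
      "loop_bh",
      "drive_bh"
    ],
    [
      "drive_bh",
      "block_fh",
      "push_bh",
      "block_fh",
      "push_bh",
      "block_fh",
      "loop_bh",
      "block_fh",
      "loop_bh",
      "loop_fh"
    ],
    [
      "drive_bh",
      "block_bh"
    ],
    [
      "block_fh",
      "push_bh",
      "block_fh"
    ],
    [
      "drive_bh",
      "drive_fh",
      "loop_bh",
      "push_fh"
    ],
    [
      "push_fh",
      "drive_bh",
      "loop_fh",
      "drive_bh",
      "block_fh"
    ],
    [
      "drive_bh",
      "block_fh",
      "loop_bh",
      "loop_fh",
      "push_fh",
      "drive_bh"
    ],
    [
      "block_fh",
      "block_bh",
      "loop_fh",
      "drive_bh",
      "push_bh",
      "block_fh",
      "drive_bh"
    ],
    [
      "block_bh",
      "loop_bh",
      "loop_fh",
      "loop_fh",
      "block_bh",
      "loop_fh",
      "push_bh",
      "block_bh"
    ],
    [
      "drive_fh",
      "push_bh",
      "loop_bh",
      "drive_fh",
      "loop_bh",
      "block_fh",
      "push_bh",
      "block_fh",
      "block_bh"
    ],
    [
      "loop_fh",
      "drive_bh",
      "loop_bh",
      "block_fh",
      "push_bh",
      "drive_fh",
      "block_bh",
      "loop_fh",
      "push_fh",
      "block_bh"
    ],
    [
      "loop_fh",
      "loop_bh"
    ],
    [
      "drive_bh",
      "push_fh",
      "loop_bh"
    ]
  ]
}
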